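"""Copy-number population statistics.

V_ST is the copy-number analogue of F_ST: the fraction of total
copy-number variance explained by between-population differences,
(V_T − V_S)/V_T, where V_S is the size-weighted mean within-population
variance. Both variances use the population (divide-by-n) estimator —
using the same estimator on both sides is what bounds V_ST ≤ 1.

The module also provides a label-permutation differentiation test, a
latitude regression with genome-wide principal components as covariates
(to separate clinal selection signals from population structure), an
empirical null built from correlations at random background loci, and
the donor/acceptor reciprocal-correlation check used to support
interlocus gene conversion between paralogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .nulls import bonferroni

logger = logging.getLogger(__name__)

__all__ = [
    "CNMatrix",
    "VstResult",
    "PopulationCovariates",
    "vst",
    "cn_differentiation_test",
    "latitude_regression",
    "genomic_shuffle_null",
    "donor_acceptor_correlation",
]


@dataclass
class CNMatrix:
    """Diploid copy-number estimates, samples × loci."""

    values: np.ndarray
    samples: np.ndarray
    populations: np.ndarray
    loci: list  # (chrom, start, end) 1-based inclusive, as reported

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.samples = np.asarray(self.samples, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if np.any(self.values < 0):
            raise ValueError("copy-number values must be non-negative")
        n, m = self.values.shape
        if self.samples.shape != (n,) or self.populations.shape != (n,):
            raise ValueError("sample and population labels must match row count")
        if len(self.loci) != m:
            raise ValueError("one locus definition per column required")

    def locus_values(self, locus):
        return self.values[:, self._locus_index(locus)]

    def _locus_index(self, locus):
        if isinstance(locus, (int, np.integer)):
            return int(locus)
        for i, loc in enumerate(self.loci):
            if loc == locus or loc[0] == locus:
                return i
        raise KeyError(f"unknown locus {locus!r}")

    @classmethod
    def from_tsv(cls, path):
        """Read a TSV with columns: sample, population, one column per locus."""
        df = pd.read_csv(path, sep="\t")
        loci = [(c, 0, 0) if ":" not in c else _parse_locus(c)
                for c in df.columns[2:]]
        return cls(df.iloc[:, 2:].to_numpy(float), df.iloc[:, 0].to_numpy(object),
                   df.iloc[:, 1].to_numpy(object), loci)

    def to_tsv(self, path):
        cols = {loc[0] if loc[1] == 0 else f"{loc[0]}:{loc[1]}-{loc[2]}": self.values[:, i]
                for i, loc in enumerate(self.loci)}
        pd.DataFrame({"sample": self.samples, "population": self.populations, **cols}
                     ).to_csv(path, sep="\t", index=False)


def _parse_locus(label):
    chrom, span = label.split(":")
    a, b = span.replace(",", "").split("-")
    return (chrom, int(a), int(b))


@dataclass
class VstResult:
    locus: object
    pop_a: str
    pop_b: str
    v_total: float
    v_within: float
    v_st: float
    p: float | None = None
    p_bonferroni: float | None = None


@dataclass
class PopulationCovariates:
    """Latitude per sample plus genome-wide principal components.

    ``latitude`` is in degrees; with ``use_absolute`` (default, matching
    the usual clinal analysis) the absolute value enters the regression.
    PCs are centered per component.
    """

    latitude: np.ndarray
    pcs: np.ndarray
    use_absolute: bool = True

    def __post_init__(self):
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.pcs = np.atleast_2d(np.asarray(self.pcs, dtype=float))
        if self.pcs.shape[0] != self.latitude.shape[0]:
            raise ValueError("latitude and PCs must cover the same samples")
        if self.pcs.shape[1] and np.abs(self.pcs.mean(axis=0)).max() > 1e-6 * max(
                1.0, np.abs(self.pcs).max()):
            self.pcs = self.pcs - self.pcs.mean(axis=0)

    @property
    def effective_latitude(self):
        return np.abs(self.latitude) if self.use_absolute else self.latitude


def _vst_value(values, labels, pop_a, pop_b):
    x = values[labels == pop_a]
    y = values[labels == pop_b]
    pooled = np.concatenate([x, y])
    v_t = float(np.var(pooled))  # population (divide-by-n) variance throughout
    v_s = float((len(x) * np.var(x) + len(y) * np.var(y)) / (len(x) + len(y)))
    v_st = 0.0 if v_t == 0 else (v_t - v_s) / v_t
    return v_t, v_s, float(v_st)


def vst(cn: CNMatrix, locus, pop_a, pop_b):
    """V_ST between two populations at one locus."""
    values = cn.locus_values(locus)
    for pop in (pop_a, pop_b):
        if (cn.populations == pop).sum() < 2:
            raise ValueError(f"population {pop}: need >= 2 samples for V_ST")
    v_t, v_s, v_st = _vst_value(values, cn.populations, pop_a, pop_b)
    return VstResult(locus, pop_a, pop_b, v_t, v_s, v_st)


def cn_differentiation_test(cn: CNMatrix, locus, pop_a, pop_b, n_perm=10000,
                            seed=0, n_tests=1):
    """Label-permutation test of copy-number differentiation on V_ST.

    p is the add-one fraction of label permutations whose V_ST is at
    least the observed value.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if n_perm < 100:
        logger.warning("n_perm=%d gives very coarse p-values", n_perm)
    result = vst(cn, locus, pop_a, pop_b)
    mask = np.isin(cn.populations, [pop_a, pop_b])
    values = cn.locus_values(locus)[mask]
    labels = cn.populations[mask].copy()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _vst_value(values, perm, pop_a, pop_b)[2] >= result.v_st:
            hits += 1
    result.p = (1 + hits) / (n_perm + 1)
    result.p_bonferroni = bonferroni(result.p, n_tests)
    return result


def latitude_regression(cn_values, covariates: PopulationCovariates, n_pcs=10):
    """Copy number ~ latitude + Σ PC_i, with the unadjusted correlation.

    Returns a dict with the raw Pearson R and p, the latitude
    coefficient from the PC-adjusted least-squares fit, and its t-test
    p-value. With ``n_pcs = 0`` the fit reduces exactly to simple linear
    regression.
    """
    y = np.asarray(cn_values, dtype=float)
    lat = covariates.effective_latitude
    if y.shape[0] != lat.shape[0]:
        raise ValueError("copy numbers and covariates must cover the same samples")
    if n_pcs > covariates.pcs.shape[1]:
        raise ValueError(f"requested {n_pcs} PCs but only "
                         f"{covariates.pcs.shape[1]} available")
    if y.shape[0] < n_pcs + 3:
        raise ValueError("need at least n_pcs + 3 observations")
    raw_r, raw_p = stats.pearsonr(lat, y)
    design = np.column_stack([lat] + [covariates.pcs[:, i] for i in range(n_pcs)])
    names = ["latitude"] + [f"PC{i+1}" for i in range(n_pcs)]
    # incremental rank check names the first collinear column
    X = sm.add_constant(design)
    rank = 1
    for j in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 2])
        if new_rank == rank:
            raise ValueError(f"collinear covariate: {names[j]}")
        rank = new_rank
    fit = sm.OLS(y, X).fit()
    return {
        "raw_r": float(raw_r),
        "raw_p": float(raw_p),
        "adjusted_coef": float(fit.params[1]),
        "adjusted_p": float(fit.pvalues[1]),
        "adjusted_se": float(fit.bse[1]),
        "n": int(y.shape[0]),
        "n_pcs": int(n_pcs),
    }


def genomic_shuffle_null(target_correlation, background_correlations):
    """Empirical p for a latitude correlation against random background loci.

    p is the add-one fraction of background loci with |R| at least the
    target's |R| — the genomic-shuffling control for how often clinal
    correlations of this strength arise by demography alone.
    """
    bg = np.asarray(background_correlations, dtype=float)
    bg = bg[np.isfinite(bg)]
    if bg.size == 0:
        raise ValueError("empty background correlation set")
    if bg.size < 100:
        logger.warning("background has only %d loci; p resolution is coarse",
                       bg.size)
    hits = int((np.abs(bg) >= abs(target_correlation)).sum())
    return float((1 + hits) / (bg.size + 1))


def donor_acceptor_correlation(cn: CNMatrix, donor_locus, acceptor_locus,
                               by_population=False):
    """Pearson correlation of donor vs acceptor paralog copy number.

    A gene-conversion event copying the donor over the acceptor changes
    the two paralog-specific copy numbers reciprocally, so segregating
    IGC alleles produce a negative correlation across samples.
    """
    x = cn.locus_values(donor_locus)
    y = cn.locus_values(acceptor_locus)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero copy-number variance at donor or acceptor locus")
    r, p = stats.pearsonr(x, y)
    out = {"r": float(r), "p": float(p), "n": int(len(x))}
    if by_population:
        per = {}
        for pop in np.unique(cn.populations):
            m = cn.populations == pop
            if m.sum() >= 3 and np.var(x[m]) > 0 and np.var(y[m]) > 0:
                rr, pp = stats.pearsonr(x[m], y[m])
                per[str(pop)] = {"r": float(rr), "p": float(pp), "n": int(m.sum())}
        out["per_population"] = per
    return out
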