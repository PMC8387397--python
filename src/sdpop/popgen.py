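"""Site-frequency, LD and TMRCA statistics on polarized haplotype matrices.

The central container is :class:`HaplotypeMatrix`: a binary matrix of
haplotypes × segregating sites in which 0 denotes the ancestral allele
(assigned from an outgroup such as chimpanzee) and 1 the derived allele.
All frequency-spectrum statistics (Tajima's D, Fay & Wu's H, θ_π, θ_W,
θ_H) are computed per genomic window from the derived-allele count
spectrum; Fay & Wu's H and Thomson's TMRCA estimator are only meaningful
on polarized data and refuse unpolarized input.

Coordinates are 0-based half-open internally; ``positions`` are 1-based
bp as in VCF. Conversion from the 1-based inclusive convention used in
reports happens at the I/O layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel in haplotype matrices

__all__ = [
    "HaplotypeMatrix",
    "WindowStatRecord",
    "LDRecord",
    "ThomsonResult",
    "window_partition",
    "sfs",
    "tajima_d",
    "fay_wu_h",
    "theta_pi",
    "theta_w",
    "theta_h",
    "windowed_stats",
    "thomson_tmrca",
    "ld_pair",
    "maf_filter",
    "find_tagging_snvs",
    "derived_allele_bootstrap",
]


@dataclass
class HaplotypeMatrix:
    """Binary derived-allele matrix (haplotypes × sites).

    Parameters
    ----------
    data
        int8 array of shape (n_haplotypes, n_sites); 0 = ancestral,
        1 = derived, -1 = missing call.
    positions
        1-based bp coordinate per site, strictly increasing.
    chrom
        Chromosome / contig label shared by all sites.
    populations
        Population label per haplotype.
    polarized
        True when 0/1 encode ancestral/derived via an outgroup. Several
        statistics (Fay & Wu's H, Thomson's TMRCA, the SFS) require this.
    """

    data: np.ndarray
    positions: np.ndarray
    chrom: str = "chr1"
    populations: np.ndarray | None = None
    polarized: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("haplotype data must be 2-D (haplotypes × sites)")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (self.data.shape[1],):
            raise ValueError("positions length must equal number of sites")
        if self.data.shape[1] and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.data, (MISSING, 0, 1)).all():
            raise ValueError("haplotype entries must be 0, 1 or -1 (missing)")
        if self.data.shape[1] and (self.data != MISSING).sum(axis=0).min() < 1:
            raise ValueError("every site must have at least one observed allele")
        if self.populations is None:
            self.populations = np.array(["pop0"] * self.data.shape[0], dtype=object)
        else:
            self.populations = np.asarray(self.populations, dtype=object)
            if self.populations.shape != (self.data.shape[0],):
                raise ValueError("one population label per haplotype required")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.data[:, idx],
            self.positions[idx],
            chrom=self.chrom,
            populations=self.populations,
            polarized=self.polarized,
        )

    def subset_populations(self, names) -> "HaplotypeMatrix":
        mask = np.isin(self.populations, list(names))
        return HaplotypeMatrix(
            self.data[mask],
            self.positions,
            chrom=self.chrom,
            populations=self.populations[mask],
            polarized=self.polarized,
        )


@dataclass
class WindowStatRecord:
    """Per-window summary statistics; NaN marks undefined statistics."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    n: int
    segregating_sites: int
    pi: float
    theta_w: float
    theta_h: float
    tajima_d: float
    faywu_h: float


@dataclass
class LDRecord:
    pos_a: int
    pos_b: int
    d: float
    d_prime: float
    r2: float
    maf_a: float
    maf_b: float


@dataclass
class ThomsonResult:
    """Thomson TMRCA estimate: mean derived-mutation load over μ·L."""

    tmrca_generations: float
    tmrca_years: float | None
    derived_counts: np.ndarray = field(repr=False)
    mu_times_length: float = 0.0


# ---------------------------------------------------------------------------
# windows


def window_partition(regions, window_size):
    """Tile half-open regions into non-overlapping windows.

    A terminal partial window is kept on its own iff it spans at least
    half the window size; otherwise it is merged into the previous
    window (or kept alone when the region is shorter than one window).

    Parameters
    ----------
    regions : list of (chrom, start, end)
        Non-overlapping 0-based half-open intervals.
    window_size : int
        Window span in bp.

    Returns
    -------
    list of (chrom, start, end)
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows = []
    for chrom, start, end in regions:
        if end <= start:
            raise ValueError(f"empty region {chrom}:{start}-{end}")
        span = end - start
        n_full, rem = divmod(span, window_size)
        edges = [start + i * window_size for i in range(n_full + 1)]
        if rem == 0:
            pass
        elif rem >= window_size / 2 or n_full == 0:
            edges.append(end)  # partial window stands alone
        else:
            edges[-1] = end  # merge remainder into the last full window
        windows.extend((chrom, a, b) for a, b in zip(edges[:-1], edges[1:]))
    return windows


# ---------------------------------------------------------------------------
# spectrum and estimators


def sfs(matrix: HaplotypeMatrix, window=None):
    """Derived-allele count spectrum S_1..S_{n-1} for one window.

    Sites fixed for the derived allele among the observed haplotypes are
    excluded from the spectrum (they are not segregating) and returned
    separately. Haplotypes with any missing call inside the window are
    dropped (complete-case per window).

    Returns
    -------
    spectrum : ndarray of length n-1 (S_i at index i-1)
    n : int
        Number of complete-case haplotypes in the window.
    n_fixed_derived : int
    """
    if not matrix.polarized:
        raise ValueError("site-frequency spectrum requires a polarized matrix")
    data = matrix.data
    if window is not None:
        chrom, start, end = window
        if chrom != matrix.chrom:
            data = data[:, :0]
        else:
            in_win = (matrix.positions > start) & (matrix.positions <= end)
            data = data[:, in_win]
    complete = ~(data == MISSING).any(axis=1)
    data = data[complete]
    n = data.shape[0]
    spectrum = np.zeros(max(n - 1, 0), dtype=np.int64)
    if n < 2 or data.shape[1] == 0:
        return spectrum, n, 0
    counts = data.sum(axis=0, dtype=np.int64)
    n_fixed = int((counts == n).sum())
    seg = counts[(counts > 0) & (counts < n)]
    np.add.at(spectrum, seg - 1, 1)
    return spectrum, n, n_fixed


def theta_pi(spectrum, n):
    """Pairwise-diversity estimator θ_π = Σ_i S_i · 2 i (n−i) / (n(n−1))."""
    i = np.arange(1, n)
    return float(np.sum(np.asarray(spectrum) * 2.0 * i * (n - i)) / (n * (n - 1)))


def theta_w(spectrum, n):
    """Watterson's estimator θ_W = S / a₁ with a₁ = Σ_{i<n} 1/i."""
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(np.sum(spectrum) / a1)


def theta_h(spectrum, n):
    """Fay & Wu's θ_H = Σ_i 2 i² S_i / (n(n−1)), weighting high-frequency derived sites."""
    i = np.arange(1, n)
    return float(np.sum(np.asarray(spectrum) * 2.0 * i * i) / (n * (n - 1)))


def _tajima_constants(n):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajima_d(spectrum, n):
    """Tajima's D from the derived-allele spectrum.

    D = (θ_π − θ_W) / sqrt(e₁ S + e₂ S (S−1)) with the 1989 variance
    constants. Returns NaN (missing) when S = 0: the statistic is a 0/0
    form there, not zero.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    spectrum = np.asarray(spectrum)
    s = int(spectrum.sum())
    if s == 0:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    num = theta_pi(spectrum, n) - s / a1
    den = np.sqrt(e1 * s + e2 * s * (s - 1))
    return float(num / den)


def fay_wu_h(spectrum, n, normalized=False):
    """Fay & Wu's H = θ_π − θ_H (unnormalized, the original definition).

    Negative H indicates an excess of high-frequency derived alleles, a
    classic footprint of positive selection (hitchhiking). Requires a
    polarized spectrum; sites fixed for the derived allele must already
    be excluded. Returns NaN when S = 0.

    With ``normalized=True`` the variance-standardized form of Zeng et
    al. (2006) is returned: (θ_π − θ_L)/sqrt(Var), θ_L = Σ i S_i/(n−1).
    """
    if n < 2:
        raise ValueError("Fay & Wu's H requires n >= 2")
    spectrum = np.asarray(spectrum)
    if len(spectrum) != n - 1:
        raise ValueError("spectrum must have length n-1 (fixed sites pre-excluded)")
    s = int(spectrum.sum())
    if s == 0:
        return float("nan")
    pi = theta_pi(spectrum, n)
    if not normalized:
        return float(pi - theta_h(spectrum, n))
    i = np.arange(1, n)
    theta_l = float(np.sum(spectrum * i) / (n - 1))
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    tw = s / a1
    theta_sq = s * (s - 1.0) / (a1**2 + a2)  # unbiased estimator of θ²
    var = (
        tw * (n - 2.0) / (6.0 * (n - 1.0))
        + theta_sq
        * (18.0 * n * n * (3.0 * n + 2.0) * np.sum(1.0 / np.arange(1, n + 1) ** 2)
           - (88.0 * n**3 + 9.0 * n * n - 13.0 * n + 6.0))
        / (9.0 * n * (n - 1.0) ** 2)
    )
    return float((pi - theta_l) / np.sqrt(var))


def windowed_stats(matrix: HaplotypeMatrix, windows):
    """Compute a :class:`WindowStatRecord` for every window.

    Per-window sample size is the complete-case count (haplotypes with
    any missing genotype inside the window are dropped for that window).
    """
    if not windows:
        raise ValueError("empty window list")
    records = []
    for chrom, start, end in windows:
        spectrum, n, _ = sfs(matrix, (chrom, start, end))
        s = int(spectrum.sum())
        if n >= 2 and s > 0:
            pi = theta_pi(spectrum, n)
            tw = theta_w(spectrum, n)
            th = theta_h(spectrum, n)
            h = fay_wu_h(spectrum, n)
        else:
            pi = tw = th = h = float("nan")
        d = tajima_d(spectrum, n) if n >= 4 else float("nan")
        records.append(
            WindowStatRecord(chrom, start, end, n, s, pi, tw, th, d, h)
        )
    return records


def thomson_tmrca(matrix: HaplotypeMatrix, mu, length, generation_time=None):
    """Thomson's TMRCA estimator T̂ = (1/n) Σ_i d_i / (μ·L).

    d_i is the number of derived mutations carried by haplotype i,
    including sites fixed for the derived allele (every mutation on the
    lineage back to the MRCA counts). Missing calls contribute 0 to d_i.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if length <= 0:
        raise ValueError("sequence length must be positive")
    if not matrix.polarized:
        raise ValueError("Thomson's estimator requires a polarized matrix")
    d_i = (matrix.data == 1).sum(axis=1).astype(float)
    ml = mu * length
    t_gen = float(d_i.mean() / ml) if d_i.size else 0.0
    t_years = t_gen * generation_time if generation_time is not None else None
    return ThomsonResult(t_gen, t_years, d_i, ml)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_pair(matrix: HaplotypeMatrix, site_a, site_b):
    """Two-site LD from phased haplotype counts.

    D = p_AB − p_A p_B, D′ = D/D_max (Lewontin), r² = D²/(p_A q_A p_B q_B).
    Alleles are counted over haplotypes observed at both sites.
    """
    col_a = matrix.data[:, site_a]
    col_b = matrix.data[:, site_b]
    ok = (col_a != MISSING) & (col_b != MISSING)
    a, b = col_a[ok].astype(float), col_b[ok].astype(float)
    n = len(a)
    if n == 0:
        raise ValueError("no haplotypes observed at both sites")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic site: LD undefined")
    p_ab = float(np.mean(a * b))
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDRecord(
        int(matrix.positions[site_a]),
        int(matrix.positions[site_b]),
        float(d),
        float(d_prime),
        float(r2),
        float(min(p_a, 1 - p_a)),
        float(min(p_b, 1 - p_b)),
    )


def maf_filter(matrix: HaplotypeMatrix, threshold):
    """Retain sites whose minor allele frequency is strictly above ``threshold``."""
    if not 0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    obs = matrix.data != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, matrix.data, 0).sum(axis=0) / obs.sum(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf > threshold
    if not keep.any():
        warnings.warn("MAF filter removed every site", stacklevel=2)
    return matrix.take_sites(np.flatnonzero(keep))


def find_tagging_snvs(matrix: HaplotypeMatrix, group_a, group_b):
    """Sites perfectly separating two haplotype groups.

    Returns positions (sorted) where one allele is carried by every
    haplotype of ``group_a`` and by none of ``group_b``.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups overlap")
    sub_a = matrix.data[group_a]
    sub_b = matrix.data[group_b]
    all1_a = (sub_a == 1).all(axis=0)
    all0_a = (sub_a == 0).all(axis=0)
    all1_b = (sub_b == 1).all(axis=0)
    all0_b = (sub_b == 0).all(axis=0)
    sep = (all1_a & all0_b) | (all0_a & all1_b)
    return [int(p) for p in matrix.positions[sep]]


# ---------------------------------------------------------------------------
# bootstrap


def derived_allele_bootstrap(target_counts, reference_pool, n_boot=1000, seed=0,
                             tail="le"):
    """Empirical bootstrap p-value for a derived-allele load comparison.

    Draws ``n_boot`` samples of size len(target) with replacement from
    the reference pool and reports the add-one fraction whose mean is
    ≤ (tail='le') or ≥ (tail='ge') the target mean.
    """
    target = np.asarray(target_counts, dtype=float)
    pool = np.asarray(reference_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty reference pool")
    if pool.size < target.size:
        raise ValueError("reference pool smaller than target")
    if tail not in ("le", "ge"):
        raise ValueError("tail must be 'le' or 'ge'")
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_boot, target.size), replace=True)
    means = draws.mean(axis=1)
    obs = target.mean()
    hits = (means <= obs).sum() if tail == "le" else (means >= obs).sum()
    return float((1 + hits) / (n_boot + 1))
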