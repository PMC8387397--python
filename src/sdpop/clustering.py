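"""Haplotype encoding, LD pruning, haplotype PCA, k-means cluster-number
selection by the WSS elbow, haplotype heterozygosity, and the
archaic-homogeneity permutation test.

The clustering recipe: encode phased haplotypes as 0/1 derived-allele
vectors using an outgroup for polarization, prune tightly linked sites
(r² > 0.4 within a window), run a haplotype-based PCA, keep the top N
components whose variance fractions cumulatively exceed 0.9, choose the
cluster number k where the drop in within-group sum of squares (WSS)
falls below a threshold delta, and assign haplotypes with k-means at
that k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .popgen import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PcaModel",
    "ClusterModel",
    "encode_haplotypes",
    "ld_prune",
    "haplotype_pca",
    "choose_k",
    "haplotype_heterozygosity",
    "homogeneity_permutation",
]


@dataclass
class PcaModel:
    loadings: np.ndarray  # sites × components
    variance_fractions: np.ndarray
    scores: np.ndarray  # haplotypes × components
    n_informative: int  # smallest N with cumulative variance fraction > 0.9


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray
    wss_trace: np.ndarray  # WSS(k) for k = 1..k_max
    delta: float
    centers: np.ndarray | None = None


def encode_haplotypes(genotypes, positions, outgroup_alleles, ref_alleles,
                      alt_alleles, chrom="chr1", populations=None):
    """Polarize phased genotypes into a derived-allele HaplotypeMatrix.

    ``genotypes`` is an int array (haplotypes × sites) of 0 = REF,
    1 = ALT, -1 = missing; ``outgroup_alleles`` gives the outgroup
    (ancestral) base per site. Sites whose outgroup call matches the REF
    keep their encoding; sites where it matches the ALT are flipped;
    sites with a third allele or a missing outgroup call are dropped
    with a logged count.
    """
    geno = np.asarray(genotypes)
    positions = np.asarray(positions, dtype=np.int64)
    keep = []
    flip = []
    n_dropped = 0
    for j in range(geno.shape[1]):
        anc = outgroup_alleles[j]
        if anc == ref_alleles[j]:
            keep.append(j)
            flip.append(False)
        elif anc == alt_alleles[j]:
            keep.append(j)
            flip.append(True)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d sites with outgroup mismatch or missing call",
                    n_dropped)
    data = geno[:, keep].astype(np.int8)
    for col, do_flip in enumerate(flip):
        if do_flip:
            observed = data[:, col] != MISSING
            data[observed, col] = 1 - data[observed, col]
    return HaplotypeMatrix(data, positions[keep], chrom=chrom,
                           populations=populations, polarized=True)


def ld_prune(matrix: HaplotypeMatrix, r2_threshold=0.4, window=50):
    """Greedy left-to-right LD pruning.

    Scanning sites by position, a site is dropped when its r² with any
    retained site within the trailing ``window`` (site count) exceeds
    the threshold. Mirrors the usual variant-pruning recipe.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    data = matrix.data
    kept: list[int] = []
    for j in range(data.shape[1]):
        drop = False
        for i in reversed(kept[-window:]):
            r2 = _r2(data[:, i], data[:, j])
            if r2 is not None and r2 > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
    return matrix.take_sites(np.array(kept, dtype=int))


def _r2(col_a, col_b):
    ok = (col_a != MISSING) & (col_b != MISSING)
    a = col_a[ok].astype(float)
    b = col_b[ok].astype(float)
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        return None
    d = np.mean(a * b) - pa * pb
    return float(d * d / (va * vb))


def haplotype_pca(matrix: HaplotypeMatrix):
    """Haplotype-based PCA via SVD of the column-centered 0/1 matrix.

    Missing calls are mean-imputed per site before centering. Variance
    fractions come from the squared singular values; ``n_informative``
    is the smallest N whose cumulative variance fraction exceeds 0.9.
    """
    data = matrix.data.astype(float)
    obs = matrix.data != MISSING
    col_mean = np.where(obs, data, 0).sum(axis=0) / obs.sum(axis=0)
    data = np.where(obs, data, col_mean[None, :])
    centered = data - data.mean(axis=0)
    if not np.any(centered):
        raise ValueError("all haplotypes identical: PCA undefined (zero variance)")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    scores = u * s
    n_informative = int(np.searchsorted(np.cumsum(frac), 0.9) + 1)
    n_informative = min(n_informative, len(frac))
    return PcaModel(vt.T, frac, scores, n_informative)


def choose_k(scores, k_max=20, delta=None, seed=0, n_restarts=10):
    """Select k by the WSS elbow rule and assign haplotypes by k-means.

    For each k = 1..k_max, k-means (k-means++ init, ``n_restarts``
    restarts, best WSS kept) is run on the score matrix; one extra
    restart is seeded from the best (k−1) centers plus the worst-fit
    point, which guarantees a non-increasing WSS trace. The chosen k is
    the smallest with WSS(k) − WSS(k+1) < delta (k_max if none
    qualifies). ``delta=None`` uses a scale-aware default of 0.5% of
    WSS(1).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite values in PCA scores")
    n = scores.shape[0]
    if n < k_max + 1:
        warnings.warn(f"only {n} haplotypes for k_max={k_max}; "
                      "WSS trace will be degenerate at high k", stacklevel=2)
    k_max = min(k_max, n)
    wss = np.empty(k_max)
    models = []
    prev = None
    for k in range(1, k_max + 1):
        best = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                      random_state=seed).fit(scores)
        if prev is not None:
            # warm-start init: previous centers plus the worst-fit point
            dists = np.min(
                ((scores[:, None, :] - prev.cluster_centers_[None]) ** 2).sum(-1),
                axis=1)
            init = np.vstack([prev.cluster_centers_, scores[np.argmax(dists)]])
            warm = KMeans(n_clusters=k, init=init, n_init=1,
                          random_state=seed).fit(scores)
            if warm.inertia_ < best.inertia_:
                best = warm
        wss[k - 1] = best.inertia_
        models.append(best)
        prev = best
    if delta is None:
        delta = 0.005 * wss[0] if wss[0] > 0 else 0.0
    chosen = k_max
    for k in range(1, k_max):
        if wss[k - 1] - wss[k] < delta:
            chosen = k
            break
    model = models[chosen - 1]
    return ClusterModel(chosen, model.labels_.copy(), wss, float(delta),
                        model.cluster_centers_.copy())


def haplotype_heterozygosity(assignments, corrected=True):
    """Haplotype heterozygosity h = (n/(n−1)) (1 − Σ p_i²).

    The probability that two randomly drawn haplotypes belong to
    different classes, with the n/(n−1) small-sample correction by
    default (``corrected=False`` gives the plug-in form).
    """
    labels = np.asarray(assignments)
    n = labels.size
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / n
    h = 1.0 - float(np.sum(p**2))
    if corrected:
        h *= n / (n - 1)
    return float(h)


def homogeneity_permutation(pool_assignments, m=8, n_perm=100000, seed=0,
                            mode="without_replacement"):
    """Probability that m random haplotypes all fall in one cluster.

    Permutation test for the homogeneity of a small group (e.g. the
    archaic haplotypes) against the cluster structure of a modern pool:
    draws m haplotypes from ``pool_assignments`` and reports the add-one
    fraction of draws landing entirely in a single cluster. With
    ``mode='with_replacement'`` this converges to Σ_c p_c^m.
    """
    pool = np.asarray(pool_assignments)
    if m < 1:
        raise ValueError("m must be >= 1")
    if mode not in ("with_replacement", "without_replacement"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "without_replacement" and m > pool.size:
        raise ValueError(f"m={m} exceeds pool size {pool.size}")
    codes = np.unique(pool, return_inverse=True)[1]
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 100000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        if mode == "with_replacement":
            draws = codes[rng.integers(0, codes.size, size=(b, m))]
        else:
            draws = np.array([codes[rng.choice(codes.size, m, replace=False)]
                              for _ in range(b)])
        hits += int((draws == draws[:, :1]).all(axis=1).sum())
        done += b
    return float((1 + hits) / (n_perm + 1))
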