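"""Windowed sequence-identity profiles, empirical IGC-tract calls, and
full-length transcript (FLNC) read assignment filters.

Recent interlocus gene conversion homogenizes a stretch of an acceptor
paralog to its donor, leaving a run of perfect identity embedded in
otherwise diverged duplicate sequence. The detector slides a 500 bp
window with 100 bp step over a pairwise alignment and calls a tract
wherever more than two consecutive windows are at exactly 100% identity
(literal 1.0 — no epsilon; a single substitution breaks the run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IdentityProfile",
    "IGCTract",
    "FlncAlignmentRecord",
    "identity_profile",
    "detect_igc_tracts",
    "project_to_sequence",
    "assign_flnc_reads",
    "read_aligned_fasta_pair",
]


@dataclass
class IdentityProfile:
    """Per-window identity fractions over alignment columns."""

    starts: np.ndarray  # 0-based alignment-column start per window
    window: int
    step: int
    identity: np.ndarray
    gap_policy: str = "gap-mismatch"

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.identity = np.asarray(self.identity, dtype=float)
        finite = self.identity[np.isfinite(self.identity)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("identity fractions must lie in [0, 1]")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("windows must be ordered")


@dataclass
class IGCTract:
    start: int  # alignment columns, 0-based half-open
    end: int
    n_windows: int


@dataclass
class FlncAlignmentRecord:
    read_id: str
    target_id: str
    identity: float  # fraction in [0, 1]
    overlap: int  # aligned bp
    orf_length: int  # amino acids

    def __post_init__(self):
        if not 0 <= self.identity <= 1:
            raise ValueError("identity must be a fraction in [0, 1]")
        if self.overlap < 0:
            raise ValueError("overlap must be non-negative")


def identity_profile(seq_a, seq_b, window=500, step=100, gap_policy="gap-mismatch"):
    """Sliding-window identity between two rows of a pairwise alignment.

    Columns where either sequence has a gap count as mismatches under
    the default ``gap-mismatch`` policy (insertions break identity,
    which is conservative for gene-conversion detection); under
    ``gap-exclude`` they are removed from the denominator, and a window
    with no counted columns gets identity NaN.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if window < step:
        raise ValueError("window must be >= step")
    if gap_policy not in ("gap-mismatch", "gap-exclude"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    gap = (a == b"-") | (b == b"-")
    match = (a == b) & ~gap
    n = len(a)
    starts = np.arange(0, max(n - window, 0) + 1, step, dtype=np.int64)
    if n < window:
        starts = np.array([0], dtype=np.int64)
    cum_match = np.concatenate([[0], np.cumsum(match)])
    cum_gap = np.concatenate([[0], np.cumsum(gap)])
    ends = np.minimum(starts + window, n)
    matches = cum_match[ends] - cum_match[starts]
    if gap_policy == "gap-mismatch":
        denom = (ends - starts).astype(float)
    else:
        denom = (ends - starts) - (cum_gap[ends] - cum_gap[starts]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(denom > 0, matches / denom, np.nan)
    return IdentityProfile(starts, window, step, ident, gap_policy)


def detect_igc_tracts(profile: IdentityProfile, min_windows=3):
    """Call gene-conversion tracts as runs of >2 consecutive 100%-identity windows.

    A maximal run of strictly-1.0 windows of length ``min_windows`` or
    more (default 3: "more than two") becomes one tract spanning from
    the first window's start to the last window's end. Because windows
    overlap when the step is smaller than the window, spans of nearby
    runs can overlap; such tracts are merged, so the returned list is
    non-overlapping and the call idempotent.
    """
    perfect = profile.identity == 1.0  # exact: the criterion is literal 100%
    tracts = []
    i = 0
    m = len(perfect)
    while i < m:
        if perfect[i]:
            j = i
            while j + 1 < m and perfect[j + 1]:
                j += 1
            run = j - i + 1
            if run >= min_windows:
                tracts.append(IGCTract(
                    int(profile.starts[i]),
                    int(profile.starts[j]) + profile.window,
                    run,
                ))
            i = j + 1
        else:
            i += 1
    merged = []
    for t in tracts:
        if merged and t.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = IGCTract(prev.start, max(prev.end, t.end),
                                  prev.n_windows + t.n_windows)
        else:
            merged.append(t)
    return merged


def project_to_sequence(tract: IGCTract, aligned_seq):
    """Map a tract's alignment-column span to ungapped sequence coordinates."""
    arr = np.frombuffer(aligned_seq.encode(), dtype="S1")
    is_base = arr != b"-"
    cum = np.concatenate([[0], np.cumsum(is_base)])
    return int(cum[tract.start]), int(cum[min(tract.end, len(arr))])


def assign_flnc_reads(records, min_identity=0.99, min_overlap=200,
                      multimap_tol=0.0001, min_reads=10, min_orf=200):
    """Assign full-length transcript reads to duplicate haplotypes.

    Filters follow the standard stringent recipe for near-identical
    paralogs: a placement counts only with identity strictly above
    ``min_identity``, overlap of at least ``min_overlap`` bp and an ORF
    of at least ``min_orf`` aa; a multi-mapped read keeps every
    placement whose identity is within ``multimap_tol`` (strictly) of
    its best; an isoform/target is reported only when supported by
    strictly more than ``min_reads`` reads.

    Returns ``(assignments, retained_targets)`` where assignments maps
    target id → sorted list of read ids.
    """
    by_read = {}
    for rec in records:
        if rec.identity <= min_identity:
            continue
        if rec.overlap < min_overlap:
            continue
        if rec.orf_length < min_orf:
            continue
        by_read.setdefault(rec.read_id, []).append(rec)
    assignments = {}
    for read_id, recs in by_read.items():
        best = max(r.identity for r in recs)
        for r in recs:
            # round the gap so a difference exactly at the tolerance is not
            # admitted through floating-point representation error
            if round(best - r.identity, 12) < multimap_tol:
                assignments.setdefault(r.target_id, set()).add(read_id)
    assignments = {t: sorted(reads) for t, reads in assignments.items()}
    retained = sorted(t for t, reads in assignments.items()
                      if len(reads) > min_reads)
    return assignments, retained


def read_aligned_fasta_pair(path):
    """Read the first two records of an aligned FASTA as a sequence pair."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need at least two aligned sequences")
    a, b = str(records[0].seq), str(records[1].seq)
    if len(a) != len(b):
        raise ValueError(f"{path}: sequences are not aligned (unequal lengths)")
    return a, b
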