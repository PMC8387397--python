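"""Format ingestion/emission and the standard variant/sample quality filters.

Coordinate conventions: report-style region strings are 1-based
inclusive (commas and en-dashes tolerated, e.g.
``chr7:143,501,000–143,521,000``); everything internal is 0-based
half-open. The conversion is centralized here and round-trips
losslessly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "parse_region",
    "format_region",
    "read_vcf",
    "write_vcf",
    "write_matrix_tsv",
    "read_bed",
    "write_bed",
    "read_outgroup_tsv",
    "filter_variants",
    "filter_samples",
    "records_to_haplotypes",
    "window_records_to_frame",
]

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)\s*[-–—]\s*([\d,]+)$")


def parse_region(region):
    """Parse a 1-based inclusive region string to (chrom, start, end) half-open."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ValueError(f"cannot parse region string {region!r}")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise ValueError(f"bad region bounds in {region!r}")
    return chrom, start1 - 1, end1


def format_region(chrom, start, end):
    """Format a half-open interval back to the 1-based inclusive convention."""
    return f"{chrom}:{start + 1:,}-{end:,}"


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple
    qual: float
    genotypes: np.ndarray = field(repr=False)  # haplotypes (2 per sample); -1 missing
    phased: bool = True
    nearest_indel_bp: float = float("inf")

    @property
    def is_indel(self):
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_biallelic_snv(self):
        return (not self.is_indel) and len(self.alts) == 1


def read_vcf(path, require_phased=True):
    """Read a (plain or bgzipped) VCF into VariantRecords.

    Multiallelic sites are kept in the record list (the haplotype
    builder drops them with a logged count); the per-SNV distance to
    the nearest indel is computed here, at ingest.

    Returns (records, sample_names).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        gts = []
        phased = True
        for g in v.genotypes:
            alleles = g[:-1]
            phased = phased and bool(g[-1]) if len(alleles) > 1 else phased
            if len(alleles) == 1:  # haploid (archaic-style) call: pseudo-diploid
                alleles = [alleles[0], alleles[0]]
            gts.extend(-1 if a is None or a < 0 else a for a in alleles[:2])
        records.append(VariantRecord(
            chrom=v.CHROM,
            pos=int(v.POS),
            ref=v.REF,
            alts=tuple(v.ALT),
            qual=float(v.QUAL) if v.QUAL is not None else float("nan"),
            genotypes=np.asarray(gts, dtype=np.int8),
            phased=phased,
        ))
    if require_phased and any(not r.phased and (r.genotypes != MISSING).any()
                              for r in records):
        raise ValueError(f"{path}: unphased genotypes present")
    _annotate_indel_distance(records)
    return records, samples


def _annotate_indel_distance(records):
    indel_pos = {}
    for r in records:
        if r.is_indel:
            indel_pos.setdefault(r.chrom, []).append(r.pos)
    for chrom in indel_pos:
        indel_pos[chrom] = np.array(sorted(indel_pos[chrom]))
    for r in records:
        pos = indel_pos.get(r.chrom)
        if pos is None or pos.size == 0 or r.is_indel:
            continue
        i = np.searchsorted(pos, r.pos)
        cands = []
        if i < pos.size:
            cands.append(abs(int(pos[i]) - r.pos))
        if i > 0:
            cands.append(abs(int(pos[i - 1]) - r.pos))
        r.nearest_indel_bp = float(min(cands))


def filter_variants(records, min_qual=20.0, indel_radius=10):
    """Drop low-quality variants and SNVs adjacent to indels.

    A record is removed when QUAL < ``min_qual`` (strict: QUAL exactly
    at the threshold is retained; a missing QUAL passes) or when it
    lies within ``indel_radius`` bp of an indel. Indel records
    themselves are also removed. Counts are logged.
    """
    kept = []
    n_qual = n_indel = n_near = 0
    for r in records:
        if r.qual < min_qual:
            n_qual += 1
            continue
        if r.is_indel:
            n_indel += 1
            continue
        if r.nearest_indel_bp <= indel_radius:
            n_near += 1
            continue
        kept.append(r)
    logger.info("variant filter: %d low-QUAL, %d indels, %d within %d bp of "
                "indels removed; %d kept", n_qual, n_indel, n_near,
                indel_radius, len(kept))
    return kept


def filter_samples(records, samples, max_missing=0.10):
    """Drop samples with a missing-genotype fraction strictly above the cap.

    Returns (records with the sample's haplotype columns removed,
    retained sample names, dropped sample names).
    """
    if not records:
        return records, list(samples), []
    geno = np.stack([r.genotypes for r in records])  # variants × haplotypes
    n_hap = geno.shape[1]
    if n_hap != 2 * len(samples):
        raise ValueError("genotype columns do not match sample count")
    miss = geno == MISSING
    per_sample = miss.reshape(len(records), len(samples), 2).any(axis=2).mean(axis=0)
    keep = per_sample <= max_missing
    dropped = [s for s, k in zip(samples, keep) if not k]
    if not keep.any():
        raise ValueError("sample filter removed every sample")
    if dropped:
        logger.info("sample filter: dropped %s (> %.0f%% missing)",
                    dropped, 100 * max_missing)
    hap_keep = np.repeat(keep, 2)
    out = []
    for r in records:
        out.append(VariantRecord(r.chrom, r.pos, r.ref, r.alts, r.qual,
                                 r.genotypes[hap_keep], r.phased,
                                 r.nearest_indel_bp))
    return out, [s for s, k in zip(samples, keep) if k], dropped


def records_to_haplotypes(records, samples, outgroup=None, populations=None):
    """Build a polarized HaplotypeMatrix from biallelic SNV records.

    ``outgroup`` maps (chrom, pos) → ancestral base; when given, sites
    are polarized through :func:`sdpop.clustering.encode_haplotypes`
    (outgroup-mismatch sites dropped); without it the matrix is
    ALT-dosage encoded and flagged unpolarized.
    """
    from .clustering import encode_haplotypes

    snvs = [r for r in records if r.is_biallelic_snv]
    n_multi = sum(1 for r in records if not r.is_biallelic_snv)
    if n_multi:
        logger.info("dropped %d multiallelic/indel records at haplotype build",
                    n_multi)
    if not snvs:
        raise ValueError("no biallelic SNVs to build haplotypes from")
    chroms = {r.chrom for r in snvs}
    if len(chroms) > 1:
        raise ValueError("haplotype matrix must be single-chromosome")
    geno = np.stack([r.genotypes for r in snvs]).T  # haplotypes × sites
    positions = np.array([r.pos for r in snvs], dtype=np.int64)
    if populations is None:
        populations = np.array(
            [s for s in samples for _ in range(2)], dtype=object)
    else:
        populations = np.asarray(populations, dtype=object)
        if populations.size == len(samples):
            populations = np.repeat(populations, 2)
    if outgroup is None:
        return HaplotypeMatrix(geno.astype(np.int8), positions,
                               chrom=chroms.pop(), populations=populations,
                               polarized=False)
    chrom = chroms.pop()
    anc = [outgroup.get((r.chrom, r.pos), "N") for r in snvs]
    matrix = encode_haplotypes(geno, positions, anc,
                               [r.ref for r in snvs],
                               [r.alts[0] for r in snvs],
                               chrom=chrom, populations=populations)
    if matrix.n_sites == 0:
        raise ValueError("no sites survived outgroup polarization")
    return matrix


def write_vcf(matrix: HaplotypeMatrix, path, sample_prefix="sample"):
    """Write a minimal phased VCF; the derived allele is the ALT.

    Consecutive haplotype pairs become diploid samples; an odd trailing
    haplotype is written as a haploid GT.
    """
    n = matrix.n_haplotypes
    n_samples = (n + 1) // 2
    names = [f"{sample_prefix}{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(matrix.n_sites):
            col = matrix.data[:, j]
            gts = []
            for i in range(0, n - 1, 2):
                a = "." if col[i] == MISSING else str(col[i])
                b = "." if col[i + 1] == MISSING else str(col[i + 1])
                gts.append(f"{a}|{b}")
            if n % 2:
                a = "." if col[-1] == MISSING else str(col[-1])
                gts.append(a)
            fh.write(f"{matrix.chrom}\t{matrix.positions[j]}\t.\tA\tT\t.\tPASS\t"
                     f".\tGT\t" + "\t".join(gts) + "\n")


def write_matrix_tsv(matrix: HaplotypeMatrix, path):
    df = pd.DataFrame(matrix.data,
                      columns=[str(p) for p in matrix.positions])
    df.insert(0, "population", matrix.populations)
    df.insert(0, "haplotype", [f"hap{i}" for i in range(matrix.n_haplotypes)])
    df.to_csv(path, sep="\t", index=False)


def read_bed(path):
    """Read a BED file into (chrom, start, end) half-open tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals, path, names=None):
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            name = names[i] if names else f"region{i}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_outgroup_tsv(path):
    """Read an outgroup allele table (chrom, pos, ancestral base) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "pos", "base"])
    return {(r.chrom, int(r.pos)): str(r.base).upper() for r in df.itertuples()}


def window_records_to_frame(records):
    """WindowStatRecords → tidy DataFrame (1-based inclusive report coordinates)."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in records],
        "start": [r.start + 1 for r in records],
        "end": [r.end for r in records],
        "n": [r.n for r in records],
        "S": [r.segregating_sites for r in records],
        "pi": [r.pi for r in records],
        "theta_w": [r.theta_w for r in records],
        "theta_h": [r.theta_h for r in records],
        "tajima_d": [r.tajima_d for r in records],
        "faywu_h": [r.faywu_h for r in records],
    })
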