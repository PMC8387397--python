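# Methods

`sdpop` implements the statistical core of a population-genetic and
structural-diversity analysis of a segmental-duplication (SD) locus:
windowed selection scans with simulated and empirical nulls, copy-number
differentiation, gene-conversion profiling, and haplotype clustering.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data generators do and do
not emulate.

## Coalescent simulator

The simulator (`sdpop.simulate`) implements the structured Kingman
coalescent with:

- per-population diploid effective sizes `N_e` and forward exponential
  growth rates (backwards, a growing population shrinks; waiting times
  under piecewise-exponential size use the inverse integrated hazard, with
  the hazard capped when a backwards-growing size bounds the cumulative
  hazard below the exponential draw);
- scheduled events: `split` (backwards merger of a derived population into
  its ancestor), `size_change`, `migration_change` (backwards per-lineage
  migration rates);
- ancient sampling: sample groups enter the ancestry at their sampling
  time in generations, so archaic-style haplotypes carry no mutations
  younger than their sampling time by construction.

Mutations follow the infinite-sites model: the number of mutations is
Poisson(total branch length × μ × L); each mutation lands on a branch with
probability proportional to its length and receives a unique integer
position in [0, L), redrawing on collision. Each simulated window is one
non-recombining genealogy and windows are independent. This is deliberate:
the windows analysed are 2 kb — short relative to typical human
recombination distances — and every downstream statistic is a per-window
quantity, so intra-window recombination would perturb none of the
expectations tested while complicating the genealogy machinery. The
simulator is validated against closed forms (Watterson's E[S] = θ·a₁,
E[TMRCA] = 2(1−1/n)·2N_e, cross-group divergence 2μ(t_split + 2N_anc))
and cross-checked against msprime in the test suite; msprime is used only
as an independent oracle, never as the implementation.

Time is in generations everywhere; conversion to years happens only at
reporting, via `generation_time` (default 29 years, the conventional
human value). The default mutation rate is 1.25 × 10⁻⁸ per bp per
generation (the standard human pedigree-based rate); tests and the
verification script inflate μ so that desk-scale windows carry realistic
numbers of segregating sites at small N_e (θ = 4 N_e μ L matching the
study conditions, e.g. θ = 10 per 2 kb window with n = 20 haplotypes).

One gap is documented rather than modelled: matching local mutation- and
recombination-rate variation per window. μ and r are exposed per model
config; no procedure for inferring local rates is provided.

### Other generators

`simulate_cn_genotypes` draws diploid copy numbers as the sum of two
independent haploid cassette-count alleles per population (haplotypes at
such loci carry one to three cassette copies, so diploid CN spans 2–6; a
single haploid class fixed at 1 reproduces the archaic/outgroup "fixed
CN 2" configuration). `plant_igc` builds an aligned duplicate pair with
i.i.d. mismatches at a chosen divergence (default fixtures use 2%,
typical of recently diverged SD paralogs) and a planted identical tract
with known truth coordinates. `simulate_star_genealogy` is a toy
post-sweep genealogy (all lineages coalescing at one point; every
mutation a singleton) used only as a directional power control.

What the generators do *not* emulate: sequencing error, phasing error,
reference bias, GC-biased read depth, linked selection, and real
recombination maps. Passing tests therefore demonstrate correctness of
the statistics and detectors under their model assumptions, not
robustness to those artefacts.

## Window statistics

Per window the package reports S, θ_π, θ_W = S/a₁, θ_H = Σ 2i²S_i/(n(n−1)),
Tajima's D (1989 variance constants) and Fay & Wu's H = θ_π − θ_H (the
original unnormalized form; the variance-normalized form of Zeng et al.
2006 is available behind a flag). Conventions:

- S = 0 windows yield a missing marker (NaN), not 0, for both D and H —
  both statistics are 0/0 forms there. Downstream summaries drop missings.
- Per-window n is complete-case: haplotypes with any missing call inside
  the window are dropped for that window (simpler and more conservative
  than pairwise deletion).
- Sites fixed for the derived allele are excluded from S and the spectrum
  but counted in Thomson's per-haplotype derived loads d_i, since the
  TMRCA estimator T̂ = mean(d_i)/(μL) uses every mutation on each lineage
  back to the MRCA.
- Windows tile regions left to right; a terminal partial window is kept
  on its own iff it spans ≥ half the window size, otherwise it is merged
  into the preceding window. (A region list of 20 kb + 12 kb + 20 kb
  therefore yields 26 two-kb windows.)
- Coordinates are 1-based inclusive at the I/O boundary (the reporting
  convention of the field, e.g. `chr7:143,501,000–143,521,000`, commas
  and en-dashes tolerated) and 0-based half-open internally; the
  conversion lives in `sdpop.io` and round-trips losslessly.

LD is computed from phased haplotype counts: D = p_AB − p_A p_B,
Lewontin's D′ = D/D_max, r² = D²/(p_A q_A p_B q_B); the MAF filter is
strict (> threshold), matching the usual "> 10%" informativeness cutoff
for LD work.

## Null inference

Observed window sets are summarized by their **median**; the null is the
distribution of medians of equal-count window sets drawn with replacement
from the null values (genome-background windows from a user TSV, or
neutral simulations). The one-tailed empirical p-value is add-one:
p = (1 + r)/(n + 1), which can never be 0; Bonferroni correction is
min(1, m·p). The median-of-window-sets aggregation is an assumption — the
aggregation behind published genome-versus-locus comparisons of this kind
is typically unstated — chosen because per-group medians are what such
analyses report. Null distributions require ≥ 100 values (warning below
1,000). The joint (D, H) comparison reports quadrant occupancy fractions
(e.g. D < 0 ∧ H < 0, the hitchhiking corner) for observed and simulated
clouds plus a resampling p for the observed fraction.

## Copy-number statistics

V_ST = (V_T − V_S)/V_T with V_S the size-weighted mean within-population
variance. Both V_T and V_S use the population (divide-by-n) variance
estimator: the literature is ambiguous between n and n−1, and using the
same estimator on both sides is what guarantees V_ST ≤ 1. V_T = 0 is
defined as V_ST = 0 (no differentiation where there is no variation).
The copy-number differentiation test is implemented as a label-permutation
test on V_ST (add-one p); this is our interpretation of an
otherwise-unspecified procedure and is flagged as such.

The latitude analysis fits `CN ~ latitude + Σ PC_i` by OLS (statsmodels),
reporting both the raw Pearson correlation and the PC-adjusted latitude
coefficient with its t-test p — the PCs absorb population structure that
is itself correlated with latitude. Latitude enters as absolute value by
default. Collinear covariates abort with the offending component named.
The genomic-shuffle null compares |R| at the target locus against the
|R| distribution over random background SD loci (add-one empirical p).

## Sequence identity and gene conversion

Identity profiles slide a 500 bp window with 100 bp step over a pairwise
alignment. Gap columns count as mismatches by default (conservative for
gene-conversion detection, since insertions break identity); a
`gap-exclude` policy is available. Tracts are called as maximal runs of
**more than two** consecutive windows at *exactly* 100% identity — no
epsilon, the criterion is literal — spanning from the first window start
to the last window end; because windows overlap, nearby runs whose spans
overlap are merged, making the caller idempotent and its output
non-overlapping. At 2% flanking divergence a 500 bp window is perfect
with probability ≈ 0.98⁵⁰⁰ ≈ 4 × 10⁻⁵, which is why the false-tract rate
on 10 kb tract-free pairs is ≈ 0 (verified over 100 seeds).

FLNC transcript assignment keeps placements with identity strictly
> 99%, overlap ≥ 200 bp, and ORF ≥ 200 aa (configurable down to 100 aa —
both cutoffs circulate for this filter and the stricter one is the
default); multi-mapped reads keep all placements within 0.01% identity
of their best (the gap is rounded to 12 decimals so a difference exactly
at the tolerance is excluded despite floating-point representation), and
isoforms need strictly more than 10 supporting reads.

## Haplotype clustering

Haplotypes are encoded 0/1 against an outgroup-derived ancestral state
(sites whose outgroup base matches neither allele are dropped with a
logged count), optionally LD-pruned (greedy left-to-right, dropping the
later site of any pair with r² > 0.4 within a trailing window), and
decomposed by SVD of the column-centered matrix. The top N components are
those whose variance fractions cumulatively exceed 0.9. For k = 1..k_max
(default 20), k-means (k-means++, 10 restarts) yields WSS(k); one extra
restart is warm-started from the best (k−1) centers plus the worst-fit
point, which guarantees a non-increasing WSS trace deterministically —
plain restarts can produce rare inversions. The chosen k is the smallest
with WSS(k) − WSS(k+1) < delta. The historical delta of 500 is a
data-scale value; the default here is scale-aware (0.5% of WSS(1)) so the
rule transfers to synthetic data. Haplotype heterozygosity is
(n/(n−1))(1 − Σp_i²) by default (uncorrected form by flag; the correction
choice is not standardized in the sources this follows).

The homogeneity permutation test asks how often m haplotypes drawn from
the modern pool fall into a single cluster (add-one p). Both
with-replacement (converging to Σ_c p_c^m) and without-replacement modes
exist; without-replacement is the default since a real sample of m
haplotypes is drawn without replacement.

## Filters

Variant filter: drop QUAL < 20 (missing QUAL passes; QUAL exactly 20 is
retained) and SNVs within 10 bp of an indel (distance annotated at
ingest); indel records themselves are excluded from analysis. Sample
filter: drop samples with > 10% missing genotypes (exactly 10% is
retained). Haploid archaic-style GT calls are accepted and duplicated to
pseudo-diploid at ingest. The two filters commute whenever the variant
filter does not change which samples cross the missingness threshold.

## Verification script

`scripts/acceptance.py` recomputes, from scratch at run time: the
centering (mean within 3 Monte-Carlo SE of 0) and left skew of Fay & Wu's
H over 1,000 neutral replicates (n = 20, θ = 10 per 2 kb window); the
maximum absolute deviation of D, H, θ_π, θ_W, θ_H, D′, r² and V_ST from
brute-force oracles over 200 random small instances; KS uniformity of the
two permutation/resampling p-value procedures under their nulls (500
repetitions each); simulator moment ratios and Thomson-estimator relative
bias over 2,000 replicates; recovery rates for planted IGC tracts,
planted 3-cluster structure and reciprocal copy-number changes; and the
filter boundary checks. Problem sizes (1,000–2,000 replicates, 100 seeds
per recovery experiment) were chosen as the smallest giving stable
Monte-Carlo estimates of each quantity.

## Known limitations

- No intra-window recombination; no recombination maps.
- No sweep simulation beyond the star-genealogy toy; power statements are
  directional only.
- The genome background in tests is a simulated stand-in at reduced scale
  for a real ~10⁶-window genome scan table (any such TSV is accepted).
- t-SNE visualization of clusters is out of the computational core; the
  cluster model is defined by PCA + k-means alone.
- Multiallelic sites are dropped at haplotype building (with a logged
  count), not split.
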