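# Methods

This note records the models, estimators, defaults and deliberate design
choices behind `heteropop`, in the order the pipeline runs them.

## The synthetic panel generator

The generator emulates the statistical structure of a GBS-genotyped
diversity panel of maize inbred lines: several hundred near-homozygous
lines descending from K ancestral germplasm pools, biallelic SNPs on 10
chromosomes with density rising toward the telomeres, a small residual
heterozygosity, and missing calls.

**Model.** Each locus j draws an ancestral frequency
p_j ~ Uniform(0.05, 0.95); keeping the base frequency away from the
boundary makes the MAF filter's behavior controllable by the drift
parameter rather than by the base draw.  Group k's frequency follows the
Balding–Nichols construction
P_kj ~ Beta(p_j(1−F_k)/F_k, (1−p_j)(1−F_k)/F_k), so E[P_kj] = p_j and the
expected differentiation of group k from the ancestor is F_k.  Line i
draws admixture proportions Q_i ~ Dirichlet(α) (optionally forced one-hot
for a "pure" fraction of lines) and its per-allele alt probability at
locus j is π_ij = Σ_k Q_ik P_kj.

**Inbreeding.** With probability 1 − `residual_het_rate` one allele is
drawn and doubled (dosage 0 or 2); otherwise two independent alleles are
drawn.  The parameter is the rate of independent-draw events, so the
observed heterozygous-call fraction is `residual_het_rate` × E[2π(1−π)]
(roughly 0.4× the rate) — the generated matrices are {0,2}-dominated, which
is what the QC and subgroup-masking rules assume.  Missingness is MCAR at
`missing_rate`; no informative-missingness mechanism is modeled.

**Map geometry.** SNP density is piecewise constant: the outer 10% of each
chromosome end carries `telomere_enrichment` times the density of the
middle 80%, so the expected outer/middle density ratio equals the factor
exactly and reduces to uniform at 1.  No quantitative centromere/telomere
ratio is established for real maize panels; the factor is a free parameter
(default 3).

**Defaults** (the study conditions used by the test suite and the
acceptance script): 200 lines × 2000 loci, 10 chromosomes of 200 Mb,
K = 3, F = 0.3, Dirichlet α = 0.2 (most lines strongly attached to one
group, a minority admixed — the shape a structured breeding panel shows),
residual_het_rate = 0.02, missing_rate = 0.05, seed-driven and
byte-reproducible (one root seed, deterministic per-stage substreams).

A second, deliberately simple generator (`simulate_block_panel`) produces
block-copy panels: perfectly correlated loci within fixed-length haplotype
blocks, independent across blocks.  It is the linkage truth used by the
LD-decay and block-detection oracles; the main generator has no linkage.

**What the generator does not emulate:** coalescent genealogies, realistic
recombination maps and LD between drift and linkage, allele-frequency
spectra from selection, genotyping-error structure of real GBS (paralogous
tags, depth-dependent het miscalls), or relatedness/pedigree structure
within groups.  Passing recovery tests on these panels shows the
estimators work under the stated model, not that real data meet the model.

## QC

Loci are retained when MAF ≥ 0.05, missing rate ≤ 0.20 and heterozygote
fraction ≤ 0.05 (all configurable).  The three criteria are evaluated
independently on the raw calls (a locus failing several is counted under
each, removed once), which makes the filter order-free and idempotent.
MAF uses non-missing calls with heterozygotes contributing one copy of
each allele; per-line QC is deliberately not applied.  For
subgroup-specific analyses a stricter preparation is used: heterozygous
calls are set missing, then loci with > 10% missing are dropped.

## Diversity statistics

For alt frequency p (q = 1 − p): MAF = min(p, q); GD = 1 − (p² + q²);
PIC = GD − 2p²q²; H = heterozygous fraction of non-missing calls.
PIC ≤ GD identically and GD ≤ 0.5 for biallelic loci.  All-missing columns
are flagged undefined and excluded from summaries.  Moving-window GD uses
a 10-Mb window; the window step is not fixed by the windowed-GD convention
itself, so the default is window/10 (1 Mb).  Adjacent-locus distances are
within-chromosome only and banded at 0–0.1, 0.1–1, 1–5, 5–10, 10–25,
25–50, 50–75 and > 75 kb.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete lines (composite LD) — appropriate for unphased,
near-homozygous data and invariant to allele relabeling.  |D′| needs
haplotype frequencies: homozygous×homozygous lines contribute known
haplotypes, single hets half-known ones, and double hets are ambiguous
between coupling and repulsion; an EM iteration resolves them.  Pairs with
fewer than two complete lines or monomorphic on the complete subset are
undefined, skipped and counted.

Segment LD averages all within-segment pair r² in fixed 50-kb segments.
Decay curves bin pair r² by log-spaced distance (pairs capped at 1 Mb
separation by default to bound the O(m²) pair count) and fit an
isotonic-decreasing curve to the per-bin means — raw binned means are
non-monotone, and a crossing rule needs monotonicity.  The decay distance
is the first bin midpoint where the fit reaches r² = 0.1; a threshold of
1 returns 0 (LD starts at r² = 1 at zero distance) and a never-crossing
curve reports infinity.  For unlinked loci the background composite r² is
≈ 1/n at n lines.

## Haplotype blocks and tagSNPs

Confidence bounds on |D′| come from the profile likelihood of the observed
3×3 two-locus genotype counts on a 101-point |D′| grid (allele frequencies
and the sign of D held at their estimates), normalized and read at the
5th/95th percentiles.  Pairs with fewer than 10 complete lines are
uninformative.  Gabriel-style calls use the Haploview-default thresholds,
all exposed in `GabrielConfig`: strong LD when CI_low ≥ 0.70 and
CI_high ≥ 0.98, strong recombination when CI_high < 0.90.  A candidate
span is a block when its outermost pair is strong and ≥ 95% of its
informative pairs are strong; maximal non-overlapping spans are kept
longest-first (bp length, ties leftmost).  Candidate width is capped at 50
consecutive loci.

TagSNPs are a greedy set cover per block: repeatedly pick the locus
tagging the most untagged members at r² ≥ 0.8, ties to the lower position.
A greedy cover naturally yields more than one tag per block for internally
heterogeneous blocks; haplotype-frequency-based tagging is out of scope.
Loci outside any block are their own tags, so the tag set spans the map.

## Kinship

VanRaden's centered relationship K = ZZ′ / (2Σp_j q_j) with Z the
column-centered dosage matrix, monomorphic loci excluded and missing
dosages mean-imputed (acceptable bias at the ≤ 20% missingness enforced
upstream).  For the "relative kinship" report, negative off-diagonals are
floored at 0 — the scale on which unrelated pairs sit at or near zero —
and the raw matrix is retained alongside.

## Admixture model

Binomial likelihood ℓ(Q,P) = Σ_ij g_ij ln π_ij + (2−g_ij) ln(1−π_ij) with
π = QP, missing entries skipped, P clamped to [1e-6, 1−1e-6].  Fitting is
plain EM — the E-step allocates each observed alt (ref) allele to source k
proportional to Q_ik P_kj (Q_ik(1−P_kj)), the M-step renormalizes expected
counts — rather than quasi-Newton block relaxation: the stationary points
are the same and the monotone-likelihood contract is easy to state and
test.  Defaults: relative tolerance 1e-6, max 2000 iterations, 5 random
restarts keeping the best likelihood (restarts matter because the
likelihood is multimodal in label space and worse).  K = 1 is closed-form.
Label switching is resolved by ordering groups by descending total Q mass;
biological naming is the assignment module's job via indicator lines.

**K selection.** Masking cross-validation: non-missing entries are
partitioned into 5 random folds; each fold is masked in turn, the model
refit on the rest, and the error is the mean of (g − 2π̂)² over held-out
entries, averaged over folds.  Squared deviance and the binomial deviance
differ in scale but agree in where the minimum sits on well-separated
panels, which is the property used here.  CV fits use 1 restart and at
most 300 iterations at tolerance 1e-5 — the curve's argmin, not the exact
error value, is the product.

**Fst.** Nei-style ratio of sums across loci,
Fst = Σ(H_T − H_S) / ΣH_T, with H_S the mean within-group gene diversity
and H_T the gene diversity of the pooled mean frequency.  A Hudson-style
ratio-of-averages estimator with sample-size correction is available as a
labeled alternative (`method="hudson"`); it is the estimator the
simulation oracles use, since its expectation under Balding–Nichols
equals the drift parameter.  The Fst tree is UPGMA (average linkage) on
the Fst matrix, emitted as Newick with ultrametric heights (a two-group
matrix gives a cherry of height Fst/2).

**PCA.** SVD of the centered (optionally frequency-standardized) dosage
matrix with mean-imputed missing values; components ordered by variance,
sign fixed so each component's largest-magnitude loading is positive.

## Group assignment

Default ID is argmax Q, ties broken by column order and flagged.  The
adjusted rule, with A the top and B the runner-up group: A if Q_A > 0.5
and Q_A − Q_B > 0.1; A_Para if Q_A > 0.5 and Q_A − Q_B < 0.1, or
Q_A ≤ 0.5 and Q_A − Q_B ≥ 0.15; otherwise Mixed.  The gap exactly 0.1
(with Q_A > 0.5) is excluded by both strict inequalities as printed; it
resolves here to the clear assignment A and is flagged, favoring the
stronger claim and making the rule total.  One published worked example
(a line with top Q 0.35 and gap 0.09 labeled Para) contradicts the rule
as printed, which yields Mixed for that row; the implementation follows
the printed rule and the discrepancy is asserted as such in the test
suite rather than papered over with unstated thresholds.

Indicator-line validation counts a line concordant when the base group of
its adjusted ID (Para stripped) equals its known group; Mixed is
discordant.  Group shares are reported both with Para folded into the
base group and with adjusted labels verbatim, plus an optional supergroup
rollup.

## Group-specific loci

Per-group frequencies use het-masked calls of each group's assigned lines
(groups under 10 lines excluded).  Classification flags are independent
per locus: unique_A when segregating in A (MAF ≥ 0.05) but not in B;
neutral-in-A/fixed-in-B when freq_A ∈ [0.30, 0.70] and freq_B < 0.10 or
> 0.90; differential when |freq_A − freq_B| ≥ 0.50.  The neutral and
fixed band edges are this package's operational choices — "neutral" and
"near fixed" are qualitative notions — and all are config-exposed.
"Unique" is operationalized as private polymorphism (segregating in
exactly one group), not private allele.

## Numerical and engineering choices

- Genotypes are int8 dosages with −1 for missing; coordinates 1-based
  inclusive everywhere (native VCF convention, no shifts).
- All stochastic stages derive substreams deterministically from one root
  seed; fixed seed ⇒ byte-identical artifacts, which the tests assert.
- The |D′| grid likelihood is evaluated for the whole grid in one einsum;
  the EM for Q/P runs entirely in BLAS matmuls.
- Degenerate inputs fail loudly: all-monomorphic kinship input, K >
  n_lines, empty held-out CV sets, Q rows not summing to 1, ragged
  matrices.
- Problem sizes in the test suite and acceptance script (panels up to
  200 × 2000, CV over K = 1..6, five replicate seeds) are chosen as the
  smallest at which the recovery properties under test are stable.

## Known limitations

- The admixture EM can need many iterations near-convergence on weakly
  structured panels; the CV iteration cap trades exact convergence for
  the argmin property.
- D′ confidence intervals condition on estimated allele frequencies
  (profile, not joint, uncertainty), as block-callers conventionally do.
- Hudson Fst requires group sample sizes; the Nei form does not correct
  for finite samples and is slightly upward-biased for small groups.
- The pipeline's block stage on unlinked simulated panels finds few or no
  blocks (correctly), so the tagSNP subset is nearly the full locus set
  there; block-rich behavior is exercised by the block-copy generator.
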