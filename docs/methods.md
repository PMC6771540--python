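# Methods

This note documents the models, parameter choices and numerical decisions
behind `droughtcross`, and what the synthetic scenarios do and do not show
about real data.

## Study design and central objects

The package targets a comparative drought time course: three rosette
species (Ath, Aly, Esa), two watering arms (WW well-watered, WD
water-deficit), four sampling timepoints (T0, T5, T11, T14 — days after
watering stop) and three biological replicates, i.e. 24 samples per species
and 72 in total. The central in-memory object is `ExpressionMatrix`
(features × samples TPM with typed sample metadata); cross-species analyses
operate on the expressed-mutual-ortholog (EMO) table, the set of
one-to-one-to-one ortholog triples whose members all pass the expression
filter in their own species.

## Expression processing

Gene abundance is the sum of its transcripts' TPM (column totals are
conserved when nothing is dropped). The working log scale is
log2(TPM + c) with pseudocount c = 1, chosen so that the expression filter
"some sample with log2TPM ≥ 1" is equivalent to "some sample with
TPM ≥ 1"; the threshold comparison is inclusive. The filter is applied per
species before orthology, so "expressed" is a species-level property.
Duplicate feature rows are an error rather than being silently summed.

## Orthology

One-to-one pairs are reciprocal best hits over BLAST tabular hits filtered
at E ≤ 10⁻³ (inclusive). "Best" uses a fully deterministic tie-break chain:
max bitscore, then min E-value, then max percent identity, then
lexicographically smallest subject id — so ortholog calls are reproducible
for any input order. Triples require triangle closure: the A–B, A–C and B–C
assignments must agree; inconsistent triangles are dropped and counted.
A relaxed mode (`require_closure=False`) admits a triple when the B–C pair
is merely absent, but closure is the default because it guarantees
one-to-one-to-one semantics. Hit ids are assumed to be gene ids; a
protein→gene map can be applied upstream when they are not.

## Fold changes and response timing

log2FC = log2((mean TPM_WD + 1)/(mean TPM_WW + 1)) per gene and timepoint,
on replicate means with the same pseudocount as the filter; this keeps
fold changes finite and damped at very low abundance. Up/down calls are
inclusive at ≥ 1 / ≤ −1. "Drought-specific" genes are expressed
(log2TPM ≥ 1) in at least one WD sample after stress onset and never in any
WW sample nor at T0 — operationalizing "expressed only in response to
drought".

A species' timing profile over T5/T11/T14 is: induced iff any
log2FC ≥ 1; first peak = earliest induced timepoint; highest peak = argmax
fold change over induced timepoints, earliest winning ties. The
cross-species segment code combines which species are induced with
first-peak agreement: `common-synchronous` / `common-shifted` (all three),
`X+Y-synchronous` / `X+Y-shifted` (exactly two), `X-specific` (one),
`none`. These canonical codes name response patterns directly rather than
enumerating arbitrary diagram sectors.

## Permutation overlap test

Null model: each species' regulated set is redrawn independently and
uniformly without replacement from the EMO background, and the full
intersection is counted; p = #{null ≥ observed}/N with N = 1000 by default,
reported as "< 1/N" when the observed value is never reached (the
conventional floor for an empirical p of zero). The exceedance comparison
is ≥, not >. The test generalizes to k species and is run separately per
timepoint × direction stratum. Because the statistic is discrete, the
p-value is uniform only on its attainable levels; the calibration tests
check P(p ≤ t) = t at those levels rather than at arbitrary α.

## Co-expression modules

The network chain is authored from scratch (scipy supplies only the
average-linkage agglomeration):

1. Pearson correlation across all 72 samples jointly (zero-variance genes
   get correlation 0, with a warning).
2. Unsigned soft-threshold adjacency a = |r|^β with β = 16 by default; a
   signed variant ((1+r)/2)^β is available. β is fixed, not fitted — the
   scale-free-fit procedure for choosing β is out of scope.
3. TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), TOM_ii = 1,
   computed via one matrix product and symmetrized against roundoff;
   clustering runs on 1 − TOM.
4. Average linkage (UPGMA) on the condensed dissimilarity;
   scipy's nearest-neighbor-chain algorithm is deterministic.
5. Deterministic tree cut: cut at `cut_height_fraction` (default 0.99) **of
   the root merge height**; branches with ≥ `min_module_size` (default 30,
   a field convention) genes become modules, smaller ones stay
   "unassigned". A quantile of the merge heights was considered and
   rejected: β = 16 drives most TOM dissimilarities to ≈ 1, so high
   quantiles of the merge heights coincide with the root and collapse the
   dendrogram into a single module even when planted blocks are cleanly
   separated; a fraction of the root height — the convention of the
   canonical tree-cutting implementation — separates them reliably.
6. Eigengene = first right singular vector of the module's gene-standardized
   expression (unit norm over samples), sign-oriented to correlate
   positively with the module's mean standardized profile (removing the PCA
   sign ambiguity); variance explained = leading eigenvalue fraction.
7. Closest-first merging while min eigengene dissimilarity
   1 − r < 0.1 (r > 0.9), recomputing eigengenes after each merge;
   idempotent by construction. Final labels are M1, M2, … by decreasing
   size.

Module–trait statistics: Pearson r of each eigengene with one-hot species,
treatment (WD = 1) and timepoint rank; two-sided p from the t distribution
with n − 2 df; BH FDR over the whole module × trait family. Both 0.05
(default) and any other FDR threshold are configurable rather than
hard-coded, since reasonable analyses use 0.05 or 0.1.

## Enrichment

Classic one-sided Fisher: p = P(X ≥ k), X ~ Hypergeom(N, K, n), via scipy's
survival function; BH step-up via statsmodels. Terms with no annotated gene
in the universe are skipped so the FDR family contains only testable terms.
The default universe is the expressed set (EMO set for EMO-level
analyses). Optional true-path propagation closes annotations over a term
DAG (cycle detection via networkx). Decorrelation schemes (elim/weight
style) are deliberately not implemented.

## Phenotype metrics

All formulas exactly as defined: RGR = (ln A_t − ln A_{t−Δt})/Δt per
consecutive-day interval (telescoping: interval RGRs time-average to the
total log growth); stockiness = 4π·area/perimeter² (1 for a circle);
compactness = area/convex-hull area (1 for convex rosettes); stomatal
index = guard cells/epidermal cells as printed in the source protocol,
with the conventional stomata/(stomata + epidermal) variant behind a flag;
cells per leaf = leaf area × cell density, unrounded; aperture ratio
R_wl = ostiole width/length; anthocyanin index = (A530 − A657)/g fresh
weight (may legitimately be negative). Survival is percent per replicate
with across-replicate mean and sample SD (ddof = 1).

The first growth-reduction day uses a one-sided Welch t-test (WD < WW) per
shared day at α = 0.05, returning the earliest significant day. Welch was
chosen because WD shrinks both mean and variance of areas; one-sided
because the question is directional. Days with fewer than two plants per
arm are skipped; two identical zero-variance groups are treated as
non-significant.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` sub-streams
(seed, seed+1, seed+2, seed+3 for expression, orthology, annotations,
growth), so stages are individually reproducible and byte-identical under a
fixed seed.

**Expression.** Gene base levels are normal on log2 (log-normal TPM means),
mean 4.5, SD 2.5 — a wide, realistic dynamic range in which ~2% of genes
fail the expression filter; planted genes are floored at log2 = 3 so the
structure of interest survives filtering. Module genes follow a latent
factor model over the joint 72-sample axis: member profile
= √ρ·latent + √(1−ρ)·noise, so `within_correlation` ρ is the *realized*
pairwise correlation (the idiosyncratic term is the module genes' noise;
stacking extra residual noise on top would silently dilute ρ). Trait-
associated modules mix a standardized trait vector into the latent at
weight 0.7. Non-module genes get independent log2 noise of SD 0.4 —
typical bulk RNA-seq replicate scatter. Planted drought induction is
defined on the pseudocounted fold-change scale: at an induced timepoint the
WD abundance is (TPM + 1)·2^lfc − 1, so measured log2FC equals the planted
effect exactly at zero noise. Default planted effects are 2–3 log2 units
(strong drought markers) with timing classes mirroring the qualitative
biology: an early-responding species (Aly, first peak T5/T11), a late but
broad responder (Ath, T14, the largest specific set) and a tempered
responder (Esa). Gene TPM is split over 1–3 transcripts by fixed
Dirichlet(5) weights.

**Orthology.** True pairs get mutual top hits with bitscores uniform in
300–800 and E-values derived from them; paralog decoys (rate 0.2) point at
a random other family with a bitscore scaled by 0.4–0.8 — strictly lower,
so decoys can never displace a true RBH (precision stays 100% by
construction; what is tested is that the pipeline *realizes* that).
`missing_rate` (default 0.05) removes a family's hits for a species pair;
`fraction_one_to_one` (default 0.9) removes a family from orthology
entirely. Ground-truth triples are the families with hits present in all
three pairs.

**Growth.** WW area follows a logistic curve (species-specific maxima
1500/1200/900 mm², rate 0.45 d⁻¹, midpoint day 7) with per-plant log-scale
size variability (SD 0.10) and day wobble. WD curves are *paired
counterfactuals*: each WD plant reuses its WW twin's noise stream, and
after the planted divergence day (Ath 5, Aly 3, Esa 8 — encoding the
early/late response ordering) its log-growth increments are scaled by
1 − 0.5. Pairing makes the planted day identifiable as "the first
significant day": with independent noise the day-wise test would fire
before the true day at rate ≈ α per preceding day, which is a property of
the test, not a generator defect. Independent arms remain available
(`paired=False`) and are used for null calibration. Perimeter and hull are
derived from area through plant-day draws of stockiness (0.35–0.75) and
compactness (0.55–0.95), keeping both metrics in (0, 1]. Survival is
Bernoulli per species (0.76/0.96/0.98) over 3 replicates × 27 plants.

**What the generators do not emulate**: count-level sampling noise
(negative-binomial overdispersion) — the pipeline consumes TPM, so noise is
log-normal; library-size and batch artifacts; correlated gene-gene
structure beyond the planted modules; alignment/quantification errors
upstream of the TPM tables; genuine sequence evolution behind the BLAST
scores; senescence or death dynamics in the growth curves. Tests passing on
this synthetic data therefore certify the *inference machinery* (recovery
of planted structure, exactness of formulas, correctness of null
distributions), not robustness to every artifact of real experiments.

## Problem sizes and runtimes

The default pipeline scenario uses 5000 ortholog families (≈ 3800 EMOs
after orthology and filtering), chosen as a desk-scale stand-in for a
~16k-EMO experiment: it exercises every code path, keeps the TOM matrix
(n² dense) around 115 MB, and completes a full run in well under a minute
on one CPU. The module-recovery scenario (4 × 60-gene modules,
within-correlation 0.8, 200 noise genes, 24 samples) recovers planted
assignments at adjusted Rand ≥ 0.96 across seeds with eigengene–latent
|r| > 0.99. Permutation exactness uses the 5-element background whose
3-way singleton overlap distribution is exactly enumerable (p = 5/125).

## Known limitations

- The tree cut is a single static cut with a minimum branch size — a
  deliberately simple, fully deterministic variant of dynamic tree cutting;
  it does not re-examine nested sub-branches, so modules separated only
  below the cut height are merged.
- β = 16 is taken as given; no scale-free-topology fit is provided.
- The permutation test treats species' regulated sets as exchangeable with
  uniform draws; it does not condition on per-gene expression level or
  network structure.
- Enrichment p-values are classic Fisher and inherit the usual DAG
  correlation between nested terms.
- `first_growth_reduction_day` performs no multiplicity correction across
  days; it answers "earliest day significant at α", matching the standard
  day-wise read-out of growth phenotyping.
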