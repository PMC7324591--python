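# Methods

This note documents the models, the numerical choices and the limits of what
the synthetic-data tests demonstrate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## TCR-β repertoire statistics

A clonotype is the exact triple (V call, J call, CDR3 string). Allele
suffixes on gene calls (`TRBV7-2*01` → `TRBV7-2`) are stripped by default
(`strip_alleles`), because V/J annotation granularity varies across samples;
clonotype identity is otherwise literal string equality.

**Noise filter.** Two stages, in fixed order: (1) drop clones with fewer
than `min_count = 3` reads; (2) keep the most strongly expressed
`keep_rank_fraction = 0.90` of the survivors. Stage 2 has two
interpretations and both are implemented: the default *rank* rule keeps the
top ⌈0.9·n⌉ clones by count (the phrase quantifies clones, not reads); the
alternative *mass* rule keeps the shortest count-sorted prefix reaching 90%
of reads (`mode="mass"`). Ties in count are always broken lexicographically
on the clonotype key, making top-K selection deterministic. Frequencies are
renormalized over retained clones; pre-filter frequencies are kept in a
`raw_frequency` column. The applied parameters are recorded on the filtered
repertoire, so re-filtering with identical parameters is a no-op — this is
what makes the filter idempotent despite the rank rule's ⌈0.9·n⌉ otherwise
shrinking on every application. Filtering a repertoire to nothing is a
warning, not an error (empty sorted samples do occur).

**Sharing.** `overlap% = |keys(ref) ∩ keys(query)| / |keys(ref)| × 100`,
always normalized by the reference (the Treg repertoire in the pTreg
analysis, the tumor repertoire in the trafficking analysis). The statistic
is symmetric in the numerator only. Top-K clone tracking reports, per
target sample, the cumulative frequency ("summary mass") of the K
highest-count reference clones in that target, with frequency 0 for absent
clonotypes. We read the per-sample percentages of the tracked-clone stacked
charts as this frequency mass, not as a detected-clone count; the mass and
count readings coincide only for uniform repertoires.

## Consensus differential expression

**Normalization.** Each sample is scaled by (mean of all sample totals)/(its
total). A single multiplicative factor per sample preserves within-sample
ratios exactly. One normalization is used for all three statistics; the
original three-package analysis this machinery descends from would have used
each package's own normalization, a divergence we accept for
reproducibility's sake.

**Flags and the P50 universe.** Signal flag = 1 iff normalized count ≥ 20
(strict boundary: 19.999… → 0, exactly 20 → 1). A gene enters the test
universe for a comparison iff flagged in at least half of the compared
samples, evaluated on exact rationals (2·k ≥ n): 2 of 4 samples suffice,
2 of 5 do not. Genes outside the P50 universe are not tested at all.

**Three statistics.** All run on the normalized counts.

- *NB-Wald*: per-gene negative binomial. Dispersion by pooled method of
  moments, α̂ = (s² − μ)/μ², shrunk toward a mean–dispersion trend
  α(μ) = a₀ + a₁/μ fitted across genes (mixing weight 0.5, configurable)
  and floored at the trend — with few replicates the moment estimate is
  noisy downward, and an underestimated dispersion inflates the Wald
  statistic (nominal 5% behavior measured in the suite). Wald statistic
  z = log f̂ / SE with the delta-method variance
  SE² = (1/μ_A + α)/n_A + (1/μ_B + α)/n_B, two-sided normal p.
  Fold estimate: ratio of group means.
- *Moderated t*: on log2(count + 0.5). Per-gene pooled variance s² shrunk
  toward the prior s₀² (mean of per-gene variances) with d₀ = 4 prior
  degrees of freedom: s̃² = (d₀s₀² + d s²)/(d₀ + d), d = n_A + n_B − 2;
  t referred to d + d₀ df. Fold estimate: 2^(mean log2 difference)
  (geometric-mean fold).
- *Exact rank*: Wilcoxon rank-sum, exact null for group sizes ≤ 10 without
  ties, tie-corrected normal approximation otherwise; constant genes get
  p = 1. Fold estimate: median of all pairwise sample ratios
  (Hodges–Lehmann style).

**Consensus.** U (or D) iff *every* statistic has p ≤ 0.05 and linear fold
≥ 1.2 (or ≤ 1/1.2), both bounds inclusive, with agreeing direction
(direction agreement is config-exposed). The reported fold is the median of
the three estimates. A gene missing from any method is N. Genes with zero
counts in a group are excluded (p reported missing).

The consensus is monotone in both thresholds and, being an intersection, its
null call rate can never exceed any single test's rate. Its false-discovery
behavior under planted effects deserves a caveat: the three statistics are
computed from the same samples and are strongly correlated, so the
intersection deflates the null rate far less than independence would
suggest. Under the generator's planted-effect conditions (10% of genes at
fold 4, 6 vs 6, dispersion 0.1) the suite measures sensitivity ≈ 1.0 with a
false-discovery proportion around 0.15–0.2; the property test asserts the
simulation-derived bound (FDP ≤ 0.25 per seed). Pushing FDP lower at these
settings would require deliberately conservative component tests or a
multiplicity correction, which the consensus rule does not include.

**Venn signatures.** Per-gene (NI, I, T) call triples map to exactly one
class: UUU → common Treg signature, DDD → common Tconv signature, a single
non-N call → that tissue's unique up/down class, NNN → unclassified,
anything else → other. Genes absent from a tissue's table (e.g. failing its
P50 filter) count as N there.

Matched-patient pairing is *not* modeled (unpaired contrasts), matching the
group-comparison design; a paired mode is left as an extension.

## Ratio survival screen

Genes are screened against the reference gene (*FOXP3*) in three steps.

1. *Correlation filter*: Pearson r of raw RPM across patients, pass iff
   r > 0.5 (strict) and mean RPM > 20 (strict). Zero-variance genes are
   excluded with a reason rather than failed. Log-scale and Spearman
   variants are options; raw-RPM Pearson is the default.
2. *Ratio and split*: per-patient gene:reference RPM ratio; patients with
   reference RPM = 0 are dropped (count logged). Median split with ties to
   "low" — deterministic and conservative for the high-risk call
   (config-exposed). Multi-gene signatures z-standardize each gene's ratio
   across patients and average (`mean_z`, default) or take the geometric
   mean of raw ratios; the combination rule is an assumption, stated as
   such, since no canonical definition exists.
3. *Survival comparison*: Kaplan–Meier product-limit curves and the
   two-group log-rank test (χ² = (ΣO−E)²/ΣV on the hypergeometric model,
   1 df), both delegated to `lifelines` behind the module surface, for OS
   and DFS. Risk direction is "poor" iff the high-ratio group's KM curve is
   lower at the last time point common to both curves. Raw log-rank
   p-values are reported (no multiplicity correction, matching the original
   screen's practice); a Benjamini–Hochberg column is appended for
   convenience.

Zero total events yields p = 1 with a warning; an empty group is an error.
The chi-square reference is an asymptotic approximation: against an exact
permutation reference it agrees to Monte-Carlo error at n = 100 per group,
but at n ≤ 12 the deviation can reach ~0.1 (and below n = 8 the permutation
distribution itself is discrete in steps of ~0.1). The test suite therefore
checks the *statistic* against the permutation oracle exactly and allows
that documented margin on the p-value.

The TCGA-BRCA-like subtype composition (562 Luminal A : 209 Luminal B :
190 Basal : 82 Her2+) is available as a preset and as a metadata filter;
no TCGA download is required or performed.

## CD4 gating

Inputs are pre-thresholded categorical calls — continuous fluorescence and
instrument-specific thresholds are out of scope. The CD45RA/FOXP3 scheme is
a fixed six-entry map (the five named classes plus `unclassified` for the
CD45RA+ FOXP3-high corner outside the printed gates). The helper tree
evaluates Tfh (PD-1 high AND CXCR5+) first — a PD-1-high CXCR5+ CXCR3+ cell
is Tfh, not Th1; the precedence is a design decision and config-exposed —
then the chemokine tree as written, then `non_polarized` (all assessed
chemokine receptors negative), then `other` for unnamed combinations (e.g.
CXCR3− CCR6+ CCR4−) rather than forcing them into non-polarized. The
classifier is total: all 2·2·2·2·2·3 = 96 marker combinations map to
exactly one class (enumerated in tests). CRTh2 may be present in event
tables but is not used in classification. Treg-side "Th-like" gating uses
the identical rules (the populations follow the same chemokine-receptor
pattern).

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed). A global seed expands
to per-generator seeds by hashing `"{seed}:{component-name}"` (SHA-256,
31-bit), so adding a generator never perturbs existing outputs.

- *Repertoires*: clone counts multinomial over Zipf(α) probabilities;
  defaults α = 1.2 for Treg-like and 0.6 for Tconv-like samples — chosen to
  reproduce the qualitative Treg > Tconv clonality ordering, not fitted to
  data. Shared clonotypes are planted as an exact count
  (round(fraction · n) keys sampled without replacement), so measured
  overlap differs from the planted fraction only through read-sampling
  dropout (< 0.1 points at the default 100 reads/clone). Key order is
  shuffled before Zipf assignment so planted clones are not systematically
  the most expanded.
- *Counts*: log-normal gene means (median 150), NB(μ, α) counts, uniform
  library-size factors in [0.7, 1.3]; planted genes get their mean
  multiplied by the true fold in one group (half up, half down).
- *Cohorts*: every panel gene is reference·exp(0.3 + 0.3ε), so all pass the
  correlation filter by construction; only the planted gene's ε drives the
  exponential event-time hazard (base 1/1500 per day, log-hazard β on the
  standardized log ratio). DFS is the minimum of death and an independent
  recurrence process, guaranteeing DFS ≤ OS; censoring is an independent
  exponential calibrated to the requested censoring fraction under β = 0.
- *Events*: cells drawn from archetypes that fix every marker, so noiseless
  mixtures are recovered exactly; optional uniform label noise.

What passing tests therefore show: the implementations compute the intended
statistics correctly, recover planted structure, and are calibrated under
their model assumptions. What they do not show: robustness to features of
real data the generators omit — sequencing-depth differences between
samples' repertoires, PCR amplification noise on clone counts, batch
effects and gene–gene correlation in expression, non-proportional hazards,
marker spillover or gating drift, or the pairing structure of matched
patient samples.

## Problem sizes used in the default runs

Simulation-based checks use 200 oracle instances (≤ 50 clones), 1000-clone
repertoires × 10 seeds for sharing recovery, 2000 log-rank null simulations
at n = 100/group, 2000-gene count matrices (10 seeds for planted recovery),
20 screen cohorts of n = 300, and 2000-cell event tables — sizes chosen so
the whole suite and the acceptance script each complete in about a minute
while keeping Monte-Carlo error well inside the asserted tolerances.
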