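# tregpipe

Reusable, tested re-implementation of the computational analyses used in
studies of regulatory T cells (Tregs) in breast-cancer tumor-draining lymph
nodes (TDLNs): TCR-β clonotype filtering and repertoire-sharing statistics,
a three-test differential-expression consensus with background flagging, a
reference-gene-ratio survival screen, and deterministic CD4+ T-cell gating —
plus a synthetic-data generator so every stage is testable without any
download.

It is aimed at computational immunologists who want these bespoke analysis
steps as a library and CLI with known statistical behavior, rather than as
one-off scripts.

## What it computes

**TCR repertoire sharing** (`tregpipe.repertoire`). Clonotypes are the exact
(V, J, CDR3) triple. Samples are denoised by removing clones with fewer than
3 reads, then keeping the 90% most strongly expressed clones (rank rule by
default; a cumulative-mass rule is available). Clonal expansion is summarized
by the cumulative frequency curve (rank r ↦ Σ of the top-r clone
frequencies). Sharing between a reference repertoire R (e.g. Tregs) and a
query Q (e.g. Tconvs) is

    overlap% = |keys(R) ∩ keys(Q)| / |keys(R)| × 100,

and the top-K tumor clones can be tracked into lymph-node samples (per-target
"summary mass" = cumulative frequency of the K reference clones in that
sample).

**Consensus differential expression** (`tregpipe.deg`). Counts are scaled to
the mean per-sample coverage; normalized counts ≥ 20 are flagged as signal;
genes flagged in at least half of the compared samples (the "P50" universe)
are tested with three complementary statistics — a negative-binomial Wald
test with trend-shrunk dispersion, an empirical-Bayes moderated t on
log2 counts, and an exact Wilcoxon rank-sum test. A gene is called up (U)
or down (D) only when all three tests have p ≤ 0.05 and linear fold ≥ 1.2
in a consistent direction. Per-tissue calls over (NI, I, T) are combined into
Venn signature classes: UUU (common Treg signature), DDD (common Tconv
signature), tissue-unique, other.

**Ratio survival screen** (`tregpipe.survival`). Candidate genes must
correlate with the reference gene *FOXP3* (Pearson r > 0.5) and exceed 20
RPM on average. Per patient, score = gene RPM / FOXP3 RPM; the cohort is
split at the median (ties → low) and the low/high groups compared by
Kaplan–Meier curves and the two-group log-rank test for overall and
disease-free survival. Multi-gene signatures average z-standardized ratios.

**CD4 gating** (`tregpipe.gating`). Deterministic classification from
categorical marker calls: the CD45RA/FOXP3 five-way scheme (naive Treg,
effector Treg, FOXP3+ non-Treg, memory Tconv, naive Tconv) and the
chemokine-receptor helper tree — Th1 (CXCR3+), Th2 (CXCR3−CCR6−CCR4+),
Th17 (CXCR3−CCR6+CCR4+CCR10−), Th22 (CXCR3−CCR6+CCR4+CCR10+),
Tfh (PD-1^high CXCR5+, with precedence) — plus per-sample frequency tables
and paired Pearson correlations.

**Synthetic data** (`tregpipe.simulate`). Zipf repertoires with exact
planted sharing, negative-binomial count matrices with planted fold changes,
proportional-hazards cohorts whose risk is tied to a gene:FOXP3 ratio, and
archetype-based marker tables — all pure functions of (parameters, seed)
with serialized ground truth.

## Worked example

```python
from tregpipe import simulate
from tregpipe.repertoire import filter_repertoire, subset_overlap, expansion_index
from tregpipe.survival import screen

reps, gt = simulate.gen_linked_repertoires(n_patients=1, n_clones=1000, seed=42)
by = {r.sample_id: r for r in reps}
treg, tconv = by["P1_NI_Treg"], by["P1_NI_Tconv"]
treg_f, tconv_f = filter_repertoire(treg), filter_repertoire(tconv)  # min 3 reads, top 90%
print(f"NI Treg: {len(treg)} clones -> {len(treg_f)} after filtering")
print(f"NI Tconv: {len(tconv)} clones -> {len(tconv_f)} after filtering")
print(f"Treg top-50 cumulative frequency: {expansion_index(treg_f, 50):.3f}")
print(f"Tconv top-50 cumulative frequency: {expansion_index(tconv_f, 50):.3f}")
ov = subset_overlap(treg, tconv)
print(f"Treg clonotypes shared with Tconv: {ov.numerator}/{ov.denominator} = {ov.percent:.1f}%")

cohort, gt2 = simulate.gen_survival_cohort(n=300, beta=0.7, seed=42)
table = screen(cohort, gt2.params["gene_panel"])
print(table[["r", "passed", "os_p", "os_direction"]].round(4))
```

prints:

```
NI Treg: 1000 clones -> 885 after filtering
NI Tconv: 1000 clones -> 900 after filtering
Treg top-50 cumulative frequency: 0.769
Tconv top-50 cumulative frequency: 0.279
Treg clonotypes shared with Tconv: 170/1000 = 17.0%
                 r  passed    os_p os_direction
gene
CD80        0.8843    True  0.0000         poor
CCR8        0.8409    True  0.0293         good
HAVCR2      0.8175    True  0.3853         poor
GENE_NULL1  0.8659    True  0.1850         good
GENE_NULL2  0.8063    True  0.0603         good
```

The Treg repertoire is markedly more clonally expanded than the Tconv one
(top-50 mass 0.77 vs 0.28, the Zipf exponents the generator plants); 17% of
Treg clonotypes are shared with Tconvs (the planted pTreg-like sharing
fraction); and the survival screen recovers the planted risk gene (CD80:
high CD80:FOXP3 ratio → poor overall survival, log-rank p < 1e-4) while the
null genes stay near their nominal behavior.

A CLI mirrors the library:

```bash
tregpipe simulate repertoires --out sim/ --seed 1
tregpipe tcr overlap sim/P1_NI_Treg.tsv sim/P1_NI_Tconv.tsv --raw
tregpipe run --out run1/ --seed 7          # full pipeline + manifest
```

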