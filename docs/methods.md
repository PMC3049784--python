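# Methods

## Study design being emulated

CD34+ cells from three tissues — bone marrow (BM), mobilized peripheral
blood (MPB), umbilical cord blood (UCB) — sorted into G0 and G1
cell-cycle fractions.  Expression: 3 replicates per (tissue, phase)
group, 18 arrays, 43,356 probes.  Proteomics: label-free LC/MS
intensities for 646 proteins, 3–5 biological replicates per group (we
fix 4, the midpoint), each protein carrying an identification-quality
priority rank 1–4.  Sort purity is checked by qRT-PCR of Ki67, which
must be 90–95% lower in G0 than in G1 cells.

## Intensity model of the simulator

Each feature *i* has a baseline `b_i ~ Normal(μ_b, σ_b)` on the log2
scale (defaults μ_b = 8, σ_b = 2 for arrays; 20 ± 2 for LC/MS, mimicking
typical fluorescence vs spectral-intensity magnitudes — the scale is
irrelevant after median normalization).  A sample of phase G0/G1 in
tissue *t* measures

    log2 x_ij = b_i ± e_it / 2 + ε_ij,   ε_ij ~ Normal(0, σ_noise)

with `+` for G0 and `−` for G1, so the expected G0/G1 ratio is exactly
`2^{e_it}`.  `e_it` is the planted signed log2 effect: ±`effect_size`
where the feature is DE in tissue *t*, 0 elsewhere.  Intensities are
`2^{log2 x}` — a log-normal model, standard for both platforms, and
strictly positive by construction.

Class membership is assigned deterministically from the design (regions
in declaration order, nulls last), so Venn-region sizes are exact for
every seed; only the noise is random.  Defaults: `effect_size = 2`
(4-fold) for genes, `1` (2-fold) for proteins, `noise_sd = 0.1`.  At
those settings a planted feature sits ~24 standard errors from the null,
so DE recovery is deterministic in practice and the printed counts
reproduce exactly; the `analysis/05` script maps how recovery degrades
when noise grows toward the effect size.  Engraftment-class features
have planted effect exactly 0 in UCB — an idealization of "unchanged in
UCB" (observed UCB ratios in the source data hover near 1 rather than
at 1).

The replica design pins every printed margin: per-tissue DE totals
10,256 / 1,705 / 2,685 with direction splits 4522/5734, 840/865,
1432/1253; BM∩MPB = 643 containing a triple overlap of 159; pattern
classes 132/207/54/91.  Two quantities are *not* printed anywhere and
were fixed once: the BM∩UCB-only and MPB∩UCB-only regions (set to 0,
single-tissue counts absorb the remainder) and the direction split of
the 159 triple-overlap genes (80/79, the split that satisfies all three
per-tissue margins simultaneously).  Ki67 is generated as one scalar
per (tissue, phase) group — it is measured by qRT-PCR, not on the
array — with G0 = (1 − reduction) × G1, default reduction 0.93.

What the simulator does **not** model: probe cross-hybridization, batch
or dye effects, missing values, intensity-dependent variance, probe-to-
gene multiplicity, or raw spectra.  Passing tests therefore demonstrate
the correctness of the inference chain (normalization, testing,
set algebra, classification, clustering, FDR logic) under a clean
log-normal signal — not robustness to real-array artifacts.

## Statistical choices

**DE caller.** The original arrays were analyzed with a proprietary
per-probe error model; we substitute a two-sample unequal-variance
(Welch) t-test on log2 median-normalized intensities — the closest
transparent standard — and state it as a deliberate divergence.  Fold
change is the ratio of *linear* normalized group means, reported as
G0/G1.  "At least two-fold" is inclusive (`≥ 2`).  No multiple-testing
correction on the gene side (the source design thresholds raw p at
0.01 together with the fold filter); a Benjamini–Hochberg switch exists
but is off by default.

**Welch small-sample conservatism.** With 3 replicates per group the
Satterthwaite df is itself estimated from the data and the Welch test
is conservative: on simulated global nulls the realized type-I rate at
p < 0.01 is ≈ 0.005, while Student's t — whose equal-variance
assumption the generator satisfies exactly — is calibrated at 0.0098.
The calibration test asserts exact calibration for the
matched-assumption Student test and one-sided control for the shipped
Welch caller.  Conservatism only reinforces the fold-change filter; it
cannot inflate the planted counts.

**Degenerate variance.** When both groups have zero variance the t
statistic is undefined; the convention is p = 0 for unequal means and
p = 1 for identical groups (only reachable with noiseless input).

**Protein caller.** Fold change is `max/min` of the group means (≥ 1 by
definition, matching how differential protein expression is quoted as
largest-to-smallest intensity ratio), thresholded at 1.5 on the linear
scale; significance via Welch t + BH over the tested (priority-
filtered) set at FDR < 5%.  The upstream quantification algorithm of
the source data is proprietary; this stand-in feeds the same set-logic
layer, which is what the package exists to test.  The "62 BM DE
proteins" vs "25 at priorities 1–2" counts are reconciled as two
priority filters over the same calls; the replica design plants both
layers (37 extra BM-only DE proteins at priorities 3–4).

**Subtraction semantics.** Membership-based: a gene DE in UCB in *any*
direction is subtracted from BM∩MPB.  Under membership semantics the
identity `|targets| = |BM∩MPB| − |triple|` is exact.  A direction-aware
variant (UCB removes only when its direction matches BM) is exposed via
`identify_targets(..., direction_aware=True)` for sensitivity analysis.

**Ki67 gate.** Inclusive at 90% reduction, no upper rejection bound:
the quoted 90–95% band describes observed purity; a purer sort cannot
invalidate itself.

**Clustering.** Average linkage on Euclidean distances between log2,
per-feature mean-centered profiles of the normalized intensities
(ratio-based profiles are a reasonable alternative; mean-centered
log-intensities were chosen as the convention of the viewer software
family this style of heat map comes from).  Rows are sorted by feature
id before linkage so distance ties break lexicographically and the tree
is deterministic.  Average-linkage merge heights are monotone, and the
exported Newick encodes them as ultrametric branch lengths.

**Concordance.** A pure join: proteins whose mapped gene id lies in the
gene DE set.  The id map is partial by design; unmapped proteins
(hypothetical/putative identifications) are counted separately, never
as mismatches.

## Problem sizes in tests and scripts

The acceptance-style tests and `scripts/acceptance.py` run the full
43,356-feature replica (a few seconds of compute).  Unit and property
tests use reduced universes (10–2,000 features; 16,000 for pipeline
determinism runs) that keep the complete planted region structure where
the test needs it.  Calibration loops pool 25 seeds × 2,000 null
features (type-I) and 80–100 null protein tables (FDR), sizes at which
binomial/Monte-Carlo error bounds in the assertions are meaningful.

## Known limitations

- One probe = one feature; probe-to-gene collapsing is out of scope, so
  "genes" in outputs means array features.
- The proprietary error models behind the original p-values cannot be
  reproduced; real-data counts would differ from planted-replica counts
  wherever those models disagree with Welch + BH.
- The simulator's UCB-effect idealization (exactly 0) makes the
  subtraction cleaner than on real arrays, where near-threshold UCB
  calls could remove true targets.
- No external-knowledge stages (GO/pathway enrichment, stem-cell
  signature comparisons) — they depend on curated databases, not on the
  inference logic implemented here.
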