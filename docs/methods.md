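# Methods

## The estimation problem

Two G-protein-coupled receptors, the ghrelin receptor (*Ghsr*) and the
cannabinoid receptor type 1 (*Cnr1*), act on overlapping brain circuits, and
the cells co-expressing both are candidates for integrated signaling. A deep
droplet scRNA-seq atlas measures both genes well but carries no anatomy; a
MERFISH-style spatial dataset carries anatomy (structures of the Allen
common coordinate framework) but a limited gene panel. Both share one
hierarchical cluster taxonomy, which makes a transfer estimator possible:
estimate per-cluster co-expression in the deep data, then distribute it over
each structure's observed cluster composition in the spatial data.

## Pipeline model and assumptions

**Positivity.** A cell is positive for gene *g* when log2(CPM) > 3, CPM
being the gene's count divided by the cell's total transcript count times
10^6. The inequality is strict, so CPM exactly 2³ = 8 is negative; zero
counts short-circuit to negative, so no pseudocount or log of zero is ever
needed (positivity only requires comparing CPM with 2^threshold). A second
rule — raw count >= 1, no normalization — matches the convention used for
smaller published scRNA-seq sets. Library size is taken from the cell
metadata when present and computed as the matrix row total otherwise; a
two-gene matrix cannot supply transcriptome totals implicitly, so synthetic
datasets always carry the metadata column.

**Transfer.** est_X(s) = Σ_c ⌊ n(c,s) · p̂_X(c) ⌋. Each (cluster,
structure) contribution is floored to its integer part *before* summing;
the alternative (floor after summing) is available behind a switch
(`apportion(..., floor_per_cluster=False)`). Flooring per contribution
follows the stated order of operations of the source procedure
(apportion per cluster, round, then summarize). Clusters observed spatially
but absent from the deep data contribute zero positives and are logged —
silently dropping them would hide taxonomy mismatches. The estimator
assumes a cluster's positive fraction is the same wherever the cluster
occurs in the brain (no within-cluster spatial gradient of expression).

**Partial-volume correction.** The spatial sections (10 µm at 200 µm
spacing) miss part of some structures; each structure carries a
covered-volume fraction f ∈ (0, 1] and corrected = raw / f. This is a ratio
estimator: it assumes the covered part of a structure is compositionally
representative of the whole.

**Calibration.** Corrected counts live on the scale of the sectioned
sample, not the brain. A single proportionality factor k maps them to
whole-brain counts, fitted by least squares through the origin against
literature-reported reference populations: k = Σᵢ litᵢ·estᵢ / Σᵢ estᵢ². A
single factor (no intercept, unweighted) is used because the relation is a
pure sampling proportion; the closed form is verified in tests against a
brute-force one-dimensional minimization. Calibrated counts are rounded
half away from zero to integers.

**Reporting.** Per structure: the three counts; double-positive percentages
relative to each gene's single-positive count (one decimal, half away from
zero; reported as *missing* — not 0.0 — when the denominator is zero, to
distinguish "no Ghsr+ cells" from "no overlap"); integer neurotransmitter
percentages of the apportioned double-positives (each cluster contributes
via its taxonomy label — GABA, GABA-Glyc, Glut-GABA, Glut, Chol, Dopa, or
none — never via marker inference); density = double-positive count /
volume; and the selection flag, strict on both cut-offs (> 350 cells and
> 50 cells/mm³). Regions roll up as [listed/total]: double-positives summed
over selected versus all structures.

## Synthetic data generator

The generator emulates the *structure* of the real inputs at desk scale,
with ground truth retained:

- **Taxonomy**: 50 clusters, 80% neuronal; neurons draw a neurotransmitter
  label (Glut 45%, GABA 30%, Dopa 10%, others 5% each), non-neurons are
  `none`.
- **Expression rates**: gene B (Cnr1-like) is broadly expressed, p_B ~
  U(0.2, 0.9) per cluster; gene A (Ghsr-like) is appreciable in 15% of
  clusters (p_A ~ U(0.01, 0.06)) and background (< 0.002) elsewhere, which
  reproduces the ~100-fold whole-dataset prevalence imbalance between the
  receptors. Co-expression is parameterized by an odds multiplier θ on the
  cell-level 2×2 table (Plackett construction; θ = 1 is independence);
  default θ = 2, a moderate enrichment consistent with a majority of
  A-positive cells being B-positive while B-positives rarely carry A.
- **Counts**: only the two genes of interest are simulated, at the scale
  the positivity rule operates on — a latent positivity indicator drawn
  from the joint, then a count conditional on the indicator that is
  guaranteed to land on the correct side of the active rule (minimum
  positive count + Poisson(2) excess when positive). Library sizes are
  lognormal (median 10^4, σ_log 0.4), typical of droplet data.
- **Spatial side**: 20 structures over five parent regions, volumes
  U(0.2, 1) mm³, 40 000 cells/mm³, a Dirichlet mixture over 10 clusters
  each. The sectioning scheme (10 µm at 200 µm spacing) observes a fraction
  thickness/interval = 5% of each structure's cells at full coverage, so
  the true calibration factor is k_true = 20; observed counts are Poisson
  with mean whole_count × 0.05 × covered_fraction. Sectioning is emulated
  as this per-structure coverage fraction, not as geometric section
  placement — the correction operates at the fraction level.
- **References**: seven populations named for the classic hypothalamic
  calibration markers, with configured true whole-brain counts; literature
  counts equal truth times lognormal noise (σ configurable, default 0,
  i.e. noise-free — the relation between literature and atlas counts is
  not specified by any source, so the noise model is a parameter rather
  than an assertion).

One integer seed drives everything through fixed, independent substreams
(`default_rng([seed, stream])`), so each generator is deterministic on its
own and identical configs produce byte-identical outputs.

**What the generator does not emulate**: transcriptome-wide expression,
doublets/ambient RNA, spatial coordinates or segmentation error,
within-cluster expression gradients, and cross-platform detection
differences between droplet and imaging-based counts. Passing recovery
tests therefore demonstrate the estimator's correctness under its own
assumptions, not robustness to violations of them on real data.

## Numerical choices

- Rounding is half away from zero throughout (numpy's default rounds half
  to even): one decimal for gene-relative percentages, nearest integer for
  neurotransmitter columns and calibrated counts. A few cells of the
  published table differ by 0.1 from this rule (consistent with truncation
  in the source); the worked examples use the self-consistent cells.
- Floor bias: 0 ≤ Σ_c n(c,s)·p(c) − est(s) < #{c : n(c,s) > 0}. At desk
  scale (n(c,s) of order 10–100 and small p_AB) this bias is a substantial
  fraction of the small double-positive counts, and after calibration it is
  amplified by k; recovery tests therefore bound estimates by
  3·SE + k·(number of contributing clusters), with SE combining the
  binomial error of the deep fraction estimates and the Poisson error of
  the spatial composition (delta method). At atlas scale (n(c,s) in the
  thousands) the same bias is negligible.
- Degenerate inputs: zero library size, genes missing from the matrix,
  cells without cluster labels, non-positive covered fractions, all-zero
  reference estimates, and double-positives without single-positives all
  raise errors naming the offending record; groups with zero
  double-positive cells report an *empty* composition, not zeros.

## Problem sizes

Default study conditions: 50 clusters × ~200 cells ≈ 10^4 deep cells,
~2.6×10^4 spatial cells over 20 structures, 7 references. The full test
suite runs in a few seconds; the acceptance script in under a minute.

## Known limitations

- The published headline atlas tallies (16 425 Ghsr+, 1 648 932 Cnr1+,
  9 554 double-positive cells) derive from ~4 million-cell datasets and are
  used here only as printed inputs to the summary arithmetic; the package
  does not re-derive them.
- Which structures received partial-volume correction in the original
  analysis, and with what fractions, is not recorded; coverage fractions
  are inputs.
- The selection filter and the region roll-up reproduce the published
  table's logic, but the published "Other" row aggregates structures that
  are not listed individually, so its bracket cannot be recomputed from
  the listed rows.
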