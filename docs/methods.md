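# Methods

This note documents the models, numerical choices and limitations behind
`dfurescue`. The package analyses a three-state clinical design — diabetic
skin without ulcer (DS), non-healing ulcer (DFUNH), healing ulcer (DFUH) —
treated as a pseudo-trajectory DS → DFUNH → DFUH. A "rescue" entity is one
whose change over the first contrast reverses over the second.

## Quality control and normalization

Cells are retained when all of the following hold: genes detected within
[500, 10,000] and total UMIs within [1,000, 100,000] (range bounds
inclusive), mitochondrial UMI fraction < 0.30 and hemoglobin UMI fraction
< 0.05 (strict, following the "< 30%" / "< 5%" notation). Mitochondrial
genes are identified by the configurable ID prefix `MT-`; hemoglobin genes
by an explicit list (HBB, HBA1, HBA2) — both are conventions, not data.

Normalization is log1p-CP10k: `norm = ln(1 + count · 1e4 / total_umi)`.
We deliberately use this simple library-size model rather than a
regression-based variance stabilization: every downstream statistic is
either a rank test, a mean, or a robust location estimate, all of which
log-CP10k serves, and the simple form keeps the scale-invariance
(per-cell count scaling changes nothing) and idempotence properties
testable exactly.

## Composition analysis

Group-level proportions divide each cell type's count by the group's total
cell count. Rescue classification uses
`l1 = log2((p_DFUNH + ε)/(p_DS + ε))` and
`l2 = log2((p_DFUH + ε)/(p_DFUNH + ε))` with threshold 0.1 on both; the
pseudo-proportion ε = 0.5/N_group (Haldane-style) guards absent cell types,
which are additionally flagged degenerate. Significance of abundance
changes uses Welch's unequal-variance t-test on per-sample proportions —
the unequal-variance form is the safer default when group sizes and
dispersions differ; samples are unpaired (different subjects). Two
degenerate rules avoid meaningless output: identical zero-variance samples
give p = 1, and fewer than two samples per group gives NaN rather than an
exception. Note that time reversal of the triple preserves the rescue
class (down-then-up read backwards is still down-then-up); it is
proportion inversion that exchanges rescue-up and rescue-down — the test
suite asserts both symmetries.

## Differential expression and rescue DEGs

Per eligible cell type (≥ 3 cells in both groups; "fewer than three"
excludes only ≤ 2) and per gene, a two-sided Mann–Whitney / Wilcoxon
rank-sum test runs on the normalized layer. Two p-value routes:

* exact enumeration of the U null when the combined sample has ≤ 16
  observations and no ties;
* otherwise a tie-corrected normal approximation with continuity
  correction plus the Edgeworth fourth-cumulant term. The U null is
  symmetric, so the first correction beyond the normal involves its excess
  kurtosis, γ₂ = −(6/5)(n₁² + n₂² + n₁n₂ + n₁ + n₂)/(n₁n₂(N+1)); adding
  `−φ(z)(γ₂/24)(z³ − 3z)` to the normal CDF keeps the two-sided p within
  ~6·10⁻⁴ of exact enumeration already at n₁ = n₂ = 8, against ~10⁻² for
  the plain continuity-corrected normal. Below n ≈ 5 no smooth
  approximation can track the (very discrete) exact law closely, but those
  cases always take the exact route anyway.

log₂FC is computed on back-transformed means with a +1 stabilizer,
`log2(mean(expm1(a)) + 1) − log2(mean(expm1(b)) + 1)`, the convention of
single-cell marker testing; a plain difference of mean logs is available
via `logfc_mode="mean_diff"`. Genes unexpressed in both groups get p = 1
and log₂FC = 0. BH adjustment is applied within each (cell type, contrast)
stratum, mirroring per-cell-type marker testing. No minimum-fraction-
expressed filter is applied by default.

Rescue DEGs are matched per (gene, cell type): rescue-up requires passing
|log₂FC| > 0.25 and adjusted p < 0.01 downward in DFUNH-vs-DS and upward
in DFUH-vs-DFUNH. Gene-level (tissue) sets are unions over cell types;
cross-tissue shared sets are intersections of those unions. The 0.25/0.01
defaults are the analysis-level cutoffs; the figure-level alternative
(0.5/0.05) is reachable through `RunConfig`.

## Trend clustering (STEM-style)

Model profiles are integer step templates: all (2c+1)^(T−1) step vectors
with steps in [−c, c], as cumulative value vectors starting at 0. When the
enumeration exceeds the profile budget m, a greedy max-min selection keeps
m representatives under the distance 1 − Pearson r (undefined correlations
against the flat profile count as distance 1), always retaining the flat
profile; ties go to the lowest enumeration id, making selection
deterministic. Defaults c = 2, m = 50.

Gene series are translated to start at 0 and assigned to the profile with
maximal Pearson correlation (constant series to the flat profile; ties to
the lowest id). Per-profile significance permutes the timepoint order —
all T! permutations when T! fits the permutation budget, sampled
otherwise — and compares the observed gene count to a binomial tail at the
mean permuted assignment frequency, Bonferroni-corrected over profiles at
α = 0.05.

A profile is a rescue-down trend when its value vector attains its global
maximum strictly inside the series with positive net change before and
negative after (rescue-up mirrored at the minimum); extrema touched at an
endpoint never qualify, and for zigzag profiles qualifying both ways the
larger excursion from the starting value decides (an exact tie is
"other"). For the three-state bulk series the timepoint order is fixed to
DS → DFUNH → DFUH, the healing narrative's order.

The cross-dataset logic intersects single-cell rescue genes with
significant bulk rescue-trend genes (direction-matched, symbols
uppercased) to give "common" genes, then removes genes showing the same
reversal during acute (non-diabetic) wound healing to give "unique" genes
specific to the diabetic process.

## Gene-set activity

Module scores bin all genes into 24 equal-size bins by mean expression;
each member gene draws 100 control genes with replacement from its bin,
and the score is the per-cell mean member expression minus mean control
expression. Calibration on effect-free simulations uses pathway-sized
(~100-gene) random sets, for which the per-set mean |score| stays below
0.05; small sets (≲ 20 genes) fluctuate more because a single member from
the heavy-tailed top expression bin moves the mean.

Preranked GSEA sorts genes by a metric (for single-cell input: log₂FC of
genes passing adjusted p < 0.05 and |log₂FC| > 0.5), walks the list adding
|metric|^p / Σ_hits |metric|^p at members and subtracting 1/(N − n_set)
elsewhere, and reports the extreme running-sum deviation as ES ∈ [−1, 1].
The null permutes gene labels (nperm = 1000 default); NES divides ES by
the mean |null ES| of the same sign, and p is the one-sided same-sign tail
with the +1 correction, which makes the p-value provably valid
(conservative). Across a collection, BH adjustment is applied and
significance requires adjusted p < 0.05 and |NES| ≥ 1.

## Cell–cell communication

For an edge (sender type, receiver type, LR pair) within one clinical
group, ligand abundance L is the Tukey trimean (Q1 + 2Q2 + Q3)/4 of
normalized ligand expression over sender cells (geometric mean across
multiple ligand genes), receptor abundance R the geometric mean over
receptor subunits of their trimeans in receiver cells, and the
communication probability the Hill mass-action form `L·R/(Kh + L·R)` with
Kh = 0.5 — monotone in both inputs, zero when either side is silent, and
bounded in [0, 1). Plain means are available via `method="mean"`.

Differential LR classification computes ligand log₂FC within the sender
type and receptor log₂FC within the receiver type (mean over subunits),
using the differential module's statistics; "within-type" is the only
biologically coherent placement since the same gene can move oppositely in
different compartments. An edge is up when both log₂FCs ≥ 0.2 and down
when both ≤ −0.2 (boundaries inclusive, matching the "≥ 0.2" rule);
edges whose sender or receiver type fails DE eligibility stay
unclassified. Rescue edges reverse class across the two contrasts.
Pathway summaries sum edge probabilities by pathway label; signaling-role
decompositions and mediator molecules are out of scope.

## Differentiation score and ROC screening

The differentiation score keeps the core signal of transcriptional
diversity: per-cell gene counts, the 200 genes (configurable) whose
expression best correlates with gene counts, their mean expression per
cell, and a rank normalization to [0, 1] (higher = less differentiated).
The original method's diffusion smoothing and NNLS regression are omitted
as refinements orthogonal to the ordering signal; subpopulations are
ordered by median score. Constant gene counts across cells give the
degenerate all-0.5 output with a flag.

ROC screening uses the Mann–Whitney identity AUC = U/(n₊·n₋) with ties
counted ½, which equals the trapezoidal area under the empirical ROC
curve exactly. When no positive class is specified the higher-mean class
is taken as positive (AUC ≥ 0.5) and flagged auto-oriented. Biomarker
calls use AUC > 0.7.

## Synthetic cohorts and what they do (not) show

`simulate_cohort` draws a three-group cohort: 3 samples per group, 200
cells per sample, 1,000 genes over 8 skin cell types. Counts are
negative-binomial (gamma–Poisson) with gene-level dispersion 0.5 — the
canonical overdispersed scRNA-seq count model, heavy-tailed enough to
exercise rank tests — with log-normal baseline means (meanlog 0, sdlog 1)
scaled to ~2,000 UMIs per cell and per-cell library factors
log-normal(0, 0.3) so QC has something to filter. Each cell type carries
5 marker genes at 5× baseline, making type identity real without
clustering. Default composition is keratinocyte-dominant (differentiated
keratinocytes 25%, stable across groups), as in real skin tissue, with
two planted composition effects: a fibroblast collapse-and-recovery
(0.20 → 0.10 → 0.18) and an M1/M2 ratio reversal (1.5 → 0.55 → 1.29).

Planted expression effects multiply the NB mean by group-specific factors:
20 rescue genes (half down-then-up at folds 0.5 / 2.0, half mirrored) in
the differentiated-keratinocyte compartment, and 3 ligand–receptor
reversals (one with a two-subunit receptor) between fibroblast senders and
basal-keratinocyte receivers. Planted genes are drawn from the top decile
of baseline expression: a fold change on a gene observed in only a few
cells per group is biologically and statistically vacuous at this
sequencing depth, and hosting the expression effects in a compositionally
stable type keeps the two planted effect classes unconfounded. All planted
effects, baselines and the seed are recorded in a JSON truth manifest.

Trend-series generators emit gene × timepoint mean matrices as
`baseline + step pattern + N(0, σ)` with σ = 0.1 by default; the acute
series plants 20 up-up-down and 20 down-down-up genes over four healing
timepoints among 160 flat background genes.

What the simulator does **not** emulate: doublets, ambient RNA, batch and
donor effects, gene–gene correlation, realistic marker co-expression
programs, or the marginals of any real dataset. Passing recovery tests
therefore demonstrates that the statistical machinery is correct and
calibrated at realistic effect sizes and depths — not that any particular
biological conclusion transfers to real cohorts.

## Determinism and seeds

Every randomized stage takes a seed; pipeline stages derive per-stage
seeds from the master seed as `(seed · 1000003 + crc32(stage)) mod 2³¹`,
so partial re-runs replay the exact random stream of a full run.
Identical (configuration, seed) pairs reproduce outputs bit for bit.

## Problem sizes used in validation

The validation suite runs the default cohort (1,800 cells before QC,
1,000 genes), 20-seed replications for null calibration and composition
recovery, 100-vector BH comparisons, full enumeration of the n₁ = n₂ = 8
rank-sum null, 100 random gene sets for GSEA calibration, and
100 random ROC instances — sizes chosen to give stable empirical rates
while keeping the whole suite fast on a laptop.

## Known limitations

* Pseudo-replication: cells are treated as exchangeable within groups for
  DE (as in the emulated analysis); donor-level random effects are not
  modeled — only the composition test operates at sample level.
* The STEM three-state "series" has T = 3, so profile space is coarse
  (9 profiles at c = 1) and permutation granularity is 1/6.
* LR scoring omits the original tool's permutation p-values on edges;
  classification rests on the log₂FC thresholds, as in the headline
  analysis being reproduced.
* The differentiation score is an ordering statistic; it does not place
  cells on a trajectory graph and cannot identify branch points.
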