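# dfurescue

Three-state "rescue" analysis of wound-healing transcriptomes.

Diabetic foot ulcers (DFUs) separate clinically into wounds that heal and
wounds that do not. Comparing only ulcer against intact skin mixes both
fates; the informative question is which features *change* when diabetic
skin (DS) becomes a non-healing ulcer (DFUNH) and then *reverse* in ulcers
that heal (DFUH). `dfurescue` implements that three-state rescue logic as a
reusable, tested pipeline for transcriptomics data — single-cell UMI counts
with cell-type labels and group-level pseudo-bulk series — aimed at
computational biologists studying chronic-wound cohorts or any other
disease / non-recovery / recovery triple.

## The rescue framework

Every analysis level applies the same two-contrast pattern. Writing
Δ₁ for the unhealing contrast (DFUNH vs DS) and Δ₂ for the healing
contrast (DFUH vs DFUNH), an entity is

* **rescue-up** if Δ₁ < 0 and Δ₂ > 0 (lost in non-healing, restored in
  healing), and
* **rescue-down** if Δ₁ > 0 and Δ₂ < 0,

with level-specific effect measures and thresholds:

| level | effect measure | thresholds |
| --- | --- | --- |
| cell-type composition | log₂ fold change of group proportions | \|log₂FC\| > 0.1, Welch t-test on per-sample proportions at p < 0.05 |
| gene expression per cell type | Wilcoxon rank-sum per gene, log₂FC of back-transformed means | \|log₂FC\| > 0.25, BH-adjusted p < 0.01 |
| pseudo-bulk trends | STEM-style model-profile clustering over the DS → DFUNH → DFUH series | profile enrichment at Bonferroni p < 0.05 |
| ligand–receptor signaling | Hill mass-action probability `L·R/(0.5 + L·R)` with trimean expression; log₂FC of ligand (sender) and receptor (receiver) | both \|log₂FC\| ≥ 0.2 |

Supporting stages: QC filtering (500–10,000 genes detected, 1,000–100,000
UMIs, mitochondrial fraction < 30%, hemoglobin fraction < 5%) with
log1p-CP10k normalization; control-binned module scores; preranked GSEA
with permutation NES (significant at adjusted p < 0.05 and |NES| ≥ 1); a
transcriptional-diversity differentiation score for subpopulation
ordering; and Mann–Whitney ROC screening (biomarker at AUC > 0.7). A
negative-binomial simulator generates labeled cohorts with planted effects
and a ground-truth manifest, so every stage is testable without any data
download.

## Worked example

```python
import dfurescue as dr

expr, truth = dr.simulate_cohort(seed=1)          # 1800 cells, 1000 genes
filtered, report = dr.filter_cells(expr)
norm = dr.normalize(filtered)
print(f"cells: {report.n_input} -> {report.n_retained} after QC")

table = dr.proportions(norm)
sizes = norm.meta.groupby("group").size().to_dict()
for r in dr.rescue_cell_types(table, thr=0.1, group_sizes=sizes):
    if r.rescue_class != "none":
        print(f"{r.entity}: {r.rescue_class} (log2FC {r.l1:+.2f} then {r.l2:+.2f}, "
              f"p = {r.p_unhealing:.3f} / {r.p_healing:.3f})")

un = dr.de_all_cell_types(norm, "DFUNH", "DS")
he = dr.de_all_cell_types(norm, "DFUH", "DFUNH")
sets = dr.call_deg_sets(un, he, logfc_thr=0.25, adjp_thr=0.01)
up, down = sets.gene_level("rescue_up"), sets.gene_level("rescue_down")
print(f"rescue DEGs: {len(up)} up, {len(down)} down")
planted = {r.gene for r in truth.rescue_genes}
print(f"planted rescue genes recovered: {len((up | down) & planted)}/20")
```

prints

```
cells: 1800 -> 1656 after QC
Fibro: rescue_up (log2FC -0.83 then +0.63, p = 0.001 / 0.010)
M1: rescue_up (log2FC -0.60 then +0.49, p = 0.056 / 0.069)
M2: rescue_down (log2FC +0.74 then -0.76, p = 0.031 / 0.041)
SMC: rescue_down (log2FC +0.54 then -0.29, p = 0.116 / 0.283)
T_lympho: rescue_down (log2FC +0.39 then -0.75, p = 0.052 / 0.010)
VasEndo: rescue_up (log2FC -0.64 then +0.22, p = 0.065 / 0.316)
rescue DEGs: 13 up, 12 down
planted rescue genes recovered: 20/20
```

The simulator planted a fibroblast collapse (proportion 0.20 → 0.10 → 0.18)
and 20 two-fold expression reversals in differentiated keratinocytes; the
pipeline recovers the composition shift (|log₂FC| well past 0.1 on both
contrasts, significant abundance change) and all 20 planted genes. The
other composition calls trace the planted M1/M2 ratio reversal and
multinomial sampling noise around the 0.1 threshold — the per-sample
t-test column is what separates supported calls from noise.

## Command line

Each stage is also exposed as a subcommand over the on-disk formats
(Matrix Market + TSV sidecars, GMT, CSV, TSV tables):

```bash
dfurescue --outdir out --seed 1 simulate
dfurescue --outdir out qc out/bundle
dfurescue --outdir out composition out/filtered
dfurescue --outdir out de-rescue out/filtered
dfurescue --outdir out stem out/acute_series.tsv
dfurescue --outdir out cellcomm out/filtered out/lr_database.csv
dfurescue --outdir out run-all
```

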