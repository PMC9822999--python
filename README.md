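# cytospatial

Spatial and statistical analysis of multiplexed-imaging cell tables for
contrasting tumor immune microenvironments — in particular exhausted
(IE1, with PD-1^high T cells) versus non-exhausted (IE2) breast-tumor
immune environments — together with a ground-truth synthetic generator
that makes every stage testable without any image data.

## Who this is for

Computational biologists working with imaging mass cytometry (IMC) or
similar segmented single-cell imaging data: one row per cell with μm
centroid coordinates, an approximate cell radius, a cell-type label,
marker intensities, cytokine mRNA probe counts including the *DapB*
negative-control probe, and (optionally) gene counts for
signature/crosstalk analyses.

## What it computes

- **Cytokine calling** — per cell and cytokine, the difference
  `d = count_cytokine − count_DapB` is compared against an empirical
  null built by symmetrizing the non-positive tail of the difference
  distribution (`{d ≤ 0} ∪ {−d : d ≤ 0}`); upper-tail empirical
  p-values (add-one smoothed) are Benjamini–Hochberg corrected per
  cytokine and a cell is *expressing* when `q < 0.01`.
- **Neighbor graphs** — contact graph (cell circumferences expanded by
  8 μm, overlap ⇒ neighbors; on the disk model
  `dist ≤ r_i + r_j + 2·8 μm`), 25 μm fixed-radius graph, and
  k-nearest-neighbor lists (k = 10, deterministic tie-break).
- **Cytokine patches and milieus** — patches are connected components
  (≥ 3 cells, 25 μm rule) of cells all expressing a cytokine (or any
  cytokine); milieus extend patches by 30 μm. Per image, cell-type
  enrichment/depletion in milieus is a two-sided Fisher's exact test at
  p < 0.01, summarized across images as % enriched − % depleted.
- **Pairwise neighborhood analysis** — for every ordered cell-type pair
  (A, B), the mean number of B contact-neighbors per A cell is compared
  to a null from 1000 label permutations per image (the permutation null
  conditions on type frequencies); interaction/avoidance at p < 0.01.
- **kNN composition, contact and distance statistics** — composition of
  the 10 nearest neighbors per T-cell subtype stratified by TLS status;
  fraction of PD-1^high vs PD-1^low T cells with ≥ 1 migDC direct
  neighbor (exact paired Wilcoxon over patients); distance to the
  nearest T cell; proportion of PD-1^high cells among the 10 closest
  T cells (T_regs excluded).
- **Gene-signature scores** — `score = Σ_g log(1 + 10⁴·x_g/total)` for
  T-cell-attraction, T-cell-suppression, M1, M2 and seeded random
  control signatures, with Spearman correlations (exact p for small n).
- **Ligand–receptor crosstalk** — regularized geometric-mean score
  `√(l·r) / (μ + √(l·r))` over a curated LR list; interactions counted
  at score ≥ 0.4; pair-specific interactions by top-100 / top-5
  coefficient of variation; per-patient IE1-vs-IE2 enrichment by exact
  Wilcoxon rank-sum (p < 0.05, mean score > 0.4).
- **IE comparison** — any per-image feature is averaged per patient and
  compared between IE groups with the exact two-sided Wilcoxon rank-sum
  test (medians and IQRs reported).

The synthetic generator plants all of this structure with known ground
truth: Poisson probe backgrounds (`DapB ~ Pois(λ0)`, expressers get
`Pois(λ0+Δ)`), clustered cytokine expressers with a 5:1 IE1:IE2
expressing-cell contrast, Thomas-process attraction and thinning-based
avoidance, TLS-like B-cell aggregates, co-elevated signature genes in
designated myeloid cells, and IE1-boosted checkpoint ligands.

## Worked example

```python
from cytospatial.synthetic import SimConfig, simulate
from cytospatial import calling, patches
from cytospatial.pipeline import ie_compare

cfg = SimConfig(seed=1, n_patients_per_ie=7, images_per_patient=2,
                cells_per_image=3500, with_genes=False, with_markers=False)
ds, truth = simulate(cfg)                      # 98,000 cells, 28 images
calls = calling.call_cytokines(ds, alpha=0.01)

print(patches.expressing_fractions(calls, ds).to_string(index=False))
comparison = ie_compare(patches.expressing_fraction_per_image(calls, ds), ds)
print(comparison.to_string(index=False))
```

prints

```
ie_label  n_cells  n_expressing  fraction
     IE1    49000          1207  0.024633
     IE2    49000           243  0.004959
            feature  n_ie1  n_ie2  median_ie1  iqr_ie1  median_ie2  iqr_ie2        p
expressing_fraction      7      7       0.025 0.001643    0.004571 0.001429 0.000583
```

i.e. the fraction of cells called cytokine-expressing is ~5× higher in
IE1 than IE2 (the planted contrast), and the patient-averaged exact
rank-sum test flags the difference at p = 2/C(14,7) ≈ 5.8 × 10⁻⁴, the
smallest two-sided p attainable with 7 patients per group.

The same pipeline is available from the shell:

```sh
cytospatial all --out runs/demo --seed 7
cytospatial simulate --out runs/demo2 --config my_run.yaml
```

Each stage writes tidy CSVs (`calls.csv`, `patches.csv`,
`enrichment.csv`, `interactions.csv`, `composition.csv`, `scores.csv`,
`ie_enriched.csv`, `ie_comparison.csv`, …) plus `report.json` and the
fully serialized `config.yaml`; re-running an identical configuration
reproduces every output byte for byte.

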