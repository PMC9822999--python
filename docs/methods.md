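# Methods

This note documents the models implemented in `cytospatial`, the
parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions that make every run
reproducible.

## Data model

A dataset is three tables. Cells carry continuous μm centroid
coordinates (origin top-left, y downward, 1 px ≡ 1 μm), an approximate
equivalent-circle radius standing in for segmentation-mask extent, a
cell-type label from a declared palette, and prefixed measurement
columns (`mk_` marker intensities, `cy_` cytokine probe counts with
`cy_DapB` as the negative control, `gx_` gene counts). Images are
1 mm × 1 mm regions by default with a TLS status in
{none, immature, mature}; patients carry the immune-environment label
(IE1 = exhausted, with PD-1^high T cells; IE2 = non-exhausted). Cells
are modelled as disks because the pipeline consumes tables, not masks;
this is the minimal geometry that supports a contact rule. An optional
quality rule reports (never silently removes) cells with disk area
outside 8–600 px².

## Cytokine expression calling

For cytokine *k* and cell *i*, `d_ik = count_ik − count_i,DapB`. Under
exchangeable probe noise a non-expressing cell has `d` symmetric about
zero, so the null is estimated per cytokine by reflecting the
non-positive tail of the empirical differences:
`null = {d ≤ 0} ∪ {−d : d ≤ 0}`. The p-value is the upper-tail
empirical probability with add-one smoothing (minimum attainable p is
`1/(n_null+1)`), Benjamini–Hochberg corrected per cytokine across all
cells (per-cytokine families, because prevalence differs by probe), and
thresholded at q < 0.01. The null pools cells dataset-wide by default;
a per-image option exists because it is not obvious which is
preferable when staining efficiency varies between images.

**Operating characteristics.** The call is made per cell from a single
count pair, so its power is bounded by the overlap of the count
distributions. With background rate λ0 = 1 and boost Δ = 5 (expresser
counts ~ Pois(6)), even the Neyman–Pearson oracle on the raw count
reaches only ≈0.85 sensitivity at 2% false-positive rate
(`P(Pois(1) ≥ 4) = 0.019`, `P(Pois(6) ≥ 4) = 0.849`); under BH-FDR
0.01 the realized sensitivity is ≈0.4 at 10% prevalence, and lower at
lower prevalence. The false-call rate stays well below 1%. Downstream
contrasts are robust to this: sensitivity attenuates both IE groups
equally, so the called expressing-fraction *ratio* recovers the planted
ratio almost unbiasedly (see the acceptance outputs). Note also that
BH with an empirical null needs enough cells to resolve small
p-values; at fewer than ~50k cells per family and ~1% prevalence the
procedure is intentionally conservative and may call nothing.

## Neighbor structures

Three explicit rules, all boundary-inclusive (≤) and exactly equal to
their brute-force definitions (KD-trees are only an index):

- **contact**: `dist(i,j) ≤ r_i + r_j + 2·e` with expansion e = 8 μm.
  Both cells are expanded because the mask-expansion procedure expands
  every cell's circumference; whether the disk analogue should carry
  one or two 8 μm slacks is not decidable from a mask-based
  description, so `mode="single"` provides the alternative.
- **radius**: centroid distance ≤ 25 μm (patch neighbor rule).
- **knn**: the k = 10 nearest other cells, optionally restricted to a
  candidate type set and/or excluding types (e.g. the ten closest
  T cells excluding T_regs); distance ties break by ascending cell_id
  so results are bit-reproducible; short candidate lists are returned
  as-is with the candidate count.

No border correction is applied: cells near image borders simply have
truncated neighborhoods, matching per-ROI analysis practice.

## Patches, milieus, enrichment

Patch = connected component (chains allowed, not cliques — a clique
reading would make large patches geometrically impossible) of ≥ 3
qualifying cells in the 25 μm graph; qualifying means expressing the
named cytokine (specific) or any cytokine (general). Milieu = all
cells within 30 μm (centroid-to-centroid) of any patch member, patch
included. Per image and milieu kind, the milieus are merged into one
in-milieu indicator so each cell is counted once, and cell-type
enrichment uses the conditional two-sided Fisher exact test (p < 0.01,
direction by the sample odds ratio; degenerate margins give p = 1).
Only images containing both the cell type and the milieu kind count
toward the cross-image summary (% enriched − % depleted). The
fraction of cytokine⁺ cells of selected types lying inside specific
patches is reported per image and aggregated by TLS status.

## Pairwise neighborhood permutation test

Statistic: mean over A cells of the number of B neighbors in the
contact graph (directional; both (A,B) and (B,A) are evaluated; A cells
with zero neighbors stay in the average — excluding them would bias
toward interaction). Null: 1000 uniform permutations of the image's
type labels with the graph fixed; permuting labels conditions on the
observed type counts, which is precisely the correction for relative
cell-type frequency. One shared permutation stream per image evaluates
all pairs jointly (efficiency and joint reproducibility).
`p_high = (1 + #{perm ≥ obs})/(1 + n_perm)`, `p_low` analogously;
interaction if `p_high < 0.01`, avoidance if `p_low < 0.01`; if both,
the smaller p wins and exact ties are not significant. A
total-count variant of the statistic is available. No multiplicity
correction is applied across pairs or images (raw p thresholding is the
convention this analysis follows); the summary reports, per pair, the
fraction of images called interaction minus called avoidance.

## Gene signatures

`score_c = Σ_{g∈sig} log(1 + 10⁴ · x_gc / total_c)` — counts-per-10k
normalization with natural log and pseudocount 1 (the concrete
realization of "normalized by total count and log-transformed"; base
and pseudocount are not externally fixed, and the scale is
configurable). The score is invariant under uniform per-cell count
scaling and strictly increasing in any signature-gene count at fixed
total. Shipped signature files (T-cell attraction, T-cell suppression,
M1, M2; six genes each) are editable placeholders for user-supplied
lists. Score agreement uses Spearman correlation at cell, cluster, or
patient level; p-values are exact by permutation enumeration for
n ≤ 9 (full enumeration at the n = 12 sometimes quoted for exactness
would require 479M permutations; 9! = 362,880 is the practical limit)
and t-approximate beyond.

## Ligand–receptor crosstalk

Score `√(l·r)/(μ + √(l·r))` with l, r the mean library-normalized
ligand/receptor expression in sender/receiver and μ the global mean of
the expression matrix (configurable): bounded in [0,1), 0.5 at
l = r = μ, monotone in both means. "True" interactions are scores
≥ 0.4. Specificity: per type pair, the 100 top-scoring pairs are
ranked by the coefficient of variation of their scores across all type
pairs and the top 5 kept (name-order fallback, flagged, when all CVs
vanish). The IE comparison scores each patient separately (types with
< 10 cells in a patient are skipped) on coarse metaclasses
(T/NK, myeloid, tumor, stromal, B lineage) — fine T subtypes routinely
fall below the per-patient cell minimum — and applies the exact
two-sided Wilcoxon rank-sum per (type pair, LR pair), retaining
p < 0.05 (uncorrected, deliberately) with overall mean score > 0.4.
Autocrine vs paracrine is labelled by sender == receiver. The shipped
20-pair curated list covers checkpoint (PD-L1/PD-1, CD80/CTLA-4,
Gal-9/TIM-3, PVR/TIGIT), chemokine and cytokine axes; users can
substitute their own.

## IE comparison harness

Per-image features are averaged per patient and compared between IE
groups by the exact two-sided Wilcoxon rank-sum test, with group
medians and IQRs. This patient-averaged rank test (rather than a
mixed-effects model) is the package's comparison procedure: it is
assumption-light, exact at cohort sizes of ~7 per group, and matches
the fallback used when mixed models fit poorly.

## Exact tests

Rank-sum: full enumeration of label assignments (mid-ranks for ties)
when both groups are ≤ 10 and C(n+m, n) ≤ 250k; normal approximation
otherwise. Signed-rank: zeros dropped; exact null via dynamic
programming over doubled (integer) ranks — identical to enumerating
all 2ⁿ sign assignments — for n ≤ 25. Two-sided p is the null mass at
least as far from the null mean as observed, with a 1e-9 tolerance so
mid-rank ties are not lost to floating-point noise. All-zero paired
differences are undefined and reported as p = 1 with a warning.

## Synthetic generator

The generator emulates the statistical skeleton the analyses assume,
per image (default 1 mm², 4000 cells; 7 patients per IE × 4 images):

- **Composition**: multinomial with per-IE type frequencies; IE1
  carries ~7% PD-1^high T cells, IE2 ~1% — the defining contrast.
- **Probe counts**: `cy_DapB ~ Pois(λ0=1)`; each cytokine adds
  `Pois(Δ=5)` for expressers. Poisson is the simplest noise model
  under which the difference statistic is well-behaved.
- **Expressers**: per-cytokine fractions (defaults 1.5% each in IE1,
  0.3% in IE2, ten cytokines) claim *disjoint* cell sets, so the
  fraction of cells expressing ≥ 1 cytokine is their sum (15% vs 3%, a
  5:1 ratio undiluted by overlap). A Poisson number of compact
  clusters (4–8 cells nearest a random center, nominal spread 15 μm)
  seeds future patches; the rest are dispersed.
- **Attraction** (default migDC ↔ PD-1^high CD8 T): fraction θ = 0.8 of
  both types placed around shared uniform parents with σ = 20 μm
  (Thomas-type process — O(n), strength interpretable, sufficient to
  power the permutation test; Gibbs models would be overkill).
- **Avoidance** (default tumor vs B, θ = 0.9): tumor cells form nests
  (70% around parents, σ = 60 μm); B proposals within 40 μm of a tumor
  cell are rejected with probability θ and re-drawn.
- **TLS**: mature = 70% of B cells in a dense 80 μm disc; immature =
  loose Gaussian aggregate with σ = 120 μm.
- **Radii**: log-normal, median 5 μm, clipped to [2, 15] μm (plausible
  cell sizes; only the contact rule consumes radii).
- **Genes**: ~100 genes — signature genes, curated LR genes, and 60
  housekeeping filler genes at rate 1. The filler complement is sized
  so that any 6-gene signature is a minor fraction of the per-cell
  library; with a much smaller background, disjoint normalized scores
  anti-correlate through the shared denominator (a compositional
  artifact absent from transcriptome-scale data). 30% of
  myeloid/migDC cells carry ×8 co-elevated attraction *and*
  suppression genes (producing the positive score correlation);
  checkpoint/chemotactic ligands are ×3–4 boosted in IE1 patients,
  FLT3LG ×3 in IE2.

Identical configuration ⇒ byte-identical output. Ground truth records
expresser flags, planted cluster members, the pair-effect table, and
signature-positive cells.

**What is not emulated**: pixel-level images and segmentation error,
marker spillover, spatially varying cell density and tissue
architecture beyond the planted structures, transcriptome-wide counts,
batch effects, and any coupling between cytokine expression and cell
type (expressers are drawn uniformly across types). Passing tests on
this generator therefore validate the *statistical machinery* — exact
tests, graph constructions, calibration, power against planted
effects — not biological conclusions about real tissue.

## Problem sizes and determinism

The test suite and the acceptance script run on reduced but honest
sizes chosen as the package's standard analysis conditions: 1500–3500
cells per image and 2 images per patient for power/calibration runs
(the permutation statistic is image-local, so power depends on per-image
density, which stays realistic), 10k-cell images for calling operating
characteristics, and 10 generator seeds for seed-fraction summaries.
All randomness flows from one root seed through stage-name-hashed
substreams (`pipeline.stage_seed`); re-running any configuration
reproduces outputs byte for byte, and CSV floats are written with 10-12
significant digits (round-trip differences ≤ 1e-9 relative).

## Known limitations

- Per-cell cytokine calling sensitivity is fundamentally limited at
  low boost-to-background ratios (see operating characteristics above).
- The milieu uses centroid distances; mask-border dilation would differ
  near large cells.
- The empirical-null calling is conservative on small datasets.
- Spearman p-values are exact only to n ≤ 9.
- The curated LR list is deliberately small; results on real data
  should use a full database via `load_lr_pairs(path)`.
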