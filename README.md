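# imctme

Spatial tumour-micro-environment analysis of imaging-mass-cytometry (IMC)
single-cell data.

## What this package is for

Multiplexed tissue imaging (IMC: ~35 metal-tagged antibodies at ~1 µm
resolution) yields, after segmentation, a *marked point pattern* per region
of interest (ROI): one centroid and one raw mean intensity vector per cell.
`imctme` implements the downstream quantitative workflow used to compare
tumour cohorts — here modelled on vestibular schwannoma, a Schwann-cell
tumour dichotomized into *static* (< 20% volume change/year) and *growing*
(≥ 20%/year) cases — from such tables:

1. **Quantification** — per-marker scaling of raw intensities to the
   cohort-wide 99.9th percentile (clipped to [0, 1]), cell densities per mm²,
   and normality-gated statistics: Shapiro–Wilk, then two-tailed
   Pearson/Spearman correlation with linear regression against growth rate,
   and t-test / Mann–Whitney / 2-way ANOVA for group comparisons.
2. **Phenotyping** — Leiden clustering of normalized expression on a kNN
   graph, followed by declarative rule-table annotation (e.g. alternatively
   activated TAMs: CD16ʰⁱ CX3CR1ʰⁱ CD163⁺ CD11b⁺) into six hierarchical cell
   types and ~15 granular populations, with sub-clustering of Ki-67⁺
   proliferative cells.
3. **Cell neighbourhoods** — per ROI, a Delaunay graph pruned at the 99th
   percentile of edge lengths; each cell's neighbourhood is all cells within
   l = 3 graph steps, summarized by composition, shape, distribution and
   proximity features; neighbourhoods clustered by a Gaussian mixture model
   whose K is selected by Fowlkes–Mallows (FMI) stability over subsampled
   refits; clusters annotated tumour-/vasculature-/immune-enriched
   (fold-change FC ≥ 1) and proliferative; inter-neighbourhood affinity
   scored as observed/expected edge counts against a label-permutation null.
4. **Spatial association** — quadrat correlation matrices (100 µm quadrats,
   Pearson on counts, Benjamini–Hochberg gated at 0.05) and border-corrected
   cross-pair correlation functions

       ĝ(r) = |W| / (n_A·n_B) · Σ_{a∈A} N_[r,r+dr)(a) / area_W(a; r, r+dr)

   over r = 0–300 µm with a 95% bootstrap CI; a pair is called positively
   (negatively) associated when the CI at the bin containing r = 20 µm lies
   above (below) 1. Pairs significant under both screens form a directed
   adjacency network weighted by g(r = 20 µm) and % connections.
5. **Synthetic cohorts** — a simulator producing multi-ROI marked point
   patterns with known ground truth: Poisson, Thomas (clustered) and linked
   (cross-attracting) populations, lognormal marker noise, planted
   density–growth slopes and planted neighbourhood mosaics, so every stage
   is testable without any data download.

The packaged fixtures transcribe the study cohort's clinical table (nine
cases: four static, five growing, growth rates −40.00 to 266.67 %/yr) and
its 35-antibody panel.

## Worked example

```python
import imctme as it

scenario = it.default_scenario(seed=7, roi_width_um=400, roi_height_um=400,
                               rois_per_case=2)
table, cases, geometry, truth = it.simulate_cohort(scenario)
print(f"simulated {table.n_cells} cells, {len(cases)} cases, "
      f"{len(geometry)} ROIs")

table = it.normalize_expression(table)          # 99.9th-percentile scaling
labelled, assignment = it.phenotype(table, seed=0)

dens = it.cell_density(labelled, geometry, stratum="case×population")
tam = {c.case_id: dens[(c.case_id, "alt_act_tam")] for c in cases}
res = it.correlate_with_growth(tam, cases)
print(f"alt. act. TAM density vs growth rate: {res.method} "
      f"r = {res.r:.2f}, p = {res.p_two_tailed:.4f}, "
      f"slope = {res.slope:.2f} cells/mm^2 per %/yr")
```

prints

```
simulated 11168 cells, 9 cases, 18 ROIs
alt. act. TAM density vs growth rate: spearman r = 0.53, p = 0.1392, slope = 1.09 cells/mm^2 per %/yr
```

The simulator plants a positive density–growth slope for alternatively
activated TAMs; the recovered correlation is positive (r = 0.53) but, at
nine cases and two small 0.16 mm² ROIs each, not individually significant —
the expected behaviour at this sampling depth (the sign-recovery rate
across replicates is one of the quantities the acceptance script measures).
The Spearman branch was chosen automatically because the growth rates fail
Shapiro–Wilk normality.

The same workflow is available as a CLI over YAML configs:

```bash
imctme run-all --outdir out --seed 7
imctme simulate --outdir out2 --seed 1      # individual stage verbs
```

Each run writes CSV artifacts and a `manifest.json` recording the config
hash and seed; identical config + seed reproduces every output byte for
byte.

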