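# Methods

This note documents the models, estimators, numerical choices and known
limitations of `imctme`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A cohort is a set of cases, each with several rectangular ROIs. Coordinates
are continuous µm with the origin at the ROI top-left corner and y
increasing downward (image convention). ROI geometry is supplied explicitly
in metadata rather than inferred from coordinate extrema, because the
extrema of a sparse pattern underestimate the imaged area and would bias
per-mm² densities upward. Cases are classified *growing* iff the
preoperative volumetric growth rate is ≥ 20 %/year; stored classification
columns are always recomputed from this rule and discrepancies logged.

## Expression normalization

Raw mean intensities are scaled per marker to the pooled, cohort-wide
99.9th percentile P (linear interpolation between order statistics) and
clipped: `norm = min(raw, P)/P ∈ [0, 1]`. Pooling across the cohort (not
per ROI or per case) keeps per-case averages on a common scale, which the
downstream per-case averaging presupposes. Values above P are clipped to 1
rather than allowed to exceed it, so the output is genuinely bounded. A
marker whose percentile is 0 maps to all-zeros with a warning.
Normalization is scale-equivariant (raw × k gives identical output) and
idempotent once the scaling value is fixed.

## Phenotyping

Cells are clustered with Leiden (RBConfiguration partition, resolution 1.0
by default, seeded) on a union-symmetrized Euclidean k-nearest-neighbour
graph (k = 15) of the normalized expression vectors. Neither the resolution
nor k is a published constant of the underlying study design; both are
config values.

"Manual annotation" is mechanized as a declarative rule table so runs are
reproducible. Cluster mean profiles are z-scored per marker **across
clusters** (population sd, ddof 0); a rule's expectations are evaluated as

* `high`: z ≥ +0.5, `low`: z ≤ −0.5,
* `pos`: cluster mean strictly above the across-cluster median,
  `neg`: strictly below, `any`: ignored.

A rule matches only if *all* expectations hold; among matching rules the one
with the most non-`any` expectations wins, ties broken by table order.
Unmatched clusters are `other`; clusters with equal labels are merged
(`merged_from` records the provenance). Two levels are applied to the same
partition: a coarse table producing six hierarchical types (myeloid,
neoplastic, lymphoid, vascular, proliferative, other) and a granular table
producing ~15 populations; proliferative cells are Leiden-re-clustered and
annotated with a third table (proliferative alternatively activated TAMs,
transitioning monocytes, PD-L1⁺ Schwann cells).

Two caveats shape the shipped default tables. For a marker expressed in k
of n clusters, the background z is −√(k/(n−k)); a `low` gate therefore
only separates cleanly when k/n ≳ 1/5, and rules keyed on a population's
positive markers are more robust to how finely Leiden splits the data.
Similarly `pos`/`neg` are unreliable for markers at indistinguishable
background level in more than half the clusters (the median ties). The
classically-activated-TAM rule consequently keys on CD68⁺ CD56⁺ CD74-high;
its CD16-low/CX3CR1-low contrast with the alternatively activated signature
is kept as documentation, and the full negative-gated signature remains
available to users via custom rule tables.

## Cell neighbourhoods

Per ROI, cells are joined by Delaunay triangulation and long links removed
at the 99th percentile of that ROI's edge lengths (per ROI because cell
density differs across ROIs). The percentile is the `higher` order
statistic, so only edges strictly beyond it are removed and degenerate
small graphs keep all edges; duplicate coordinates are jittered by ≤ 1e−6
µm; fewer than three (or collinear) cells fall back to a complete graph.
A cell's neighbourhood is every cell within l = 3 graph steps (BFS,
inclusive of the target).

Feature groups (this package's concretization; all config-switchable):

* **composition** — fraction of each population among members (sums to 1);
* **shape** — convex-hull area (µm²) and circularity 4πA/P² ∈ (0, 1];
  neighbourhoods of < 3 cells or degenerate hulls get area 0, circularity 1;
* **distribution** — mean and sd of member distances to the neighbourhood
  centroid (µm);
* **proximity** — mean length of graph edges internal to the neighbourhood.

Features are z-scored, and the geometry groups (shape, distribution,
proximity) are additionally scaled by 0.25 before clustering. Composition
is the primary discriminator; at equal weight, the geometry features —
which vary smoothly in space (window-edge truncation, domain boundaries)
and have near-degenerate directions — dominate the GMM likelihood and
planted domain structure is unrecoverable. For the same reason each GMM
component's covariance is floored at `reg_covar = 0.1` (on the z scale),
preventing tiny-variance geometry directions from absorbing the fit.

Clustering is a full-covariance Gaussian mixture, k-means initialized. K is
selected by stability: for each candidate K, 10 fits on random 80%
subsamples; the score is the mean pairwise Fowlkes–Mallows index of their
labellings restricted to shared cells; the highest-scoring K wins, ties to
the smaller K (parsimony). The default K range starts at 2 because a
one-component model has FMI ≡ 1 and would always win. The final model is
refit on all cells with a fixed seed, taking the best of 10 k-means
restarts (deterministic given the seed).

FMI = TP/√((TP+FP)(TP+FN)) over item pairs, computed from the contingency
table; two all-singleton partitions have no co-clustered pair and score 0
by convention (matching scikit-learn's implementation, which serves as an
independent cross-check in the tests).

Cluster annotation: FC(population, cluster) = within-cluster frequency /
overall frequency; populations with FC ≥ 1 are enriched; the cluster's
category is the compartment (tumour = neoplastic, vasculature = vascular,
immune = myeloid + lymphoid) with the largest summed enriched FC, and it is
proliferative if any proliferative population is enriched.

Neighbourhood proximity: observed(a,b) counts retained edges joining
clusters a and b pooled over ROIs (diagonal entries count within-cluster
edges twice, consistently in numerator and denominator); expected is the
mean over label permutations **within each ROI** (preserving each ROI's
graph and label counts — robust to degree heterogeneity, unlike a closed
form); O/E is reported with 0/0 → 0. One labelling of a single ~1000-edge
graph fluctuates around 1 with sd ≈ 1/√(expected count) per entry (±0.1 is
roughly 1σ); calibration statements therefore pool several ROIs, as the
per-case analysis does.

Group comparisons: per-cluster per-case occupancy proportions (each case
sums to 1) are compared static-vs-growing by two-tailed Mann–Whitney;
category-level and proliferative/non-proliferative proportions by 2-way
ANOVA (group × category) with interaction. With only two complementary
categories the proportions are collinear and the interaction term is
rank-deficient; statsmodels flags this but the group contrasts remain
interpretable.

## Spatial association

**Quadrats.** "100 µm" quadrats are 100 µm-sided squares (a literal 100 µm²
quadrat would be sub-cellular), gridded from the ROI origin; only fully
contained quadrats are used and cells are assigned half-open
([x0, x0+side) × [y0, y0+side), boundary cells to the higher-index
quadrat). The QCM is pairwise Pearson correlation of per-quadrat counts
(needs ≥ 10 quadrats), two-tailed p-values BH-adjusted over all unordered
pairs, non-significant entries set to 0. Zero-variance populations are
reported as 0 with a note. Per-ROI matrices are summarized to a group by
requiring a pair to be gated-significant in ≥ 50% of the ROIs in which both
populations occur (configurable fraction).

**Cross-PCF.** Bins are left-closed of width dr = 10 µm over r = 0–300 µm;
"g(r = 20 µm)" is the bin containing 20 µm, i.e. [20, 30). The estimator is
border-corrected by the exact annulus∩window area: senders always lie
inside the rectangular window, so the disc∩rectangle area decomposes into
four quadrant integrals with a closed form, vectorized over senders × bin
edges. Auto-PCF (sender = receiver) excludes self-pairs and normalizes by
n(n−1). Toroidal and uncorrected modes exist for oracle tests. Pooling over
the ROIs of a group sums each sender's border-corrected contributions
within its own ROI and normalizes by pooled totals and summed window area;
with one ROI this reduces exactly to the single-ROI estimator.

**Bootstrap call.** Senders and receivers are resampled independently with
replacement (within each ROI when pooled); the CI is the percentile 2.5/97.5
band over 200 resamples; the call is positive when the CI at the r = 20 µm
bin lies above 1, negative when below, else none. Resampling both point
sets roughly doubles the variance relative to the estimator's sampling
error, so the CI is conservative: under CSR almost no bins exclude 1
(measured by the acceptance script), and detecting a linked pair at
σ = 10 µm requires either a sparse sender type or pooling ROIs — single-ROI
single-pair power at typical densities is limited, which is why the
pipeline and the acceptance experiments evaluate pairs on a group's pooled
ROIs.

**Topographical correlation map.** On 100 µm tiles, score =
(observed sender·receiver co-count − permutation mean) / permutation sd,
with labels permuted within the ROI; sd 0 → score 0. The exact formula of
the adapted method is not published; this permutation-z definition is this
package's concretization.

**Adjacency network.** Directed edge sender→receiver iff the unordered pair
is QCM-significant and the PCF call is not none; edge weight g(r=20 µm);
`% connections` = 100 × (retained graph edges joining sender-type to
receiver-type cells) / (retained edges incident to at least one sender-type
cell), so a sender's percentages over receivers sum to ≤ 100. Node weight is
relative abundance. Exported as GraphML/edge-list CSV.

## Statistics

Correlations against growth rate use Shapiro–Wilk (α = 0.05) on each
variable; Pearson if both pass, else Spearman; a least-squares line is fitted
on the raw pairs regardless of branch, so the reported slope always refers
to the data scale. Fewer than 4 pairs or zero variance is an error. Group
comparisons use the same gate (t-test vs Mann–Whitney); groups of n < 3
cannot be tested for normality and fall back to Mann–Whitney with a
warning. BH adjustment is the textbook step-up with enforced monotonicity.

## Synthetic cohorts

The simulator emulates the statistical structure of a segmented IMC cohort;
its defaults are the package's study conditions:

* **Cohort**: 4 static + 5 growing cases; growth rates uniform on the
  printed ranges [−40, 16] and [28, 267] %/yr; 6 ROIs per case of
  1000 × 1000 µm.
* **Populations**: 15 named populations across six hierarchies with marker
  mean vectors mirroring the shipped annotation rules; baseline intensities
  total ≈ 4100 cells/mm², the density implied by a ~223k-cell cohort over
  9 × 6 ROIs of 1 mm².
* **Spatial processes**: homogeneous Poisson; Thomas (Neyman–Scott) with
  Poisson parents in a 3σ-padded window and Gaussian(σ)-scattered offspring,
  out-of-window offspring discarded (bounded tissue; calibration is
  approximate near edges and tests tolerate this); linked processes placing
  each point at a uniformly chosen partner point plus isotropic Gaussian
  displacement (cross-type attraction; σ = 0 makes points coincide).
  Parent rate defaults to intensity/mean_offspring so growth effects scale
  cluster numbers.
* **Noise**: marker value = mean × LogNormal(0, σ) with σ = √ln(1+CV²) so
  the multiplicative CV equals `noise_cv` (default 0.3). The factor's mean
  e^{σ²/2} slightly exceeds 1; the percentile normalization absorbs this.
* **Growth effects**: per-population linear intensity slopes
  (alternatively activated TAMs +1.5, their proliferative fraction +0.2
  cells/mm² per %/yr) — the simplest structure that makes the correlation
  analyses recoverable; slopes are validated to keep intensities
  non-negative over the generated growth-rate range.
* **Mosaics**: K random centres tile an ROI into Voronoi domains; each
  cell's population is drawn from its domain's composition; the domain is
  recorded as ground truth for neighbourhood-recovery experiments.

What the simulator does **not** emulate: pixel-level images beyond toy
stacks, marker spillover, acquisition noise, segmentation errors, cell
shapes and sizes, within-population expression gradients, or anisotropic
tissue architecture. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated generative
assumptions, not performance on real tissue.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale versions of the study
conditions — ROIs of 300–700 µm sides, 1–3 ROIs per case, 5–20 replicates —
keeping relative structure (population mix, densities, noise) identical to
the defaults; these sizes are the package's own choices for its verification
experiments. The pipeline derives all stage seeds from one global seed via
`SeedSequence((seed, stage_index))`, every stochastic routine consumes only
derived seeds, and re-running an identical config reproduces byte-identical
CSVs (asserted in the suite); the manifest records the config hash, seed
and per-stage outputs, and completed stages are skipped on re-run.

## Known limitations

* Leiden resolution and k are heuristics; on real cohorts the annotation
  rule tables must be adapted to the panel at hand.
* The stability-selected K can be ambiguous when domain structure is
  hierarchical (a stable coarse merge can compete with the true K).
* The bootstrap CI is conservative (see above); negative calls additionally
  require the expected count at 20 µm to be large enough for the CI to
  separate from 1.
* Quadrat- and tile-based statistics depend on the grid origin; partial
  edge quadrats are excluded rather than weighted.
* The cross-PCF border correction assumes rectangular windows.
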