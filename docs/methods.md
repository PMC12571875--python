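# Methods

This note documents the models behind glomscape, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## The synthetic cohort generator

The generator (`glomscape.synthetic`) produces segmented-cell spatial
transcriptomics cohorts with ground truth for every downstream stage.  It
is first-class, tested code: the recovery evaluations treat it as the
definition of the study conditions.

**Geometry.** Each sample is a square field (default 1,100 µm) holding
non-overlapping glomerulus discs (radius 90 ± 15 µm, rejection-sampled
with ≥100 µm between disc boundaries so that instancing by single linkage
at 30 µm can never bridge two glomeruli).  The periglomerular niche is an
exact annulus of 100 µm around each disc; all remaining tissue is
tubulointerstitial.  Real glomeruli are irregular; discs and exact annuli
were chosen so that the 100-µm compartment assignment is exactly
checkable.  Cell positions are uniform within each region with
per-compartment densities (glomerular 8, periglomerular 5,
tubulointerstitial 4.5 cells per 1,000 µm²), giving roughly 200 cells per
glomerulus cross-section — the scale of a segmented tissue section.

**Latent severity.** Each glomerulus draws a severity s ∈ [0, 1] from a
per-condition Beta distribution (control Beta(1.5, 12), SLE Beta(3, 5),
ANCA-GN Beta(4, 3), anti-GBM Beta(6, 2)), ordering the conditions by
median severity while letting their supports overlap — individual control
glomeruli can be sicker than individual disease glomeruli, which is what
makes a *common* trajectory across conditions meaningful.

**Composition.** Cell-type fractions per (condition, compartment) default
to the packaged profiles (`data/compositions.yaml`); the headline medians
(glomerular podocyte / PEC / mesangial / fibrotic-mesangial / macrophage,
periglomerular and tubulointerstitial T cells) follow the published
crescentic-glomerulonephritis cohort, and the remaining fractions are
plausible fill-ins summing to 100%.  Severity perturbs compositions with
slopes **centred on the condition's median severity** (PEC +0.10·Δs,
podocyte −0.08·Δs, mesangial→fibrotic-mesangial transfer 0.08·Δs,
glomerular macrophage +0.03·Δs, peri/tubulointerstitial T cell +0.03·Δs,
then clip and renormalize): because each per-type response is monotone in
s, the across-glomerulus *median* composition stays at the configured
value, which is the property the recovery evaluations measure.
Between-glomerulus jitter is Dirichlet with total concentration 800.
With ~200 cells per glomerulus the per-glomerulus multinomial noise gives
the median over 40 ROIs a standard error of ≈0.7 percentage points; the
±2-point recovery checks leave room for this.

**Expression.** Counts are negative binomial (size 10; size → ∞ is the
Poisson limit) with per-type mean vectors over the packaged 480-gene
panel: background 0.03 counts/gene, six markers per type at 4.0 — markers
over a hundredfold above background, as in curated imaging panels — for a
median of roughly 35–40 transcripts per cell, the shallow depth typical
of this data type.  Fibrotic mesangial cells carry the mesangial
programme plus the ECM signature (COL1A1, COL4A1, FN1, LUM, TIMP1 at
3.0); fibroblasts make some matrix constitutively (1.0).  Severity acts
multiplicatively in PECs: a hump-shaped PDGF programme
(×(1 + 6·4s(1−s)), receptor/effector genes only — PECs receive PDGF, they
do not secrete it), a saturating TGFβ programme (×(1 + 6·sat(s)),
sat(s) = s/(s+0.3) rescaled), a linear fibrosis programme (×(1 + 25·s))
and rising PDGF receptors.  Endothelial and mesangial cells produce PDGF
ligands with the hump profile; macrophages and (fibrotic) mesangial cells
produce TGFβ ligands linearly — the planted source/target structure the
communication analysis must recover.  The fibrosis slope (25) is the
smallest round value at which the per-cell fibrosis score, computed from
five genes at these depths, resolves severity (Spearman ≥ 0.5 in PECs);
weaker slopes drown in counting noise.

**Protein channel.** Every cell is a regular hexagon (circumradius 4 µm).
The Ki-67-like intensity of a PEC is `8 + 60·4s(1−s)` with lognormal
cell-to-cell spread (CV 0.4); all other types sit at 8; off-cell
background is 2.  Rasterisation fills pixels whose centres fall in the
polygon, so a noise-free configuration gives exact pixel-count × model
value sums.

**What is not emulated:** raw transcript spots, optical blur,
segmentation errors, transcript spillover between adjacent cells,
irregular glomerular shapes, spatial sub-structure within compartments
(real PECs line Bowman's capsule; generated types are uniform within
their compartment), and batch/slide effects on expression.  Passing
recovery tests therefore show the pipeline is correct under its stated
assumptions, not that it is robust to segmentation artefacts or spillover.

## Cell typing

Label transfer uses multinomial logistic regression with L2 penalty on
log1p counts normalized to 1,000 per cell; the regularization strength is
chosen by 5-fold cross-validation over the grid 10⁻²…10² (the classical
recipe names no grid; a symmetric log grid is the default).  Confidence
is the winning class probability; clusters with median confidence
strictly below 0.6 can be dropped.  Prediction intersects the model's
genes with the data's (≥50% overlap required) and is invariant to library
size and gene order.

Fibrotic mesangial cells are a disease state rather than an atlas label:
the reference labels them "mesangial" and the pipeline recovers them by
relabeling mesangial-labelled cells inside glomerular domains whose
fibrosis score exceeds the 90th percentile of control mesangial cells
(percentile configurable).  By construction ~10% of the control mesangial
pool sits above its own 90th percentile, most of which is the true
fibrotic fraction hiding in the pool; the residual false-relabel rate on
truly healthy mesangial cells is a fraction of a percentage point.

## Niche annotation and compartments

Per sample: k-nearest-neighbour spatial graph (k = 15 by default; the
end-to-end pipeline uses k = 8, which smears the glomerular boundary
less at the generator's densities), features = mean of own + neighbours'
normalized expression, PCA to 20 components, Leiden clustering (RB
configuration, resolution 1.0) of the k-NN graph in PC space.  Clusters
whose mean podocyte-marker score (PODXL/NPHS2/PTPRQ) exceeds the
within-sample across-cluster mean + 1 SD are glomerular.

Two refinements address systematic boundary biases of
neighbour-aggregated clustering, both measured against ground truth:

1. **Halo erosion** (`refine_glomerular_mask`): smoothing annexes a rim
   of periglomerular cells into glomerular clusters; masked cells whose
   12 nearest neighbours are masked at a rate below 0.8 are dropped.
2. **Geometric membership** (`fill_glomerulus_hulls`): at the rim,
   per-cell cluster membership follows the cell's *own* expression, so
   e.g. podocyte rim cells pull themselves in while tubular rim cells
   fall out — a selection on type that biases composition estimates.
   After instancing, every cell inside the convex hull of a component
   (buffered by the component's median cell spacing) joins it, making
   membership spatial rather than transcriptional.  On tissue where a
   type specifically lines the boundary this trade-off should be
   re-examined; both steps are parameters.

Glomeruli are single-linkage connected components (link distance 30 µm,
≥15 cells); components are never allowed to cross sample boundaries.
Compartment assignment is centroid-to-centroid: a non-glomerular cell
within 100 µm of the nearest glomerular cell is periglomerular and
belongs to that glomerulus (ties → lower id).  Whether the published
100-µm expansion is measured from the glomerular cell set or from a
fitted boundary polygon is not stated; nearest-glomerular-cell distance
is used here.  Composition tables are per ROI-compartment (glomerular,
periglomerular) and per sample (tubulointerstitial), with per-condition
medians treating absent types as zero fractions.

## Crescent trajectory

Pseudo-bulk: raw counts summed per ROI, normalized to 10,000, log1p.
PCA is centred; all panel genes are used (no highly-variable-gene
subsetting — with a 480-gene targeted panel every gene is deliberate); an
optional switch restricts to HVGs.  PC1's sign is fixed so that the
control median is not above the non-control median.

ROI clusters: K-means for k = 2…10, K chosen at the maximum discrete
curvature (second difference) of the inertia curve; clusters with a
control fraction above 0.6 are merged ("predominantly control",
quantified); final labels C1…Cn in order of ascending median PC1.  The
number of clusters after merging is data-driven, not forced to four.

Diffusion pseudotime uses scanpy's diffusion map and `dpt` on a 10-NN
graph in 10-PC space — the established implementation of the method this
analysis defers to — rooted at a control ROI drawn uniformly under the
seed, rescaled to [0, 1].  Disconnected ROIs (infinite pseudotime) are
placed at the far end.  Quadrants Q1–Q4 come from an exact O(k·n²)
dynamic-programming Jenks natural-breaks (the usual helper package is
deliberately not a dependency; the implementation is checked against
exhaustive enumeration).

Clinical correlation: per-patient median PC1 vs eGFR, albuminuria, age
(Spearman, two-sided t approximation; ≥5 patients, constant covariates
flagged); ANCA risk encoded low=1/medium=2/high=3.  Differential
expression between C1 and the rest is a gene-wise OLS with slide
dummies; Benjamini–Hochberg across testable genes (no procedure is named
in the source analysis; BH is the field default); a slide factor
confounded with the split is dropped with a warning; zero-variance genes
are flagged and excluded from the correction.

## Pathway scores and trends

A cell's score for a set is the mean over present set genes of the
gene-wise z-scored log-normalized expression; constant genes contribute
zero.  Expression-bin-matched background scoring (the scanpy-style
alternative) needs background pools that a 480-gene targeted panel cannot
provide, so mean-of-z-scores is the default and `method="binned"` the
documented alternative.  The fibrosis set {COL1A1, COL4A1, FN1, LUM,
TIMP1} is a pragmatic ECM default and overridable; the exact per-cell
scoring rule and fibrosis set of the original analysis are not public,
so both are configuration, not claims.

Trends along the trajectory are OLS quadratics of per-cell (or per-ROI)
values on (1, PC1, PC1²) with analytic pointwise 95% bands; when the
curvature is negative the peak −b/(2c) is reported.  In the recovery
evaluations the reference peak is the generator's noiseless hump pushed
through the same quadratic estimator on the same axis, so the comparison
isolates pipeline error from the quadratic approximation of the
(nonlinear) severity→PC1 mapping, which both fits share.

## Spatial ligand–receptor model

This module is an explicitly simplified stand-in for full-featured
interaction tools: probability = h(L̄)·h(R̄)·π, with

- L̄, R̄: truncated means (trim 0.1: drop ⌊trim·n⌋ per tail) over
  source/target cells of ligand/receptor log-normalized expression
  (geometric mean across multi-gene complexes);
- π: the fraction of ordered (source, target) cell pairs within range —
  250 µm for secreted signaling, 10 µm for contact — computed per slide
  and pooled by pair count.  Hard truncation replaces diffusion-style
  distance weighting;
- h(u) = u/(0.5 + u): a fixed half-saturating response replacing a
  fitted mass-action model.  Both constants are configuration.

Slides are laid out left-to-right with a gap of 10× the interaction
range before analysis so cross-slide pairs can never interact.  Type
pairs need ≥10 cells per side.  Significance: cell-type labels permuted
within each slide, probabilities recomputed, p = (1 + #{perm ≥ obs}) /
(1 + n_perm) (add-one rule keeps p in (0, 1]); 100 permutations by
default.  Differential networks subtract aggregated matrices of
significant edges (α = 0.05); the incoming-signals table lists all
significant interactions toward a target type sorted by probability.

## Protein integration

Pixel membership is a boundary-inclusive pixel-centre test (partial-pixel
handling is not defined by the source procedure); overlapping polygons
each count shared pixels.  Registration is assumed done.  Positivity
defaults to an Otsu split of the target type's per-cell mean intensities
— with well-separated modes any gap threshold yields the same classes
and Otsu's argmax lands just above the lower mode, which is correct but
worth knowing when inspecting thresholds — with a fixed-quantile
alternative, since no positivity rule is stated for the original
measurement.

## Drug scoring

The three scores are implemented exactly as defined (see README).
Action labels are matched case-insensitively by substring in the order
inhibitor, antagonist, binder, activator, agonist — "antagonist" must be
tested before "agonist" — and unlisted actions get weight 0 while still
counting toward the overlap and S_b.  Duplicate (drug, gene) rows keep
the maximum weight, with a warning.  Drugs with S_f ≥ 0.1 are ranked by
S_f, ties by drug id.  The packaged drug table is a synthetic
DrugBank-style fixture (licensing prevents redistributing the real one).

## Pipeline, seeding, and problem sizes

`run_pipeline` requires exactly one of real input paths or a synthetic
block.  A single global seed fans out to per-stage seeds through
`SeedSequence(seed, spawn_key=(stage_index,))`, so inserting a stage
never perturbs earlier stages' randomness; reruns reproduce all outputs
exactly.

Default problem sizes are chosen for single-CPU work: recovery
evaluations use 40 glomerular ROIs per condition (10 samples × 4
glomeruli, ≈120k cells for two conditions) for composition recovery and
the 20-sample four-condition default cohort (≈120k cells, 80 ROIs) for
trajectory and dynamics; permutation calibrations use a few hundred
cells and 200 permutations.  Each evaluation completes in about one to
two minutes.

## Known limitations

- The compartment pipeline is validated on disc-shaped glomeruli with
  compositionally uniform compartments; boundary refinements (erosion,
  hull fill) would need re-tuning for irregular or boundary-structured
  tissue.
- The communication model's hard range cutoff and fixed half-saturation
  are simplifications; its probabilities are comparable within a run,
  not calibrated across datasets.
- The classifier assumes the reference and target share the severity-0
  expression regime for each type; strong disease-specific programmes
  absent from the reference would lower confidence rather than transfer.
- Median-of-40-ROIs composition estimates carry ≈0.7-point standard
  errors from counting noise alone; recovery within ±2 points is the
  designed resolution, not an exact identity.
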