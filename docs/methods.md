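# Methods

This note documents the statistical procedures, the synthetic-cohort model
and the numerical choices behind `ppgrid`, in the order the pipeline runs
them.

## Data model and conventions

An 8×8 posterior-pole grid holds 64 superpixel mean thicknesses (µm) for
one eye and one retinal segmentation. Cells are named `r.c` with row 1
inferior, row 8 superior, column 1 temporal and column 8 nasal *in
right-eye convention*. Files store grids in device (per-eye) convention;
at ingest every left-eye grid is column-reflected so that all downstream
statistics see right-eye anatomy and never branch on laterality. Mirroring
is an involution and commutes with all per-cell statistics (tested).

Eight segmentations are analysed: complete retina, RNFL, GCL, GCLIPL
(GCL + inner plexiform layer), GCC (ganglion cell complex = RNFL + GCL +
IPL), OPLONL (outer plexiform + outer nuclear layers), IRL and ORL
(inner/outer retinal layers); and two grid orientations: tilted ~7° along
the disc–fovea axis (the device's native export) and horizontalized.

Thickness is carried as real-valued µm. The cohort file format accepts
integers or reals; writing uses 17 significant digits so a read/write
round trip is bit-exact. Clinical covariates may be missing; group and
laterality may not.

## ROC machinery

**Orientation.** AUC = P(control thicker than glaucoma), ties counted ½
(Mann–Whitney with midranks). Glaucomatous thinning therefore maps to
AUC > 0.5 and the heatmap rule "AUC ≥ 0.70 = discriminative" needs no
sign handling. Midranks were chosen because device exports are often
integer-rounded, making ties common.

**Inference.** Standard errors come from DeLong's placement-value
decomposition; the paired test for two markers on the same eyes uses the
placement covariance. Confidence intervals are Wald on the AUC scale,
truncated to [0, 1] — symmetric CIs, matching how such tables are usually
printed — and p-values use the standard normal reference without
small-sample corrections (group sizes in scope are ≥ 30).

**Degeneracy.** A single-marker AUROC with vanishing placement variance
(all values tied) reports AUC 0.5-with-ties, se 0, p 1 and a flag. A
paired comparison with zero variance of the placement difference is
degenerate (z = 0, p = 1) when the two AUCs agree — e.g. marker B a
strictly increasing transform of marker A — but when the AUCs differ with
zero variance (perfect separation in opposite directions) the difference
is deterministic and is reported as z = ±∞, p = 0.

Validation: exhaustive pairwise counting on random tie-rich instances,
equality with scikit-learn's `roc_auc_score` point estimate, bootstrap
variance agreement within 25% at n = 100/group, and paired-test type-I
error within 99% binomial bounds of 5% over 2000 exchangeable binormal
replicates.

## Heatmaps, selection and global indices

Each (segmentation, orientation) yields 64 per-cell AUROCs. Colour rule:
blue AUC ≤ 0.5, white 0.60–0.69, red AUC ≥ 0.70. The legend leaves
(0.5, 0.6) and (0.69, 0.70) unnamed; they are rendered as an INTERMEDIATE
class and never affect selection, which uses only the inclusive ≥ 0.70
rule. Selection is recomputed independently per segmentation and per
orientation.

Per eye, the **mean index** is the average thickness over the selected
cells and the **weighted index** the average of thickness × cell-AUROC
over the same cells. The weighted index divides by the number of selected
cells; dividing by the sum of weights instead would rescale every eye by
the same positive constant and leave every AUROC-level result identical,
so only the count denominator is exposed. When all selected weights are
equal the two indices are exactly proportional and their comparison is
exactly degenerate (tested as an identity, not approximately).

A (segmentation, orientation) is **excluded** from ranking and cutoff
analysis when its selection is empty or its index AUROC is below 0.70;
every exclusion carries a reason string into the run report. Ranking ties
break by the fixed segmentation enumeration order (RETINA, RNFL, GCL,
GCLIPL, GCC, OPLONL, IRL, ORL) for determinism.

When the tilted and horizontalized grids select different cell sets, the
orientation comparison still proceeds, each orientation using its own
selection: the comparison is between the two analysis products, not
cell-matched quantities.

## Cutoffs and diagnostic validity

Classification rule: an eye whose (mean-index) thickness is *below* the
cutoff is called glaucomatous; at or above, healthy. Candidate cutoffs are
the midpoints between consecutive distinct pooled index values, extended
by one candidate below the minimum and one above the maximum; since no
observed value can equal a midpoint, the boundary convention never changes
a result on real candidates. The chosen cutoff minimises |Se − Sp|, then
maximises Se + Sp, then takes the smallest cutoff — the equal-and-high
criterion plus deterministic tie-breaks. Se, Sp, PPV and NPV are reported
as percentages with Wald 95% CIs (p̂ ± 1.96·√(p̂(1−p̂)/n), truncated to
[0, 100]); denominators are n_glaucoma, n_control, positive calls and
negative calls respectively, and a zero PPV/NPV denominator yields an
undefined, flagged value. `choose_cutoff` is tested for exact agreement
with an independent brute-force search.

## Cohort statistics

Quantitative group contrasts use the classical pooled-variance two-sample
t-test (df = n₁ + n₂ − 2), computable from raw values or from per-group
(mean, SD, n) summaries with identical results; qualitative contrasts use
Pearson χ² without continuity correction, df = 1. Normality is screened
with a one-sample Kolmogorov–Smirnov test against a normal with
sample-estimated parameters; its p-value is conservative in this usage
(Lilliefors effect) and it is used only as a gate, never as a reported
endpoint.

## Synthetic cohort model

The generator's defaults are the study conditions the pipeline is meant to
face: 136 control and 163 POAG eyes, ~76% of eyes contributed as fellow
pairs (299 eyes from ~185 subjects), tilt 7°, roughly half left eyes.

**Fields and grids.** Each eye carries a continuous thickness field per
segmentation over the macular square (8 × 8 cell units); a grid in
orientation θ is the per-cell average of the field over the lattice
rotated by θ about the grid centre, computed with a fixed 5×5
Gauss–Legendre quadrature per cell (fixed order for determinism). At
θ = 0 the two orientations are produced identically, hence bit-identical.

**Anatomy.** Deterministic cell means are anchored to the disc–fovea
(tilted) lattice — macular damage is organised around that axis, which is
the device's rationale for tilting — by solving the linear cell-averaging
system for an interpolated node lattice; the horizontalized grid sees the
same anatomy slightly smeared. Baselines are stylised: a per-layer level
(complete retina ≈ 285 µm, RNFL ≈ 48 µm, GCC ≈ 90 µm, …) plus a mild
annular thickening of inner layers and a smooth sub-cell foveal
depression. The default damage pattern removes thickness in an arcuate
annulus (radius ≈ 2.6 cells, width ≈ 1.1 cells) with temporal-inferior
emphasis, sparing the foveal centre and the outer layers (OPLONL, ORL
carry zero effect); per-layer peak effects are 1.05–1.40 × the layer's
noise SD. The ring width matters: a band much narrower than a grid cell
is blurred more by one lattice than the other and manufactures a spurious
orientation difference.

**Noise.** The random part of the field is a stationary isotropic
Gaussian random field (squared-exponential covariance, correlation length
0.6 cells), reduced analytically to the joint distribution of its 128
cell averages (64 cells × 2 orientations) and scaled so each cell average
has marginal SD exactly σ (per-layer σ: retina 12, RNFL 5, GCL 3.5,
GCLIPL 5.5, GCC 7, OPLONL 8, IRL 10, ORL 7 µm). Isotropy makes the two
lattices' noise exactly exchangeable — a rigidly rotated cell sees the
same distribution — so neither orientation is favoured by construction,
while the finite correlation length leaves each orientation independent
noise of realistic size: the same-cell correlation between orientations
is ≈ 0.94, consistent with superpixel test-retest repeatability. Two
further components, neither changing any cell's marginal SD: a per-eye
global thickness factor (variance share 0.5, shared by all cells and both
orientations of an eye) and a per-subject intercept (share 0.3, shared by
fellow eyes). The global factor is essential: with independent cell noise
an index averaging ~25 cells would have its noise shrunk ~5-fold and
index AUROCs would saturate near 1, which no real cohort shows. The
subject intercept creates the eye-clustering that the analysis — like the
cross-sectional design it emulates — deliberately ignores.

**Severity.** Each glaucoma eye scales the whole damage pattern by
s ~ N(1, 0.4²), shared across its segmentations: a pooled POAG group
spans early to advanced disease (visual-field MD dispersions of several
dB), and this is what keeps index AUROCs in the realistic 0.75–0.85 band.
With an untilted grid the expected per-cell AUROC has the closed form
Φ(δ/√(2σ² + τ²δ²)), reducing to the binormal Φ(δ/(σ√2)) at τ = 0;
`expected_cell_auroc` exposes it as a test oracle (it errors for tilted
configurations, where lattice rotation mixes neighbouring cells).

**Demographics.** Subject age, sex, IOP, BCVA, cup/disc ratio, MD and PSD
are drawn from group-typical normal distributions with physiologic
clipping; fellow eyes share subject-level attributes. These feed the
cohort-statistics stage structurally and are not linked to the thickness
model (severity and MD are drawn independently — a known simplification).

**Determinism and positivity.** One `numpy` Generator seeded from the
config drives everything; identical configs give byte-identical cohorts.
Emitted thickness is floored at 0.5 µm; baselines sit ≥ 5 SD above the
floor, so the truncation is an inert safety net.

**Tilt sign.** Anatomically the disc is nasal, so in right-eye convention
the tilt is counter-clockwise; left eyes, written to file in device
convention, show it clockwise. The magnitude of the tilt, not its sign,
drives every orientation-level result.

## What the synthetic cohort does and does not show

Passing tests on synthetic cohorts demonstrates that the pipeline
recovers implanted spatial damage, calibrates its tests, applies the
selection/exclusion rules correctly, and behaves sensibly under the
study-scale design. It does not validate the clinical numbers of any real
cohort: the generator's Gaussian fields lack vascular shadows, segmentation
artifacts, floor effects in advanced disease, and axial-length/age effects
on thickness. Two structural caveats observed in simulation: the direction
of the (non-significant) tilted-vs-horizontal difference is not stable
across seeds, and the weighted index is often *statistically* (though
never materially, ΔAUC ≈ 0.002) better than the mean index because the
paired comparison of two near-identical markers is extremely powerful.

## Problem sizes in tests

The test-suite Monte-Carlo sizes are chosen to make each check decisive at
desk scale: closed-form recovery at 2000–5000 eyes/group (3 SE band),
DeLong calibration over 2000 replicates (99% binomial bounds), damaged-cell
argmax recovery over 20–200 seeds, outer-layer exclusion over 50
study-scale runs, and oracle equivalences over 150–1000 random instances.
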