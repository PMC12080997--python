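# Methods

## Framewise binding potential

Under a bolus-plus-constant-infusion protocol the tracer reaches a binding
equilibrium in which the distribution volume ratio of a target region
against a reference tissue devoid of specific binding equals the
instantaneous activity ratio. The package therefore computes, per region r
and frame t,

    BP_ND(r, t) = C(r, t) / C(ref, t) − 1,

and never estimates total or non-displaceable distribution volumes
separately: framewise binding potentials are only defined at equilibrium,
where the ratio suffices. The reference tissue defaults to cerebellar grey
matter (`Cer`), configurable. The bolus-to-infusion ratio k_bol is
expressed in minutes of infusion contained in the bolus; when k_bol matches
the inverse plasma elimination rate the bolus exactly pre-fills the plasma
steady state and the plasma concentration is flat from the start of the
scan.

Full kinetic modelling (SRTM, Logan graphical analysis), arterial input
functions and partial-volume correction are out of scope.

## Discard and detrend

The first 20 min of each scan are perfusion-dominated and are discarded
(frames are kept when their midpoints reach `discard_min`). Residual uptake
drift is removed per region with a least-squares *continuous* linear spline
(hat-function basis) with knots every 20 min aligned to the retained-window
start; a per-segment independent-line variant is available
(`continuous=False`). Continuity is the default because independent
segments introduce jumps at segment boundaries that inflate short-window
correlations. The fit is a linear projection, hence detrending is
idempotent; residuals are re-centred to exact zero mean per region.

## Connectomes and group statistics

Subject connectomes are pairwise Pearson correlations between regional
series, Fisher z-transformed with r clipped to ±(1 − 1e−7) so every entry
is finite. Matrices are exactly symmetric with zero diagonals;
zero-variance regions (possible in degenerate synthetic inputs) produce
zero edges plus a warning rather than failure. Group inference is a
two-sided one-sample t-test of each unique edge's z against zero with
Bonferroni correction over the R(R−1)/2 edges — deliberately conservative
and assumption-light where a specific family-wise procedure is not
dictated. Sub-threshold edges are zeroed only in the display matrix
(`thresholded_mean_z`), never in stored values.

Sliding windows are half-open [s, s + 20) min on frame midpoints, stepping
5 min from 20 to 60 min by default (nine windows on an 80-min scan); the
step is configurable down to one frame. Network strength is the mean
within-network unique-edge z (node strength: mean z of a node's
within-network edges) — means rather than sums keep networks of different
sizes comparable. Time-resolved strength is tested per window against the
baseline window with paired t-tests, Benjamini–Hochberg-corrected across
windows, plus a single paired final-vs-baseline test.

## Small-world analysis

Connectomes are binarized by keeping the strongest positive-z edges up to a
target edge density (default 0.25), with ties broken by the fixed
region-pair order; proportional thresholding compares PET and fMRI
connectomes at equal sparsity, and negative edges are excluded first. The
small-world coefficient is Humphries–Gurney
σ = (C/C_rand)/(L/L_rand), with C the mean nodal clustering coefficient, L
the characteristic path length on the largest connected component, and the
null the mean over degree-preserving double-edge-swap rewirings (10·|E|
swaps, 100 draws by default). σ depends only on the edge ranking, not the
z scale. Group-level small-worldness is a one-sided one-sample t-test of
subject σ against 1.

## Spatial group ICA

Per subject, in-mask voxel series restricted to the analysis window
(default 30–80 min) are voxelwise standardized; subjects are concatenated
along time; dimensionality is reduced to the component count by principal
components and unmixed with a symmetric fixed-point ICA (logcosh contrast,
tolerance 1e−6, at most 1000 iterations, deterministic seeded
initialization). Spatial maps are z-scored over in-mask voxels and
sign-aligned to positive skewness; display thresholding keeps voxels with
|z| ≥ 1.96 (two-sided p ≤ 0.05). Regional scores are means and SDs of the
*unthresholded* maps over atlas regions. For PET the intended input is the
framewise DVR−1 series (reference-normalized, detrended), which makes
components binding-driven rather than perfusion-driven. Component counts
default to 2 for PET and 10 for BOLD-style data and are fully
configurable. Temporal ICA, dual regression and model-order estimation are
out of scope.

## Displacement-challenge analysis

Static uptake images sum the frames whose midpoints fall in a half-open
window and are normalized to unit whole-brain(-mask) mean. Period
contrasts (baseline 30–40 min vs early 50–60 min; early vs late 70–80 min)
are voxelwise two-sample t-maps with Bonferroni control over in-mask
voxels; a paired variant is available behind a flag (the unpaired test is
the default convention even though periods are within-subject; random-field
or cluster-based corrections are not implemented, and Bonferroni is the
stricter choice). Regional summaries are voxel means/SDs of t in
matrix-position order.

Connectivity change per region is the paired-t statistic of global MC
strength (mean z to all other regions) between a pre-challenge and a
post-challenge window; the binding-vs-connectivity comparison is a Pearson
correlation of the two regional t-vectors, both signed so that reductions
are negative.

Displacement onset is detected as the first sustained excursion (three
consecutive frames) of a binding time course below a threshold. Two
thresholds are provided: a baseline mean − k·SD band, and a fractional-drop
threshold placed 25% of the way from the baseline mean to the
post-displacement plateau mean. The fractional form is preferred when
comparing onsets across curves of different displacement depths: for a
saturating drop the lag to cross a fixed *fraction* of the full amplitude
is independent of the amplitude, whereas an SD band is crossed later by
shallower curves.

## The synthetic cohort generator

The generator emulates the acquisition protocol: an 80-min simultaneous
scan, 1-min PET frames (80 frames), TR = 2 s BOLD (2400 volumes),
bolus+infusion with k_bol = 38.7 min. What it plants, and why:

- **Reference kinetics.** Plasma is one-compartment (elimination 1/38.7 per
  min by default) fed by constant infusion plus a bolus of k_bol minutes of
  infusion; the reference tissue follows one-tissue kinetics (efflux
  k2 = 0.15/min, unit equilibrium distribution volume). The curve is linear
  in the infusion rate, rises monotonically and is flat to well under 1%
  per min after 40 min.
- **Baseline binding.** A graded density profile: subcortical network
  regions 2.6→1.8, salience regions 1.45→0.95, remaining regions
  0.85→0.35 (evenly spaced within class, position order). Densities vary
  region to region, as transporter expression does; flat class values would
  also make rank-based validation against planted values degenerate.
- **Molecular networks.** Two planted networks — subcortical (VTA, Th, MB,
  PAG, Hyp) and salience (Str, Cg, NAc, Amyg, Ins, mPFC) — whose member
  regions share a network-wide latent AR(1) fluctuation (SD 6% of BP,
  3-min correlation time) on top of private AR(1) fluctuations (SD 4%).
  Regional PET activity is ref(t)·(1 + BP_r(t)) plus Gaussian noise with
  SD 2% of activity per 1-min frame, scaled by 1/√(frame duration) as a
  counting-noise proxy. Note that reference-region noise enters every
  region's DVR−1 series as a common term, so even between-network
  correlations are positive — as in real ratio-based molecular connectomes;
  planted structure appears as the within- minus between-network contrast.
- **Challenge.** An MDMA-like displacement at 40 min: occupancy rises from
  exactly 0 along a saturating-exponential onset reaching 95% of its
  plateau within 10 min (time constant 10/ln 20 ≈ 3.34 min). Subcortical
  regions respond immediately (plateau 0.40), salience regions after a
  10-min delay (plateau 0.25), and all other regions receive a small
  background occupancy of 0.15 scaled by their relative baseline density —
  a displacing drug binds available transporters brain-wide, producing the
  density-graded effect profile rather than a strictly network-confined
  one. Occupancy multiplies BP_ND by (1 − occ). An optional
  `coupling_reduction` attenuates a network's shared-fluctuation loading
  after the challenge, planting a connectivity reduction beyond what
  occupancy alone produces. The saturating-exponential onset (rather than a
  logistic sigmoid) keeps occupancy identically zero before the challenge.
- **BOLD.** Order-1 autoregressive innovations (lag-1 correlation 0.4)
  mixed through the same network structure with loading 0.5; no
  hemodynamic response convolution (resting-state only) and no challenge
  coupling into BOLD.
- **Voxel painting.** Regional values can be painted into a toy
  block-geometry atlas (48 regions + reference, 3×3×3-voxel blocks on a
  7×7 grid) with per-voxel noise (SD 5%), for voxel-level analyses. The
  geometry is synthetic; block adjacency carries no anatomical meaning.
- **Determinism.** All randomness flows from one seed through spawned
  per-subject generators; identical configurations give byte-identical
  outputs.

For ICA validation a separate helper plants two spatially disjoint
patterns on the network supports with alternating-sign, zero-sum weights
per pattern. Signed zero-sum weights make the two spatial sources exactly
uncorrelated over voxels, as the ICA model assumes; two disjoint
all-positive blobs are negatively correlated by construction
(cov = −p₁p₂) and no orthogonal unmixing can recover them perfectly.

### What the generator does not emulate

No projection-domain PET physics (scatter, randoms, reconstruction
artefacts), no anatomy-faithful geometry or partial-volume effects, no
subject-level kinetic variability in the reference tissue, no motion, no
physiological noise structure in BOLD beyond AR(1), and no pharmacokinetic
plasma modelling of the challenge drug. Passing tests therefore
demonstrate the correctness and sensitivity of the analysis chain under
its own model assumptions, not performance on real scanner data.

## Problem sizes and numerical choices

Validation suites run cohorts of 11–30 subjects at the protocol's native
80-frame / 2400-volume resolution, with Monte-Carlo loops of 100–200
replicates for calibration/power checks and 6–20 replicates where a mean
over cohorts is reported — sizes chosen to keep each check well inside a
desk-scale compute budget while leaving clear statistical margins.
Tolerances: exact algebraic identities are checked at 1e−9..1e−12;
projection idempotence at 1e−8; correlation clipping at 1 − 1e−7 bounds
|z| ≤ arctanh(1 − 1e−7) ≈ 8.4. Windows are always half-open [start, end)
on frame midpoints, which is unambiguous for 1-min frames. Degenerate
inputs: zero-variance regions warn and zero their edges; disconnected
graphs restrict path length to the largest component (logged) and fully
disconnected graphs raise; swap-saturated graphs (e.g. complete graphs)
keep their degree sequence under the null sampler.

## Known limitations

- The 48-region table's published source lists one duplicated matrix
  position (thalamus right / periaqueductal gray); the packaged table uses
  the contiguous 1..48 numbering.
- Bonferroni over edges/voxels is conservative; no permutation or
  random-field alternative is provided.
- The small-world σ of a given real dataset depends on the binarization
  convention; per-subject σ values are comparable within this package's
  convention (proportional threshold, positive edges) but not across
  conventions.
- Group ICA here is a single decomposition of concatenated data; no
  back-reconstruction of subject-level maps.
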