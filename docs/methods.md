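# Methods

## The problem

Resting-state fMRI group studies in neurodegenerative disease compare
voxelwise functional-connectivity (FC) maps between patients and
controls. Two data-quality problems routinely mask true group
differences. First, subtle technical artifacts — signal offsets confined
to a few acquisition slices (sudden within-volume motion, partial
k-space corruption) or widespread signal-level defects — are hard to
see in the raw 4D series, in motion parameters, or even in ICA
components. Second, gray-matter (GM) atrophy mixes cerebrospinal fluid
(CSF) into cortical voxels; CSF carries strong cardiorespiratory
pulsation that contaminates connectivity estimates.

`cvqc` implements the two corresponding countermeasures and the group
pipeline that benefits from them:

1. **Coefficient-of-variation (CV) mapping** as a single-volume quality
   summary. For each voxel, CV = σ(X)/X̄ over time; a subject's 3D CV
   map is compared voxelwise against a normative reference (mean and SD
   CV maps over a large healthy cohort) and reduced to two scalar
   artifact scores per run.
2. **Gray-matter-restricted group ICA (gmICA)**: temporal-concatenation
   spatial ICA run on GM voxels only, followed by dual regression and
   permutation-based voxelwise group inference.

Everything is validated end to end on a synthetic BOLD phantom with
known ground truth.

## CV and tSNR maps

CV = sample SD (divisor t−1) over the mean of each voxel's time series;
tSNR is the reciprocal, mean over sample SD. Voxels whose mean (CV) or
SD (tSNR) falls below a floor of 1e−6 × the run's median absolute
intensity are marked invalid and set to 0 rather than producing
division blow-ups in background air. On jointly valid voxels
CV × tSNR = 1 to machine precision, and both maps are invariant to
global intensity rescaling.

CV maps are computed after initial-volume dropping and temporal
high-pass filtering but **before** spatial smoothing and GM masking:
filtering removes drift that would inflate CV everywhere, while
smoothing would blur exactly the slice-localised artifacts the map must
expose.

## Normative reference and artifact scores

Single-subject CV maps from an artifact-free reference cohort are
merged into voxelwise mean and sample-SD maps; a subject's deviation
map is z = (CV − mean)/max(SD, floor) on the joint valid mask. Two
scores summarise a run:

- **stripe score** — max over slices of the mean |z| within the slice,
  minus the median over slices of the same quantity. High when one or a
  few slices deviate en bloc; invariant to global shifts. Slices
  holding fewer than half the median per-slice valid-voxel count are
  excluded from both the max and the median: the mean over a
  handful of edge-slice voxels is dominated by sampling noise and
  would otherwise drive the max for clean runs.
- **defect score** — fraction of valid voxels with |z| > 3; high for
  widespread signal defects.

A run is flagged when either score exceeds its threshold. Thresholds
default to median + 5·MAD of the normative cohort's own score
distributions. Because a reference that contains the scored subject
deflates its z values, normative runs are scored against leave-one-out
references so that their score distribution matches the out-of-sample
scoring of study subjects. The original procedure this automates was
expert visual inspection; the two explicit scores make the exclusion
decision reproducible, and their thresholds are a stated convention,
not an estimate of any published criterion.

Flagged and retained runs are compared on mean tSNR (within a
data-driven brain mask) with a two-sided Mann–Whitney U test: exact
enumeration of all label assignments for combined n ≤ 12 (correct under
ties), the tie-corrected normal approximation otherwise.

## Preprocessing

Order: drop initial volumes (default 3, T1 saturation) → temporal
high-pass → (CV maps are taken here) → Gaussian smoothing (default
5 mm FWHM; σ = FWHM/(2√(2 ln 2)), zero-padding boundary) → masking.

The high-pass filter is a Gaussian-weighted running-line (local linear)
detrend with σ = cutoff/(2·TR) volumes (default cutoff 100 s). At each
time point the series is fit by a weighted straight line and the local
intercept subtracted; the kernel truncates at the series edges and the
slope term absorbs slow edge trends. The filtered fluctuation is
recentred at the voxel's original mean. The filter is characterised by
its measured gain rather than by coefficient-level compatibility with
any toolbox implementation: on 199-volume TR 1.8 s sinusoids, gain is
≈0.98 at period 50 s and ≈0.16 at period 400 s.

GM masks are partial-volume maps binarised at 0.5, block-averaged to
the BOLD grid when grids differ by integer factors. For group analysis
a shared voxel set is required; the group GM mask keeps voxels present
in at least half of the included subjects' binary masks (a full
intersection would shrink catastrophically under per-subject atrophy,
while each subject's own atrophy still expresses itself through their
signal).

## Group ICA

Within each subject, every voxel's series is demeaned and scaled to
unit sample variance; subjects are stacked along time. The stack is
reduced to k dimensions by PCA and unmixed by spatial FastICA (log-cosh
contrast, symmetric decorrelation, tolerance 1e−6, max 1000 iterations,
seeded); non-convergence is an error, not a partial result. Component
maps are z-scored over voxels and their sign fixed so spatial skewness
is non-negative, which makes decompositions reproducible across seeds
up to component order. k defaults to 3 for the small phantoms; it is
fully configurable (a 50-component decomposition is only meaningful at
real-brain voxel counts). No automatic model-order estimation is
attempted.

Maps are thresholded by a Gaussian/gamma mixture: a central Gaussian
for the null background, a positive-tail gamma for activation (an
optional negative-tail gamma when needed), fit by EM with
moment-matching gamma M-steps; a voxel is active when the posterior
probability of the activation class exceeds 0.5, weighting false
positives and false negatives equally. If EM fails to converge the
conventional |z| > 2.3 cut is used with a warning. Components are
assigned to named network templates by maximal spatial Pearson
correlation (ties to the lower index; |r| < 0.2 reports unmatched).

## Dual regression and inference

Stage A regresses each volume's voxel vector on the (voxel-demeaned)
group maps, giving per-subject component time courses, which are
variance-normalised to unit sample variance. Stage B regresses each
voxel's (time-demeaned) series on those time courses plus an intercept;
the coefficients are the subject's spatial maps. Rank-deficient designs
are rejected with the offending component pair reported. On noise-free
rank-one constructions the two stages invert the construction exactly.

Group differences use a pooled-variance two-sample t per voxel with
family-wise error controlled by max-statistic permutation of group
labels: the maximum |t| over voxels is recorded per permutation and
p_fwe(v) = (1 + #{max ≥ |t(v)|})/(n_perm + 1) for random permutations,
or the plain fraction over all assignments when exhaustive enumeration
is feasible (auto-selected when the number of assignments is below
n_perm). Ties count as exceeding, which is conservative. Voxelwise FWE
correction is used rather than cluster or threshold-free enhancement,
and only two-group contrasts are supported. Bonferroni correction
(p·m capped at 1) is applied when one template matches several
near-duplicate components; m is the number of matched components.
Difference-map summaries report voxel count, volume, the peak voxel
index and mean/SD/min/max of t over significant voxels.

## The phantom

The generator emulates the *structure* of a clinical rs-fMRI study on a
small pre-aligned grid (default 32×32×12 voxels of 4 mm, 100 volumes,
TR 1.8 s): an ellipsoidal brain with a CSF core (normalised radius
< 0.25), a WM ring (< 0.6) and a GM shell; spherical networks on the
shell sharing band-limited (0.01–0.1 Hz) Gaussian time courses; white
noise everywhere; a shared 0.20–0.26 Hz pulsation regressor confined to
CSF. Per-subject network amplitudes are drawn around the group level
(SD 15% of the control amplitude) and recorded in a ground-truth
ledger, as are all artifact footprints.

Default amplitudes are chosen to be realistic for 1.5 T EPI: baseline
1000, noise SD 20 (tSNR 50), control network amplitude 10 (contrast-to-
noise 0.5), CSF pulsation amplitude 60. A group deficit is encoded by
reducing the patient amplitude of one network (default 50%). Atrophy
removes a fraction of GM voxels (default 10%) per patient — sampled
with double weight near network regions — zeroing both the
partial-volume map and the network contribution there. Artifacts are
additive offsets injected last: `stripe` on chosen slices × volumes,
`signal_defect` over a fixed anterior half-brain region × volumes. No
published amplitude exists for either artifact class, so the canned
scenarios state theirs explicitly (stripe 10× noise SD on 3 slices for
20% of volumes in the detection scenario; 15× noise SD on 4 slices for
50% of volumes in the mechanism scenario).

What the phantom does **not** model: head motion, registration error,
susceptibility distortion, scanner drift, physiological recording
traces, k-space effects, or realistic anatomy. Passing tests therefore
show that the algorithms invert this forward model under realistic
amplitude ratios — not that detection rates transfer to any scanner's
artifact population.

## Evaluation scenarios and problem sizes

The canned scenarios in `cvqc.scenarios` freeze the study conditions
used by the test suite and by `scripts/acceptance.py`:

- *QC detection*: 25 subjects, 5 with stripes; normative cohort of 60
  (the reference construction mirrors a large healthy cohort at reduced
  size; larger normative cohorts mainly stabilise the MAD-based
  thresholds).
- *Recovery*: 20 subjects, three equal-amplitude networks, k = 3.
- *Null validity*: 200 repetitions of a 12×12×8, 30-volume, 6v6 cohort
  with exchangeable groups; dual regression against the true maps and
  199 permutations per repetition.
- *Mechanism*: 24 subjects, true deficit in one network, high-amplitude
  stripes in 4 subjects; gmICA arms with 2000 permutations, plus a
  size-matched random-exclusion control.
- *CSF contrast*: 16 subjects, k = 4, matched seeds for wbICA vs gmICA.

## Numerical conventions

- Sample SD (divisor n−1) throughout, for CV, tSNR and reference maps.
- All randomness flows from one seed through named `SeedSequence`
  substreams (per subject in the generator; per stage in the pipeline),
  so cohorts, ICA initialisation, permutations and random exclusions
  are independently reproducible and any substream can be re-derived.
- Degenerate inputs are explicit: constant series are invalid voxels,
  not infinities; empty masks, rank-deficient designs, sub-minimum
  grids and contradictory artifact specifications are rejected with
  errors.
- Exhaustive permutation enumeration replaces Monte Carlo whenever the
  assignment count fits the permutation budget.

## Known limitations

- The flagging thresholds are a convention (median + 5·MAD); on real
  data they would need calibration against expert judgment.
- The group ICA approximates probabilistic ICA pipelines: no explicit
  noise model or model-order estimation, and no claim of numerical
  compatibility with any reference implementation.
- Registration, motion correction and brain extraction are out of
  scope; inputs are assumed pre-aligned with exact tissue maps.
- Peak coordinates in summaries are voxel indices, not standard-space
  millimetres.
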