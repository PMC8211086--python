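# Methods

`nirslayout` re-creates, on fully synthetic data, a comparison of four ways
of designing sparse fNIRS optode layouts that incorporate increasing
amounts of subject-specific imaging information:

* **LIT** — a literature-style anatomical ROI on a shared atlas head model;
* **PROB** — the subject's own head model with a leave-one-subject-out
  probabilistic functional ROI;
* **iFMRI** — the subject's own head model with the subject's own
  functional ROI;
* **fVASC** — as iFMRI, with vasculature added to the head model as a
  seventh tissue class.

Each approach produces, per task, a two-channel layout (three optodes, one
shared); the merged per-subject montage is driven through a forward fNIRS
simulator and the full signal-analysis chain, and the approaches are
compared on ROI t-values and contrast-to-noise ratios across the cohort.

## Head phantoms and ROIs

The phantom is a concentric-layer hemisphere (outside → scalp → skull →
CSF → gray matter → white matter along depth) on a regular voxel grid;
vasculature, when enabled, is carved as thin random tubes inside scalp and
gray matter at a configurable voxel fraction (default 1.5%). The
algorithms under test depend only on the labeled tissue-depth structure,
so an idealized geometry keeps every stage fast and checkable. Defaults:
outer radius 40 mm; scalp 3, skull 4, CSF 2, gray matter 4 mm; subject
grids at 1 mm, the atlas grid at 2 mm. All phantoms share one outer
geometry; subjects differ by a small random jitter of the inner layer
thicknesses (SD 0.4 mm), and the atlas is the mean geometry. Real heads
differ far more (cortical folding, inhomogeneous layers); the phantom
captures only the depth structure that photon transport actually sees.

130 scalp positions emulate an extended 10-20 template via farthest-point
sampling of the outer surface with a fixed seed. One position template is
shared by all subjects, which makes the LIT design subject-independent (as
a standardized cap template would); per-subject digitization error is not
modeled.

A task's functional ROI is a gray-matter spherical cap (radius 9 mm)
centered at a task-specific scalp direction, jittered tangentially per
subject (SD 5 mm). The subject's probabilistic ROI is the voxelwise mean
of the *other* subjects' binary maps (leave-one-subject-out). The
anatomical (LIT) ROI lives on the atlas grid and is displaced tangentially
by 15 mm by default, emulating a literature ROI that mislocates the
cohort's true activation site; setting the offset to zero gives a
correctly-placed literature ROI.

## Photon transport and channel sensitivity

A single-scalar-loop voxel Monte Carlo kernel (numba-compiled,
single-threaded, deterministic per seed) propagates pencil beams: step
lengths ~ Exp(mu_t) using the tissue at the segment start, absorbed weight
w·mu_a/mu_t deposited at the interaction voxel, Henyey–Greenstein
scattering, Russian roulette below 1e-3 weight (survival 0.1; roulette is
unbiased, the threshold only trades variance for speed). Refractive
indices are all 1, so boundaries are matched and photons leaving the grid
are lost. Optical coefficients per tissue are the standard mean-wavelength
values recorded in `phantom.TABLE_OPTICAL_PROPERTIES`; one effective
wavelength is simulated (no per-wavelength Jacobians).

Fluence is the absorbed-weight estimator dep/(mu_a·V·N). In a homogeneous
half-space it agrees with the extrapolated-boundary diffusion solution
(implemented in `transport.semi_infinite_diffusion_fluence` as the
independent reference) within ~15–20% at 10–25 mm from the entry point with
1e5 photons — the residual is diffusion-approximation plus voxelization
error, stable across radii.

A channel's PMDF is the unit-sum-normalized voxelwise product of its source
and detector fluences. The raw product is maximal in the superficial
voxels adjacent to the optodes (the fluence singularity dominates); the
familiar mid-channel "banana" maximum holds at cortical depth, so checks
of the mid-channel property restrict to voxels deeper than 10 mm.
Channel-to-ROI sensitivity is 100 × (PMDF mass inside the ROI) / (PMDF
mass inside the brain domain); the domain defaults to gray plus white
matter and is configurable, since "% sensitivity" leaves the denominator
open. Because the scalar factorizes into dot products of fluence vectors,
`SensitivityEngine` scores all position pairs with one Gram-matrix product
per ROI.

Per-optode photon counts: 1e5 by default for single simulations (a
desk-scale stand-in for the 1e8-photon GPU runs the full-scale procedure
uses), 8000 per optode inside the cohort study — enough for stable channel
*ranking*, which is all the optimizer consumes.

## Layout design

Candidate channels are all position pairs at 20–45 mm; the optimizer prunes
to 25–40 mm and sweeps every candidate as a seed, pairing it with the best
remaining channel sharing one of its optodes; the best (seed, partner) sum
wins, with lexicographic tie-breaks. The sweep is exhaustive over
optode-sharing pairs, which the tests verify against brute force. Channel
selection is role-free (any position may be source or detector). At
hardware assembly the shared optode becomes the source by default (a
`shared_role` switch exists), so eight merged layouts yield eight sources,
each with a short-distance detector at 8 mm. Optodes closer than 5 mm
merge into one physical optode (the merge radius is a design choice; the
full-scale procedure merged by hand).

Layouts are designed for all three mental-imagery tasks (12 per subject);
two tasks per subject enter the measured session (default
mental-calculation and mental-rotation), giving 8 layouts and at most 24
optodes before merging.

## Forward simulation

Per normal channel, Δ[HbO](t) is the sum over tasks of (10-s boxcar ⊛
double-gamma HRF, unit single-trial peak) × amplitude; Δ[HbR] = −1/3 ×
Δ[HbO]. The amplitude is 0.02 µM per percent of the channel's sensitivity
to the task's *true* (individual) ROI, putting well-targeted channels at
~0.4–0.8 µM single-trial peaks. Crucially, the truth sensitivities come
from an independent transport run (own seed) on the subject's vascularized
head: re-using the estimates the approaches optimized over would hand the
informed approaches a winner's-curse amplitude inflation.

The superficial signal is a shared per-run course (Mayer wave near 0.095 Hz
plus a slow drift, 0.6 µM HbO scale) added to every channel, plus a smaller
channel-specific course (0.2 µM) that short-separation regression cannot
remove; short channels carry only superficial signal. AR(1) noise
(φ = 0.6, SD 1.5e-3 OD) and sparse motion artifacts (0.5-s spikes at 5×
noise SD, rare baseline shifts) are added in OD; intensity is
baseline·exp(−OD) at 760/850 nm, 7.8125 Hz. Schedules: six runs, six 10-s
trials per task per run, rest gaps uniform on {20..24} s (mean 22 s), no
task more than twice in a row. What this generator does **not** emulate:
heart-beat and respiration bands, wavelength-dependent transport,
optode-coupling drifts, and real cortical geometry — so passing tests
demonstrate internal consistency of the chain, not field performance.

## Analysis chain

Intensity → OD (natural log, run-mean reference) → channel rejection at
CV ≥ 7.5% (either wavelength) → motion detection on OD (windowed signal
change against 50× the SD of one-sample differences, or 5 OD absolute;
flags dilated ±1 s) → modified Beer–Lambert with the general age/wavelength
DPF polynomial and Prahl extinction coefficients → short-separation
regression (slope-only projection on the nearest short channel, on
*unfiltered* concentrations) for the GLM path, and a zero-phase order-1000
FIR band-pass [0.008, 0.25] Hz (forward-backward, reflection padding) for
the block-average path. The 0.008 Hz edge at order 1000 leaves a small DC
leak (~−20 dB after two passes) — inherent to the stated design, and
irrelevant after per-trial baselining.

The GLM uses task regressors (boxcar ⊛ HRF; the HbR column scaled by −1/3
so its beta is on the HbO scale), DCT confounds below 0.009 Hz, an
intercept, and indicator columns for motion segments. AR prewhitening:
OLS fit, Burg AR of the residuals with AIC order selection up to 4×fs
(Burg chosen over Yule–Walker for its lower bias at strong
autocorrelation, which directly sets CI calibration), whitening of y and
X, whitened OLS, one re-estimation pass. Multirun estimates stack per-run
whitened systems with shared task columns and per-run confound blocks.
The ROI statistic combines the two layout channels with contrast weights
0.5 (falling back to 1.0 on a survivor if the other was CV-rejected);
the off-diagonal of the channel covariance uses the whitened-residual
cross-correlation with runs trimmed to a common length, and the t uses the
smaller channel dof — the full-scale description leaves both open.

Block averages span −4 s to 15 s after trial offset with per-trial
[−4, 0) s baselining and motion-masked samples excluded;
CNR = |mean(dur) − mean(pre)| / sqrt(var(dur) + var(pre)) with pre
[−4, 0) s and dur [5, 15] s (the square root follows the standard CNR
definition; identical windows give 0 by convention before the zero-
denominator sentinel). The ROI CNR uses the mean of the two member
channels' block averages.

## Group comparison

Friedman tests across the four approaches (rows are subject, or
subject × task when tasks are pooled), then one-sided Wilcoxon signed-rank
tests per approach pair (alternative: the more-informed approach is
larger; scipy's exact path at small n), Benjamini–Hochberg corrected
within each family of six pairs. Percent-significant counts subjects with
one-sided ROI p < 0.05. A task is dropped from group statistics below 5
subjects (mirroring the infeasible two-subject inner-speech group).
Friedman dof is the standard k−1.

Layout similarity per approach pair: shared channels (0–2) and the
Euclidean distance between optode centers of gravity. The fMRI comparison
uses a synthetic t-field (Gaussian profile around the true ROI center over
gray matter, plus voxel noise) and inverse-distance projection weights
over gray matter within a 20-mm sphere of the channel midpoint.

## Calibration and problem sizes

* AR-GLM CI coverage is checked over 500 simulated runs of the real design
  (one ~7-min run at 7.8125 Hz) with AR(1) φ = 0.8: coverage sits near 94%
  versus nominal 95% (the residual-based AR estimate is slightly
  optimistic), while naive OLS covers far below 90%.
* The null-calibration study makes the four approaches exchangeable —
  identical true ROI (no jitter, no literature offset), identical geometry
  (no thickness jitter), no vasculature — because any systematic model
  difference (e.g. a vascularized truth model, or leave-one-out maps
  fitted to other subjects' anatomy) is a real effect, not a
  false positive. The shared atlas engine gets four times the per-subject
  photon count (it emulates a precomputed high-photon database and is
  computed once), because its Monte Carlo draw is shared by every
  subject's LIT difference and would otherwise correlate the whole
  cohort. The null cohort has eight subjects: at six, the exact
  signed-rank test reaches corrected significance on full sign-consistency
  alone (probability 1/32 per family), an artifact of the test's
  discreteness rather than miscalibration. Twenty replicate 8-subject
  studies at reduced sizes (60 positions, 6000 photons, two runs, three
  trials per task, filter order 250) keep the whole check inside a few
  minutes.
* The headline study runs 16 subjects at the default sizes above in a few
  minutes of CPU time.

## Known limitations

* The step-length sampling uses the tissue at the segment start, blurring
  interfaces by up to one scattering length; CSF's near-zero mu_t makes it
  an almost ballistic gap, as in the full-scale model.
* The atlas/subject distinction reduces to resolution and a small
  thickness jitter, so the LIT penalty is dominated by the configurable
  ROI mislocation rather than atlas anatomy mismatch.
* Only three tissue-boundary effects enter the Beer-Lambert path through a
  single DPF per wavelength; partial-volume (partial pathlength) effects
  are not modeled, so absolute concentration scales are nominal.
* Wilcoxon families are correlated across metrics/chromophores; the
  "any q < 0.05" null rate is therefore checked empirically rather than
  assumed to equal the nominal level.
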