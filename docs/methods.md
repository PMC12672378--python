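# Methods

## Signal model

A spectrally resolved fiber-photometry recording is a matrix of frames
Y (n_frames × n_wavelengths), each row one emission spectrum acquired in
a 30-ms exposure triggered at 25 Hz. With K co-expressed fluorophores
whose reference emission shapes S_k(λ) are known, each background-
subtracted frame is modelled as a non-negative linear mixture

    y(λ, t) = Σ_k a_k(t) · S_k(λ) + ε(λ, t),

where a_k(t) is fluorophore k's abundance in detector counts and ε is
frame noise. The shapes are peak-normalized and collected as columns of
the mixing matrix M; unmixing solves min‖M a − y‖₂ per frame, by default
under a ≥ 0 (abundances are physical; with closely overlapped spectra
the unconstrained solution can go sign-unstable at low SNR). OLS is
retained for diagnostics. Implementation note: the series solver does
one batched OLS solve and re-solves under the constraint only the frames
whose unconstrained solution has a negative entry — when the OLS
solution is feasible it *is* the NNLS solution, so this is exact. No
temporal regularization or smoothing is applied across frames; each
spectrum is unmixed independently.

Identifiability is summarized by the condition number of the
L2-column-normalized M and the pairwise spectral cosine similarities.
A condition number above 1e6 logs a warning; above 1e12 the reference
set is rejected as singular.

## Ratiometric ΔF/F₀ and bleaching correction

The control fluorophore (tdTomato) is insensitive to the biology of
interest, so the ratio r(t) = a_sensor(t)/a_control(t) cancels any
common multiplicative gain (excitation power drift, fiber bending)
exactly. Frames where the control falls below 10% of its median are
flagged invalid and excluded. Photobleaching is corrected by ordinary
least squares on the pre-stimulation window (default 0–60 s, at least
10 frames, required to precede the first train); the fitted line,
extrapolated over the whole session, is the theoretical baseline F₀(t)
and the reported signal is ΔF/F₀% = 100·(r − F₀)/F₀. The fit must stay
positive over the session; a baseline crossing zero is an error.

Two orderings are provided because figure-style and methods-style
descriptions of this analysis differ on it:

* `ratio_first` (default): fit the baseline to the *ratio*. The ratio
  inherits artifact cancellation before the regression, and when both
  channels bleach at the same relative rate the ratio is exactly flat,
  making the linear baseline exact.
* `per_channel`: fit a line to each unmixed coefficient and form the
  ratio of the baseline-normalized channels afterwards.

Neither mode is labelled "the" published behaviour; on equal-bleach
sessions they agree to numerical precision.

## Epoch summaries and statistics

Each stimulation epoch is reduced to one percent change per channel
under a window policy: `last_half_mean` (default; the last 30 s of a
60-s train, chosen because responses with ~10-s onset kinetics have not
equilibrated early in the train), `full_epoch_mean`, or `peak` (signed
extremum). Multi-trial subjects are averaged within subject before any
group statistics (n = animals).

Dose–response tables report per-intensity mean ± s.e.m. with n; s.e.m.
is undefined (NaN) for a single subject. The paired E/I comparison
tabulates per-subject Δglu − Δgaba; a negative difference means
glutamate signalling is suppressed more than GABA.

Tests: (1) within-subject one-way ANOVA (closed-form sum-of-squares
partition, no sphericity correction by default, Greenhouse–Geisser
behind a flag) followed by Dunnett each-vs-control comparisons —
adjusted p-values from the equicorrelated (ρ = ½) multivariate-t
formulation evaluated by a seeded 1e5-draw Monte Carlo, since exact
Dunnett quantiles lack a simple closed form; a labelled, unadjusted
sequential-pairs report (100 vs 150, 150 vs 200) is emitted alongside
because dose–response figures are often annotated that way. (2) paired
two-tailed t-test. (3) between-groups one-way ANOVA with Tukey HSD.
Adjusted p-values are clamped to be ≥ the raw p-values so Monte-Carlo
error cannot violate monotonicity.

## Reference spectra

The sensors' tabulated emission spectra are not published, so the
packaged shapes are parametric approximations: two-sided Gaussians with
a narrower blue flank and longer red tail, peaking at 512 nm (GCaMP),
510 nm (GFP-based), 528 nm (Venus-based) and 581 nm (tdTomato), sampled
on a 480–650 nm, 1-nm grid. The Venus/GFP pair has a spectral cosine of
0.80, reproducing the closely-overlapped-sensors regime that motivates
spectral unmixing. User-supplied reference CSVs override the packaged
shapes everywhere; resampling between grids is linear (monotone, no
negative overshoot).

## Synthetic sessions

The generator emulates the study's session structure: a 60-s baseline,
then 60-s trains at 100/150/200 µA (130 Hz, 60 µs monophasic cathodic;
a 20-Hz low-frequency variant keeps everything else fixed) separated by
5-min gaps, sampled at 25 Hz on the 1-nm grid. Per channel,

    a(t) = a₀ · (1 − b·t/60) · (1 + e(t)/100),

with linear fading fraction b per minute and percent effect e(t)
relaxing exponentially toward (plateau + artifact) during a train
(onset τ) and back toward 0 afterwards (offset τ), plus an optional
brief initial excursion at train onset. Frames are mixed through the
reference shapes and get additive Gaussian noise with sd = 1% of the
summed channel amplitudes (an optional √signal-scaled term is off by
default). Everything is driven by one seed; per-subject seeds are
seed + subject index, so any subject can be regenerated independently.

Preset ground-truth plateau effects are the observed condition means of
the experiments each preset emulates and live in one human-readable
packaged table (`data/presets.yaml`). Choices the data do not pin down,
made once and documented here rather than tuned:

* Kinetics: presynaptic calcium onset/offset τ = 1 s (terminal calcium
  tracks the train nearly instantly); postsynaptic calcium onset 10 s,
  offset 60 s (gradual suppression, slow recovery), with a +3%, 5-s-wide
  initial transient; transmitter sensors onset 10 s with offsets 90 s
  (glutamate) vs 30 s (GABA), i.e. GABA recovers faster. These τ values
  are generator choices, not measurements.
* Amplitudes: sensors 600–800 counts, tdTomato 1000 counts (arbitrary
  detector units; only ratios matter downstream).
* Bleaching: 2 %/min linear on every channel of a session — fading is
  dominated by the shared excitation path, and a common relative rate is
  what makes the ratio's linear baseline exact. An exponential bleach
  stress option (default 0.5 %/min) exercises the model-mismatch case;
  its linear-fit bias is positive and stays below 1% over a 16-min
  session at that decay.
* Stimulation artifact: applied additively inside e(t) on the
  green/yellow channel only. The non-responsive parent fluorophores
  show a small ratio change at higher currents, so the artifact cannot
  be common-mode; modelling it on the sensor channel reproduces that,
  and an equal-artifact setting exists to verify it cancels in the
  paired E/I difference.
* The chemogenetic preset has no trains: each condition
  (vehicle/CNO/DBS) is its own session with a 60-s baseline and one
  120-s effect epoch, a scaled-down stand-in for the original
  5-min-baseline/5-min-treatment sessions.

What the generator does **not** emulate: biological between-subject
variability in effect size (subjects differ only by noise seed, so
recovery tests probe the pipeline, not animal-to-animal scatter),
hemodynamic or pH artifact waveforms beyond the additive term, motion
artifacts (only their common-mode cancellation is represented via the
gain-invariance property), vesicle-depletion biophysics, and detector
nonlinearity. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to everything
real recordings contain.

## Numerical choices and test problem sizes

Ratios are undefined below the control floor (flagged, excluded);
R² of a frame fit is 1 when both residual and total variation vanish;
peak normalization pins the maximal sample to exactly 1; CSV I/O writes
17 significant digits and reads with round-trip float parsing so files
reproduce arrays bit-exactly. The Dunnett Monte Carlo and the whole
pipeline are deterministic given the seed.

The test suite runs most sessions at a scaled-down acquisition (5–10 Hz
frames, 2-nm grid, 60-s inter-train gaps) — the estimators are
identical, only the problem size changes; end-to-end recovery checks
and the acceptance script use the full default acquisition (25 Hz, 1-nm
grid, 5-min gaps, 25 subjects). The 200-cohort paired-test power check
uses the scaled acquisition with cohorts of n = 8.

## Known limitations

Extrapolating the 60-s baseline fit across a ~15-min session amplifies
the fitted-slope noise by the lever arm (~13× at the last train), which
dominates the per-subject uncertainty of late-epoch summaries (≈1 pp
per subject at default noise for the overlapped-sensor channels); with
slow (10-s) onset kinetics the last-half window also sits ≈1.6% of the
effect below the true plateau. Both are properties of the prescribed
baseline-and-window procedure, not of the solver, and both are visible
in the recovery diagnostics that `run_pipeline` reports against the
generator's ground truth. Blind unmixing (unknown reference spectra) is
out of scope, as are oscillation/beta-band analyses and behavioral
statistics.
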