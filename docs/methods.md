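# Methods

This note documents the models, defaults and numerical choices behind
`mothpupil`, and what the synthetic-data generator does and does not
emulate.

## Measurement model

The measured quantity per frame is the integrated density over a circular
ROI: ROI area × mean grey value, equal to the sum of member-pixel grey
values when the area is the member-pixel count.  Pixel membership is
pixel-centre-within-radius — a deterministic stand-in for the manual ROI
selection an experimenter would do in ImageJ.  One fixed ROI per stack is
assumed (the preparation does not move); per-frame ROI tracking is out of
scope.

Consumer cameras compress luminance nonlinearly.  The transfer is modelled
as `Y_out = A·Y_in^γ` and fitted to chart calibration pairs by nonlinear
least squares in the original response space, initialised from the log–log
linear regression (which is already exact on noiseless pairs).  The
default calibration shipped with the package, `A = 16.71`, `γ = 0.58`, is
the measured transfer of the NIR USB-microscope setup the pipeline
targets.  Measured values are linearised with the inverse,
`Y_corr = (Y_meas/A)^(1/γ)`; values beyond the calibrated range are
corrected by extrapolation of the power law and flagged in the log rather
than clipped.

## Kinetic model

Opening and closing time courses are summarised by the two-parameter
log-logistic sigmoid

    f(t) = 1 / (1 + exp(b (log t − log t50)))

the time-domain form of the Lipetz response–intensity relation.  `t50`
(seconds) is the time at half brightness; `b` is the slope of the linear
part of the sigmoid on a log-time axis and is dimensionless, so `t50`
rescales with the time unit while `b` does not.

Sign convention: **closing b > 0** (f decreasing), **opening b < 0**
(f increasing).  The source literature is internally inconsistent on this
point (one passage associates b < 0 with closing, another explicitly
states b > 0 for closing); we adopt the explicit statement, which also
matches the algebra of f.

"Forcing the curve through the origin" is implemented as the absence of
offset and amplitude parameters: the asymptotes are pinned at 0 and 1.
For opening (b < 0) this literally gives f(0+) = 0; for closing the curve
starts at 1, and the constraint is read as pinning the asymptotes rather
than the point (0, 0).  Fitting closing curves on brightness or on
1 − brightness gives identical (|b|, t50), so the choice is immaterial.

Numerical choices:

* A sample at t = 0 cannot enter the log-time loss; it is shifted forward
  by half a sample interval (configurable) before fitting.
* Initialisation: t50 from the interpolated 0.5-crossing; b from the
  quartile crossings, `b₀ = 2·ln 3 / (log t₀.₂₅ − log t₀.₇₅)`.  When
  crossings are absent (curves that never reach half-range in the
  recorded span) a coarse grid over b ∈ ±{0.5, 1, 2, 4, 8} and t50
  candidates extending to 10× the recording span seeds the optimiser.
* Optimisation is on (b, log t50) with tolerance 1e-10 on the sum of
  squares, at most 500 iterations; non-convergence is reported as an
  explicit status with the optimiser's message, never silently.
* R² = 1 − SS_res/SS_tot, SS_tot about the curve mean.

### Normalisation and its bias

Each corrected curve is min–max rescaled to [0, 1] using the extremes of
the full series, then (for opening) the initial transient is excluded and
the retained rising limb re-normalised.  Two systematic effects of this
convention are worth knowing:

* **Truncation**: if the recording ends before the response completes
  (e.g. a closing curve stopped while f ≈ 0.06), the observed minimum is
  not the true asymptote and the rescaled curve is steeper than the truth
  (b biased up, t50 down).  Recording for several multiples of t50 makes
  this negligible.
* **Noise extremes**: with additive noise the observed min/max overshoot
  the plateaus, compressing the signal and biasing b slightly downward.

Both effects vanish as noise → 0 and recording length → ∞; the
Monte-Carlo recovery tests characterise the estimator itself on direct
noisy samples of f, where it is unbiased to well under 5%.

### Bump exclusion

Dark re-opening recordings begin with a transient brightness surge
("bump", typically within the first 5–15 min) attributed to the preceding
UV exposure.  Detection: smooth with a centred 5-sample moving average,
find the minimum of the smoothed curve within a 20-min search window
(covering the reported transient span), and declare the bump present when
a local maximum precedes that minimum with prominence ≥ 0.05 normalised
units.  The maximum may sit at the very first sample — the surge is
effectively instantaneous at the recording timescale — and the prominence
guard rejects flat starts and noise wiggles.  The curve is then trimmed at
the windowed minimum (where the sigmoid rise starts), re-zeroed and
re-normalised.  Normalise → trim → re-normalise ordering is a pipeline
choice; the alternative order differs only through the trimmed samples'
contribution to the first normalisation.

## Intrinsic rhythm

Constant-darkness series are modelled as alternating open/closed plateaus
with switch times at `phase_offset + k·period` (default period 12 h,
matching the 12:12 entrainment the recordings follow), transitions drawn
from the same log-logistic family (slope 6, half-crossing at the switch
time, onset 0.5 h before — a ~10-min transition at the 5-min cadence), and
an optional linear drift in normalised brightness (default 0; negative
values reproduce the irreversible closure of small preparations).

Switch detection is a hysteresis crossing detector on the smoothed
(3-sample, 15-min) and — when estimable — drift-detrended curve: a switch
is recorded when the trace crosses from below 0.3 to above 0.7 or vice
versa, timed at the interpolated 0.5-crossing, with a 2-h refractory
interval.  The thresholds are detector defaults chosen for large-amplitude
switching; they are not measured quantities.  A transition centred exactly
at the recording end reaches its half-crossing only at the final sample
and cannot clear the hysteresis band, so the detector reports one switch
fewer than the generator stored in that configuration — the period
estimate is unaffected.

Period = mean of successive switch differences (with SD).  Drift = slope
of a least-squares line through per-cycle open-plateau medians (central
60% of each plateau), which is robust to the rhythm itself; it requires a
span of at least two nominal periods and two complete open plateaus.

## Statistics

Gaussian-family GLMs with identity link are fitted as OLS (identical
estimates and likelihood).  The hierarchy is
`response ~ (sex + species + temperature)^n` for n = 0..3 with all factors
categorical; consecutive orders are compared with sequential F-tests, and
a more complex order is accepted iff p < α (default 0.05) **and** its AIC
is below the last accepted model's.  AIC follows the OLS convention
(parameter count excludes the residual-variance parameter); reference
implementations that count it report values exactly 2 higher, and model
comparison is unaffected.  Designs with empty cells truncate the hierarchy
at the highest full-rank order, with a warning.

Estimated marginal means average model predictions over the full level
grid of the other factors (equal cell weights).  Pairwise differences use
the studentized-range (Tukey) adjustment on the model's residual df; with
two levels this reduces to the plain t-test.  The compact letter display
assigns one letter per maximal clique of the non-significance graph,
ordered by clique mean — levels sharing a letter do not differ at α.
The implementation was validated against R's emmeans on a fixed dataset;
the frozen reference values live in the test suite.

Eye-width cross-checks use the Pearson correlation (t transform, two
sided) between stereomicroscope and CT-scan diameters from the packaged
morphometry table (six species×sex rows, both diameter aspects, 12 pairs;
the stereo values are means of 10 individuals — individual-level data are
not packaged).

## Synthetic generator: what it does and does not emulate

The generator reproduces the *statistical structure* the analysis assumes:
log-logistic kinetics with a camera nonlinearity on top, an additive
exponential-decay bump (held at peak height until decay starts — the
simplest shape matching a sudden surge that falls to a minimum), square-ish
12-h switching with log-logistic transitions, linear drift, and additive
Gaussian noise (σ default 0.03 normalised units, applied after the camera
nonlinearity but before the amplitude, floored at zero).  Temperature can
enter only as a multiplicative factor on t50 supplied by the caller
(Q10-style); no kinetic law is modelled.

It does **not** emulate: optical image formation in superposition eyes,
biphasic/inflected closing shapes, photochemical after-effects of UV
stimulation, preparation movement, or non-Gaussian sensor noise.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every artefact of real recordings.

Rendered frames are 8-bit grayscale discs (background, dim eye disc,
pupil disc carrying the series value as its grey level) with
pixel-centre-within-radius membership; they exist to exercise the imaging
module end to end, not to look like real eyes.

## Problem sizes

Defaults used throughout tests and the reproduction script: 24 chart
patches; closing recordings 900 s at 1 Hz; opening recordings 90 min at
1 frame/min; intrinsic recordings 36 h at 1 frame/5 min; 50 replicate
seeds for Monte-Carlo recovery and 200 for the model-selection operating
characteristics.  These sizes match the recording designs the generator
emulates and give Monte-Carlo standard errors well inside the asserted
tolerances.
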