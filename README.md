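# mothpupil

Analysis pipeline for **superposition-eye pupillometry** — quantifying how
the "superposition pupil" of moth compound eyes opens and closes.  In
dark-adapted superposition eyes the tapetal reflection appears as a bright
disc at the eye centre; its brightness, monitored with a NIR-illuminated
USB microscope, proxies the light-adaptation state of the eye.  The
package turns such recordings (image stacks or pre-extracted brightness
series) into kinetic and circadian parameters and compares them across
species, sex and temperature.

Intended users: visual-ecology and insect-physiology labs analysing
pupil-dynamics recordings, and anyone needing a tested reference
implementation of the underlying curve-fitting and model-selection
statistics.

## What it computes

1. **Reflectance extraction** (`mothpupil.imaging`) — per-frame integrated
   density (ROI area × mean grey value) over a circular region of
   interest.
2. **Camera linearisation** (`mothpupil.calibration`) — fits the camera
   transfer `Y_out = A·Y_in^γ` from chart calibration pairs and applies
   the inverse `Y_corr = (Y_meas/A)^(1/γ)`.
3. **Kinetics** (`mothpupil.curves`) — min–max normalisation, detection
   and exclusion of the transient brightness "bump" at the start of dark
   re-opening, and a two-parameter log-logistic fit

   `f(t) = 1 / (1 + exp(b·(log t − log t50)))`

   with slope `b` (closing: b > 0, opening: b < 0) and half-brightness
   time `t50`.
4. **Intrinsic rhythm** (`mothpupil.rhythm`) — hysteresis detection of
   spontaneous open/closed switches in 36-h constant-darkness recordings,
   mean switching period, and the slow irreversible closure drift.
5. **Statistics** (`mothpupil.stats`) — hierarchical Gaussian-GLM
   selection over `response ~ (sex + species + temperature)^n`, n = 0..3
   (sequential ANOVA + AIC rule), with estimated-marginal-mean pairwise
   contrasts (Tukey adjustment, compact letter display).
6. **Morphometry** (`mothpupil.morphometry`) — interommatidial angle
   (180°/count), algebraic least-squares circle fit for eye radius, and a
   packaged per-species eye-measurement table.
7. **Synthetic data** (`mothpupil.synthetic`) — seeded generators for all
   of the above, with retrievable ground truth, so the full pipeline is
   testable end to end without any recordings.

The fittable stages are also exposed as scikit-learn-style estimators
(`GammaTransfer`, `LogLogisticRegressor`, `RhythmAnalyzer`) that support
`get_params`/`set_params` and `clone`.

## Worked example

Simulate a 15-min UV-induced closing recording (1 frame/s) as seen through
a gamma-nonlinear camera, then run the analysis chain:

```python
from mothpupil import (DEFAULT_CAMERA, KineticTruth, NoiseModel,
                       correct, fit_log_logistic, normalize,
                       simulate_induced_series)

series = simulate_induced_series(
    KineticTruth(b=2.5, t50_s=300.0), duration_s=900.0, dt_s=1.0,
    calib=DEFAULT_CAMERA, noise=NoiseModel(sigma=0.03, seed=7),
)
curve = normalize(correct(series, DEFAULT_CAMERA))
fit = fit_log_logistic(curve)
print(f"b = {fit.b:.2f}, t50 = {fit.t50:.0f} s, R2 = {fit.r_squared:.3f}")
```

Output:

```
b = 2.37, t50 = 257 s, R2 = 0.977
```

The fitted slope and half-time sit near the generating truth (b = 2.5,
t50 = 300 s); the gap is the footprint of min–max normalising a noisy,
finitely long recording (see `docs/methods.md`), and R² ≈ 0.98 indicates
the sigmoid describes the curve well.  The same workflow is available from
the shell:

```bash
mothpupil simulate induced --seed 7 --out closing.csv
mothpupil fit closing.csv --direction closing --calib calib.json
mothpupil rhythm intrinsic.csv --low 0.3 --high 0.7
mothpupil compare records.csv --response b --factor species
```

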