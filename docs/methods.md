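# Methods

## Rate law and estimation

Each denaturation stage is treated as a single-step solid-state reaction
with conversion degree α ∈ [0, 1] under a linear heating ramp β (K/min):

    dα/dt = A · exp(−E/(R·T)) · f(α),        T = T₀ + β·t,

with R = 8.314 J/(mol·K).  Two reaction models are registered: F1
(first order, f = 1−α, integral form g = −ln(1−α)) and F2 (second
order, f = (1−α)², g = (1−α)⁻¹ − 1).  The registry is open: a model is
a (symbol, g, f, order) record and anything with g(0) = 0, g strictly
increasing and f = 1/g′ can be added.

Parameters are estimated by the Coats–Redfern linearization

    ln(g(α)/T²) = ln(A·R/(β·E)) − E/(R·T),

fit by ordinary least squares of y = ln(g(α)/T²) on x = 1/T over the
conversion window α ∈ [0.05, 0.95] (default; at least 10 points
required).  E = −slope·R and A = (β·E/R)·exp(intercept).  The classical
correction factor (1 − 2RT/E) is dropped: for protein denaturation
E/RT is of order 30–150, and the induced bias in E is below 0.1% —
orders of magnitude below sample-to-sample scatter.  Model selection
maximizes the r² of the linearized fit, with ties (Δr² < 1e−6) broken
toward the lower reaction order; a regression with nonpositive E is
marked rejected rather than raised, so callers can report per-model
failure reasons.

The conversion window default [0.05, 0.95] excludes both the noisy foot
of the transition (where g is dominated by baseline error) and the
plateau (where g_F2 diverges); it is exposed in `RunConfig`.

## Peak extraction

Thermograms are baseline-corrected by subtracting the straight line
through the signal at two anchor temperatures (the pipeline default
anchors at the grid endpoints).  Transitions are segmented on the
Savitzky–Golay-smoothed signal (window 11 points, polynomial order 3 by
default): apices are local maxima with prominence ≥ 5% of the signal
maximum; the boundary between adjacent transitions is the minimum of
the smoothed signal between apices; the outermost onset/end sit at the
1%-of-peak-height crossings.  T_d is the apex of the smoothed corrected
signal, interpolated to sub-grid resolution by a local parabola and
reported to 2 decimals.  Enthalpy is the trapezoidal area of the
corrected heat flow over time (mW·min → mJ) divided by the sample mass,
with negative corrected values clipped to zero so that ΔH and α remain
well defined under noise.

Building α(T) as a partial-area ratio is sensitive to how much of the
transition the window truncates.  Hard-normalizing α to 0/1 at the
window edges after the 1%-height cut steepens the Coats–Redfern line
enough to bias E by 1–2%, so `conversion_from_peak` estimates the cut
tail areas by exponential-flank extrapolation (the flanks of an
Arrhenius-driven peak decay nearly exponentially in T; the missing area
is y_b/|d ln y/dT| at the boundary) and folds them into the
normalization.  The correction is only applied where the boundary
signal is below 5% of the window maximum — i.e. at genuine tail cuts —
and never at the valley boundaries between overlapping peaks, where
extrapolation would double-count the neighbour's contribution.  Each
tail estimate is capped at 5% of the window area.

## Synthetic data

The DSC generator inverts the measurement model: stage i contributes
heat flow mass·ΔH_i·β·(dα_i/dT)/60 mW, α_i is integrated by a classical
fixed-step 4th-order Runge–Kutta scheme with an internal step ≤ 0.1 K
(refined independently of the output grid; halving the step moves α by
< 1e−6), and the summed stage signals get a linear instrument baseline
and Gaussian noise from a seeded generator — the same seed reproduces
the thermogram bit for bit.  Pre-exponential factors are placed from
target peak temperatures via the Kissinger relation, which is exact for
F1 under this rate law; for F2 the closed form seeds a bracketing
search so the numerically located rate maximum lands on the target.
Ground truth records the numerical rate-maximum temperature of each
stage from the noiseless signal, and flags stages whose maxima sit
closer than 2 K.

The default four-stage recipe places rate maxima at 43.45, 56.79,
69.01 and 77.91 °C (the average denaturation temperatures of myosin,
sarcoplasm, connective tissue and actin in herring muscle) with models
F1/F1/F2/F1, activation energies 300/320/500/420 kJ/mol, enthalpies
1.2/0.8/0.5/0.7 J/g, 15 mg sample mass and β = 5 K/min on a 20–95 °C,
0.1 K grid.  The E values are chosen to give four distinct but
overlapping endotherms spanning roughly 40–82 °C; published per-sample
(E, A) values for this system behave as regression outputs and are
mutually inconsistent with the printed peak temperatures under any
standard non-isothermal rate law, so they are never used as simulation
inputs (see `denatkin.published`).

The rheology generator builds log G'(T) as a C¹ piecewise-cubic (PCHIP)
curve through knots shaped by three landmarks: a gentle minimum at IP1,
a slope increase from 0.008 to 0.024 per K at T_gel, a maximum at IP2,
then a mild plateau and decline.  G''(T) declines from 2.6 kPa at 20 °C
to 1.8 kPa at IP1 (a 31% drop), stays nearly flat through mid-sweep and
falls again past the plateau.  G'(20 °C) is derived from the configured
initial phase angle (12.3°) and G''(20 °C), so δ at the sweep start is
correct by construction.  Noise is multiplicative log-normal.  Defaults:
IP1 = 40 °C, T_gel = 53 °C, IP2 = 70 °C on a 20–85 °C, 0.25 °C grid.

What the generators do *not* emulate: instrument thermal-lag
convolution, pan-mass effects, moisture-evaporation endotherms, curved
(non-linear) baselines, and any coupling between the thermal and
rheological observables.  Passing the closed-loop tests therefore shows
the estimators are correct for the stated measurement model, not that
they are robust to every artefact of real instruments.

## Rheology feature extraction

All derivative work is done on log G' (scale invariance) after
Savitzky–Golay smoothing; non-uniform grids are resampled internally.
IP1 is the global minimum of smoothed log G' in the lower half of the
temperature range, IP2 the global maximum above IP1 — operationalizing
"inflexion points" as the extrema bracketing the gelation rise, which
is unambiguous on plateaued data where a literal second-derivative zero
is not.  Both are refined by a local quadratic fit; a monotone sweep
(extrema on the boundary) is rejected.  T_gel is the maximum positive
curvature of smoothed log G' strictly inside (IP1+2, IP2−2) °C;
curvature below 1e−6 K⁻² counts as numerically zero, so a log-linear S2
segment has no gel point.  Sweeps at different oscillation frequencies
are analyzed independently.

## Surrogate and agreement statistics

Spearman's R is computed as the Pearson correlation of mid-ranks (ties
get their average rank, which matters on conversion plateaus); constant
input is rejected because the coefficient is undefined.  The surrogate
is a 1-input → tanh hidden layer (default 24 units) → linear output
perceptron trained on standardized temperature by the L-BFGS
quasi-Newton minimizer of the mean squared error from a seeded random
initialization (scikit-learn backend, regularization disabled,
tolerance 1e−10, max 500 iterations); identical seed and data reproduce
identical weights, and exhausting the iteration budget sets a
`converged=False` flag instead of raising.  Hidden-unit counts in the
reference study range from 21 to 53 per curve; the default of 24 is a
representative choice, not a prescription, and is a parameter.

## Known limitations

- Valley-splitting of overlapping transitions (segmentation at the
  smoothed-signal minimum) preserves T_d and ΔH well — the four-peak
  default recovers T_d within ~0.4 °C and ΔH within ~4% at 1% noise —
  but the truncated flanks carry too little information for reliable
  F1-vs-F2 discrimination or unbiased E on heavily overlapped stages
  (the 8.9 K-separated stages 3–4 of the default recipe).  Resolving
  that would need true peak deconvolution (e.g. multi-peak shape
  fitting), which is out of scope.
- The Coats–Redfern estimate assumes a single-step rate law per stage
  and a single heating rate; isoconversional (model-free) methods are
  not implemented.
- Baseline correction is linear between two anchors.  Anchors must sit
  where the signal has genuinely decayed; anchoring on an undecayed
  transition tail tilts the corrected signal and biases E.
- The gel-point definition is the curvature bend of log G', not the
  G' = G'' cross-over; the two generally differ.
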