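# Methods

This note documents the models implemented in `flashcal`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Calorimeter run analysis

**Model.** A quasi-adiabatic graphite calorimeter: the outer jacket is held at
constant temperature while the core drifts freely. The measurement is the
core-temperature record sampled at 5 Hz; an irradiation of 0.4–0.8 s deposits
a step of order 10 mK on a baseline of order 297.7 K. Dose to the core is
`c(T_eval) · ΔT` (1 J kg⁻¹ ≡ 1 Gy); dose to water multiplies by the five
correction factors (impurity, gap, stopping-power ratio, fluence, source
distance), whose defaults are the values determined for the reference field
(1.0016, 1.0029, 1.1210, 0.9713, 1.0000; product 1.09373). The correction
factors themselves are *inputs* here: deriving them requires Monte Carlo
particle transport, which is out of scope.

**Drift extraction.** Quadratic (degree fixed at 2) ordinary least squares on
the pre- and post-irradiation windows, both extrapolated to a common
evaluation time; ΔT is the offset between the two extrapolations.

Choices where the procedure is conventionally underdetermined:

- *Evaluation time*: the midpoint of the irradiation window. For symmetric
  heat deposition this is exact; for any pre/post drifts differing only by a
  constant offset, ΔT is independent of the evaluation time anyway (verified
  as a property test).
- *Fit windows*: 60 s immediately before beam-on, and 60 s starting after a
  2 s post-irradiation guard that lets heat redistribute between calorimeter
  components. Both configurable.
- *T_eval* for evaluating c(T): the pre-drift extrapolation at the evaluation
  time. Over a ~10 mK ambiguity this changes c by < 0.01%, i.e. it is
  irrelevant at the budget's precision.
- *Negative ΔT* is flagged, not rejected: background and cooling runs are
  legitimate inputs.

**Numerics.** Fits are performed in window-centred coordinates (time and
temperature): the raw basis (t ≈ 120 s, T ≈ 297.7 K) would lose ~5 digits in
the normal equations, visibly degrading the noiseless round-trip identity.
The centred representation is used for prediction; expanded raw-basis
coefficients (K, K s⁻¹, K s⁻²) are reported. The noiseless round trip
dose → step → dose closes to ~1e-13 relative.

**Repeat runs.** `aggregate_runs` returns mean, sample SD (ddof = 1), and the
relative standard error 100·(SD/√n)/mean — the Type A contribution of the
repeated-measurement strategy (≥ 20 repeats per field targets ~0.04%).

## Ionisation-chamber chain

`D_w = |Q| · k_TP · k_elec · k_pol · k_ion · N_D,w · k_Q` with
`k_TP = (T/T_ref)(P_ref/P)`; reference conditions resolve per chamber from
its calibrating laboratory (293.2 K or 295.2 K, 1013.3 mbar). `k_elec`
defaults to 1. Polarity: `k_pol = (|M₊| + |M₋|)/(2|M_op|)`. Voltages are
stored signed (default operating point −400 V, collecting negative charge);
all recombination arithmetic uses magnitudes.

**Jaffé classification.** 1/M vs 1/V is fitted with degree-1 and degree-2
polynomials; the beam is called *continuous* when the quadratic fit reduces
the RSS by more than 50% (configurable) and its quadratic coefficient is
positive, else *pulsed*. The threshold is a package convention — any
classification rule needs a numeric criterion, and a 50% RSS reduction with
the physically required sign is robust at realistic noise (≥ 95% correct at
0.1% reading noise over 200 seeds, tested).

**Two-voltage estimator (continuous beam).** With r = V₁/V₂,
`k_ion(V₁) = (r² − 1)/(r² − M₁/M₂)`. This inverts the near-saturation model
`f(V) = 1/(1 + ξ²/V²)` *exactly* (algebraically — r² cancels; verified
numerically for random parameter sets). Readings with M₁/M₂ ≥ r² raise a
non-physical-readings error; estimates outside (1, 2) are flagged.

**Three-voltage estimator.** `1/M = a + b/V + c/V²` through the n highest
voltages (exact solve for n = 3, least squares for more);
`k_ion(V_op) = (a + b/V_op + c/V_op²)/a`, `M_sat = 1/a`. The quadratic
reciprocal form is a documented convention consistent with the continuous-beam
Jaffé behaviour. Fitting *above* the operating voltage matters: the
extrapolated intercept error scales with the product of the fitted reciprocal
voltages, so a 600/500/400 V fit is ~5× less model-biased than 400/300/200 V
when an initial-recombination (1/V) component is present. This is also why
the estimator comparison (below) conditions on that fit layout.

**Method divergence.** Under the combined generative model (initial +
general recombination, initial share 30% of the excess), the two-voltage
formula misattributes the 1/V component and errs by roughly
`k·(A/V₁)·(4k − 6)/3` while the high-voltage three-voltage fit errs only
through the neglected 1/V³ cross-term. For true corrections of 5–25% the
three-voltage estimate is closer to truth in essentially every noisy
realisation (tested at ≥ 95% over 200 seeds). With the *same* model but a
small initial share (3%), the 400/300/200 V fit stays within 0.5% of truth up
to k_ion = 1.25 (tested). The package never corrects for charge
multiplication; the generator can produce it, the estimators ignore it,
matching measurement practice.

## Uncertainty budget

Relative components in percent, Type A and Type B, combined in quadrature;
the overall (1σ) value is the quadrature of the two *unrounded* totals.
Components are treated as uncorrelated. Rounding policy: class totals to two
decimals, overall to one (the precision such budgets are tabulated at).
Entries quoted as bounds ("< 0.01") enter at their bound value
(conservative); using zero instead changes no rounded total of the shipped
budget — both behaviours are tested. Quadrature of the shipped (printed,
hence rounded) Type B components gives 0.845, which this package rounds to
0.85 where the source tabulation shows 0.84; the unrounded source components
are unknown, so last-digit agreement is not attainable and the tests assert
agreement within ±0.01. The asymmetric-triangular standard uncertainty
`sd² = (a² + m² + b² − am − ab − mb)/18` converts limits derived from two
independent computations of a correction factor into a standard uncertainty
(cross-checked against a 10⁶-draw sampling oracle).

## Synthetic data

**Traces.** Pre-drift quadratic baseline; the true step is back-computed from
the target dose through the same c(T)/correction chain the analysis applies,
which makes noiseless closure exact by construction (an identity check, not
evidence about real data); a linear intra-irradiation ramp (the analysis
never looks inside the window, so the shape is irrelevant to midpoint
extrapolation); optional post-irradiation slope change (visible in real
records; default 0, exposed as a parameter); white Gaussian noise, default
50 µK — chosen below the 100 µK sensing-system uncertainty of the instrument
being emulated, since the per-run noise magnitude is not otherwise
documented. Defaults: 297.7 K baseline, 7.8 Gy target, delivery time drawn
uniformly from 0.4–0.8 s, 240 s record at 5 Hz.

**Run series.** True doses jittered by a relative SD (0.18% in the tests,
reproducing the ~0.04%/√20 repeat strategy); per-run noise seeds spawned from
a master `SeedSequence`, so series are reproducible and runs independent.
Heat exchange between consecutive runs is not modelled (full reset between
runs).

**Saturation curves.**
`M(V) = M_sat · [1/(1 + A/V)] · [1/(1 + ξ²/V²)] · (1 + m·V) · (1 + ε)`,
truth `k_ion(V) = (1 + A/V)(1 + ξ²/V²)`. Relative reading noise defaults to
1e-4, interpreted as the SD of a mean over a few tens of repeated deliveries
normalised to the beam monitor — single-shot repeatability would be ~10×
larger, and the three-voltage intercept amplifies point noise by a factor
~30, so per-point averaging is what makes the method usable at all.
`curve_recipe_for_k_ion` builds recipes with an exact target correction and a
chosen initial-recombination share.

**What passing tests do not show.** The generators emulate the *structure* of
the measurements, not the beamline: no correlated (1/f) sensor noise, no
heat-transfer transients beyond the guard interval, no beam temporal
microstructure, no real calibration coefficients (the shipped chamber
registry carries placeholder N_D,w values, marked as such). Closure results
therefore validate the estimators under their stated models, not the
instrument.

## Known limitations

- Active-isothermal calorimeter operation is not modelled (quasi-adiabatic
  only).
- Pulsed-beam (dose-per-pulse) recombination models are out of scope; the
  Jaffé classifier will label such data pulsed, but no pulsed k_ion estimator
  is provided.
- The uncertainty module combines relative components only; it does not
  propagate sensitivity coefficients through the dose equation or model
  correlations.
- Problem sizes in tests and the acceptance script (e.g. 50 replicate series
  of 20 runs; 200-seed estimator comparisons) are the package's chosen desk
  scale: large enough that the statistical assertions have comfortable
  margins, small enough to run in seconds.
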