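"""Graphite-calorimeter run analysis.

A quasi-adiabatic graphite calorimeter realises absorbed dose from first
principles: the radiation-induced temperature rise of a thermally isolated
graphite core, multiplied by the specific heat capacity of graphite, gives
dose-to-graphite; a chain of multiplicative correction factors converts it to
the clinically relevant quantity, absorbed dose-to-water.

The analysis of a single run is:

1. fit quadratic drift curves to the core temperature before and after the
   irradiation window (:func:`fit_drift`);
2. extrapolate both drifts to a common evaluation time (by default the
   midpoint of the irradiation window) and read the temperature rise off the
   offset between them (:func:`extract_temperature_rise`);
3. multiply by the specific heat capacity evaluated at the run temperature
   (:func:`dose_to_core`) and by the correction-factor product
   (:func:`dose_to_water`).

All temperatures are kelvin and all times are seconds internally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .errors import (
    DegenerateFitError,
    InsufficientReplicatesError,
    InvalidWindowError,
    NonPhysicalValueError,
)

#: Sanity bounds for a core temperature record (kelvin).
TEMPERATURE_SANITY_K = (250.0, 350.0)

#: Sanity bounds for any single multiplicative correction factor.
FACTOR_SANITY = (0.8, 1.3)


@dataclass(frozen=True)
class TemperatureTrace:
    """Sampled core-temperature record of one calorimeter run.

    Parameters
    ----------
    times : array-like
        Sample times in seconds from run start, strictly increasing.
    temperatures : array-like
        Core temperature in kelvin, same length as ``times``.
    irradiation_start, irradiation_end : float
        Bounds of the beam-on window in seconds; must lie inside the
        sampled interval.
    sample_rate : float
        Nominal sampling rate in Hz (the instrument acquires at 5 Hz).
    """

    times: np.ndarray
    temperatures: np.ndarray
    irradiation_start: float
    irradiation_end: float
    sample_rate: float = 5.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", temp)
        if t.ndim != 1 or t.shape != temp.shape:
            raise ValueError("times and temperatures must be 1-D and the same length")
        if t.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (self.irradiation_start < self.irradiation_end):
            raise InvalidWindowError("irradiation_start must precede irradiation_end")
        if self.irradiation_start < t[0] or self.irradiation_end > t[-1]:
            raise InvalidWindowError("irradiation window must lie inside the sampled interval")
        lo, hi = TEMPERATURE_SANITY_K
        if temp.min() <= lo or temp.max() >= hi:
            raise NonPhysicalValueError(
                f"temperatures outside the sanity range {TEMPERATURE_SANITY_K} K"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def irradiation_midpoint(self) -> float:
        return 0.5 * (self.irradiation_start + self.irradiation_end)


@dataclass(frozen=True)
class DriftModel:
    """Quadratic drift fit ``T(t) = c0 + c1*t + c2*t**2`` over a time window.

    ``coefficients`` are in ascending order (K, K/s, K/s^2); ``residual_rms``
    is the RMS of the fit residuals in kelvin.  Internally the fit is stored
    centred on the window (``t_center``, ``y_center``) and predictions use the
    centred form, which keeps extrapolation at full double precision; the raw
    coefficients are the expanded equivalent for reporting.
    """

    coefficients: tuple[float, float, float]
    window: tuple[float, float]
    residual_rms: float
    n_points: int
    t_center: float = 0.0
    y_center: float = 0.0
    centered_coefficients: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.window[0] < self.window[1]):
            raise InvalidWindowError("fit window must have t_lo < t_hi")
        if self.residual_rms < 0:
            raise ValueError("residual RMS cannot be negative")

    def predict(self, t):
        """Evaluate (or extrapolate) the drift polynomial at time ``t``."""
        t = np.asarray(t, dtype=float)
        if self.centered_coefficients is not None:
            d0, d1, d2 = self.centered_coefficients
            dt = t - self.t_center
            return self.y_center + d0 + d1 * dt + d2 * dt**2
        c0, c1, c2 = self.coefficients
        return c0 + c1 * t + c2 * t**2


@dataclass(frozen=True)
class SpecificHeatModel:
    """Linear temperature model of the specific heat capacity of graphite.

    ``c(T) = intercept + slope * (T - reference_K)`` in J kg^-1 K^-1, with T
    in kelvin.  Defaults are the experimentally measured values for the
    calorimeter core.  Valid over the trace sanity range (250, 350) K.
    """

    intercept: float = 651.57
    slope: float = 2.74
    reference_K: float = 273.15

    def __call__(self, temperature_K: float) -> float:
        return specific_heat(self, temperature_K)


def specific_heat(model: SpecificHeatModel, temperature_K: float) -> float:
    """Specific heat capacity of graphite at ``temperature_K`` (J kg^-1 K^-1)."""
    lo, hi = TEMPERATURE_SANITY_K
    if not (lo < temperature_K < hi):
        raise NonPhysicalValueError(
            f"specific-heat model is only valid for T in ({lo}, {hi}) K, got {temperature_K}"
        )
    c = model.intercept + model.slope * (temperature_K - model.reference_K)
    if c <= 0:
        raise NonPhysicalValueError("specific heat evaluated to a non-positive value")
    return c


@dataclass(frozen=True)
class CorrectionFactors:
    """Multiplicative factors converting dose-to-core into dose-to-water.

    k_imp
        Impurity correction for non-graphite mass in the core (thermistors,
        epoxy, wires).
    k_gap
        Correction for the vacuum gaps that thermally isolate the core.
    s_wg
        Water-to-graphite mass-stopping-power ratio.
    k_fl
        Fluence correction between water and graphite at equivalent depths.
    k_z_cal
        Source-distance (inverse-square) correction; unity when measurement
        and reference distances coincide.
    """

    k_imp: float = 1.0016
    k_gap: float = 1.0029
    s_wg: float = 1.1210
    k_fl: float = 0.9713
    k_z_cal: float = 1.0000

    def __post_init__(self) -> None:
        lo, hi = FACTOR_SANITY
        for name, value in self.as_dict().items():
            if not (lo < value < hi):
                raise NonPhysicalValueError(
                    f"correction factor {name}={value} outside sanity range ({lo}, {hi})"
                )

    def as_dict(self) -> dict[str, float]:
        return {
            "k_imp": self.k_imp,
            "k_gap": self.k_gap,
            "s_wg": self.s_wg,
            "k_fl": self.k_fl,
            "k_z_cal": self.k_z_cal,
        }

    @property
    def product(self) -> float:
        return self.k_imp * self.k_gap * self.s_wg * self.k_fl * self.k_z_cal


@dataclass(frozen=True)
class TemperatureRise:
    """Result of the drift-offset extraction for one run."""

    delta_T: float
    T_eval: float
    eval_time: float
    pre_fit: DriftModel
    post_fit: DriftModel
    nonpositive: bool


@dataclass(frozen=True)
class CalorimeterRunResult:
    """Full analysis of one calorimeter run."""

    delta_T: float
    T_eval: float
    dose_to_core: float
    dose_to_water: float
    factors: CorrectionFactors
    diagnostics: dict = field(default_factory=dict)


def fit_drift(trace: TemperatureTrace, window: tuple[float, float]) -> DriftModel:
    """Least-squares quadratic fit of the temperature drift over ``window``.

    The window is ``[t_lo, t_hi]`` (inclusive), must contain at least four
    samples, and must not overlap the irradiation window.
    """
    t_lo, t_hi = float(window[0]), float(window[1])
    if not (t_lo < t_hi):
        raise InvalidWindowError("fit window must have t_lo < t_hi")
    # Overlap uses open irradiation interval so a window may abut it exactly.
    if t_hi > trace.irradiation_start and t_lo < trace.irradiation_end:
        raise InvalidWindowError(
            f"fit window ({t_lo}, {t_hi}) overlaps the irradiation window "
            f"({trace.irradiation_start}, {trace.irradiation_end})"
        )
    mask = (trace.times >= t_lo) & (trace.times <= t_hi)
    n = int(mask.sum())
    if n < 4:
        raise DegenerateFitError(f"drift fit needs >= 4 samples in the window, got {n}")
    t = trace.times[mask]
    y = trace.temperatures[mask]
    # Centre both axes before fitting: the window midpoint is ~100 s and the
    # baseline ~300 K, so raw-basis normal equations would lose ~5 digits.
    tc = float(t.mean())
    yc = float(y.mean())
    d0, d1, d2 = np.polynomial.polynomial.polyfit(t - tc, y - yc, deg=2)
    # Expand to raw-time coefficients for reporting.
    c2 = d2
    c1 = d1 - 2.0 * d2 * tc
    c0 = yc + d0 - d1 * tc + d2 * tc * tc
    residuals = (y - yc) - (d0 + d1 * (t - tc) + d2 * (t - tc) ** 2)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return DriftModel(
        coefficients=(float(c0), float(c1), float(c2)),
        window=(t_lo, t_hi),
        residual_rms=rms,
        n_points=n,
        t_center=tc,
        y_center=yc,
        centered_coefficients=(float(d0), float(d1), float(d2)),
    )


def default_windows(
    trace: TemperatureTrace, guard_s: float = 2.0, fit_length_s: float = 60.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default pre/post drift-fit windows for a trace.

    Pre window: the ``fit_length_s`` seconds immediately before beam-on.
    Post window: ``fit_length_s`` seconds starting ``guard_s`` after beam-off
    (the guard lets heat redistribute inside the calorimeter stack).  Both are
    clipped to the sampled interval.
    """
    pre = (max(float(trace.times[0]), trace.irradiation_start - fit_length_s), trace.irradiation_start)
    post_lo = trace.irradiation_end + guard_s
    post = (post_lo, min(float(trace.times[-1]), post_lo + fit_length_s))
    return pre, post


def extract_temperature_rise(
    trace: TemperatureTrace,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    eval_time: float | None = None,
    *,
    guard_s: float = 2.0,
    fit_length_s: float = 60.0,
) -> TemperatureRise:
    """Temperature rise from the offset between extrapolated drift curves.

    Both drifts are extrapolated to ``eval_time`` (default: midpoint of the
    irradiation window) and the rise is the post-drift minus the pre-drift
    value there.  ``T_eval`` is the pre-drift extrapolation at ``eval_time``,
    the temperature at which the specific heat is evaluated.

    A non-positive rise is allowed (background or cooling runs) but flagged.
    """
    if pre_window is None or post_window is None:
        d_pre, d_post = default_windows(trace, guard_s=guard_s, fit_length_s=fit_length_s)
        pre_window = pre_window or d_pre
        post_window = post_window or d_post
    if pre_window[1] > trace.irradiation_start + 1e-12:
        raise InvalidWindowError("pre-drift window must end at or before irradiation start")
    if post_window[0] < trace.irradiation_end - 1e-12:
        raise InvalidWindowError("post-drift window must start at or after irradiation end")
    pre_fit = fit_drift(trace, pre_window)
    post_fit = fit_drift(trace, post_window)
    if eval_time is None:
        eval_time = trace.irradiation_midpoint
    delta = float(post_fit.predict(eval_time) - pre_fit.predict(eval_time))
    t_eval = float(pre_fit.predict(eval_time))
    return TemperatureRise(
        delta_T=delta,
        T_eval=t_eval,
        eval_time=float(eval_time),
        pre_fit=pre_fit,
        post_fit=post_fit,
        nonpositive=delta <= 0,
    )


def dose_to_core(
    delta_T: float, T_eval: float, model: SpecificHeatModel | None = None
) -> float:
    """Absorbed dose to the graphite core: ``c(T_eval) * delta_T`` (Gy).

    1 J kg^-1 = 1 Gy, so the product of a specific heat in J kg^-1 K^-1 and a
    temperature rise in K is directly a dose in Gy.
    """
    if not math.isfinite(delta_T):
        raise NonPhysicalValueError("delta_T must be finite")
    model = model or SpecificHeatModel()
    return specific_heat(model, T_eval) * delta_T


def dose_to_water(dose_core: float, factors: CorrectionFactors | None = None) -> float:
    """Convert dose-to-core to dose-to-water via the correction-factor chain."""
    factors = factors or CorrectionFactors()
    if any(v <= 0 for v in factors.as_dict().values()):
        raise NonPhysicalValueError("all correction factors must be positive")
    return dose_core * factors.product


def k_z_distance(measurement_sdd: float, reference_sdd: float) -> float:
    """Inverse-square source-distance correction ``(SDD_meas / SDD_ref)^2``."""
    if measurement_sdd <= 0 or reference_sdd <= 0:
        raise NonPhysicalValueError("source-to-detector distances must be positive")
    return (measurement_sdd / reference_sdd) ** 2


def graphite_equivalent_thickness(water_depth_g_cm2: float, scaling_factor: float) -> float:
    """Graphite mass thickness equivalent to a water depth (g cm^-2).

    The scaling factor (graphite-to-water mass-thickness ratio at the beam
    quality in use) is supplied by configuration; for the reference setup a
    water depth of 5.2 g cm^-2 corresponds to 5.9 g cm^-2 of graphite.
    """
    if water_depth_g_cm2 <= 0 or scaling_factor <= 0:
        raise NonPhysicalValueError("depth and scaling factor must be positive")
    return water_depth_g_cm2 * scaling_factor


@dataclass(frozen=True)
class RunSummary:
    """Mean, sample SD and relative standard error of repeated runs."""

    n: int
    mean: float
    sd: float
    rel_se_pct: float


def aggregate_runs(doses: Sequence[float]) -> RunSummary:
    """Aggregate repeated run doses: mean, sample SD, relative SE in percent.

    The relative standard error ``100 * (SD / sqrt(n)) / mean`` is the Type A
    uncertainty contribution of the repeated measurements.
    """
    d = np.asarray(list(doses), dtype=float)
    if d.size < 2:
        raise InsufficientReplicatesError("need at least two runs to aggregate")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if mean == 0:
        raise NonPhysicalValueError("mean dose is zero; relative SE undefined")
    rel_se = 100.0 * (sd / math.sqrt(d.size)) / abs(mean)
    return RunSummary(n=int(d.size), mean=mean, sd=sd, rel_se_pct=rel_se)


def analyze_trace(
    trace: TemperatureTrace,
    *,
    factors: CorrectionFactors | None = None,
    heat_model: SpecificHeatModel | None = None,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    eval_time: float | None = None,
    guard_s: float = 2.0,
    fit_length_s: float = 60.0,
) -> CalorimeterRunResult:
    """End-to-end analysis of one run: trace -> dose-to-water."""
    factors = factors or CorrectionFactors()
    heat_model = heat_model or SpecificHeatModel()
    rise = extract_temperature_rise(
        trace,
        pre_window=pre_window,
        post_window=post_window,
        eval_time=eval_time,
        guard_s=guard_s,
        fit_length_s=fit_length_s,
    )
    d_core = dose_to_core(rise.delta_T, rise.T_eval, heat_model)
    d_water = dose_to_water(d_core, factors)
    diagnostics = {
        "eval_time_s": rise.eval_time,
        "pre_window_s": list(rise.pre_fit.window),
        "post_window_s": list(rise.post_fit.window),
        "pre_residual_rms_K": rise.pre_fit.residual_rms,
        "post_residual_rms_K": rise.post_fit.residual_rms,
        "pre_n_points": rise.pre_fit.n_points,
        "post_n_points": rise.post_fit.n_points,
        "nonpositive_delta_T": rise.nonpositive,
        "guard_s": guard_s,
    }
    return CalorimeterRunResult(
        delta_T=rise.delta_T,
        T_eval=rise.T_eval,
        dose_to_core=d_core,
        dose_to_water=d_water,
        factors=factors,
        diagnostics=diagnostics,
    )
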