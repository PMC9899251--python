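"""Generative models for every input the pipeline consumes.

Nothing here touches an instrument: calorimeter temperature traces, repeated
run series, and chamber saturation curves are generated from explicit models
with known ground truth, so every analysis stage can be exercised and its
estimators validated for bias at a desk.

Trace model
-----------
A slow quadratic baseline drift, a heating step of ~10 mK produced by a
0.4-0.8 s delivery (back-computed from a target dose-to-water through the
same specific-heat and correction-factor chain the analysis uses), a linear
temperature ramp during the beam-on window, an optional post-irradiation
slope change, and additive white Gaussian noise (default 50 uK, below the
100 uK resolution of the sensing system being emulated).

Saturation-curve model
----------------------
reading(V) = M_sat * [1/(1 + A/V)] * [1/(1 + xi^2/V^2)] * (1 + mult*V) * (1 + noise)

i.e. a continuous-beam general-recombination term (quadratic in 1/V near
saturation), an optional initial-recombination term (linear in 1/V), and an
optional charge-multiplication term growing with voltage.  The true
correction is k_ion(V) = (1 + A/V)(1 + xi^2/V^2); multiplication is never
corrected for by the estimators, mirroring measurement practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calorimetry import CorrectionFactors, SpecificHeatModel, TemperatureTrace, specific_heat
from .chamber import SaturationCurve
from .errors import NonPhysicalValueError


@dataclass(frozen=True)
class TraceRecipe:
    """Generative parameters for one calorimeter run.

    The true temperature step is back-computed from ``dose_to_water_Gy``
    through the correction-factor product and the specific heat evaluated at
    the pre-drift temperature at the irradiation midpoint, so analysing a
    noiseless generated trace returns the recipe's dose exactly.

    ``duration_s=None`` draws the delivery time uniformly from
    ``duration_range_s`` (0.4-0.8 s, the range of delivery times emulated).
    """

    baseline_K: float = 297.7
    pre_drift_linear_K_per_s: float = 0.0
    pre_drift_quadratic_K_per_s2: float = 0.0
    post_slope_change_K_per_s: float = 0.0
    dose_to_water_Gy: float = 7.8
    factors: CorrectionFactors = field(default_factory=CorrectionFactors)
    heat_model: SpecificHeatModel = field(default_factory=SpecificHeatModel)
    duration_s: float | None = None
    duration_range_s: tuple[float, float] = (0.4, 0.8)
    irradiation_start_s: float = 120.0
    run_length_s: float = 240.0
    sample_rate_hz: float = 5.0
    noise_sd_K: float = 5e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_K < 0:
            raise NonPhysicalValueError("noise SD cannot be negative")
        if self.duration_s is not None and not (0 < self.duration_s < 10):
            raise NonPhysicalValueError("irradiation duration must be in (0, 10) s")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi < 10):
            raise NonPhysicalValueError("duration range must lie in (0, 10) s")
        if self.dose_to_water_Gy < 0:
            raise NonPhysicalValueError("target dose cannot be negative")


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth attached to a generated trace."""

    delta_T_K: float      # drift-offset at the irradiation midpoint (what the analysis estimates)
    step_K: float         # instantaneous heating step written into the trace
    dose_Gy: float
    T_eval_K: float
    duration_s: float
    seed: int | None


def _baseline(recipe: TraceRecipe, t: np.ndarray, t0: float) -> np.ndarray:
    dt = t - t0
    return (
        recipe.baseline_K
        + recipe.pre_drift_linear_K_per_s * dt
        + recipe.pre_drift_quadratic_K_per_s2 * dt**2
    )


def true_temperature_step(recipe: TraceRecipe, duration_s: float) -> tuple[float, float]:
    """Back-compute (step, T_eval) giving the recipe's dose-to-water."""
    t0 = recipe.irradiation_start_s
    mid = t0 + 0.5 * duration_s
    t_eval = float(_baseline(recipe, np.asarray([mid]), t0)[0])
    c = specific_heat(recipe.heat_model, t_eval)
    step = recipe.dose_to_water_Gy / (recipe.factors.product * c)
    return step, t_eval


def gen_calorimeter_trace(
    recipe: TraceRecipe, seed: int | None = None
) -> tuple[TemperatureTrace, TraceTruth]:
    """Generate one calorimeter run and its ground truth.

    The trace is the pre-drift polynomial before beam-on, a linear ramp of
    the true step during the beam-on window, and the pre-drift polynomial
    plus step (plus optional slope change) afterwards, with white Gaussian
    noise added throughout.  Identical ``(recipe, seed)`` pairs produce
    byte-identical traces.
    """
    use_seed = seed if seed is not None else recipe.seed
    rng = np.random.default_rng(use_seed)
    duration = recipe.duration_s
    if duration is None:
        duration = float(rng.uniform(*recipe.duration_range_s))
    t0 = recipe.irradiation_start_s
    t1 = t0 + duration
    n = int(round(recipe.run_length_s * recipe.sample_rate_hz)) + 1
    times = np.arange(n) / recipe.sample_rate_hz
    step, t_eval = true_temperature_step(recipe, duration)

    signal = _baseline(recipe, times, t0)
    during = (times >= t0) & (times <= t1)
    after = times > t1
    signal[during] += step * (times[during] - t0) / duration
    signal[after] += step + recipe.post_slope_change_K_per_s * (times[after] - t1)
    if recipe.noise_sd_K > 0:
        signal = signal + rng.normal(0.0, recipe.noise_sd_K, size=n)

    trace = TemperatureTrace(
        times=times,
        temperatures=signal,
        irradiation_start=t0,
        irradiation_end=t1,
        sample_rate=recipe.sample_rate_hz,
    )
    mid = t0 + 0.5 * duration
    # Offset between the two drift polynomials at the midpoint: equals the
    # step unless a post-irradiation slope change is present.
    delta_mid = step + recipe.post_slope_change_K_per_s * (mid - t1)
    truth = TraceTruth(
        delta_T_K=float(delta_mid),
        step_K=float(step),
        dose_Gy=recipe.dose_to_water_Gy,
        T_eval_K=t_eval,
        duration_s=float(duration),
        seed=use_seed,
    )
    return trace, truth


def gen_run_series(
    recipe: TraceRecipe,
    n_runs: int,
    inter_run_rel_sd: float,
    seed: int | None = None,
) -> list[tuple[TemperatureTrace, TraceTruth]]:
    """Generate a reproducible series of runs with jittered true doses.

    Per-run true doses are the recipe dose multiplied by
    ``1 + inter_run_rel_sd * z`` (z standard normal); per-run noise seeds are
    spawned from the master seed, so the whole series is reproducible while
    runs remain statistically independent.
    """
    if n_runs < 1:
        raise NonPhysicalValueError("n_runs must be >= 1")
    if inter_run_rel_sd < 0:
        raise NonPhysicalValueError("inter-run relative SD cannot be negative")
    master = np.random.SeedSequence(seed if seed is not None else recipe.seed)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])
    doses = recipe.dose_to_water_Gy * (
        1.0 + inter_run_rel_sd * jitter_rng.standard_normal(n_runs)
    )
    children = master.spawn(n_runs + 1)[1:]
    out = []
    for dose, child in zip(doses, children):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        run_recipe = replace(recipe, dose_to_water_Gy=float(dose), seed=None)
        out.append(gen_calorimeter_trace(run_recipe, seed=run_seed))
    return out


@dataclass(frozen=True)
class CurveRecipe:
    """Generative parameters for a saturation curve.

    ``rel_noise_sd`` is the relative SD of each mean reading; the default
    1e-4 corresponds to each voltage point being the mean of a few tens of
    repeated deliveries normalised to the beam monitor.
    """

    m_sat: float = 1.0
    xi2_V2: float = 0.0
    initial_A_V: float = 0.0
    multiplication_per_V: float = 0.0
    voltages: tuple[float, ...] = (100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 600.0)
    rel_noise_sd: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("m_sat",):
            if getattr(self, name) <= 0:
                raise NonPhysicalValueError(f"{name} must be positive")
        for name in ("xi2_V2", "initial_A_V", "multiplication_per_V", "rel_noise_sd"):
            if getattr(self, name) < 0:
                raise NonPhysicalValueError(f"{name} cannot be negative")
        v = np.asarray(self.voltages, dtype=float)
        if np.any(v <= 0) or np.unique(v).size != v.size:
            raise NonPhysicalValueError("voltages must be positive and distinct")


@dataclass(frozen=True)
class CurveTruth:
    """Ground truth for a generated saturation curve."""

    m_sat: float
    xi2_V2: float
    initial_A_V: float
    multiplication_per_V: float
    seed: int | None

    def k_ion(self, voltage: float) -> float:
        """True recombination correction at ``voltage`` (multiplication excluded)."""
        return (1.0 + self.initial_A_V / voltage) * (1.0 + self.xi2_V2 / voltage**2)


def gen_saturation_curve(
    recipe: CurveRecipe, seed: int | None = None
) -> tuple[SaturationCurve, CurveTruth]:
    """Generate a saturation curve and its ground-truth correction function."""
    use_seed = seed if seed is not None else recipe.seed
    rng = np.random.default_rng(use_seed)
    v = np.asarray(recipe.voltages, dtype=float)
    readings = (
        recipe.m_sat
        / (1.0 + recipe.initial_A_V / v)
        / (1.0 + recipe.xi2_V2 / v**2)
        * (1.0 + recipe.multiplication_per_V * v)
    )
    if recipe.rel_noise_sd > 0:
        readings = readings * (1.0 + rng.normal(0.0, recipe.rel_noise_sd, size=v.size))
    sd = np.full(v.size, recipe.rel_noise_sd) * readings
    curve = SaturationCurve(voltages=v, readings=readings, reading_sd=sd)
    truth = CurveTruth(
        m_sat=recipe.m_sat,
        xi2_V2=recipe.xi2_V2,
        initial_A_V=recipe.initial_A_V,
        multiplication_per_V=recipe.multiplication_per_V,
        seed=use_seed,
    )
    return curve, truth


def curve_recipe_for_k_ion(
    k_ion: float,
    v_op: float,
    initial_fraction: float = 0.0,
    **kwargs,
) -> CurveRecipe:
    """Recipe whose true correction at ``v_op`` equals ``k_ion``.

    ``initial_fraction`` apportions the recombination excess (k_ion - 1)
    between the initial-recombination term (linear in 1/V) and the general
    term (quadratic in 1/V): A/V_op = initial_fraction * (k_ion - 1), with
    xi^2 chosen so the product matches exactly.
    """
    if k_ion < 1:
        raise NonPhysicalValueError("target k_ion must be >= 1")
    if not (0 <= initial_fraction <= 1):
        raise NonPhysicalValueError("initial_fraction must be in [0, 1]")
    a = initial_fraction * (k_ion - 1.0) * v_op
    xi2 = (k_ion / (1.0 + a / v_op) - 1.0) * v_op**2
    return CurveRecipe(initial_A_V=a, xi2_V2=xi2, **kwargs)
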