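"""Ionisation-chamber reference dosimetry and ion-recombination analysis.

Implements the standard dose chain for a chamber calibrated in terms of
absorbed dose to water in a Co-60 beam:

    D_w = M * k_tp * k_elec * k_pol * k_ion * N_Dw * k_Q

together with the analysis of saturation curves at ultra-high dose rate:
normalisation, Jaffe-plot classification of the beam as pulsed (reciprocal
reading linear in reciprocal voltage) or continuous (quadratic), and the two-
and three-voltage ion-recombination estimators.  At averaged dose rates of
tens of Gy/s a cyclotron-delivered pencil-beam-scanned field behaves as a
continuous beam for recombination purposes, and the continuous-beam quadratic
expressions apply.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    NonPhysicalValueError,
)

GEOMETRIES = ("plane-parallel", "cylindrical")

#: Reference air temperature by calibrating laboratory (kelvin).
REFERENCE_TEMPERATURE_K = {"NPL": 293.2, "NIST": 295.2}
REFERENCE_PRESSURE_MBAR = 1013.3


@dataclass(frozen=True)
class ChamberSpec:
    """Calibration metadata for one ionisation chamber.

    ``n_dw_gy_per_c`` is the absorbed-dose-to-water calibration coefficient
    (Gy/C) and ``k_q`` the beam-quality correction from the calibration beam
    (Co-60) to the user beam.  Reference conditions follow the calibrating
    laboratory: 293.2 K (NPL) or 295.2 K (NIST), both at 1013.3 mbar.
    """

    name: str
    geometry: str
    volume_cm3: float
    electrode_spacing_mm: float
    n_dw_gy_per_c: float
    k_q: float
    ref_temperature_K: float = 293.2
    ref_pressure_mbar: float = REFERENCE_PRESSURE_MBAR
    operating_voltage_V: float = -400.0
    calibration_lab: str = "NPL"

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ConfigurationError(f"geometry must be one of {GEOMETRIES}")
        for name in ("volume_cm3", "electrode_spacing_mm", "n_dw_gy_per_c", "k_q"):
            if getattr(self, name) <= 0:
                raise NonPhysicalValueError(f"{name} must be positive")
        if not (800.0 < self.ref_pressure_mbar < 1100.0):
            raise NonPhysicalValueError("reference pressure outside (800, 1100) mbar")
        if self.ref_temperature_K <= 0:
            raise NonPhysicalValueError("reference temperature must be positive")


@dataclass(frozen=True)
class ChamberReading:
    """One corrected charge measurement.

    Charge and voltage are signed; the default operating polarity collects
    negative charge at -400 V.  ``k_elec`` is the electrometer calibration
    factor (1.0 when the electrometer is calibrated with the chamber).
    """

    charge_C: float
    voltage_V: float
    temperature_K: float
    pressure_mbar: float
    k_elec: float = 1.0

    def __post_init__(self) -> None:
        if self.voltage_V == 0:
            raise NonPhysicalValueError("polarising voltage cannot be zero")
        if self.temperature_K <= 0 or self.pressure_mbar <= 0:
            raise NonPhysicalValueError("ambient temperature and pressure must be positive")
        if self.k_elec <= 0:
            raise NonPhysicalValueError("electrometer correction must be positive")


def air_density_correction(
    temperature_K: float,
    pressure_mbar: float,
    ref_temperature_K: float,
    ref_pressure_mbar: float = REFERENCE_PRESSURE_MBAR,
) -> float:
    """Temperature-pressure correction ``(T/T_ref) * (P_ref/P)`` for vented chambers."""
    if temperature_K <= 0 or pressure_mbar <= 0:
        raise NonPhysicalValueError("temperature and pressure must be positive")
    if ref_temperature_K <= 0 or ref_pressure_mbar <= 0:
        raise NonPhysicalValueError("reference temperature and pressure must be positive")
    return (temperature_K / ref_temperature_K) * (ref_pressure_mbar / pressure_mbar)


def k_tp(reading: ChamberReading, spec: ChamberSpec) -> float:
    """Air-density correction for a reading against its chamber's reference conditions."""
    return air_density_correction(
        reading.temperature_K, reading.pressure_mbar, spec.ref_temperature_K, spec.ref_pressure_mbar
    )


def k_polarity(m_plus: float, m_minus: float, m_operating: float) -> float:
    """Polarity correction ``(|M+| + |M-|) / (2 |M_op|)``."""
    if m_operating == 0:
        raise NonPhysicalValueError("operating reading cannot be zero")
    return (abs(m_plus) + abs(m_minus)) / (2.0 * abs(m_operating))


@dataclass(frozen=True)
class SaturationCurve:
    """Chamber reading versus polarising-voltage magnitude.

    Stored sorted by ascending voltage.  ``reading_sd`` is the standard
    deviation of each mean reading (optional).  ``normalized`` records whether
    readings have been divided by the mean reading at the maximum voltage.
    """

    voltages: np.ndarray
    readings: np.ndarray
    reading_sd: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        m = np.asarray(self.readings, dtype=float)
        if v.ndim != 1 or v.shape != m.shape or v.size < 1:
            raise ValueError("voltages and readings must be 1-D, same length, non-empty")
        if np.any(v <= 0):
            raise NonPhysicalValueError("voltage magnitudes must be positive")
        if np.unique(v).size != v.size:
            raise NonPhysicalValueError("voltages must be distinct")
        if np.any(m <= 0):
            raise NonPhysicalValueError("readings must be positive")
        order = np.argsort(v)
        sd = self.reading_sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != v.shape:
                raise ValueError("reading_sd must match the curve length")
            sd = sd[order]
        object.__setattr__(self, "voltages", v[order])
        object.__setattr__(self, "readings", m[order])
        object.__setattr__(self, "reading_sd", sd)

    def __len__(self) -> int:
        return int(self.voltages.size)

    def reading_at(self, voltage: float) -> float:
        idx = np.nonzero(np.isclose(self.voltages, voltage))[0]
        if idx.size == 0:
            raise ConfigurationError(f"no reading at {voltage} V in the curve")
        return float(self.readings[idx[0]])


def normalize_saturation(curve: SaturationCurve) -> SaturationCurve:
    """Normalise readings to the mean reading at the maximum applied voltage."""
    ref = float(curve.readings[-1])  # curve is sorted ascending in voltage
    sd = None if curve.reading_sd is None else curve.reading_sd / ref
    return SaturationCurve(
        voltages=curve.voltages.copy(),
        readings=curve.readings / ref,
        reading_sd=sd,
        normalized=True,
    )


@dataclass(frozen=True)
class JaffeFit:
    """One polynomial fit of 1/M against 1/V."""

    degree: int
    coefficients: tuple[float, ...]  # ascending powers of 1/V
    rss: float


@dataclass(frozen=True)
class JaffeResult:
    """Jaffe-plot classification of the recombination regime."""

    beam_class: str  # "pulsed" | "continuous"
    linear: JaffeFit
    quadratic: JaffeFit
    rss_improvement: float  # relative RSS reduction of quadratic vs linear


def _polyfit_reciprocal(x: np.ndarray, y: np.ndarray, degree: int) -> JaffeFit:
    from numpy.polynomial import Polynomial

    poly = Polynomial.fit(x, y, deg=degree).convert()
    coeffs = np.zeros(degree + 1)
    coeffs[: poly.coef.size] = poly.coef
    rss = float(np.sum((y - poly(x)) ** 2))
    return JaffeFit(degree=degree, coefficients=tuple(float(c) for c in coeffs), rss=rss)


def jaffe_classify(curve: SaturationCurve, rel_improvement_threshold: float = 0.5) -> JaffeResult:
    """Classify the beam as pulsed or continuous from a Jaffe plot.

    Fits 1/M against 1/V with degree-1 and degree-2 polynomials.  The beam is
    called continuous when the quadratic fit reduces the residual sum of
    squares by more than ``rel_improvement_threshold`` (relative) *and* its
    quadratic coefficient is positive; otherwise pulsed.
    """
    if len(curve) < 4:
        raise InsufficientDataError("Jaffe classification needs >= 4 voltage points")
    x = 1.0 / curve.voltages
    y = 1.0 / curve.readings
    lin = _polyfit_reciprocal(x, y, 1)
    quad = _polyfit_reciprocal(x, y, 2)
    improvement = 0.0 if lin.rss == 0 else 1.0 - quad.rss / lin.rss
    continuous = improvement > rel_improvement_threshold and quad.coefficients[2] > 0
    return JaffeResult(
        beam_class="continuous" if continuous else "pulsed",
        linear=lin,
        quadratic=quad,
        rss_improvement=float(improvement),
    )


@dataclass(frozen=True)
class RecombinationEstimate:
    """An ion-recombination correction with its provenance.

    ``k_ion`` applies at the operating voltage.  Estimates below 1 or far
    above the usual range are flagged rather than rejected, because they can
    legitimately arise near the estimator's pole or from charge
    multiplication.
    """

    k_ion: float
    method: str  # "two-voltage" | "three-voltage"
    beam_class: str = "continuous"
    m_sat: float | None = None
    coefficients: tuple[float, ...] | None = None
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_ion):
            raise NonPhysicalValueError("k_ion must be finite")
        if not self.method:
            raise ValueError("method tag must be set")


#: estimates outside this range are flagged as suspect
_K_ION_PLAUSIBLE = (1.0, 2.0)


def _flag(k: float) -> tuple[bool, str]:
    lo, hi = _K_ION_PLAUSIBLE
    if k < lo:
        return True, f"k_ion < {lo}: over-saturated readings or charge multiplication"
    if k > hi:
        return True, f"k_ion > {hi}: close to the estimator's pole; correction unreliable"
    return False, ""


def k_ion_two_voltage_continuous(
    m1: float, v1: float, m2: float, v2: float
) -> RecombinationEstimate:
    """Two-voltage ion-recombination correction for a continuous beam.

    With ``r = V1/V2`` the correction at the operating voltage V1 is

        k_ion(V1) = (r^2 - 1) / (r^2 - M1/M2)

    which is exact when the collection efficiency follows the near-saturation
    continuous-beam model ``f(V) = 1 / (1 + xi^2 / V^2)``.
    """
    if v1 <= 0 or v2 <= 0 or v1 == v2:
        raise NonPhysicalValueError("need V1 > V2 > 0 with distinct voltages")
    if v1 < v2:
        raise NonPhysicalValueError("V1 must be the larger (operating) voltage")
    if m1 <= 0 or m2 <= 0:
        raise NonPhysicalValueError("readings must be positive")
    r2 = (v1 / v2) ** 2
    denom = r2 - m1 / m2
    if denom <= 0:
        raise NonPhysicalValueError(
            "M1/M2 >= (V1/V2)^2: readings inconsistent with continuous-beam recombination"
        )
    k = (r2 - 1.0) / denom
    flagged, note = _flag(k)
    return RecombinationEstimate(
        k_ion=float(k), method="two-voltage", flagged=flagged, note=note
    )


def k_ion_two_voltage_from_curve(
    curve: SaturationCurve, v_op: float | None = None, voltage_ratio: float = 2.0
) -> RecombinationEstimate:
    """Two-voltage estimate from a saturation curve.

    Uses the reading at ``v_op`` (default: the largest voltage) and the curve
    point closest to ``v_op / voltage_ratio``.
    """
    if len(curve) < 2:
        raise InsufficientDataError("two-voltage method needs at least two voltages")
    v = curve.voltages
    v1 = float(v.max()) if v_op is None else float(v_op)
    m1 = curve.reading_at(v1)
    lower = v[v < v1]
    if lower.size == 0:
        raise InsufficientDataError("no voltage below the operating voltage in the curve")
    v2 = float(lower[np.argmin(np.abs(lower - v1 / voltage_ratio))])
    m2 = curve.reading_at(v2)
    return k_ion_two_voltage_continuous(m1, v1, m2, v2)


def k_ion_three_voltage(
    curve: SaturationCurve, v_op: float, n_points: int = 3
) -> RecombinationEstimate:
    """Three-voltage (saturation-extrapolation) ion-recombination correction.

    Fits ``1/M = a + b/V + c/V^2`` through the ``n_points`` highest voltages
    of the curve (exact solve for three points, least squares for more) and
    returns ``k_ion(V_op) = (a + b/V_op + c/V_op^2) / a`` together with the
    saturated-reading estimate ``M_sat = 1/a``.  Fitting at voltages above the
    operating voltage — where the chamber is closest to saturation — keeps the
    extrapolation inside the regime where the quadratic reciprocal model holds.
    """
    if n_points < 3:
        raise InsufficientDataError("three-voltage method needs n_points >= 3")
    if len(curve) < n_points:
        raise InsufficientDataError(
            f"curve has {len(curve)} voltages, need at least {n_points}"
        )
    if v_op > float(curve.voltages.max()) + 1e-9:
        raise ConfigurationError("operating voltage must be at or below the largest fitted voltage")
    v = curve.voltages[-n_points:]
    m = curve.readings[-n_points:]
    x = 1.0 / v
    y = 1.0 / m
    vand = np.vander(x, 3, increasing=True)  # columns: 1, x, x^2
    if n_points == 3:
        try:
            coeffs = np.linalg.solve(vand, y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by distinct voltages
            raise NonPhysicalValueError("singular three-voltage system") from exc
    else:
        coeffs, *_ = np.linalg.lstsq(vand, y, rcond=None)
    a, b, c = (float(q) for q in coeffs)
    if a <= 0:
        raise NonPhysicalValueError(
            "extrapolated saturated reading is non-physical (intercept <= 0)"
        )
    k = (a + b / v_op + c / v_op**2) / a
    flagged, note = _flag(k)
    return RecombinationEstimate(
        k_ion=float(k),
        method="three-voltage",
        m_sat=1.0 / a,
        coefficients=(a, b, c),
        flagged=flagged,
        note=note,
    )


def dose_from_chamber(
    reading: ChamberReading, spec: ChamberSpec, k_ion: float, k_pol: float
) -> float:
    """Absorbed dose to water from one corrected chamber reading (Gy).

    ``D_w = |Q| * k_tp * k_elec * k_pol * k_ion * N_Dw * k_Q``.
    """
    for name, value in (("k_ion", k_ion), ("k_polarity", k_pol)):
        if value <= 0:
            raise NonPhysicalValueError(f"{name} must be positive")
    if spec.n_dw_gy_per_c is None or spec.n_dw_gy_per_c <= 0:
        raise ConfigurationError("chamber has no valid calibration coefficient")
    return (
        abs(reading.charge_C)
        * k_tp(reading, spec)
        * reading.k_elec
        * k_pol
        * k_ion
        * spec.n_dw_gy_per_c
        * spec.k_q
    )


def ratio_to_calorimeter(d_cal: float, d_chamber: float) -> float:
    """Ratio of calorimeter-determined to chamber-derived dose."""
    if d_chamber <= 0 or d_cal <= 0:
        raise NonPhysicalValueError("doses must be positive")
    return d_cal / d_chamber


def ratio_summary(ratios: Sequence[float]) -> tuple[float, float | None]:
    """Mean ratio and its Type A standard error (None for a single field)."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise InsufficientDataError("no ratios to summarise")
    mean = float(r.mean())
    if r.size < 2:
        return mean, None
    return mean, float(r.std(ddof=1) / math.sqrt(r.size))


def load_chamber_registry(path=None) -> dict[str, ChamberSpec]:
    """Load a chamber registry (name -> ChamberSpec) from a JSON file.

    Without a path, the registry shipped with the package is used.  Shipped
    calibration coefficients are placeholders (marked in the file) so that the
    chain is runnable end to end without real calibration certificates.
    """
    if path is None:
        text = resources.files("flashcal.data").joinpath("chambers.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    registry: dict[str, ChamberSpec] = {}
    for entry in raw["chambers"]:
        fields = {k: v for k, v in entry.items() if not k.startswith("_")}
        lab = fields.get("calibration_lab", "NPL")
        fields.setdefault("ref_temperature_K", REFERENCE_TEMPERATURE_K.get(lab, 293.2))
        spec = ChamberSpec(**fields)
        registry[spec.name] = spec
    return registry
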