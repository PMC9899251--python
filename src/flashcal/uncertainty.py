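"""GUM-style uncertainty budget: quadrature combination of relative components.

Components are relative standard uncertainties in percent, classified Type A
(evaluated statistically from repeated observations) or Type B (evaluated by
other means).  Uncorrelated components combine in quadrature; the overall
standard uncertainty is the quadrature of the two class totals.

Entries quoted only as upper bounds ("< 0.01") are stored as bounds and, by
default, enter the quadrature at their bound value (conservative); using zero
instead changes no rounded total for the shipped budget.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .errors import NonPhysicalValueError


def combine_quadrature(values: Iterable[float]) -> float:
    """Square root of the sum of squares; an empty list combines to 0."""
    total = 0.0
    for v in values:
        if v < 0:
            raise NonPhysicalValueError("uncertainty components cannot be negative")
        total += v * v
    return math.sqrt(total)


def triangular_std_uncertainty(lower: float, mode: float, upper: float) -> float:
    """Standard deviation of a (possibly asymmetric) triangular distribution.

    For limits ``a <= m <= b`` (with ``a < b``):

        sd = sqrt((a^2 + m^2 + b^2 - a*m - a*b - m*b) / 18)

    Used to convert a best estimate with asymmetric limits (e.g. a correction
    factor bracketed by two independent computations) into a standard
    uncertainty.
    """
    if not (lower <= mode <= upper) or not (lower < upper):
        raise NonPhysicalValueError("need lower <= mode <= upper with lower < upper")
    var = (
        lower * lower
        + mode * mode
        + upper * upper
        - lower * mode
        - lower * upper
        - mode * upper
    ) / 18.0
    return math.sqrt(var)


@dataclass(frozen=True)
class UncertaintyComponent:
    """One labelled source of relative uncertainty (percent).

    ``type_a``/``type_b`` may be ``None`` when the source contributes to only
    one class; ``*_is_bound`` marks values quoted as upper bounds.
    """

    label: str
    type_a: float | None = None
    type_b: float | None = None
    type_a_is_bound: bool = False
    type_b_is_bound: bool = False

    def __post_init__(self) -> None:
        if self.type_a is None and self.type_b is None:
            raise ValueError(f"component {self.label!r} has neither Type A nor Type B value")
        for v in (self.type_a, self.type_b):
            if v is not None and v < 0:
                raise NonPhysicalValueError("uncertainty components cannot be negative")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Ordered uncertainty components with quadrature totals.

    Rounding policy (matching the precision such budgets are tabulated at):
    class totals to 2 decimals, overall to 1 decimal.  Unrounded totals are
    always available; ``overall`` is computed from the unrounded totals.
    """

    components: tuple[UncertaintyComponent, ...]

    def __init__(self, components: Sequence[UncertaintyComponent]):
        object.__setattr__(self, "components", tuple(components))

    def _values(self, which: str, bounds_at_value: bool) -> list[float]:
        out = []
        for comp in self.components:
            v = getattr(comp, which)
            if v is None:
                continue
            if getattr(comp, f"{which}_is_bound") and not bounds_at_value:
                v = 0.0
            out.append(v)
        return out

    def total_type_a(self, bounds_at_value: bool = True) -> float:
        return combine_quadrature(self._values("type_a", bounds_at_value))

    def total_type_b(self, bounds_at_value: bool = True) -> float:
        return combine_quadrature(self._values("type_b", bounds_at_value))

    def overall(self, bounds_at_value: bool = True) -> float:
        """Overall relative standard uncertainty (1 sigma), percent, unrounded."""
        return combine_quadrature(
            [self.total_type_a(bounds_at_value), self.total_type_b(bounds_at_value)]
        )

    def summary(self, bounds_at_value: bool = True) -> dict:
        """Totals under the budget's rounding policy, plus unrounded values."""
        a = self.total_type_a(bounds_at_value)
        b = self.total_type_b(bounds_at_value)
        o = self.overall(bounds_at_value)
        return {
            "type_a_pct": round(a, 2),
            "type_b_pct": round(b, 2),
            "overall_pct": round(o, 1),
            "type_a_pct_unrounded": a,
            "type_b_pct_unrounded": b,
            "overall_pct_unrounded": o,
            "n_components": len(self.components),
        }


def _parse_cell(cell) -> tuple[float | None, bool]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None, False
    s = str(cell).strip()
    if s in ("", "-", "–"):
        return None, False
    if s.startswith("<"):
        return float(s[1:]), True
    return float(s), False


def load_budget_csv(path=None) -> UncertaintyBudget:
    """Load a budget from CSV ``label,type_A_pct,type_B_pct``.

    A ``<`` prefix marks an upper bound; empty cells mean the component does
    not contribute to that class.  Without a path, the budget shipped with the
    package (the calorimeter's dose-to-water budget) is loaded.
    """
    if path is None:
        with resources.files("flashcal.data").joinpath("uncertainty_budget.csv").open() as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    required = {"label", "type_A_pct", "type_B_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"budget CSV must have columns {sorted(required)}")
    comps = []
    for _, row in df.iterrows():
        a, a_bound = _parse_cell(row["type_A_pct"])
        b, b_bound = _parse_cell(row["type_B_pct"])
        comps.append(
            UncertaintyComponent(
                label=str(row["label"]),
                type_a=a,
                type_b=b,
                type_a_is_bound=a_bound,
                type_b_is_bound=b_bound,
            )
        )
    return UncertaintyBudget(comps)


def save_budget_csv(budget: UncertaintyBudget, path) -> None:
    """Write a budget back to the same CSV dialect ``load_budget_csv`` reads."""
    rows = []
    for c in budget.components:
        def fmt(v, bound):
            if v is None:
                return ""
            return f"<{v}" if bound else f"{v}"

        rows.append(
            {
                "label": c.label,
                "type_A_pct": fmt(c.type_a, c.type_a_is_bound),
                "type_B_pct": fmt(c.type_b, c.type_b_is_bound),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def npl_pspc_budget() -> UncertaintyBudget:
    """The shipped dose-to-water uncertainty budget for the graphite calorimeter."""
    return load_budget_csv(None)
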