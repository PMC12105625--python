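"""Theory-vs-experiment calibration: OLS fits, error metrics, linear adjustment.

Computed oxidation potentials in water are systematically high but
linearly related to the measured ones.  A benchmark regression
(E_exp = slope * E_theor + intercept) quantifies the relationship; the
*linear adjustment* then rescales predicted potentials for a family of
related compounds by the benchmark slope and anchors the intercept so a
chosen reference compound reproduces its experimental value exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "PairedObservations",
    "RegressionFit",
    "AdjustmentRule",
    "resolve_bounds",
    "fit_linear",
    "error_metrics",
    "make_adjustment_rule",
    "linear_adjust",
    "round_display",
]

_CENSOR_FLAGS = ("exact", "lower_bound")


def round_display(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table formatting."""
    value = float(value)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(abs(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(-d if value < 0 else d)


@dataclass
class PairedObservations:
    """Per-compound theoretical and experimental values, with censoring.

    A censoring flag of ``lower_bound`` marks an experimental entry that
    is only known to exceed the stored value (e.g. a voltammetric window
    limit printed as ">2.15").
    """

    compound_ids: list[str]
    theoretical: np.ndarray
    experimental: np.ndarray
    censoring: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theoretical = np.asarray(self.theoretical, dtype=float)
        self.experimental = np.asarray(self.experimental, dtype=float)
        if not self.censoring:
            self.censoring = ["exact"] * len(self.compound_ids)
        n = len(self.compound_ids)
        if not (len(self.theoretical) == len(self.experimental) == len(self.censoring) == n):
            raise ValueError("compound_ids, values and censoring must have equal length")
        if n < 2:
            raise ValueError("need at least two paired observations")
        if not (np.isfinite(self.theoretical).all() and np.isfinite(self.experimental).all()):
            raise ValueError("paired values must be finite")
        for flag in self.censoring:
            if flag not in _CENSOR_FLAGS:
                raise ValueError(f"unknown censoring flag {flag!r}")

    @property
    def n(self) -> int:
        return len(self.compound_ids)


@dataclass(frozen=True)
class RegressionFit:
    """Slope/intercept/R^2 and error metrics of a calibration fit."""

    slope: float
    intercept: float
    r_squared: float
    mse: float  # mean signed error, theoretical - experimental
    mue: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")


def resolve_bounds(pairs: PairedObservations, policy: str = "at_bound") -> PairedObservations:
    """Resolve lower-bound (censored) experimental entries before fitting.

    ``at_bound`` keeps the entry at its bound value (a conservative
    stand-in); ``drop`` removes it.  Exact entries pass through.
    """
    if policy == "at_bound":
        return PairedObservations(
            compound_ids=list(pairs.compound_ids),
            theoretical=pairs.theoretical.copy(),
            experimental=pairs.experimental.copy(),
            censoring=["exact"] * pairs.n,
        )
    if policy == "drop":
        keep = [i for i, c in enumerate(pairs.censoring) if c == "exact"]
        return PairedObservations(
            compound_ids=[pairs.compound_ids[i] for i in keep],
            theoretical=pairs.theoretical[keep],
            experimental=pairs.experimental[keep],
            censoring=["exact"] * len(keep),
        )
    raise ValueError(f"unknown bound-resolution policy {policy!r}")


def error_metrics(pairs: PairedObservations) -> tuple[float, float, float]:
    """(MSE, MUE, RMSE) of theoretical - experimental residuals.

    The signed convention is theoretical minus experimental, so a positive
    MSE means the computation overestimates.
    """
    d = pairs.theoretical - pairs.experimental
    return float(d.mean()), float(np.abs(d).mean()), float(np.sqrt((d**2).mean()))


def fit_linear(pairs: PairedObservations) -> RegressionFit:
    """Ordinary least squares of experimental on theoretical values.

    R^2 is the squared Pearson correlation.  Censored entries must be
    resolved first (:func:`resolve_bounds`); unresolved bounds are refused
    rather than silently treated as exact.
    """
    if any(c != "exact" for c in pairs.censoring):
        raise ValueError("resolve censored entries (resolve_bounds) before fitting")
    if np.ptp(pairs.theoretical) == 0:
        raise ValueError("theoretical values have zero variance; no fit possible")
    res = stats.linregress(pairs.theoretical, pairs.experimental)
    mse, mue, rmse = error_metrics(pairs)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        mse=mse,
        mue=mue,
        rmse=rmse,
        n=pairs.n,
    )


@dataclass(frozen=True)
class AdjustmentRule:
    """Slope-and-anchor recalibration of raw computed potentials.

    adjusted(c) = slope_factor * raw(c) + derived_intercept, with the
    intercept fixed so the anchor compound returns its experimental value
    exactly.
    """

    slope_factor: float
    anchor_compound: str
    anchor_experimental: float
    derived_intercept: float


def make_adjustment_rule(
    raw_values: Mapping[str, float],
    slope_factor: float,
    anchor_compound: str,
    anchor_experimental: float,
) -> AdjustmentRule:
    """Derive the intercept from the anchor compound's raw value."""
    if anchor_compound not in raw_values:
        raise ValueError(
            f"anchor compound {anchor_compound!r} is absent from the raw values"
        )
    intercept = anchor_experimental - slope_factor * raw_values[anchor_compound]
    return AdjustmentRule(
        slope_factor=slope_factor,
        anchor_compound=anchor_compound,
        anchor_experimental=anchor_experimental,
        derived_intercept=intercept,
    )


def linear_adjust(
    raw_values: Mapping[str, float],
    rule: AdjustmentRule,
) -> dict[str, float]:
    """Apply a slope-and-anchor rule to every compound's raw potential."""
    if rule.anchor_compound not in raw_values:
        raise ValueError(
            f"anchor compound {rule.anchor_compound!r} is absent from the raw values"
        )
    adjusted = {
        c: rule.slope_factor * v + rule.derived_intercept
        for c, v in raw_values.items()
    }
    # anchor identity holds exactly by construction of the intercept
    adjusted[rule.anchor_compound] = rule.anchor_experimental
    return adjusted
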