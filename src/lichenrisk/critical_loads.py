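"""Invert fitted 90%-quantile curves into critical loads and risk classes.

The reference ("maximum") response is the fitted value at the minimum
observed deposition x_min.  The percent decline at deposition x is

    decline(x) = 1 - f(x) / f(x_min)

and the critical load is the deposition at a 20% decline.  Declines of
0-20% indicate low risk, >20-50% moderate, >50-80% high and >80% very high.
Bootstrap confidence intervals for the critical load come from re-inverting
each bootstrap replicate's curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from lichenrisk.quantile import BootstrapResult, QuantileFit
from lichenrisk.synthetic import round_half_away

__all__ = [
    "RiskConfig",
    "CriticalLoadResult",
    "decline_fraction",
    "deposition_at_decline",
    "build_risk_table",
    "classify_risk",
    "cl_confidence_interval",
]


@dataclass(frozen=True)
class RiskConfig:
    """Decline anchors and risk-class boundaries (fractions of the maximum)."""

    decline_anchors: tuple[float, ...] = (0.0, 0.10, 0.20, 0.50, 0.80)
    cl_decline: float = 0.20
    class_bounds: tuple[float, float, float] = (0.20, 0.50, 0.80)
    root_tolerance: float = 1e-6

    def __post_init__(self):
        a = self.decline_anchors
        if any(not 0.0 <= v < 1.0 for v in a) or list(a) != sorted(set(a)):
            raise ValueError("anchors must be strictly increasing in [0, 1)")


def _as_curve(curve) -> Callable[[np.ndarray], np.ndarray]:
    """Accept a QuantileFit (deposition-polynomial), coefficient array, or callable."""
    if isinstance(curve, QuantileFit):
        coefs = np.asarray(curve.coef, dtype=float)
        return lambda x: np.polyval(coefs[::-1], x)
    if callable(curve):
        return curve
    coefs = np.asarray(curve, dtype=float)
    return lambda x: np.polyval(coefs[::-1], x)


def decline_fraction(curve, x, x_min: float) -> float:
    """Fractional decline of the curve at x relative to its value at x_min.

    Clipped to [0, 1]: a fitted value above the reference counts as no
    decline, and a negative fitted value as complete loss.
    """
    f = _as_curve(curve)
    ref = float(f(x_min))
    if ref <= 0:
        raise ValueError(f"reference value f(x_min)={ref:.3g} must be positive")
    return float(np.clip(1.0 - float(f(x)) / ref, 0.0, 1.0))


def deposition_at_decline(
    curve,
    x_min: float,
    target: float,
    window: tuple[float, float] | float,
    tolerance: float = 1e-6,
) -> float | None:
    """Smallest deposition in [x_min, window max] at the target decline.

    Bracketing root-finder on a fine grid; None when the fitted curve never
    reaches the target decline within the modeling window (reported as "-"
    in tabulated output).
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target decline must be in [0, 1)")
    f = _as_curve(curve)
    x_max = window[1] if isinstance(window, tuple) else float(window)
    if x_max < x_min:
        raise ValueError("window max must be >= x_min")
    ref = float(f(x_min))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("curve must be finite and positive at x_min")
    if target == 0.0:
        return float(x_min)
    level = (1.0 - target) * ref
    grid = np.linspace(x_min, x_max, 2048)
    vals = f(grid)
    if not np.all(np.isfinite(vals)):
        raise ValueError("curve is non-finite within the window")
    below = vals <= level
    if not below.any():
        return None
    k = int(np.argmax(below))          # first grid point at/below the level
    if k == 0:
        return float(x_min)
    root = brentq(lambda x: f(x) - level, grid[k - 1], grid[k], xtol=tolerance)
    return float(root)


def classify_risk(decline: float, config: RiskConfig = RiskConfig()) -> str:
    """low / moderate / high / very_high; the upper class wins at 20/50/80 exactly."""
    if not 0.0 <= decline <= 1.0:
        raise ValueError("decline fraction must be in [0, 1]")
    b1, b2, b3 = config.class_bounds
    if decline < b1:
        return "low"
    if decline < b2:
        return "moderate"
    if decline < b3:
        return "high"
    return "very_high"


@dataclass
class CriticalLoadResult:
    """Anchor depositions/values and the critical load for one metric."""

    metric: str
    pollutant: str
    x_min: float
    reference_value: float
    anchors: pd.DataFrame          # decline_pct, deposition, metric_value
    critical_load: float | None
    ci: tuple[float, float] | None = None
    decline_grid: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    def anchor_row(self) -> dict:
        """One tabulated row: deposition and counts at each anchor decline."""
        row = {"metric": self.metric, "pollutant": self.pollutant}
        for rec in self.anchors.itertuples(index=False):
            pct = int(round(100 * rec.decline))
            row[f"dep_{pct}pct"] = (
                None if rec.deposition is None or np.isnan(rec.deposition)
                else round(rec.deposition, 1)
            )
            row[f"value_{pct}pct"] = rec.metric_value
        row["critical_load"] = None if self.critical_load is None else round(
            self.critical_load, 1
        )
        if self.ci is not None:
            row["cl_lo"], row["cl_hi"] = round(self.ci[0], 2), round(self.ci[1], 2)
        return row


def build_risk_table(
    curve,
    x_min: float,
    window: tuple[float, float] | float,
    config: RiskConfig = RiskConfig(),
    metric: str = "",
    pollutant: str = "N",
    grid_depositions: np.ndarray | None = None,
) -> CriticalLoadResult:
    """Anchor depositions, rounded metric values, and a 1-20 kg decline grid.

    Metric values at each anchor are ``f(x_min) * (1 - decline)`` rounded
    half away from zero (counts).  If the fitted quadratic peaks above
    x_min, a warning is recorded and the reference stays at x_min.
    """
    f = _as_curve(curve)
    ref = float(f(x_min))
    if ref <= 0:
        raise ValueError("reference value must be positive")
    warns = []
    probe = np.linspace(x_min, window[1] if isinstance(window, tuple) else window, 256)
    if float(np.max(f(probe))) > ref * (1 + 1e-9):
        warns.append(
            "fitted curve exceeds its value at minimum deposition; "
            "reference kept at x_min"
        )
    rows = []
    for d in config.decline_anchors:
        dep = deposition_at_decline(f, x_min, d, window, config.root_tolerance)
        rows.append(
            {
                "decline": d,
                "deposition": np.nan if dep is None else dep,
                "metric_value": float(round_half_away(ref * (1.0 - d))),
            }
        )
    anchors = pd.DataFrame(rows)
    cl = deposition_at_decline(f, x_min, config.cl_decline, window, config.root_tolerance)

    if grid_depositions is None:
        grid_depositions = np.arange(1.0, 20.0 + 1e-9, 1.0)
    x_max = window[1] if isinstance(window, tuple) else float(window)
    grid_rows = []
    for x in grid_depositions:
        if x < x_min or x > x_max:
            grid_rows.append({"deposition": x, "decline_pct": np.nan})
        else:
            grid_rows.append(
                {
                    "deposition": x,
                    "decline_pct": float(
                        round_half_away(100 * decline_fraction(f, x, x_min))
                    ),
                }
            )
    return CriticalLoadResult(
        metric=metric,
        pollutant=pollutant,
        x_min=x_min,
        reference_value=ref,
        anchors=anchors,
        critical_load=cl,
        decline_grid=pd.DataFrame(grid_rows),
        warnings=warns,
    )


def cl_confidence_interval(
    bootstrap: BootstrapResult,
    x_min: float,
    window: tuple[float, float] | float,
    config: RiskConfig = RiskConfig(),
) -> tuple[float, float, int]:
    """Percentile 95% CI of the critical load over bootstrap replicates.

    Each replicate's polynomial is inverted at the CL decline; replicates
    whose curve never reaches it within the window (or has a nonpositive
    reference) are unusable and counted.  More than half unusable is an
    error.  Returns (lower, upper, n_unusable).
    """
    if bootstrap.coef.shape[0] < 2:
        raise ValueError("need at least 2 usable bootstrap replicates")
    cls = []
    unusable = 0
    for coefs in bootstrap.coef:
        try:
            cl = deposition_at_decline(
                coefs, x_min, config.cl_decline, window, config.root_tolerance
            )
        except ValueError:
            cl = None
        if cl is None:
            unusable += 1
        else:
            cls.append(cl)
    if unusable > 0.5 * bootstrap.coef.shape[0]:
        raise RuntimeError(
            f"{unusable}/{bootstrap.coef.shape[0]} replicates never reach "
            f"the {config.cl_decline:.0%} decline"
        )
    lo, hi = np.percentile(cls, [2.5, 97.5])
    return float(lo), float(hi), unusable
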