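"""Species-level extirpation risk from detection-frequency profiles.

For a species of conservation concern, extirpation risk at a given
deposition is read off its detection-frequency curve along the deposition
gradient: depositions associated with 20, 50 and 90% declines from the peak
frequency bound the low, moderate and high risk ranges; declines beyond 90%
are very high risk.  Only the descending limb beyond the peak is searched —
the rising low-deposition side of a hump-shaped species is a distributional
signal, not an extirpation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExtirpationProfile",
    "extirpation_thresholds",
    "classify_extirpation_risk",
    "profiles_to_table",
]

DECLINE_LEVELS = (0.20, 0.50, 0.90)


@dataclass
class ExtirpationProfile:
    """Deposition thresholds at fixed declines in detection frequency.

    ``thresholds`` maps decline level (0.2, 0.5, 0.9) to deposition, or to
    None when the frequency never drops that far within the observed range
    (tabulated as a blank).  ``peak_deposition`` doubles as the species'
    sensitivity rating.
    """

    species_id: str
    pollutant: str = "N"
    region: str = ""
    peak_deposition: float | None = None
    peak_frequency: float | None = None
    thresholds: dict = field(default_factory=dict)
    n_occurrences: int = 0
    shape: str = "hump"

    @property
    def rated(self) -> bool:
        return self.peak_deposition is not None and self.shape != "increaser"


def extirpation_thresholds(
    grid: np.ndarray,
    frequency: np.ndarray,
    species_id: str = "",
    n_occurrences: int = 0,
    levels: tuple[float, ...] = DECLINE_LEVELS,
    min_occurrences: int = 8,
    **meta,
) -> ExtirpationProfile:
    """Thresholds at the given declines on the curve's descending limb.

    For each level, the smallest deposition at/above the peak where the
    frequency has fallen to ``(1 - level) * peak``, linearly interpolated
    between grid points; None if the drop is not reached within the observed
    range.  A flat curve is an error; a curve peaking at the top of the
    range is flagged "increaser" with no thresholds.
    """
    grid = np.asarray(grid, dtype=float)
    freq = np.asarray(frequency, dtype=float)
    if grid.shape != freq.shape or grid.ndim != 1:
        raise ValueError("grid and frequency must be 1-D and congruent")
    if np.ptp(freq) == 0:
        raise ValueError("flat detection-frequency curve; no identifiable peak")
    if n_occurrences and n_occurrences < min_occurrences:
        raise ValueError(
            f"{n_occurrences} occurrences < {min_occurrences} required to rate"
        )
    k = int(np.argmax(freq))
    peak_x, peak_f = float(grid[k]), float(freq[k])
    prof = ExtirpationProfile(
        species_id=species_id,
        peak_deposition=peak_x,
        peak_frequency=peak_f,
        n_occurrences=n_occurrences,
        **meta,
    )
    if k == len(grid) - 1:
        prof.shape = "increaser"
        prof.thresholds = {lv: None for lv in levels}
        return prof
    prof.shape = "decreasing" if k == 0 else "hump"
    desc_x, desc_f = grid[k:], freq[k:]
    for lv in levels:
        level = (1.0 - lv) * peak_f
        below = desc_f <= level
        if not below.any():
            prof.thresholds[lv] = None
            continue
        j = int(np.argmax(below))
        if j == 0:
            prof.thresholds[lv] = float(desc_x[0])
        else:
            x0, x1 = desc_x[j - 1], desc_x[j]
            f0, f1 = desc_f[j - 1], desc_f[j]
            t = (f0 - level) / (f0 - f1) if f0 != f1 else 1.0
            prof.thresholds[lv] = float(x0 + t * (x1 - x0))
    return prof


def classify_extirpation_risk(
    profile: ExtirpationProfile, deposition: float
) -> str:
    """low / moderate / high / very_high at a deposition, from the profile.

    Boundaries are half-open with the upper class winning at an exact
    threshold, matching the community-metric risk convention.  A threshold
    that was never reached within the observed range caps the attainable
    class (frequency demonstrably did not decline that far).
    """
    if deposition < 0:
        raise ValueError("deposition must be nonnegative")
    if not profile.rated or not profile.thresholds:
        raise ValueError(f"profile for {profile.species_id!r} has no thresholds")
    t20 = profile.thresholds.get(0.20)
    t50 = profile.thresholds.get(0.50)
    t90 = profile.thresholds.get(0.90)
    if t20 is None or deposition < t20:
        return "low"
    if t50 is None or deposition < t50:
        return "moderate"
    if t90 is None or deposition < t90:
        return "high"
    return "very_high"


def profiles_to_table(profiles: list[ExtirpationProfile]) -> pd.DataFrame:
    """Species-level risk table: one row per profile, one column per decline."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "species_id": p.species_id,
                "pollutant": p.pollutant,
                "region": p.region,
                "n_occurrences": p.n_occurrences,
                "shape": p.shape,
                "dep_0pct": None if p.peak_deposition is None else round(p.peak_deposition, 1),
                "dep_20pct": _r(p.thresholds.get(0.20)),
                "dep_50pct": _r(p.thresholds.get(0.50)),
                "dep_90pct": _r(p.thresholds.get(0.90)),
            }
        )
    return pd.DataFrame(rows)


def _r(v):
    return None if v is None else round(v, 1)
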