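"""Group comparisons of sensitivity ratings: ANOM on ranks and on ADM.

Sensitivity-rating distributions are heavy-tailed (ratings are censored at
the regional deposition minimum and maximum), so group means are compared
non-parametrically: ratings are rank-transformed over all groups and each
group's mean rank is compared to the grand mean with simultaneous
analysis-of-means (ANOM) decision limits.  Spread is compared the same way
on Levene's absolute deviations from the group median (ADM).  Decision
limits use a Bonferroni-adjusted t critical value, a conservative stand-in
for exact ANOM tables.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "anom_ranks",
    "anom_variances_adm",
    "compare_rare_common",
    "gamma_diversity",
    "compare_region_proportions",
]


@dataclass
class GroupComparison:
    """ANOM decision chart in tabular form.

    One row per group: n, mean of the analysed statistic, lower/upper
    decision limits, and flags when the group mean falls outside them.
    """

    statistic: str                 # "rank" | "adm"
    table: pd.DataFrame
    grand_mean: float
    alpha: float

    @property
    def flagged(self) -> list[str]:
        t = self.table
        return list(t.loc[t["flag_low"] | t["flag_high"], "group"])


def _anom(values_by_group: dict[str, np.ndarray], alpha: float, statistic: str
          ) -> GroupComparison:
    """ANOM on the supplied per-observation values.

    Limits: grand_mean +- c * s * sqrt((N - n_i) / (N * n_i)) with
    s = sqrt(MS_error) pooled within groups and c the two-sided
    Bonferroni-adjusted t quantile at alpha / (2k), df = N - k.
    """
    groups = {}
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            warnings.warn(f"group {g!r} has n < 2 and is excluded from ANOM")
            continue
        groups[g] = v
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    N = sum(len(v) for v in groups.values())
    grand = sum(v.sum() for v in groups.values()) / N
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (N - k)
    s = np.sqrt(mse)
    c = stats.t.ppf(1.0 - alpha / (2 * k), df=N - k)
    rows = []
    for g, v in groups.items():
        n_i = len(v)
        half = c * s * np.sqrt((N - n_i) / (N * n_i)) if s > 0 else 0.0
        mean = v.mean()
        rows.append(
            {
                "group": g,
                "n": n_i,
                "mean": mean,
                "lower_limit": grand - half,
                "upper_limit": grand + half,
                "flag_low": bool(mean < grand - half),
                "flag_high": bool(mean > grand + half),
            }
        )
    return GroupComparison(
        statistic=statistic, table=pd.DataFrame(rows), grand_mean=grand, alpha=alpha
    )


def anom_ranks(
    ratings_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> GroupComparison:
    """Non-parametric ANOM: group mean ranks vs the grand mean rank.

    Ratings are rank-transformed jointly over all groups (average ranks for
    ties), which makes the comparison invariant under any strictly monotone
    transform of the ratings.
    """
    keys, sizes, pooled = [], [], []
    for g, v in ratings_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        keys.append(g)
        sizes.append(len(v))
        pooled.append(v)
    ranks = stats.rankdata(np.concatenate(pooled)) if pooled else np.array([])
    out, start = {}, 0
    for g, n in zip(keys, sizes):
        out[g] = ranks[start:start + n]
        start += n
    return _anom(out, alpha, "rank")


def anom_variances_adm(
    ratings_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> GroupComparison:
    """Levene-type ANOM for variances on |x - group median| (ADM)."""
    adm = {}
    for g, v in ratings_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        adm[g] = np.abs(v - np.median(v)) if len(v) else v
    return _anom(adm, alpha, "adm")


def compare_rare_common(
    ratings: np.ndarray,
    rarity: np.ndarray,
    alpha: float = 0.05,
) -> dict[str, GroupComparison]:
    """Two-group ANOM (ranks and ADM) of rare vs common species ratings.

    ``rarity`` holds class labels from :func:`lichenrisk.metrics.classify_rarity`;
    intermediate species are set aside.
    """
    ratings = np.asarray(ratings, dtype=float)
    rarity = np.asarray(rarity)
    groups = {
        "rare": ratings[rarity == "rare"],
        "common": ratings[rarity == "common"],
    }
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"no {g} species to compare")
    return {
        "ranks": anom_ranks(groups, alpha),
        "adm": anom_variances_adm(groups, alpha),
    }


def gamma_diversity(species: pd.DataFrame, region_detections: pd.DataFrame
                    ) -> pd.DataFrame:
    """Species counts per functional group per region (regional gamma diversity).

    ``region_detections`` needs columns species_id and region; counts sum to
    the regional species totals by construction.
    """
    d = region_detections.merge(
        species[["species_id", "functional_group"]], on="species_id"
    )
    tab = (
        d.groupby(["region", "functional_group"])["species_id"]
        .nunique()
        .rename("n_species")
        .reset_index()
    )
    return tab


def compare_region_proportions(
    count_east: int, total_east: int, count_west: int, total_west: int
) -> dict:
    """Two-proportion z-test for a group's share of the regional flora."""
    if min(total_east, total_west) <= 0:
        raise ValueError("regional totals must be positive")
    p1, p2 = count_east / total_east, count_west / total_west
    p = (count_east + count_west) / (total_east + total_west)
    se = np.sqrt(p * (1 - p) * (1 / total_east + 1 / total_west))
    z = 0.0 if se == 0 else (p1 - p2) / se
    return {
        "prop_east": p1,
        "prop_west": p2,
        "z": float(z),
        "p_value": float(2 * stats.norm.sf(abs(z))),
    }
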