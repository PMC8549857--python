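"""Per-site community metrics and per-species sensitivity ratings.

Six indicator metrics per survey site:

* total species richness (count of distinct species),
* oligotroph richness (species whose regional N rating is below 4.2
  kg N ha-1 yr-1) and S-sensitive richness (S rating below 2.7 kg S),
* forage, cyanolichen and matrix abundance indices: the sum of ocular
  abundance codes over the group's species with code >= 3, e.g. a site with
  cyanolichen codes {3, 3, 3, 4, 4} scores 18.  Codes 1-2 (fewer than ~15
  thalli per plot) are excluded because the groups fulfil their ecological
  roles mainly when abundant, and because sparse detections are the least
  repeatable part of the survey.

A species' sensitivity rating is the deposition at its maximum detection
frequency along the regional deposition gradient, estimated here with a
kernel-smoothed binomial frequency; at least 8 detections are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MetricConfig",
    "SensitivityRating",
    "load_functional_group_table",
    "assign_functional_group",
    "compute_site_metrics",
    "rate_sensitivity",
    "classify_rarity",
]

VALID_CODES = frozenset({1, 2, 3, 4})

#: genera whose functional group depends on growth form
_FORM_DEPENDENT = {"Usnea", "Ramalina"}

_PHOTOBIONT_FALLBACK = {
    ("cyano", "foliose-large"): "cyano_large",
    ("cyano", "foliose-small"): "cyano_small_med",
    ("green", "pendant"): "forage_pendant",
    ("green", "shrubby"): "forage_shrubby",
    ("green", "foliose-large"): "matrix_med_large",
    ("green", "foliose-small"): "matrix_small",
}


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds of the metric layer.

    Sensitivity cut-offs (4.2 kg N, 2.7 kg S ha-1 yr-1) are the minimum
    eastern deposition levels, applied as *strict* inequalities; they let
    eastern decreasers count as sensitive while excluding intermediately
    tolerant hump-shaped western species.  Sites with fewer than
    ``min_site_richness`` species are flagged (not dropped).
    """

    n_sensitive_cutoff: float = 4.2
    s_sensitive_cutoff: float = 2.7
    abundance_code_floor: int = 3
    min_site_richness: int = 5
    min_detections_for_rating: int = 8
    rare_fraction: float = 0.01
    common_fraction: float = 0.10
    rating_grid_size: int = 200

    def __post_init__(self):
        if self.n_sensitive_cutoff <= 0 or self.s_sensitive_cutoff <= 0:
            raise ValueError("sensitivity cut-offs must be positive")


_GROUP_TABLE: pd.DataFrame | None = None


def load_functional_group_table() -> pd.DataFrame:
    """Packaged genus -> functional group lookup (published group lists)."""
    global _GROUP_TABLE
    if _GROUP_TABLE is None:
        with resources.files("lichenrisk.data").joinpath(
            "functional_groups.csv"
        ).open() as fh:
            _GROUP_TABLE = pd.read_csv(fh)
    return _GROUP_TABLE


def assign_functional_group(
    genus: str,
    growth_form: str | None = None,
    photobiont: str | None = None,
) -> str | None:
    """Functional group for a genus; None when unassignable.

    Usnea and Ramalina split into pendant vs shrubby forage lichens by
    growth form.  An unknown genus falls back to photobiont + growth form
    when both are given, else returns None (caller should flag the species).
    """
    if not genus:
        raise ValueError("genus must be nonempty")
    genus = genus.strip()
    if genus in _FORM_DEPENDENT:
        if growth_form == "pendant":
            return "forage_pendant"
        if growth_form == "shrubby":
            return "forage_shrubby"
        return None
    table = load_functional_group_table()
    hit = table.loc[table["genus"] == genus, "functional_group"]
    if len(hit):
        return str(hit.iloc[0])
    if photobiont and growth_form:
        return _PHOTOBIONT_FALLBACK.get((photobiont, growth_form))
    return None


def _regional_rating(species: pd.DataFrame, region: str, pollutant: str) -> pd.Series:
    col = f"{pollutant.lower()}_rating_{region.lower()}"
    if col in species.columns:
        return pd.to_numeric(species[col], errors="coerce")
    return pd.Series(np.nan, index=species.index)


def compute_site_metrics(
    detections: pd.DataFrame,
    species: pd.DataFrame,
    sites: pd.DataFrame,
    config: MetricConfig = MetricConfig(),
) -> pd.DataFrame:
    """The six indicator metrics for every site.

    Sensitive-richness metrics use the rating matched to the site's own
    region; a species rated only in the other region does not count.
    Returns one row per site (sites without detections score 0 everywhere)
    with an ``excluded_low_richness`` flag for sites below the richness
    floor.
    """
    bad = ~detections["abundance_code"].isin(VALID_CODES)
    if bad.any():
        rows = detections.index[bad].tolist()[:10]
        raise ValueError(f"abundance codes outside 1-4 at rows {rows}")
    missing = set(detections["species_id"]) - set(species["species_id"])
    if missing:
        raise ValueError(f"detections reference unknown species: {sorted(missing)[:10]}")

    d = detections.merge(
        species.set_index("species_id"), left_on="species_id", right_index=True
    ).merge(sites[["site_id", "region"]], on="site_id")

    n_rating = pd.concat(
        [
            _regional_rating(species.set_index("species_id"), r, "n").rename(r)
            for r in ("East", "West")
        ],
        axis=1,
    )
    s_rating = pd.concat(
        [
            _regional_rating(species.set_index("species_id"), r, "s").rename(r)
            for r in ("East", "West")
        ],
        axis=1,
    )
    d["n_rating"] = [
        n_rating.at[sp, reg] for sp, reg in zip(d["species_id"], d["region"])
    ]
    d["s_rating"] = [
        s_rating.at[sp, reg] for sp, reg in zip(d["species_id"], d["region"])
    ]

    out = pd.DataFrame(index=pd.Index(sites["site_id"], name="site_id"))
    grouped = d.groupby("site_id")
    out["total_richness"] = grouped["species_id"].nunique()
    out["oligotroph_richness"] = grouped["n_rating"].agg(
        lambda r: int((r < config.n_sensitive_cutoff).sum())
    )
    out["s_sensitive_richness"] = grouped["s_rating"].agg(
        lambda r: int((r < config.s_sensitive_cutoff).sum())
    )
    abundant = d[d["abundance_code"] >= config.abundance_code_floor]
    for name, prefix in (
        ("forage_abundance", "forage"),
        ("cyano_abundance", "cyano"),
        ("matrix_abundance", "matrix"),
    ):
        sub = abundant[abundant["functional_group"].str.startswith(prefix, na=False)]
        out[name] = sub.groupby("site_id")["abundance_code"].sum()
    out = out.fillna(0).astype(int)
    out["excluded_low_richness"] = out["total_richness"] < config.min_site_richness
    return out.reset_index()


@dataclass
class SensitivityRating:
    """Deposition at a species' peak detection frequency, plus curve shape."""

    species_id: str
    rating: float | None
    shape: str            # "increasing" | "decreasing" | "hump" | "unrated"
    n_detections: int
    grid: np.ndarray | None = None
    frequency: np.ndarray | None = None


def detection_frequency_curve(
    site_deposition: np.ndarray,
    detected: np.ndarray,
    grid_size: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smoothed detection frequency along the deposition gradient.

    Nadaraya-Watson estimate of P(detected | deposition) with a Gaussian
    kernel on log-deposition and Silverman's rule-of-thumb bandwidth, on a
    log-spaced grid spanning the observed deposition.
    """
    x = np.asarray(site_deposition, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if np.any(x <= 0):
        raise ValueError("deposition must be positive")
    z = np.log(x)
    if np.ptp(z) == 0:
        raise ValueError("all sites share one deposition value; curve undefined")
    n = len(z)
    sd = np.std(z, ddof=1)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = 0.9 * scale * n ** (-0.2)
    grid = np.linspace(z.min(), z.max(), grid_size)
    w = np.exp(-0.5 * ((grid[:, None] - z[None, :]) / h) ** 2)
    freq = (w @ detected.astype(float)) / w.sum(axis=1)
    return np.exp(grid), freq


def rate_sensitivity(
    species_id: str,
    site_deposition: np.ndarray,
    detected: np.ndarray,
    config: MetricConfig = MetricConfig(),
) -> SensitivityRating:
    """Sensitivity rating: deposition at the peak of the frequency curve.

    Species with fewer than ``min_detections_for_rating`` detections (or an
    undefined curve) are returned unrated.  Shape is "increasing" when the
    argmax falls in the top 10% of the grid, "decreasing" in the bottom 10%,
    else "hump".
    """
    detected = np.asarray(detected, dtype=bool)
    n_det = int(detected.sum())
    if n_det < config.min_detections_for_rating:
        return SensitivityRating(species_id, None, "unrated", n_det)
    try:
        grid, freq = detection_frequency_curve(
            site_deposition, detected, config.rating_grid_size
        )
    except ValueError:
        return SensitivityRating(species_id, None, "unrated", n_det)
    k = int(np.argmax(freq))
    m = len(grid)
    if k >= 0.9 * (m - 1):
        shape = "increasing"
    elif k <= 0.1 * (m - 1):
        shape = "decreasing"
    else:
        shape = "hump"
    return SensitivityRating(
        species_id, float(grid[k]), shape, n_det, grid=grid, frequency=freq
    )


def classify_rarity(
    n_detections: int, n_sites_region: int, config: MetricConfig = MetricConfig()
) -> str:
    """'rare' below 1% of regional sites, 'common' above 10%, else intermediate."""
    if n_sites_region <= 0:
        raise ValueError("n_sites_region must be positive")
    frac = n_detections / n_sites_region
    if frac < config.rare_fraction:
        return "rare"
    if frac > config.common_fraction:
        return "common"
    return "intermediate"
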