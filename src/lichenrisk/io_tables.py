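"""Validated CSV readers/writers for survey inputs and result tables.

Input schema (UTF-8 CSV, comma, "." decimal, header row, empty string for
missing):

* detections: site_id, species_id, abundance_code (1-4)
* sites: site_id, region (East|West), deposition (kg ha-1 yr-1), plus the
  climate normals columns
* species: species_id, genus, growth_form, photobiont, functional_group,
  and the four regional rating columns

Validation is total: every failure is collected with its row number and the
dataset is either fully loaded or not at all.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dataset", "ValidationError", "read_dataset", "write_results"]

DETECTION_COLUMNS = ["site_id", "species_id", "abundance_code"]
SITE_COLUMNS = ["site_id", "region", "deposition"]
SPECIES_COLUMNS = ["species_id", "genus"]
CLIMATE_COLUMNS = [
    "mean_annual_precip_mm",
    "mean_max_aug_temp_c",
    "mean_min_dec_temp_c",
    "continentality_c",
    "cmd_mm",
]
SCHEMA_VERSION = "1"


class ValidationError(ValueError):
    """All schema/integrity failures for one dataset, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "dataset validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass
class Dataset:
    """The three input tables plus provenance metadata."""

    detections: pd.DataFrame
    sites: pd.DataFrame
    species: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, df in (
            ("detections", self.detections),
            ("sites", self.sites),
            ("species", self.species),
        ):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest[f"{name}.csv"] = _sha256(path)
        (out / "provenance.json").write_text(
            json.dumps({**self.provenance, "schema_version": SCHEMA_VERSION},
                       indent=1, sort_keys=True)
        )
        return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, cols: list[str], table: str,
                     problems: list[str]) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        problems.append(f"{table}: missing columns {missing}")
        return False
    return True


def read_dataset(
    detections_path: str | Path,
    sites_path: str | Path,
    species_path: str | Path,
    schema_version: str = SCHEMA_VERSION,
) -> Dataset:
    """Load and validate the three tables; raises ValidationError listing
    every problem (with 1-based data row numbers) on failure."""
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    problems: list[str] = []
    detections = pd.read_csv(detections_path)
    sites = pd.read_csv(sites_path)
    species = pd.read_csv(species_path)

    ok_d = _require_columns(detections, DETECTION_COLUMNS, "detections", problems)
    ok_si = _require_columns(sites, SITE_COLUMNS, "sites", problems)
    ok_sp = _require_columns(species, SPECIES_COLUMNS, "species", problems)

    if ok_d:
        codes = pd.to_numeric(detections["abundance_code"], errors="coerce")
        bad = detections.index[~codes.isin([1, 2, 3, 4])]
        for i in bad[:20]:
            problems.append(
                f"detections row {i + 1}: abundance_code "
                f"{detections.at[i, 'abundance_code']!r} not in 1-4"
            )
        dup = detections.duplicated(subset=["site_id", "species_id"])
        for i in detections.index[dup][:20]:
            problems.append(
                f"detections row {i + 1}: duplicate (site, species) pair"
            )
    if ok_si:
        dep = pd.to_numeric(sites["deposition"], errors="coerce")
        for i in sites.index[dep.isna()][:20]:
            problems.append(f"sites row {i + 1}: non-numeric deposition")
        for i in sites.index[dep <= 0][:20]:
            problems.append(
                f"sites row {i + 1}: deposition {sites.at[i, 'deposition']!r} "
                "must be positive (kg ha-1 yr-1)"
            )
        bad_region = ~sites["region"].isin(["East", "West"])
        for i in sites.index[bad_region][:20]:
            problems.append(
                f"sites row {i + 1}: region {sites.at[i, 'region']!r} "
                "not 'East' or 'West'"
            )
    if ok_d and ok_si:
        known_sites = set(sites["site_id"])
        orphan = ~detections["site_id"].isin(known_sites)
        for i in detections.index[orphan][:20]:
            problems.append(
                f"detections row {i + 1}: unknown site "
                f"{detections.at[i, 'site_id']!r}"
            )
    if ok_d and ok_sp:
        known_species = set(species["species_id"])
        orphan = ~detections["species_id"].isin(known_species)
        for i in detections.index[orphan][:20]:
            problems.append(
                f"detections row {i + 1}: unknown species "
                f"{detections.at[i, 'species_id']!r}"
            )
    if problems:
        raise ValidationError(problems)
    return Dataset(
        detections=detections,
        sites=sites,
        species=species,
        provenance={
            "source": {
                "detections": str(detections_path),
                "sites": str(sites_path),
                "species": str(species_path),
            },
            "units": "kg ha-1 yr-1",
            "schema_version": SCHEMA_VERSION,
        },
    )


def write_results(results: dict, out_dir: str | Path) -> dict:
    """Write result tables/objects deterministically and return a manifest.

    DataFrames become CSV, everything else JSON.  Empty optional sections
    (None or empty frame) are omitted and noted in the manifest, which
    carries a sha256 per file.
    """
    if not results:
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "omitted": [], "schema_version": SCHEMA_VERSION}
    for name in sorted(results):
        obj = results[name]
        if obj is None or (isinstance(obj, pd.DataFrame) and obj.empty):
            manifest["omitted"].append(name)
            continue
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                                       default=_jsonable))
        manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
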