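import numpy as np
import pandas as pd
import pytest

from lichenrisk.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def metric_dataset():
    """One metric-mode synthetic survey shared across tests (n=2000)."""
    cfg = SyntheticConfig(n_sites=2000, mode="metric", seed=42)
    detections, sites, species, truth = generate_dataset(cfg)
    return cfg, detections, sites, species, truth


@pytest.fixture(scope="session")
def species_dataset():
    """One species-mode synthetic survey (n=600 sites)."""
    cfg = SyntheticConfig(n_sites=600, mode="species", seed=7)
    detections, sites, species, truth = generate_dataset(cfg)
    return cfg, detections, sites, species, truth


@pytest.fixture()
def toy_tables():
    """Tiny hand-built detections/sites/species tables."""
    sites = pd.DataFrame(
        {
            "site_id": ["A", "B"],
            "region": ["West", "East"],
            "deposition": [1.0, 5.0],
        }
    )
    species = pd.DataFrame(
        {
            "species_id": [f"sp{i}" for i in range(7)],
            "genus": ["Lobaria", "Nephroma", "Sticta", "Peltigera", "Collema",
                      "Bryoria", "Cladonia"],
            "functional_group": ["cyano_large"] * 4 + ["cyano_small_med",
                                                       "forage_pendant",
                                                       "matrix_small"],
            "n_rating_west": [3.0, 1.0, 2.0, 4.2, 0.5, 1.5, 9.0],
            "n_rating_east": [3.0, 1.0, 2.0, 4.2, 0.5, 1.5, 9.0],
            "s_rating_west": [2.0, 1.0, 2.6, 2.7, 0.5, 1.0, 8.0],
            "s_rating_east": [2.0, 1.0, 2.6, 2.7, 0.5, 1.0, 8.0],
        }
    )
    # site A: five cyanolichens at codes 3,3,3,4,4 plus a code-1 and code-2
    detections = pd.DataFrame(
        {
            "site_id": ["A"] * 7,
            "species_id": ["sp0", "sp1", "sp2", "sp3", "sp4", "sp5", "sp6"],
            "abundance_code": [3, 3, 3, 4, 4, 1, 2],
        }
    )
    return detections, sites, species
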