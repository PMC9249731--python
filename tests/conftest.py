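"""Shared fixtures: synthetic datasets at desk scale, fitted objects."""

import numpy as np
import pandas as pd
import pytest

from mocsat import capacity, rf_model, synthgen


@pytest.fixture(scope="session")
def gen_config():
    return synthgen.GeneratorConfig(seed=11, n_profiles=1200)


@pytest.fixture(scope="session")
def profiles(gen_config):
    prof, truth = synthgen.generate_profiles(gen_config)
    return prof


@pytest.fixture(scope="session")
def profiles_truth(gen_config):
    prof, truth = synthgen.generate_profiles(gen_config)
    return truth


@pytest.fixture(scope="session")
def fits(profiles):
    return {
        mt: capacity.boundary_fit(profiles, mt, n_boot=1) for mt in ("HM", "LM")
    }


@pytest.fixture(scope="session")
def attribution_model(profiles):
    return rf_model.train_ensemble(
        profiles, "attribution", n_members=6, trees=60, seed=3
    )


@pytest.fixture(scope="session")
def grid_stack(gen_config):
    return synthgen.generate_grid(gen_config)


@pytest.fixture(scope="session")
def accrual_data(gen_config):
    records, truth = synthgen.generate_accrual(gen_config)
    return records, truth


@pytest.fixture()
def toy_profiles():
    """A tiny hand-built profile table with known structure."""
    rng = np.random.default_rng(0)
    n = 40
    cs = rng.uniform(10, 90, n)
    return pd.DataFrame(
        {
            "site_id": [f"T{i}" for i in range(n)],
            "study_id": "S0",
            "lat": rng.uniform(-60, 60, n),
            "lon": rng.uniform(-180, 180, n),
            "depth_top_cm": 0.0,
            "depth_bottom_cm": 20.0,
            "depth_class": "topsoil",
            "mat_c": rng.uniform(0, 25, n),
            "map_mm": rng.uniform(200, 2000, n),
            "cs_pct": cs,
            "soil_order": "Mollisol",
            "mineral_type": "HM",
            "vegetation": "grassland",
            "management": "natural",
            "ecosystem_group": "grassland",
            "moc_g_kg": 0.5 * cs * rng.uniform(0.2, 1.0, n),
            "poc_g_kg": rng.uniform(1, 15, n),
            "soc_g_kg": 0.6 * cs,
            "bd_g_cm3": 1.3,
            "fraction_cutoff_um": 63,
            "recovery_flag": False,
        }
    )
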