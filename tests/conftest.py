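import numpy as np
import pandas as pd
import pytest

from colitiskit import histo, mva, synth


@pytest.fixture(scope="session")
def default_config() -> synth.CohortConfig:
    return synth.CohortConfig(seed=0)


@pytest.fixture(scope="session")
def cohort(default_config):
    return synth.generate_cohort(default_config)


@pytest.fixture(scope="session")
def cleaned_profiles(cohort):
    return {a.id: histo.clean_measurements(a.crypt_profile) for a in cohort}


@pytest.fixture(scope="session")
def panel(cohort, default_config) -> pd.DataFrame:
    return synth.cohort_panel(cohort, default_config)


@pytest.fixture(scope="session")
def cytokine_panel(panel, default_config) -> pd.DataFrame:
    cyto = [a for a, u in zip(default_config.analyte_names, default_config.analyte_units)
            if u == "pg/ml"]
    return panel[cyto]


@pytest.fixture(scope="session")
def heights(cohort, cleaned_profiles) -> np.ndarray:
    return np.array([cleaned_profiles[a.id].mean_distal_height() for a in cohort])


@pytest.fixture(scope="session")
def plsr_model(cytokine_panel, heights):
    pre = mva.fit_preprocessor(cytokine_panel, "log1p")
    return mva.fit_plsr(cytokine_panel, heights, pre, k=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_profile(heights, junction_um=4000.0, spacing=500.0, animal_id="a1",
                 off_axis=None, infiltrate=None):
    """Helper: build a CryptProfile from a height list."""
    n = len(heights)
    positions = np.arange(n) * spacing
    data = pd.DataFrame(
        {
            "position_um": positions,
            "region": np.where(positions < junction_um, "distal", "proximal"),
            "height_um": np.asarray(heights, float),
            "infiltrate_score": infiltrate if infiltrate is not None else np.zeros(n, int),
            "off_axis": off_axis if off_axis is not None else np.zeros(n, bool),
        }
    )
    return histo.CryptProfile(animal_id=animal_id, data=data, junction_um=junction_um)
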