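import pandas as pd
import pytest

import shadescreen as ss
from shadescreen.analytes import ALL_VARIABLES


@pytest.fixture(scope="session")
def seed_table() -> pd.DataFrame:
    """Bundled bundled nine-germplasm seed profiles, 9 genotypes x 3 replicates."""
    return ss.generate_seed_profiles(ss.seed_presets(), n_reps=3, seed=7)


@pytest.fixture(scope="session")
def seed_profiles(seed_table) -> pd.DataFrame:
    return ss.add_derived_totals(seed_table)


@pytest.fixture(scope="session")
def seed_X_labels(seed_profiles):
    X = seed_profiles[[c for c in seed_profiles.columns if c in ALL_VARIABLES]]
    return X, seed_profiles["tolerance_class"]


@pytest.fixture(scope="session")
def seed_opls(seed_X_labels) -> ss.OplsModel:
    X, labels = seed_X_labels
    return ss.fit_opls_da(X, labels, n_predictive=2, n_orthogonal=1)


@pytest.fixture(scope="session")
def field_table() -> pd.DataFrame:
    return ss.generate_field_trial(ss.field_presets(), n_plants=10, seed=1)


@pytest.fixture(scope="session")
def leaf_table() -> pd.DataFrame:
    return ss.generate_leaf_experiment(seed=3, n_reps=200)


@pytest.fixture(scope="session")
def reference_curves() -> dict[str, ss.CalibrationCurve]:
    """Synthetic per-analyte calibration curves from the bundled reference."""
    from shadescreen.synthetic import hplc_reference

    return {
        a: ss.CalibrationCurve(
            analyte=a, slope=d["slope"], intercept=d["intercept"],
            r_squared=1.0, rt_reference=d["rt"],
        )
        for a, d in hplc_reference().items()
    }
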