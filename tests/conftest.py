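from pathlib import Path

import pandas as pd
import pytest

import trapeval as te

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def study_counts() -> pd.DataFrame:
    return te.load_study_counts()


@pytest.fixture(scope="session")
def study_table(study_counts) -> pd.DataFrame:
    return te.metric_table_from_counts(study_counts)


@pytest.fixture(scope="session")
def published_metrics() -> pd.DataFrame:
    return pd.read_csv(DATA / "published_metrics.csv", index_col="model_id")


@pytest.fixture(scope="session")
def published_ensemble_metrics() -> pd.DataFrame:
    return pd.read_csv(DATA / "published_ensemble_metrics.csv", index_col="ensemble_id")


@pytest.fixture(scope="session")
def ensemble_counts() -> pd.DataFrame:
    return te.load_study_ensemble_counts()


@pytest.fixture
def tiny_records():
    """2 images x 2 models, hand-written: model A detects img1 (target at
    rank 2), model B detects nothing."""
    mk = te.PredictionRecord
    return [
        mk("img1", "A", 1, "n02123045", 0.9),
        mk("img1", "A", 2, "n02127052", 0.5),
        mk("img1", "B", 1, "n02123045", 0.8),
        mk("img2", "A", 1, "n02110341", 0.7),
        mk("img2", "B", 1, "n02110341", 0.6),
    ]


@pytest.fixture
def tiny_truths():
    return [
        te.ImageTruth("img1", True),
        te.ImageTruth("img2", False),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A moderately sized simulated dataset shared across tests."""
    cfg = te.SyntheticConfig(
        n_images=3000,
        prevalence=0.2,
        model_profiles=[("m1", 0.7, 0.9), ("m2", 0.5, 0.95), ("m3", 0.6, 0.8)],
        correlation=0.4,
        seed=123,
    )
    records, truths = te.simulate(cfg)
    return cfg, records, truths
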