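import numpy as np
import pandas as pd
import pytest

from mobimood.pipeline import process_gps
from mobimood.preprocess import PreprocessConfig
from mobimood.synthetic import ScenarioConfig, generate_cohort

#: meters per degree of longitude at the equator (spherical-Mercator radius)
M_PER_DEG_EQ = 6_378_137.0 * np.pi / 180.0


def deg_offset(meters: float, lat: float = 0.0) -> float:
    """Longitude offset in degrees spanning ``meters`` at latitude ``lat``."""
    return meters / (M_PER_DEG_EQ * np.cos(np.radians(lat)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic study shared by read-only tests: 4 participants, 2 weeks."""
    cfg = ScenarioConfig(n_participants=4, n_days=14, master_seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    feats, qc = process_gps(tiny_cohort.gps, PreprocessConfig(n_sim=2), master_seed=11)
    return feats


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """The same tiny study written to disk in the on-disk layout."""
    out = tmp_path_factory.mktemp("study")
    cfg = ScenarioConfig(n_participants=3, n_days=7, master_seed=23)
    generate_cohort(cfg, out)
    return out
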