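import numpy as np
import pandas as pd
import pytest

from roadcline.data import SiteDataset, Standardizer
from roadcline.synthetic import SurveyDesign, TruthParams


@pytest.fixture(scope="session")
def truth() -> TruthParams:
    """Study-condition generating parameters."""
    return TruthParams()


@pytest.fixture()
def tiny_dataset() -> SiteDataset:
    """Hand-sized dataset (3 sites, 2 with cameras) for exact oracle checks."""
    sites = pd.DataFrame({
        "site": [0, 1, 2],
        "distance_km": [1.0, 5.0, 10.0],
        "camera_flag": [1, 1, 0],
    })
    counts = pd.DataFrame({
        "site": [0, 0, 1, 1, 2],
        "survey": [0, 1, 0, 1, 0],
        "temperature_std": [0.3, -0.5, 0.0, 1.2, -1.0],
        "count_melanic": [2, 1, 0, 1, 0],
        "count_gray": [3, 4, 2, 0, 1],
    })
    cameras = pd.DataFrame({
        "site": [0, 0, 0, 1, 1],
        "day": [0, 1, 2, 0, 1],
        "temperature_std": [0.1, -0.2, 0.8, 0.0, -1.5],
        "det_melanic": [1, 0, 1, 0, 0],
        "det_gray": [1, 1, 0, 1, 0],
    })
    return SiteDataset(
        sites=sites,
        counts=counts,
        cameras=cameras,
        distance_std=Standardizer.fit(sites["distance_km"].to_numpy()),
        temperature_std=Standardizer(0.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_design() -> SurveyDesign:
    """Cheap survey design for smoke-level fits."""
    return SurveyDesign(surveys_per_site=3, camera_days=25, n_camera_sites=4)
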