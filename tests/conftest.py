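import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from spherotil import synthetic
from spherotil.io_config import Config


@pytest.fixture(scope="session")
def default_config():
    return Config()


@pytest.fixture(scope="session")
def single_sphere_scene():
    """Noiseless single sphere, r = 60 um."""
    return synthetic.make_spheroid_scene(radius_um=60.0, seed=11)


@pytest.fixture(scope="session")
def touching_pair_scene():
    """Two r = 50 um spheres with 90 um center distance (touching)."""
    return synthetic.make_spheroid_scene(
        n_spheroids=2, radius_um=[50.0, 50.0],
        centers_xy_um=[(74.0, 74.0), (164.0, 74.0)], seed=12)


@pytest.fixture(scope="session")
def tcell_scene():
    """Sphere with 12 well-separated T-cell blobs and a 30% dead core."""
    return synthetic.make_spheroid_scene(
        radius_um=60.0, n_tcells=12, dead_fraction0=0.3, seed=13)


@pytest.fixture(scope="session")
def kill_scene():
    """4-timepoint scene with a growing dead core (kill rate 0.06/h)."""
    return synthetic.make_spheroid_scene(
        radius_um=45.0, kill_rate_per_h=0.06, dead_fraction0=0.1,
        n_timepoints=4, seed=14)


@pytest.fixture(scope="session")
def margin_suite():
    """12 couple tracks with events at 1.5x the classifier thresholds."""
    return synthetic.make_couple_tracks(
        n_tracks=12, translocation_frac=0.5, uropod_frac=0.25,
        margin=1.5, contact_frame=20, seed=15)


@pytest.fixture(scope="session")
def logistic_curves():
    """Noiseless logistic-decline cytotoxicity fixture (gentle decline so the
    finite-window OLS estimator is within 5% of the analytic inflection
    slope)."""
    return synthetic.make_cytotox_curves(
        decline_duration_h=10.0, duration_h=14.0, noise=0.0, seed=16)
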