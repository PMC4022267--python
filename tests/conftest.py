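"""Shared fixtures: benchmark scenario replicates and large reference clouds.

Scenario replicates are session-scoped because several tests interrogate the
same runs (calibration, power ordering, bookkeeping); seeds are the natural
sequences 0..4 (static) and 0..2 (dynamic).
"""

import numpy as np
import pytest

import bootgof as bg
from bootgof.defaults import static_design
from bootgof.evaluation import Scenario, run_scenario

STATIC_SEEDS = (0, 1, 2, 3, 4)
DYNAMIC_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def static_runs():
    """Five replicates of the static benchmark (MS1 vs MS2, n=100, B=200)."""
    return [run_scenario(Scenario.benchmark("static", n_datasets=100, B=200,
                                            base_seed=s))
            for s in STATIC_SEEDS]


@pytest.fixture(scope="session")
def dynamic_runs():
    """Three replicates of the dynamic benchmark (MD1 vs MD2, n=50, B=100)."""
    return [run_scenario(Scenario.benchmark("dynamic", n_datasets=50, B=100,
                                            base_seed=s))
            for s in DYNAMIC_SEEDS]


@pytest.fixture(scope="session")
def gauss_cloud_10k():
    """Isotropic standard bivariate normal cloud, B=1e4, with its KDE."""
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(10000, 2))
    grid, ev = bg.kde2d(pts, grid_n=128)
    return pts, grid, ev


@pytest.fixture(scope="session")
def chi2_cloud_10k():
    """(chi2_MS1, chi2_MS2) cloud at B=1e4 from a static MS1 dataset.

    Returns (stat matrix, observed chi2 pair of the generating dataset).
    """
    reg = bg.builtin_models()
    ms1, ms2 = reg["MS1"], reg["MS2"]
    ds = bg.make_fixture("static", "MS1", seed=11)
    f1 = ms1.fit(ds)
    samples = bg.generate_bootstrap_samples(ms1, f1.theta_hat, ds.design,
                                            ds.noise_model(), 10000, seed=123)
    cloud = bg.build_cloud(samples, [ms1, ms2], ["chi2:MS1", "chi2:MS2"],
                           seed=123)
    obs = (f1.chi2, ms2.fit(ds).chi2)
    return cloud.stat_matrix, obs


@pytest.fixture()
def static_fixture_dataset():
    return bg.make_fixture("static", "MS1", seed=7)


@pytest.fixture()
def noise_free_static():
    """Noise-free MS1 output on the default static design (sigma kept at 0.5)."""
    reg = bg.builtin_models()
    design = static_design()
    clean = bg.simulate(reg["MS1"], (4.0, 5.0), design)
    sigma = tuple(np.full(c.size, 0.5) for c in design.coordinates)
    return bg.Dataset(design, clean, sigma, {"kind": "synthetic"})
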