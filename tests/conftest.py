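"""Shared fixtures: a small fast assay for unit tests and the full
default benchmark report (computed once per session) for acceptance
checks."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from urivar.caller import (  # noqa: E402
    CallerConfig,
    build_training_features,
    calibrate,
    fit_forest,
)
from urivar.config import RunConfig  # noqa: E402
from urivar.noise import build_pon  # noqa: E402
from urivar.pipeline import run_pipeline  # noqa: E402
from urivar.simulate import (  # noqa: E402
    DilutionSpec,
    SimConfig,
    get_assay,
    simulate_dilution,
    simulate_pon,
)

#: 8 targets x 500 bp = 4 kb panel; fast enough for per-test simulation
SMALL_SIM = SimConfig(n_targets=8, target_len=500, seed=11)


@pytest.fixture(scope="session")
def small_sim() -> SimConfig:
    return SMALL_SIM


@pytest.fixture(scope="session")
def small_reference():
    """(assay, normals, pon) over the small panel."""
    assay = get_assay(SMALL_SIM)
    normals = simulate_pon(SMALL_SIM, n=8, seed=101)
    pon = build_pon(normals, assay.panel, snp_sites=assay.snp_sites)
    return assay, normals, pon


@pytest.fixture(scope="session")
def small_trained(small_reference):
    """A calibrated caller context on the small panel.

    The calibration target is relaxed (0.5): these fixtures exercise the
    machinery; published operating points are checked on the full-size
    benchmark.
    """
    assay, normals, pon = small_reference
    cc = CallerConfig(psi=128)
    training = simulate_dilution(
        SMALL_SIM, DilutionSpec(ratio="1:100", n_het=40, n_hom=80), seed=202
    )
    X = build_training_features(normals, pon, cc, dilutions=training)
    model = fit_forest(X, n_trees=cc.n_trees, psi=cc.psi, seed=303)
    calib = calibrate(
        model, training, pon, cc, snp_sites=assay.snp_sites,
        target_sensitivity=0.5,
    )
    return assay, normals, pon, model, cc, calib, training


@pytest.fixture(scope="session")
def default_report() -> dict:
    """The full default benchmark (50 kb panel, PON n=16, seed 1)."""
    return run_pipeline(RunConfig().seeded(1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
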