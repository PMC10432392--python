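"""Shared fixtures: phantoms, sequences and pre-simulated short runs.

Expensive objects are session-scoped; tests must not mutate them (copy
first).  Short runs use a reduced paradigm (4 events of 60 s air + 26 s
odor) and, where stated, a reduced 48 x 36 grid so the suite stays fast
while exercising the same physics as the full study conditions.
"""

import numpy as np
import pytest

from spenfmri import bold_experiment as be
from spenfmri import forward_sim as fs
from spenfmri import phantom as ph
from spenfmri import sequences as sq


@pytest.fixture(scope="session")
def phantom():
    """Full-size OB phantom (96 x 70, study FOV)."""
    return ph.make_ob_phantom(seed=1)


@pytest.fixture(scope="session")
def nodecay_phantom(phantom):
    """Same geometry with relaxation switched off (pure encoding tests)."""
    p = phantom.copy()
    p.t2_map[:] = 1e9
    p.t2prime_map[:] = np.inf
    return p


@pytest.fixture(scope="session")
def small_phantom():
    """Quarter-size phantom for run-level simulations."""
    return ph.make_ob_phantom(nx=48, ny=36, seed=1)


@pytest.fixture(scope="session")
def short_paradigm():
    return be.build_paradigm(air_s=60.0, odor_s=26.0, n_events=4, n_volumes=180)


@pytest.fixture(scope="session")
def calibrated_sigma(phantom):
    """Raw-noise sigma giving image SNR 30 for the default FR-SPEN."""
    return fs.calibrate_noise(
        phantom, sq.default_params("FR_SPEN"), target_snr=30.0, n_trials=20, seed=0
    )


@pytest.fixture(scope="session")
def small_sigma(small_phantom):
    par = sq.default_params(
        "FR_SPEN", matrix=small_phantom.shape,
        fov_mm=tuple(round(v, 6) for v in small_phantom.fov_mm),
    )
    return fs.calibrate_noise(small_phantom, par, target_snr=30.0, n_trials=20, seed=0)


def small_params(kind, small_phantom, **kw):
    return sq.default_params(
        kind,
        matrix=small_phantom.shape,
        fov_mm=tuple(round(v, 6) for v in small_phantom.fov_mm),
        **kw,
    )


@pytest.fixture(scope="session")
def short_run_pr(small_phantom, short_paradigm, small_sigma):
    """Noisy PR-SPEN run with the default activation model (reduced grid)."""
    params = small_params("PR_SPEN", small_phantom, noise_sigma=small_sigma)
    return be.simulate_run(
        small_phantom, params, short_paradigm, be.BoldModel(), seed=1
    )
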