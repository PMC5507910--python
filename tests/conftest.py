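"""Shared fixtures: phantom scans and study sweeps reused across test modules.

Heavy simulations (the resolution sweep, the gated/non-gated study grid)
are session-scoped so each is run once for the whole suite.
"""

import numpy as np
import pytest

from pcmri import (
    PhantomSpec,
    StudyDesign,
    analyze_series,
    default_acquisition,
    run_study1,
    run_study2,
    simulate_series,
)

#: analytic ground truth of the steady Poiseuille phantom
POISEUILLE = {
    "v_max": 60.0,
    "radius_mm": 0.5,
    "flow_ml_s": np.pi * 0.5**2 * 60.0 / 2.0 / 100.0,  # pi R^2 vmax / 2 = 0.23562
    "area_mm2": np.pi * 0.5**2,  # 0.7854
    "wss_n_m2": 2 * 3.5e-3 * 0.60 / 0.5e-3,  # 2 eta vmax / R = 8.4
}


@pytest.fixture(scope="session")
def steady_spec():
    """Noiseless steady Poiseuille phantom: R = 0.5 mm, v_max = 60 cm/s."""
    return PhantomSpec(v_systolic=60.0, v_diastolic=60.0, snr=np.inf)


@pytest.fixture(scope="session")
def steady_series_016(steady_spec):
    """The steady phantom scanned at the finest protocol (0.16 mm grid)."""
    params = default_acquisition(steady_spec, venc=120.0, matrix_size=256, nex=16)
    return simulate_series(steady_spec, params)


@pytest.fixture(scope="session")
def steady_result_016(steady_series_016):
    return analyze_series(steady_series_016, scan_id="poiseuille")


@pytest.fixture(scope="session")
def steady_result_063(steady_spec):
    params = default_acquisition(steady_spec, venc=120.0, matrix_size=64, nex=4)
    return analyze_series(simulate_series(steady_spec, params), scan_id="poiseuille63")


@pytest.fixture(scope="session")
def steady_result_021(steady_spec):
    params = default_acquisition(steady_spec, venc=120.0, matrix_size=192, nex=12)
    return analyze_series(simulate_series(steady_spec, params), scan_id="poiseuille21")


@pytest.fixture(scope="session")
def study2_noiseless_df():
    """Noiseless resolution sweep over 12 jittered subjects (one repeat)."""
    design = StudyDesign(n_subjects=12, n_repeats=1, master_seed=0, snr=np.inf)
    base = PhantomSpec(snr=np.inf)
    return run_study2(design, base_spec=base)


@pytest.fixture(scope="session")
def study1_noisy_df():
    """Noisy gated/non-gated x VENC grid, 12 subjects x 2 repeats."""
    design = StudyDesign(n_subjects=12, n_repeats=2, master_seed=0)
    return run_study1(design)


@pytest.fixture(scope="session")
def venc_sweep_flows():
    """Noiseless gated flow of the default phantom across the VENC range."""
    spec = PhantomSpec(snr=np.inf)
    flows = {}
    for venc in (60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0):
        series = simulate_series(spec, default_acquisition(spec, venc=venc))
        flows[venc] = analyze_series(series).flow_ml_s
    return flows
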