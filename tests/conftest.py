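import numpy as np
import pandas as pd
import pytest

import serochip as sc


@pytest.fixture()
def small_config():
    """A compact study: 6 allergens in triplicate, 2 sera, 6 mocks."""
    return sc.SimulationConfig(
        layout=sc.small_layout(6),
        n_sera=2, arrays_per_serum=6, n_mock_arrays=6, n_days=3,
        seed=0,
    )


@pytest.fixture()
def small_study(small_config):
    scans, truth = sc.simulate_study(small_config)
    return small_config, scans, truth


@pytest.fixture()
def calibrated_small(small_study):
    config, scans, truth = small_study
    mocks = [s for s in scans if s.meta.is_mock]
    proc = [sc.preprocess(s) for s in mocks]
    model = sc.calibrate(proc, config.layout)
    return config, scans, truth, model


@pytest.fixture(scope="session")
def default_study():
    """The reproducibility design at full size: 6 sera x 18 arrays + 36 mocks."""
    config = sc.SimulationConfig(seed=0)
    scans, truth = sc.simulate_study(config)
    return config, scans, truth


@pytest.fixture(scope="session")
def default_quantified(default_study):
    """Default study carried through calibration, correction and aggregation."""
    config, scans, truth = default_study
    mocks = [s for s in scans if s.meta.is_mock]
    samples = [s for s in scans if not s.meta.is_mock]
    model = sc.calibrate([sc.preprocess(s) for s in mocks], config.layout)
    processed = []
    for s in samples:
        arr = sc.preprocess(s)
        arr = sc.apply_thresholds(sc.correct(arr, model), model)
        processed.append(arr)
    per_array = sc.build_ige_matrix(processed, config.layout, model,
                                    collapse_replicate_arrays=False)
    collapsed = sc.build_ige_matrix(processed, config.layout, model,
                                    collapse_replicate_arrays=True)
    return config, truth, model, processed, per_array, collapsed
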