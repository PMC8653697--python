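import numpy as np
import pytest

import cardiorqa as cq


@pytest.fixture(scope="session")
def det_clean_ecg():
    """Zero-noise DET trace on a constant tachogram (periodic limit).

    300 bpm gives RR = 200 ms = an integer number of samples at 1 kHz, so
    every rendered beat is sample-identical.
    """
    params = cq.condition_params("DET").with_(trace_noise_fraction=0.0)
    spec = cq.TachogramSpec(mean_hr=300.0, sd_hr=0.0, n_beats=30, seed=0)
    tacho = cq.build_tachogram(spec)
    ecg = cq.synthesize_ecg(params, tacho, fs=1000.0, seed=0)
    return ecg, tacho


@pytest.fixture(scope="session")
def det_default_recording():
    """DET recording at default noise settings with its tachogram."""
    return cq.simulate_recording("DET", lf_hf_ratio=0.5, n_beats=120, fs=1000, seed=7)


def random_symmetric_rp(rng, n, density=0.3, theiler_window=1, l_min=3):
    """Random symmetric binary matrix with unit diagonal, as a RecurrencePlot."""
    upper = rng.random((n, n)) < density
    mat = np.triu(upper, 1)
    mat = mat | mat.T
    np.fill_diagonal(mat, True)
    return cq.RecurrencePlot(matrix=mat, theiler_window=theiler_window, l_min=l_min)
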