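import numpy as np
import pytest

from gazecca import CohortSimParams, GazeSimParams, generate_gaze_recording


@pytest.fixture
def default_recording():
    """20 s, 250 Hz recording with 10 saccades at 100x amplitude/jitter."""
    rec, onsets = generate_gaze_recording(GazeSimParams(seed=42))
    return rec, onsets


@pytest.fixture
def small_cohort_params():
    return CohortSimParams(n_participants=60, seed=7)


def naive_zscore_flags(signal, ths, lag, influence):
    """Brute-force reference detector: rolling mean/SD recomputed from
    scratch at every step with numpy, independent of the streaming code."""
    x = np.asarray(signal, dtype=float)
    filt = list(x[:lag])
    flags = np.zeros(len(x), dtype=np.int8)
    for i in range(lag, len(x)):
        window = np.array(filt[i - lag : i])
        m = float(np.mean(window))
        # a window of identical values has zero SD by definition
        sd = 0.0 if np.ptp(window) == 0.0 else float(np.std(window, ddof=1))
        if sd == 0.0:
            z = np.inf if x[i] > m else 0.0
        else:
            z = (x[i] - m) / sd
        if z >= ths:
            flags[i] = 1
            filt.append(influence * x[i] + (1.0 - influence) * filt[i - 1])
        else:
            filt.append(float(x[i]))
    return flags
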