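"""Canonical timing windows shared across the pipeline (milliseconds).

Epochs are half-open stimulus-locked windows [-200, 1000) ms at 1 kHz
(1200 samples); the baseline is the pre-stimulus part [-200, 0). Peak
search windows: P1 most-positive peak in [0, 200] ms, N1 most-negative
peak in [150, 250] ms, both adjustable outward in 25 ms steps within
[0, 350] ms.
"""

SFREQ_HZ = 1000.0
EPOCH_START_MS = -200.0
EPOCH_STOP_MS = 1000.0
BASELINE_MS = (-200.0, 0.0)

P1_WINDOW_MS = (0.0, 200.0)
N1_WINDOW_MS = (150.0, 250.0)
WINDOW_STEP_MS = 25.0
WINDOW_CLAMP_MS = (0.0, 350.0)


def epoch_times_ms():
    """The 1200-point epoch time grid in milliseconds."""
    import numpy as np

    step = 1000.0 / SFREQ_HZ
    return np.arange(EPOCH_START_MS, EPOCH_STOP_MS, step)
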