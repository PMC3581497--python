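"""Low-pass differentiating filters shared by segmentation and metrics."""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["differentiate", "fill_gaps"]


def fill_gaps(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate across NaN runs (edge runs held constant).

    Filtering requires a gap-free signal; callers keep their own validity
    flags, so filled samples never enter any estimate directly.
    """
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        return np.zeros_like(x)
    out = x.copy()
    idx = np.arange(x.size)
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def differentiate(x: np.ndarray, sample_rate: float, window: int = 41,
                  polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay differentiator: velocity in x-units per second.

    A polynomial-window derivative is robust to the stair-stepping left by
    the video frame clock and has zero phase; attenuation of a sinusoid is
    identical for any two signals passed through the same window, so it
    cancels in gain/phase ratios when the stimulus is differentiated with
    the same filter.
    """
    x = fill_gaps(x)
    window = int(window)
    if window % 2 == 0:
        window += 1
    window = min(window, x.size if x.size % 2 == 1 else x.size - 1)
    if window <= polyorder:
        return np.gradient(x) * sample_rate
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=1, delta=1.0 / sample_rate, mode="interp")
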