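"""Canonical hemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist


def double_gamma_hrf(
    tr: float,
    duration: float = 19.6,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1 / 6,
) -> np.ndarray:
    """Double-gamma HRF sampled at TR resolution, normalized to unit peak.

    The standard two-gamma shape: a positive response peaking ~6 s after the
    event minus a scaled undershoot peaking ~16 s.  ``duration`` is the kernel
    span in seconds; the returned kernel has ``ceil(duration / tr)`` taps.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    n_taps = int(np.ceil(duration / tr - 1e-9))
    t = np.arange(n_taps) * tr
    h = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp) - (
        undershoot_ratio
        * gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    )
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h
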