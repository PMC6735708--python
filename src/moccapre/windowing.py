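"""Sliding-window score aggregation shared by the classifiers.

Both classifiers score a window as a weighted sum of point/pair events
whose coordinates fall inside the window.  Rather than rescoring every
window, each event is converted to the half-open range of window starts
for which it is contained, and per-window scores are accumulated with a
difference array over the start grid.
"""

from __future__ import annotations

import numpy as np


def window_grid(seq_len: int, window_bp: int, step_bp: int) -> np.ndarray:
    """Window start positions: 0, step, ... while the window fits.

    A sequence shorter than the window is scored as a single window
    covering the whole sequence.
    """
    if step_bp < 1:
        raise ValueError("step must be >= 1")
    if seq_len <= window_bp:
        return np.zeros(1, dtype=np.int64)
    return np.arange(0, seq_len - window_bp + 1, step_bp, dtype=np.int64)


def scores_over_windows(
    grid: np.ndarray,
    lo_excl: np.ndarray,
    hi_incl: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Per-window sums of event weights.

    Event j contributes to windows whose start s satisfies
    ``lo_excl[j] < s <= hi_incl[j]``.  For a single occurrence with
    midpoint m in a window of width W this is ``(m - W, m]``; for a pair
    with midpoints m1 <= m2 it is ``(m2 - W, m1]``.
    """
    nwin = len(grid)
    diff = np.zeros(nwin + 1)
    if len(weights):
        i0 = np.searchsorted(grid, lo_excl, side="right")
        i1 = np.searchsorted(grid, hi_incl, side="right")
        ok = i0 < i1
        np.add.at(diff, i0[ok], weights[ok])
        np.subtract.at(diff, i1[ok], weights[ok])
    return np.cumsum(diff[:-1])
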