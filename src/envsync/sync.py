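"""Windowed phase-locking value (PLV) between two instantaneous phase series.

Each window of relative phase angles Δφ_k is mapped to unit vectors; the
PLV is the modulus of their mean,

    PLV = (1/N) · sqrt( (Σ cos Δφ_k)² + (Σ sin Δφ_k)² ),

so PLV = 1 when every Δφ_k points the same way (perfect 1:1 locking) and
PLV → 0 when the directions spread uniformly.  Here the two phase series
are those of the upper and lower envelopes of a single channel, compared
over rectangular windows of 10 s slid with 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLVSeries", "compute_plv", "windowed_plv"]

DEFAULT_WINDOW_S = 10.0
DEFAULT_OVERLAP = 0.5


@dataclass
class PLVSeries:
    """Per-window PLV values for one channel."""

    values: np.ndarray        # PLV in [0, 1], one per window
    window_start_s: np.ndarray
    window_len_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_WINDOW_S * (1 - DEFAULT_OVERLAP)
    channel: str = ""

    def __len__(self) -> int:
        return len(self.values)


def compute_plv(delta_phi: np.ndarray) -> float:
    """PLV of one window of relative phase angles (radians).

    Wrapped and unwrapped phases are equivalent here: the value depends on
    Δφ only through cos and sin.
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    n = delta_phi.size
    if n == 0:
        raise ValueError("PLV of an empty window is undefined")
    return float(np.hypot(np.cos(delta_phi).sum(), np.sin(delta_phi).sum()) / n)


def windowed_plv(
    phi_upper: np.ndarray,
    phi_lower: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    channel: str = "",
) -> PLVSeries:
    """Sliding-window PLV of Δφ = φ_upper − φ_lower (1:1 phase ratio).

    Rectangular windows of ``window_s`` seconds (N = window_s · fs samples)
    are slid by N·(1−overlap) samples; a final window that would overrun
    the record is dropped.  Window positions are reported as window START
    times in seconds.
    """
    phi_upper = np.asarray(phi_upper, dtype=float)
    phi_lower = np.asarray(phi_lower, dtype=float)
    if phi_upper.shape != phi_lower.shape:
        raise ValueError(
            f"phase series lengths differ: {phi_upper.shape} vs {phi_lower.shape}"
        )
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    n_win = int(round(window_s * fs))
    if n_win < 1 or n_win > len(phi_upper):
        raise ValueError(
            f"window of {n_win} samples does not fit a record of {len(phi_upper)}"
        )
    hop = max(int(round(n_win * (1 - overlap))), 1)

    delta = phi_upper - phi_lower
    n_windows = (len(delta) - n_win) // hop + 1
    starts = np.arange(n_windows) * hop
    # resultant length per window via cumulative sums (O(n))
    c = np.concatenate([[0.0], np.cumsum(np.cos(delta))])
    s = np.concatenate([[0.0], np.cumsum(np.sin(delta))])
    sum_c = c[starts + n_win] - c[starts]
    sum_s = s[starts + n_win] - s[starts]
    values = np.hypot(sum_c, sum_s) / n_win
    return PLVSeries(
        values=np.minimum(values, 1.0),
        window_start_s=starts / fs,
        window_len_s=n_win / fs,
        hop_s=hop / fs,
        channel=channel,
    )
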