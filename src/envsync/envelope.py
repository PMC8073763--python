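"""Non-identical upper/lower signal envelopes from half-wave extrema.

The analytic (Hilbert) envelope of a signal is identical for its upper and
lower extremes, so it carries no information about their relative phase.
Here the two envelopes are built independently: local maxima are collected
inside positive half-waves and local minima inside negative half-waves,
thinned so that retained extrema of the same kind are at least
``min_separation`` samples apart (20 by default — a hardware-friendly
artefact/noise guard), and each set is joined by a natural cubic spline.

The input is expected to be the β-filtered, approximately zero-mean signal;
half-waves are delimited by its zero crossings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["ExtremaSet", "EnvelopePair", "detect_extrema", "spline_envelope", "build_envelopes"]

DEFAULT_MIN_SEPARATION = 20  # samples


@dataclass
class ExtremaSet:
    """Retained half-wave maxima and minima of one signal."""

    max_idx: np.ndarray  # sample indices, strictly increasing
    max_val: np.ndarray
    min_idx: np.ndarray
    min_val: np.ndarray
    min_separation: int = DEFAULT_MIN_SEPARATION


@dataclass
class EnvelopePair:
    """Upper/lower spline envelopes sampled at every signal index.

    The splines pass exactly through their knots (the retained extrema);
    between sparse knots the two curves are not guaranteed to stay ordered.
    """

    upper: np.ndarray
    lower: np.ndarray
    knots: ExtremaSet


def _half_wave_extrema(x: np.ndarray, positive: bool) -> tuple[np.ndarray, np.ndarray]:
    """Earliest argmax (argmin) of every positive (negative) half-wave.

    A half-wave is a maximal run of samples with x > 0 (x < 0).  The running
    extremum of each half-wave is committed when the run ends; a run cut off
    by the record edge is still committed so the envelope reaches the edge.
    """
    y = x if positive else -x
    mask = y > 0
    if not mask.any():
        return np.empty(0, dtype=int), np.empty(0)
    # run boundaries in original coordinates
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    orig_idx = np.flatnonzero(mask)          # concatenated in-run sample positions
    yr = y[orig_idx]
    lengths_cum = np.searchsorted(orig_idx, starts)
    run_max = np.maximum.reduceat(yr, lengths_cum)
    marks = np.zeros(len(yr), dtype=np.int32)
    marks[lengths_cum] = 1
    run_id = np.cumsum(marks) - 1
    at_max = yr == run_max[run_id]
    cand = np.flatnonzero(at_max)
    # earliest index per run: first occurrence of each run id among candidates
    _, first = np.unique(run_id[cand], return_index=True)
    pos = orig_idx[cand[first]]
    # a run cut off by the record edge whose extremum sits on the edge sample
    # is not a turning point; drop it
    pos = pos[(pos > 0) & (pos < len(x) - 1)]
    return pos, x[pos]


def _enforce_separation(idx: np.ndarray, min_separation: int) -> np.ndarray:
    """Greedy left-to-right thinning: keep a candidate only if it lies at
    least ``min_separation`` samples after the previously kept one."""
    keep = []
    last = -np.inf
    for i in idx.tolist():
        if i - last >= min_separation:
            keep.append(i)
            last = i
    return np.asarray(keep, dtype=int)


def detect_extrema(x: np.ndarray, min_separation: int = DEFAULT_MIN_SEPARATION) -> ExtremaSet:
    """Half-wave extrema detection with a same-kind separation constraint.

    Maxima are the largest samples of positive half-waves, minima the
    smallest of negative half-waves; within each kind, candidates closer
    than ``min_separation`` samples to the previously retained one are
    dropped (greedy, left to right).  A constant signal yields an empty
    set and a warning.
    """
    x = np.asarray(x, dtype=float)
    if min_separation < 1:
        raise ValueError(f"min_separation must be >= 1, got {min_separation}")
    max_idx, max_val = _half_wave_extrema(x, positive=True)
    min_idx, min_val = _half_wave_extrema(x, positive=False)
    if max_idx.size == 0 and min_idx.size == 0:
        warnings.warn("no half-wave extrema found (constant or empty signal)", stacklevel=2)
    keep_max = _enforce_separation(max_idx, min_separation)
    keep_min = _enforce_separation(min_idx, min_separation)
    sel_max = np.searchsorted(max_idx, keep_max)
    sel_min = np.searchsorted(min_idx, keep_min)
    return ExtremaSet(
        max_idx=keep_max,
        max_val=max_val[sel_max] if keep_max.size else np.empty(0),
        min_idx=keep_min,
        min_val=min_val[sel_min] if keep_min.size else np.empty(0),
        min_separation=min_separation,
    )


def spline_envelope(knot_idx: np.ndarray, knot_val: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through the knots, evaluated at samples 0..n−1.

    Outside the outermost knots the envelope is held at the nearest knot
    value (no spline extrapolation).
    """
    knot_idx = np.asarray(knot_idx)
    knot_val = np.asarray(knot_val, dtype=float)
    if knot_idx.size < 2:
        raise ValueError(
            f"need at least 2 envelope knots, got {knot_idx.size}; the signal "
            "may be too short/flat, or min_separation too wide for its band"
        )
    spline = CubicSpline(knot_idx, knot_val, bc_type="natural")
    t = np.arange(n)
    out = spline(np.clip(t, knot_idx[0], knot_idx[-1]))
    return out


def build_envelopes(x: np.ndarray, min_separation: int = DEFAULT_MIN_SEPARATION) -> EnvelopePair:
    """Detect half-wave extrema and spline them into upper/lower envelopes."""
    x = np.asarray(x, dtype=float)
    ext = detect_extrema(x, min_separation)
    upper = spline_envelope(ext.max_idx, ext.max_val, len(x))
    lower = spline_envelope(ext.min_idx, ext.min_val, len(x))
    return EnvelopePair(upper=upper, lower=lower, knots=ext)
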