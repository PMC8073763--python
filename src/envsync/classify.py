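"""Two-stage σ/ρ classifier on max-PLV positions, pre-ictal zones, metrics.

Stage one finds, for each channel, the time position of its maximum PLV
over the record; these positions form the vector Vp.  Stage two builds a
tolerance band around the median μ of Vp,

    upper = μ + μ·ρ/100,    lower = μ − μ·ρ/100,

and declares abnormal activity when at least σ of the positions fall
inside [lower, upper] — channels agreeing on *when* synchronisation peaks
is the signature of an ictal or pre-ictal event.  Verification assigns
in-band positions to seven zones anchored on the clinical seizure
(zone 1 = ictal; zones 2–6 = consecutive 60-s pre-ictal slices; zone 7 =
the 1000 s before those), and accumulates TP/FP/TN/FN per record-epoch:

* TP — abnormal declared and an in-band position lies in a designated zone;
* FP — abnormal declared with no seizure annotated, or none of the in-band
  positions in any zone (both sub-cases counted, reported separately);
* TN — no abnormal activity and no seizure annotated;
* FN — seizure annotated but no abnormal activity declared.

σ may alternatively be given as a percentage of the channel count
(``sigma_mode="percent"``), rounded half-up to a count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import SeizureAnnotation
from .sync import PLVSeries

__all__ = [
    "MaxPLVPositions",
    "Boundaries",
    "ClassifierParams",
    "ConfusionCounts",
    "Metrics",
    "RecordVerdict",
    "max_plv_positions",
    "boundaries",
    "classify_abnormal",
    "sigma_count",
    "zone_intervals",
    "assign_zone",
    "evaluate_record",
    "metrics",
    "sweep",
    "classify_record",
]

ZONE_SLICE_S = 60.0     # zones 2-6: one minute each
ZONE7_LEN_S = 1000.0
N_ZONES = 7


@dataclass
class MaxPLVPositions:
    """Vp: per-channel time position (s) of the maximum PLV in a record."""

    positions_s: np.ndarray
    channel_labels: list[str]

    def __len__(self) -> int:
        return len(self.positions_s)


@dataclass(frozen=True)
class Boundaries:
    """Median-centred ρ% tolerance band on Vp."""

    mu: float
    rho: float
    upper: float
    lower: float


@dataclass(frozen=True)
class ClassifierParams:
    rho: float = 20.0
    sigma: float = 14.0
    sigma_mode: str = "count"  # "count" | "percent" (of channel count)

    def __post_init__(self) -> None:
        if self.rho < 0 or self.sigma < 0:
            raise ValueError("rho and sigma must be non-negative")
        if self.sigma_mode not in ("count", "percent"):
            raise ValueError(f"sigma_mode must be 'count' or 'percent', got {self.sigma_mode!r}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    FP_no_seizure: int = 0   # abnormal with no annotation at all
    FP_out_of_zone: int = 0  # abnormal, seizure annotated, but no in-zone hit

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        self.TP += other.TP
        self.FP += other.FP
        self.TN += other.TN
        self.FN += other.FN
        self.FP_no_seizure += other.FP_no_seizure
        self.FP_out_of_zone += other.FP_out_of_zone
        return self

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy; NaN when
    the denominator is zero."""

    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class RecordVerdict:
    """Full per-record classifier output, serialisable to JSON."""

    record_id: str
    params: ClassifierParams
    vp: MaxPLVPositions
    bounds: Boundaries
    count_in_boundary: int
    abnormal: bool
    outcome: str  # TP | FP | TN | FN
    zone_hits: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "rho": self.params.rho,
            "sigma": self.params.sigma,
            "sigma_mode": self.params.sigma_mode,
            "mu": self.bounds.mu,
            "upper": self.bounds.upper,
            "lower": self.bounds.lower,
            "count_in_boundary": self.count_in_boundary,
            "abnormal": self.abnormal,
            "outcome": self.outcome,
            "zone_hits": {str(z): c for z, c in sorted(self.zone_hits.items())},
        }


def max_plv_positions(series_per_channel: list[PLVSeries]) -> MaxPLVPositions:
    """Position of each channel's maximum PLV; ties go to the earliest window."""
    if not series_per_channel:
        raise ValueError("no PLV series given")
    pos, labels = [], []
    for k, s in enumerate(series_per_channel):
        if len(s) == 0:
            raise ValueError(f"PLV series for channel {s.channel or k} is empty")
        i = int(np.argmax(s.values))  # argmax returns the first maximum
        pos.append(float(s.window_start_s[i]))
        labels.append(s.channel or f"ch{k}")
    return MaxPLVPositions(positions_s=np.asarray(pos), channel_labels=labels)


def boundaries(vp: MaxPLVPositions, rho: float) -> Boundaries:
    """ρ% tolerance band around the median of Vp (even count: mean of the
    two central values)."""
    if len(vp) == 0:
        raise ValueError("Vp is empty")
    mu = float(np.median(vp.positions_s))
    return Boundaries(mu=mu, rho=rho, upper=mu + mu * rho / 100, lower=mu - mu * rho / 100)


def sigma_count(sigma: float, sigma_mode: str, n_channels: int) -> int:
    """Resolve σ to an absolute count (percent mode: of channel count,
    rounded half up)."""
    if sigma_mode == "count":
        return int(math.ceil(sigma)) if sigma != int(sigma) else int(sigma)
    return int(math.floor(sigma / 100 * n_channels + 0.5))


def classify_abnormal(
    vp: MaxPLVPositions, b: Boundaries, sigma: int
) -> tuple[bool, int]:
    """Abnormal-activity decision: count of Vp inside [lower, upper]
    (inclusive) compared against the σ threshold."""
    inside = (vp.positions_s >= b.lower) & (vp.positions_s <= b.upper)
    count = int(inside.sum())
    return count >= sigma, count


def zone_intervals(a: SeizureAnnotation) -> dict[int, tuple[float, float]]:
    """The seven verification zones anchored on one clinical seizure.

    Zone 1 spans the ictal interval; zones 2–6 step back in 60-s slices
    from the clinical start; zone 7 covers the 1000 s before zone 6.
    """
    z = {1: (a.start_s, a.end_s)}
    stop = a.start_s
    for k in range(2, N_ZONES):
        z[k] = (stop - ZONE_SLICE_S, stop)
        stop -= ZONE_SLICE_S
    z[N_ZONES] = (stop - ZONE7_LEN_S, stop)
    return z


def assign_zone(position_s: float, a: SeizureAnnotation) -> int | None:
    """Zone id (1..7) containing a time position, or None.

    Zone 1 is closed at both edges; zones 2–7 are closed at the earlier
    edge and open at the later one, so they tile the pre-ictal span
    without overlap and hand over to zone 1 exactly at the clinical start.
    """
    zones = zone_intervals(a)
    lo, hi = zones[1]
    if lo <= position_s <= hi:
        return 1
    for k in range(2, N_ZONES + 1):
        lo, hi = zones[k]
        if lo <= position_s < hi:
            return k
    return None


def evaluate_record(
    abnormal: bool,
    in_boundary_positions: np.ndarray | list[float],
    annotations: list[SeizureAnnotation],
    zone_filter: int | str = "any",
) -> tuple[ConfusionCounts, dict[int, int]]:
    """Confusion outcome for one record-epoch, plus zone hit counts.

    ``zone_filter`` restricts the TP condition to one zone id, or "any"
    to accept a hit in any of the seven zones.
    """
    zone_hits: dict[int, int] = {}
    for p in np.asarray(in_boundary_positions, dtype=float):
        for a in annotations:
            z = assign_zone(float(p), a)
            if z is not None:
                zone_hits[z] = zone_hits.get(z, 0) + 1
                break

    c = ConfusionCounts()
    if zone_filter == "any":
        hit = bool(zone_hits)
    else:
        hit = zone_hits.get(int(zone_filter), 0) > 0
    if abnormal:
        if annotations and hit:
            c.TP = 1
        else:
            c.FP = 1
            if annotations:
                c.FP_out_of_zone = 1
            else:
                c.FP_no_seizure = 1
    else:
        if annotations:
            c.FN = 1
        else:
            c.TN = 1
    return c, zone_hits


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy; NaN where undefined."""
    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return Metrics(
        sensitivity=ratio(c.TP, c.TP + c.FN),
        specificity=ratio(c.TN, c.TN + c.FP),
        accuracy=ratio(c.TP + c.TN, c.total),
    )


def classify_record(
    record_id: str,
    series_per_channel: list[PLVSeries],
    annotations: list[SeizureAnnotation],
    params: ClassifierParams,
    zone_filter: int | str = "any",
) -> tuple[RecordVerdict, ConfusionCounts]:
    """Run both classifier stages and the zone verification on one record."""
    vp = max_plv_positions(series_per_channel)
    b = boundaries(vp, params.rho)
    sig = sigma_count(params.sigma, params.sigma_mode, len(vp))
    abnormal, count = classify_abnormal(vp, b, sig)
    inside = vp.positions_s[
        (vp.positions_s >= b.lower) & (vp.positions_s <= b.upper)
    ]
    counts, zone_hits = evaluate_record(abnormal, inside, annotations, zone_filter)
    outcome = next(k for k in ("TP", "FP", "TN", "FN") if getattr(counts, k) == 1)
    verdict = RecordVerdict(
        record_id=record_id,
        params=params,
        vp=vp,
        bounds=b,
        count_in_boundary=count,
        abnormal=abnormal,
        outcome=outcome,
        zone_hits=zone_hits,
    )
    return verdict, counts


def sweep(
    records: list[tuple[str, list[PLVSeries], list[SeizureAnnotation]]],
    sigma_grid: list[float],
    rho_grid: list[float],
    sigma_mode: str = "percent",
    zone_filter: int | str = "any",
) -> list[dict]:
    """Metric surface over the (σ, ρ) grid, ρ-major then σ.

    For each grid point, confusion counts are accumulated over all records
    and turned into metrics.  Returns one dict per grid point with keys
    rho, sigma, TP, FP, TN, FN, sensitivity, specificity, accuracy.
    """
    if not records:
        raise ValueError("no records to sweep")
    if not sigma_grid or not rho_grid:
        raise ValueError("sigma and rho grids must be non-empty")
    rows = []
    for rho in sorted(rho_grid):
        for sigma in sorted(sigma_grid):
            params = ClassifierParams(rho=rho, sigma=sigma, sigma_mode=sigma_mode)
            total = ConfusionCounts()
            for record_id, series, anns in records:
                _, c = classify_record(record_id, series, anns, params, zone_filter)
                total += c
            m = metrics(total)
            rows.append({
                "rho": rho,
                "sigma": sigma,
                "TP": total.TP,
                "FP": total.FP,
                "TN": total.TN,
                "FN": total.FN,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
            })
    return rows
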