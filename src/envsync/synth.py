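"""Synthetic multichannel EEG with controllable envelope-phase coupling.

Real ictal EEG shows β-band bursts whose upper and lower envelopes become
phase-locked; this generator emulates exactly that feature so the full
pipeline (filter → envelopes → phase → PLV → classifier) is testable
without any recorded data.

Construction, per channel: two slow positive modulators
``u(t) = 1 + d·cos θ_u(t)`` and ``l(t) = 1 + d·cos θ_l(t)`` are the target
upper and lower envelopes.  Their phases θ advance at slightly different
base rates plus independent random walks, so outside seizures the two
envelopes drift apart in phase.  Inside an annotated seizure window the
lower modulator is pulled onto the upper one with weight ``coupling_in``
(phase-locked envelopes); outside, with weight ``coupling_out``.

The waveform is built from a β-band carrier and its second harmonic,

    x(t) = A(t)·cos(2π f_c t) + B(t)·cos(4π f_c t),
    A = (u + l)/2,   B = (u − l)/2,

which peaks at ``+u`` and troughs at ``−l`` each carrier cycle.  Because
both components sit inside the β band (f_c = 14 Hz, 2f_c = 28 Hz by
default), the upper/lower asymmetry survives the band-pass stage — a pure
amplitude-modulated tone would have identical (mirror) envelopes and
nothing to detect.  Broadband noise (white, or optionally 1/f) is added
on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EEGRecord, SeizureAnnotation, write_annotations, write_edf

__all__ = ["SynthConfig", "generate_record", "benchmark_configs", "write_benchmark"]


@dataclass
class SynthConfig:
    """Generator settings for one synthetic record.

    Defaults emulate a CHB-MIT-style record: one hour at 256 Hz, 23
    channels, a β carrier, ~1 Hz envelope modulation, strong envelope
    coupling inside seizures and none outside.
    """

    record_id: str = "synth"
    duration_s: float = 3600.0
    fs: float = 256.0
    n_channels: int = 23
    seizures: list[tuple[float, float]] = field(default_factory=list)
    carrier_hz: float = 14.0        # second harmonic 2·f_c must stay in-band
    modulator_hz: float = 1.0
    mod_depth: float = 0.6
    freq_ratio: float = 1.3         # lower/upper modulator base-rate ratio
    phase_drift: float = 0.8        # random-walk scale, rad/sqrt(s)
    coupling_in: float = 0.9
    coupling_out: float = 0.0
    noise_sd: float = 0.1
    noise_color: str = "white"      # "white" | "pink"
    amplitude_uv: float = 50.0      # µV scale of the carrier component
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_in <= 1 or not 0 <= self.coupling_out <= 1:
            raise ValueError("coupling levels must lie in [0, 1]")
        if not 0 <= self.mod_depth < 1:
            raise ValueError("mod_depth must lie in [0, 1) so envelopes stay one-signed")
        last = 0.0
        for start, end in sorted(self.seizures):
            if not 0 <= start < end <= self.duration_s:
                raise ValueError(f"seizure window ({start}, {end}) outside record")
            if start < last:
                raise ValueError("seizure windows must not overlap")
            last = end


def _noise(rng: np.random.Generator, n: int, sd: float, color: str, fs: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n) * sd
    if color == "white":
        return w
    if color == "pink":
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n, 1 / fs)
        shaping = np.ones_like(f)
        nonzero = f > 0
        shaping[nonzero] = 1 / np.sqrt(f[nonzero] / max(f[1], 1e-9))
        pink = np.fft.irfft(spec * shaping, n)
        return pink * sd / max(pink.std(), 1e-12)
    raise ValueError(f"unknown noise color {color!r}")


def generate_record(cfg: SynthConfig) -> tuple[EEGRecord, list[SeizureAnnotation]]:
    """Generate one labeled record; deterministic given ``cfg.seed``."""
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    carrier = np.cos(2 * np.pi * cfg.carrier_hz * t)
    harmonic = np.cos(4 * np.pi * cfg.carrier_hz * t)

    coupling = np.full(n, cfg.coupling_out)
    for start, end in cfg.seizures:
        coupling[int(start * fs) : int(end * fs)] = cfg.coupling_in

    samples = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        rng = np.random.default_rng([cfg.seed, ch])
        drift_sd = cfg.phase_drift / np.sqrt(fs)
        theta_u = 2 * np.pi * cfg.modulator_hz * t + np.cumsum(
            rng.standard_normal(n) * drift_sd
        ) + rng.uniform(0, 2 * np.pi)
        theta_l = 2 * np.pi * cfg.modulator_hz * cfg.freq_ratio * t + np.cumsum(
            rng.standard_normal(n) * drift_sd
        ) + rng.uniform(0, 2 * np.pi)
        m_u = cfg.mod_depth * np.cos(theta_u)
        m_l_free = cfg.mod_depth * np.cos(theta_l)
        m_l = coupling * m_u + (1 - coupling) * m_l_free
        upper = 1 + m_u
        lower = 1 + m_l
        x = 0.5 * (upper + lower) * carrier + 0.5 * (upper - lower) * harmonic
        x += _noise(rng, n, cfg.noise_sd, cfg.noise_color, fs)
        samples[ch] = cfg.amplitude_uv * x

    record = EEGRecord(
        record_id=cfg.record_id,
        samples=samples,
        fs=fs,
        channel_labels=[f"EEG{ch:02d}" for ch in range(cfg.n_channels)],
    )
    annotations = [
        SeizureAnnotation(cfg.record_id, float(s), float(e)) for s, e in cfg.seizures
    ]
    return record, annotations


def benchmark_configs(
    seed: int = 1,
    n_records: int = 10,
    n_with_seizure: int = 6,
    duration_s: float = 3600.0,
    n_channels: int = 23,
    seizure_len_s: float = 90.0,
    **overrides,
) -> list[SynthConfig]:
    """Configs for the default labeled benchmark: ``n_records`` records,
    the first ``n_with_seizure`` of which carry one seizure at a
    seed-determined position in the middle half of the record."""
    if n_with_seizure > n_records:
        raise ValueError("more seizure records requested than records")
    rng = np.random.default_rng([seed, 0xBEEF])
    configs = []
    for k in range(n_records):
        seizures: list[tuple[float, float]] = []
        if k < n_with_seizure:
            start = float(
                rng.uniform(0.25 * duration_s, 0.75 * duration_s - seizure_len_s)
            )
            seizures = [(round(start), round(start) + seizure_len_s)]
        configs.append(
            SynthConfig(
                record_id=f"synth{k:02d}",
                duration_s=duration_s,
                n_channels=n_channels,
                seizures=seizures,
                seed=seed * 1000 + k,
                **overrides,
            )
        )
    return configs


def write_benchmark(configs: list[SynthConfig], out_dir: str | Path) -> list[Path]:
    """Write each config's record as EDF plus one shared annotation file.

    Returns the written EDF paths; annotations go to ``annotations.txt``
    in the same directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    all_annotations: list[SeizureAnnotation] = []
    for cfg in configs:
        record, anns = generate_record(cfg)
        path = out_dir / f"{cfg.record_id}.edf"
        write_edf(path, record)
        paths.append(path)
        all_annotations.extend(anns)
    write_annotations(out_dir / "annotations.txt", all_annotations)
    return paths
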