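"""EDF signal I/O and plain-text seizure annotations.

EDF (European Data Format) reading is delegated to :mod:`mne`.  Writing uses a
small built-in writer restricted to the subset of plain EDF this package
produces: one 16-bit data record per second, a single sampling rate and a
microvolt physical dimension shared by all channels.

Annotations use a one-seizure-per-line text dialect::

    record_id=<id> start=<seconds> end=<seconds>

plus a tolerant reader for CHB-MIT style ``chbXX-summary.txt`` files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecord",
    "SeizureAnnotation",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "read_chb_summary",
]


@dataclass
class EEGRecord:
    """Multichannel EEG record: channels x samples, amplitudes in microvolts."""

    record_id: str
    samples: np.ndarray  # shape (n_channels, n_samples), float64, µV
    fs: float  # Hz
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's sample series by label."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in record {self.record_id!r} "
                f"(available: {self.channel_labels})"
            ) from None
        return self.samples[i]


@dataclass(frozen=True)
class SeizureAnnotation:
    """Clinically annotated seizure interval, seconds from record start."""

    record_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"invalid seizure interval [{self.start_s}, {self.end_s}] "
                f"for record {self.record_id!r}"
            )


def read_edf(path: str | Path, channels: list[str] | None = None) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord`.

    Parameters
    ----------
    path
        EDF file path.
    channels
        Channel labels to keep (default: all, in file order).

    Returns
    -------
    EEGRecord with amplitudes in µV and ``fs`` from the file header.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise KeyError(f"channel(s) {missing} not found in {path.name}; "
                           f"available: {raw.ch_names}")
        raw.pick(channels)
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    return EEGRecord(
        record_id=path.stem,
        samples=data,
        fs=fs,
        channel_labels=list(raw.ch_names),
    )


def write_edf(path: str | Path, record: EEGRecord) -> None:
    """Write an :class:`EEGRecord` as a plain 16-bit EDF file.

    One data record per second; requires an integer sampling rate and an
    integer number of seconds of data.  The physical range is chosen
    symmetric around zero and just wide enough for the data, so the
    quantisation step is ``range / 65535``.
    """
    path = Path(path)
    fs = record.fs
    if fs != int(fs):
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(fs)
    n_sec, rem = divmod(record.n_samples, fs)
    if rem:
        raise ValueError(
            f"EDF writer requires whole seconds of data ({record.n_samples} samples at {fs} Hz)"
        )
    nch = record.n_channels
    data = record.samples

    phys_amp = float(np.max(np.abs(data))) if data.size else 1.0
    phys_amp = max(phys_amp * 1.001, 1e-6)
    phys_max = float(f"{phys_amp:.6g}")  # must survive the 8-char ASCII header field
    if phys_max < phys_amp:
        phys_max *= 1.000002
        phys_max = float(f"{phys_max:.6g}")
    dig_min, dig_max = -32768, 32767

    def _field(value: str, width: int) -> bytes:
        b = value.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {value!r} ({width} chars)")
        return b.ljust(width)

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),                      # local patient id
        _field(f"Startdate X X X X {record.record_id}"[:80], 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (nch + 1)), 8),
        _field("", 44),
        _field(str(n_sec), 8),
        _field("1", 8),                             # record duration, seconds
        _field(str(nch), 4),
    ])
    sig_header = b"".join([
        b"".join(_field(lab[:16], 16) for lab in record.channel_labels),
        b"".join(_field("", 80) for _ in range(nch)),
        b"".join(_field("uV", 8) for _ in range(nch)),
        b"".join(_field(f"{-phys_max:.6g}", 8) for _ in range(nch)),
        b"".join(_field(f"{phys_max:.6g}", 8) for _ in range(nch)),
        b"".join(_field(str(dig_min), 8) for _ in range(nch)),
        b"".join(_field(str(dig_max), 8) for _ in range(nch)),
        b"".join(_field("", 80) for _ in range(nch)),
        b"".join(_field(str(fs), 8) for _ in range(nch)),
        b"".join(_field("", 32) for _ in range(nch)),
    ])

    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.rint((data + phys_max) * scale) + dig_min, dig_min, dig_max)
    digital = digital.astype("<i2")  # (nch, n_sec * fs)
    # EDF interleaves by data record: all of channel 1's second, then channel 2's...
    blocks = digital.reshape(nch, n_sec, fs).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(blocks.tobytes())


_ANNOT_LINE = re.compile(
    r"^record_id=(?P<rid>\S+)\s+start=(?P<start>[0-9.]+)\s+end=(?P<end>[0-9.]+)\s*$"
)


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Parse the ``record_id=... start=... end=...`` annotation dialect.

    Blank lines and ``#`` comments are ignored; any other malformed line
    raises with its line number.
    """
    out: list[SeizureAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _ANNOT_LINE.match(stripped)
        if m is None:
            raise ValueError(f"{path}: malformed annotation on line {lineno}: {line!r}")
        try:
            ann = SeizureAnnotation(m["rid"], float(m["start"]), float(m["end"]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        out.append(ann)
    return out


def write_annotations(path: str | Path, annotations: list[SeizureAnnotation]) -> None:
    """Write annotations in the dialect read by :func:`read_annotations`."""
    lines = [
        f"record_id={a.record_id} start={a.start_s:g} end={a.end_s:g}"
        for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_CHB_FILE = re.compile(r"^File Name:\s*(\S+?)(?:\.edf)?\s*$", re.IGNORECASE)
_CHB_START = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([0-9.]+)\s*sec", re.IGNORECASE)
_CHB_END = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([0-9.]+)\s*sec", re.IGNORECASE)


def read_chb_summary(path: str | Path) -> list[SeizureAnnotation]:
    """Tolerant parser for CHB-MIT ``chbXX-summary.txt`` seizure listings.

    Tracks the current ``File Name:`` and pairs each ``Seizure [k] Start
    Time``/``End Time`` couple under it.  Lines that match none of the three
    patterns are ignored, so montage blocks and timestamps pass through.
    """
    out: list[SeizureAnnotation] = []
    current: str | None = None
    pending_start: float | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if m := _CHB_FILE.match(stripped):
            current = m.group(1)
            pending_start = None
        elif m := _CHB_START.match(stripped):
            pending_start = float(m.group(1))
        elif m := _CHB_END.match(stripped):
            if current is None or pending_start is None:
                raise ValueError(
                    f"{path}: line {lineno}: seizure end time without a "
                    "preceding file name and start time"
                )
            out.append(SeizureAnnotation(current, pending_start, float(m.group(1))))
            pending_start = None
    return out
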