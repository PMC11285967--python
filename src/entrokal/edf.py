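"""EDF (European Data Format) input for EEG channels, plus a fixture writer.

Reading goes through :mod:`mne` (``mne.io.read_raw_edf``), which handles
the 16-bit digital-to-physical mapping and channel typing.  Writing is a
minimal standard-conformant EDF encoder used to build local test fixtures
from synthetic :class:`~entrokal.signals.SignalRecord` objects, so no
external recordings are ever required.  Signals are stored in microvolts
with a symmetric digital range of ±32767; the worst-case round-trip error
is half a digital step, i.e. max|x| / 65534.

Segment bounds are in seconds and half-open, [t_start, t_stop), with
sample index floor(t * fs) — a window that ends where the next begins
never double-counts a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ChannelNotFoundError, EdfFormatError, EmptySeriesError, ParameterError
from .signals import SignalRecord

__all__ = ["ChannelRequest", "load_edf_channel", "write_fixture_edf"]

_DIG_MAX = 32767  # symmetric 16-bit digital range


@dataclass(frozen=True)
class ChannelRequest:
    """One channel and time segment of an EDF file.

    ``channel_label`` must match the header label exactly (e.g.
    "EEG Fpz-Cz" or "FP1-F3").  ``t_stop=None`` means end of file.
    """

    path: str | Path
    channel_label: str
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self) -> None:
        if self.t_stop is not None and not self.t_start < self.t_stop:
            raise ParameterError(
                f"t_start must precede t_stop, got [{self.t_start}, {self.t_stop})"
            )


def load_edf_channel(req: ChannelRequest) -> SignalRecord:
    """Load one channel segment in physical units (microvolts).

    The sampling rate comes from the file header; downstream entropy
    windowing derives L = 5 * fs from it (500 at 100 Hz, 1280 at 256 Hz).
    """
    import mne

    path = Path(req.path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for malformed files
        raise EdfFormatError(f"{path}: not readable as EDF ({exc})") from exc
    if req.channel_label not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {req.channel_label!r} not in {path.name}; "
            f"available: {raw.ch_names}"
        )
    fs = float(raw.info["sfreq"])
    idx = raw.ch_names.index(req.channel_label)
    data = raw.get_data(picks=[idx], units="uV")[0]
    i0 = int(np.floor(req.t_start * fs))
    i1 = data.size if req.t_stop is None else int(np.floor(req.t_stop * fs))
    if not 0 <= i0 < i1 <= data.size:
        raise ParameterError(
            f"segment [{req.t_start}, {req.t_stop}) s outside recording "
            f"of {data.size / fs:.1f} s"
        )
    return SignalRecord(values=data[i0:i1], fs=fs, label=req.channel_label)


def _ascii_field(value: object, width: int) -> bytes:
    text = str(value)
    raw = text.encode("ascii")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def _physical_bound(pm: float) -> tuple[str, float]:
    """Format a physical-range bound into <= 7 chars (leaving room for the
    minus sign of the min field) and return the formatted value itself so
    the digital encoding uses exactly the scale written in the header."""
    for precision in range(6, 0, -1):
        text = f"{pm:.{precision}g}"
        if len(text) <= 7:
            return text, float(text)
    raise ParameterError(f"cannot represent physical bound {pm} in EDF header")


def write_fixture_edf(
    signals: SignalRecord | Iterable[SignalRecord],
    path: str | Path,
) -> Path:
    """Write one or more channels to a standard EDF file.

    Each :class:`SignalRecord`'s ``label`` becomes the channel label and
    must be unique; every channel needs an integer sampling rate (records
    are one second long) and finite samples.  If the signal length is not
    a whole number of seconds the final record is zero-padded.
    """
    if isinstance(signals, SignalRecord):
        signals = [signals]
    channels = list(signals)
    if not channels:
        raise ParameterError("need at least one channel")
    labels = [ch.label or f"ch{i}" for i, ch in enumerate(channels)]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate channel labels: {labels}")
    for ch in channels:
        if ch.n == 0:
            raise EmptySeriesError("cannot write a zero-length channel")
        if not np.all(np.isfinite(ch.values)):
            raise ParameterError("EDF fixture requires finite samples")
        if abs(ch.fs - round(ch.fs)) > 1e-9:
            raise ParameterError(
                f"integer sampling rate required for 1 s records, got {ch.fs}"
            )
    samples_per_record = [int(round(ch.fs)) for ch in channels]
    n_records = max(
        int(np.ceil(ch.n / spr)) for ch, spr in zip(channels, samples_per_record)
    )
    bounds = [_physical_bound(float(np.max(np.abs(ch.values))) or 1.0) for ch in channels]
    phys_text = [b[0] for b in bounds]
    phys_max = [b[1] for b in bounds]

    ns = len(channels)
    header = b"".join(
        [
            _ascii_field("0", 8),  # version
            _ascii_field("X X X X", 80),  # patient id (anonymous fixture)
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + ns), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field("1", 8),  # record duration, seconds
            _ascii_field(ns, 4),
        ]
    )
    signal_header = b"".join(
        [
            b"".join(_ascii_field(lab, 16) for lab in labels),
            b"".join(_ascii_field("", 80) for _ in channels),  # transducer
            b"".join(_ascii_field("uV", 8) for _ in channels),
            b"".join(_ascii_field(f"-{txt}", 8) for txt in phys_text),
            b"".join(_ascii_field(txt, 8) for txt in phys_text),
            b"".join(_ascii_field(-_DIG_MAX, 8) for _ in channels),
            b"".join(_ascii_field(_DIG_MAX, 8) for _ in channels),
            b"".join(_ascii_field("", 80) for _ in channels),  # prefilter
            b"".join(_ascii_field(spr, 8) for spr in samples_per_record),
            b"".join(_ascii_field("", 32) for _ in channels),
        ]
    )
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header + signal_header)
        for rec in range(n_records):
            for ch, spr, pm in zip(channels, samples_per_record, phys_max):
                seg = ch.values[rec * spr : (rec + 1) * spr]
                if seg.size < spr:
                    seg = np.concatenate([seg, np.zeros(spr - seg.size)])
                # clip guards against the header bound rounding slightly low
                digital = np.clip(
                    np.round(seg / pm * _DIG_MAX), -_DIG_MAX, _DIG_MAX
                ).astype("<i2")
                fh.write(digital.tobytes())
    return path
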