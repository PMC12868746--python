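"""Cropping, band-pass decomposition and windowing of EEG recordings.

A recording is optionally cropped to an analysis interval, optionally
broadband pre-filtered (default 1-50 Hz) with a 50 Hz notch, band-passed into
the five canonical bands, collapsed to a single analysis series per band
(channel mean by default), and cut into consecutive non-overlapping windows
(default 4 s).  All filters are zero-phase order-4 Butterworth applied
forward-backward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import BAND_EDGES, BAND_NAMES, EEGRecording

__all__ = [
    "BandDefinition",
    "BandWindow",
    "DEFAULT_BANDS",
    "crop_recording",
    "bandpass",
    "notch",
    "broadband_prefilter",
    "collapse_channels",
    "segment",
    "band_windows",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band edges for {self.name}")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high_hz} Hz reaches the "
                f"Nyquist frequency {fs / 2} Hz"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(name, *BAND_EDGES[name]) for name in BAND_NAMES
)


@dataclass
class BandWindow:
    """One analysis window of one band of one subject's collapsed series."""

    subject_id: str
    band: BandDefinition | None
    window_index: int
    data: np.ndarray
    fs: float


def crop_recording(rec: EEGRecording, start_s: float, end_s: float) -> EEGRecording:
    """Return the samples in the half-open interval [start_s*fs, end_s*fs)."""
    if not (0 <= start_s < end_s <= rec.duration_s + 1e-9):
        raise ValueError(
            f"crop bounds [{start_s}, {end_s}] outside recording of "
            f"{rec.duration_s:.3f} s"
        )
    i0 = int(round(start_s * rec.fs))
    i1 = int(round(end_s * rec.fs))
    return EEGRecording(rec.subject_id, rec.data[:, i0:i1].copy(), rec.fs, rec.label)


def _apply_sos(rec: EEGRecording, sos: np.ndarray) -> EEGRecording:
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(rec.subject_id, filtered, rec.fs, rec.label)


def bandpass(rec: EEGRecording, band: BandDefinition, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel."""
    band.validate(rec.fs)
    sos = sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                     fs=rec.fs, output="sos")
    return _apply_sos(rec, sos)


def notch(rec: EEGRecording, freq_hz: float = 50.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase notch filter (default 50 Hz mains)."""
    if freq_hz >= rec.fs / 2:
        raise ValueError("notch frequency reaches Nyquist")
    b, a = sps.iirnotch(freq_hz, q, fs=rec.fs)
    filtered = sps.filtfilt(b, a, rec.data, axis=1)
    return EEGRecording(rec.subject_id, filtered, rec.fs, rec.label)


def broadband_prefilter(rec: EEGRecording, low_hz: float = 1.0,
                        high_hz: float = 50.0, notch_hz: float | None = 50.0,
                        order: int = 4) -> EEGRecording:
    """Broadband 1-50 Hz pre-filter plus optional mains notch.

    The notch is skipped when it falls outside (or on) the pass band's upper
    edge context, i.e. when notch_hz >= Nyquist.
    """
    band = BandDefinition("broadband", low_hz, high_hz)
    out = bandpass(rec, band, order=order)
    if notch_hz is not None and notch_hz < rec.fs / 2:
        out = notch(out, notch_hz)
    return out


def collapse_channels(rec: EEGRecording, mode: str | int = "mean") -> np.ndarray:
    """Collapse channels to one analysis series (mean, or a channel index)."""
    if mode == "mean":
        return rec.data.mean(axis=0)
    if isinstance(mode, int):
        if not (0 <= mode < rec.n_channels):
            raise ValueError(f"channel index {mode} out of range")
        return rec.data[mode].copy()
    raise ValueError(f"unknown channel-collapse mode: {mode!r}")


def segment(rec: EEGRecording, window_s: float = 4.0,
            band: BandDefinition | None = None,
            collapse: str | int = "mean") -> list[BandWindow]:
    """Cut the collapsed series into consecutive non-overlapping windows.

    Returns floor(duration / window_s) windows in temporal order; a trailing
    partial window is dropped.  Window k covers samples
    [k*window_s*fs, (k+1)*window_s*fs).
    """
    if rec.duration_s < window_s:
        raise ValueError("recording shorter than one window")
    series = collapse_channels(rec, collapse)
    win_len = int(round(window_s * rec.fs))
    n_win = series.shape[0] // win_len
    return [
        BandWindow(rec.subject_id, band, k,
                   series[k * win_len:(k + 1) * win_len].copy(), rec.fs)
        for k in range(n_win)
    ]


def band_windows(rec: EEGRecording, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                 window_s: float = 4.0, collapse: str | int = "mean",
                 prefilter: bool = False) -> dict[str, list[BandWindow]]:
    """Band-pass a recording into each band and segment it into windows."""
    src = broadband_prefilter(rec) if prefilter else rec
    out: dict[str, list[BandWindow]] = {}
    for band in bands:
        filtered = bandpass(src, band)
        out[band.name] = segment(filtered, window_s, band=band, collapse=collapse)
    return out
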