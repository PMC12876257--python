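"""Signal conditioning and windowing for multi-channel EEG.

The conditioning chain is the standard scalp-EEG recipe: a whole-recording
linear detrend (slow drift removal), a 50 Hz notch against power-line
interference, and a 2-48 Hz zero-phase band-pass that excludes residual
drift below and muscular contamination above the band of interest.  All
filters are applied forward-backward so event alignment is preserved.

Analysis then proceeds on contiguous, non-overlapping 500 ms windows;
a trailing partial window is discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Event",
    "Recording",
    "WindowedRecording",
    "PreprocessSettings",
    "preprocess_recording",
    "shift_events",
    "segment_windows",
]

MODALITIES = ("MED", "WORDS", "IMG", "MM", "SENT", "VDO")
GROUPS = ("Meditator", "Non-Meditator")


@dataclass(frozen=True)
class Event:
    """A stimulus/response marker: label plus onset time in milliseconds."""

    label: str
    time_ms: float
    clipped: bool = False


@dataclass
class Recording:
    """One participant x modality multi-channel EEG recording.

    ``signal`` is channels x samples in microvolts; ``channels`` lists the
    1-based channel id of each row.  ``events`` are marker onsets in ms
    relative to recording start.
    """

    signal: np.ndarray
    fs: float = 1000.0
    channels: tuple[int, ...] = ()
    events: tuple[Event, ...] = ()
    participant_id: str = ""
    modality: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if not self.channels:
            self.channels = tuple(range(1, self.signal.shape[0] + 1))
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError("channels length must match signal rows")
        if self.fs <= 2 * 48:
            raise ValueError(f"sampling rate {self.fs} Hz too low for a 48 Hz band edge")
        self.events = tuple(self.events)
        for ev in self.events:
            if not (0 <= ev.time_ms <= self.duration_ms):
                raise ValueError(f"event {ev.label!r} at {ev.time_ms} ms outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0


@dataclass
class WindowedRecording:
    """Fixed-length, non-overlapping segments of a recording.

    ``windows`` has shape (n_channels, n_windows, samples_per_window).
    """

    windows: np.ndarray
    fs: float
    window_ms: float
    channels: tuple[int, ...]
    participant_id: str = ""
    modality: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[1]


@dataclass(frozen=True)
class PreprocessSettings:
    """Filter-chain parameters (defaults are the analysis convention)."""

    band_hz: tuple[float, float] = (2.0, 48.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    order: int = 4

    def validate(self, fs: float) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid band {self.band_hz}")
        if fs <= 2 * hi:
            raise ValueError(f"fs={fs} Hz cannot support a {hi} Hz band edge")
        if fs < 250:
            raise ValueError(f"fs={fs} Hz below the supported minimum of 250 Hz")


def preprocess_recording(
    rec: Recording, settings: PreprocessSettings | None = None
) -> Recording:
    """Detrend, notch-filter and band-pass a recording, channel by channel.

    Order of operations: linear detrend over the whole recording, zero-phase
    notch at ``notch_hz``, zero-phase Butterworth band-pass.  Returns a new
    Recording of identical shape; ``meta['preprocessed']`` records the steps.
    """
    settings = settings or PreprocessSettings()
    settings.validate(rec.fs)
    if not np.all(np.isfinite(rec.signal)):
        raise ValueError("signal contains non-finite samples")

    x = sps.detrend(rec.signal, axis=-1, type="linear")

    b_notch, a_notch = sps.iirnotch(settings.notch_hz, settings.notch_q, fs=rec.fs)
    x = sps.filtfilt(b_notch, a_notch, x, axis=-1)

    sos = sps.butter(
        settings.order, settings.band_hz, btype="bandpass", fs=rec.fs, output="sos"
    )
    x = sps.sosfiltfilt(sos, x, axis=-1)

    meta = dict(rec.meta)
    meta["preprocessed"] = {
        "detrend": "linear",
        "notch_hz": settings.notch_hz,
        "notch_q": settings.notch_q,
        "band_hz": list(settings.band_hz),
        "order": settings.order,
        "zero_phase": True,
    }
    return replace(rec, signal=x, meta=meta)


def shift_events(
    events: Sequence[Event],
    anti_alias_ms: float = 8.0,
    refresh_ms: float = 14.0,
    duration_ms: float | None = None,
) -> tuple[Event, ...]:
    """Advance event timestamps by the hardware timing corrections.

    The amplifier's anti-alias conversion delay (default 8 ms) and the
    display refresh latency (default 14 ms) add up to a 22 ms shift that
    aligns recorded markers with the physical events.  Events shifted past
    the end of the recording are clipped to ``duration_ms`` and flagged.
    """
    if anti_alias_ms < 0 or refresh_ms < 0:
        raise ValueError("timing corrections must be non-negative")
    total = anti_alias_ms + refresh_ms
    out = []
    for ev in events:
        t = ev.time_ms + total
        if duration_ms is not None and t > duration_ms:
            out.append(Event(ev.label, duration_ms, clipped=True))
        else:
            out.append(Event(ev.label, t, clipped=ev.clipped))
    return tuple(out)


def segment_windows(rec: Recording, window_ms: float = 500.0) -> WindowedRecording:
    """Cut the recording into contiguous non-overlapping windows from t = 0.

    The number of windows is ``floor(duration / window_ms)``; any trailing
    partial segment is discarded.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    win_len = int(round(window_ms * rec.fs / 1000.0))
    n_windows = rec.n_samples // win_len
    if n_windows < 1:
        raise ValueError(
            f"recording of {rec.duration_ms:.0f} ms shorter than one "
            f"{window_ms:.0f} ms window"
        )
    used = rec.signal[:, : n_windows * win_len]
    windows = used.reshape(rec.n_channels, n_windows, win_len)
    return WindowedRecording(
        windows=windows,
        fs=rec.fs,
        window_ms=window_ms,
        channels=rec.channels,
        participant_id=rec.participant_id,
        modality=rec.modality,
        group=rec.group,
        meta=dict(rec.meta),
    )
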