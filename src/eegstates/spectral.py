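"""Per-window power spectra and the four state-discrimination indices.

From every 500 ms window of every electrode we estimate a power spectrum on
a 1 Hz grid and restrict it to the 45 bins at 4, 5, ..., 48 Hz.  Normalizing
the spectrum to a probability distribution p_i = PW_i / TP yields:

* ``H``    Shannon spectral entropy, -sum p_i log2 p_i (bits).  High for a
           broadband "engaged" spectrum, low for a concentrated one.
* ``PSk``  Pearson's first skewness coefficient |mean - mode| / SD, with
           mean/SD taken as power-weighted frequency moments (Hz) and the
           mode the maximum-power bin.  Zero for a symmetric unimodal
           spectrum peaked at its center of mass.
* ``TP``   total power, sum of the 45 bin powers.
* ``DF``   dominant frequency: the max-power bin (ties to the lowest
           frequency).  A companion band label marks which classical band
           (Theta/Alpha/Beta/Gamma) carries the most summed power.
* ``DFs``  across electrodes, the sample standard deviation of each
           electrode's mean DF over windows: spatial dispersion of peaks.

The spectral estimator is a Hann-tapered periodogram zero-padded to one
second so that a half-second window lands exactly on the 1 Hz analysis
grid.  It is deliberately the simplest estimator consistent with that grid
and can be swapped behind :func:`window_psd`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import WindowedRecording

__all__ = [
    "FREQ_BINS",
    "N_BINS",
    "MAX_ENTROPY_BITS",
    "BandTable",
    "DEFAULT_BANDS",
    "ZeroPowerError",
    "window_psd",
    "window_psd_batch",
    "spectrum_to_distribution",
    "shannon_entropy",
    "pearson_skewness",
    "dominant_frequency_and_band",
    "band_dominance_time",
    "mean_mode_per_electrode",
    "dfs_index",
    "compute_index_frame",
]

#: Analysis bins: 4, 5, ..., 48 Hz inclusive (45 bins at 1 Hz spacing).
FREQ_BINS = np.arange(4, 49, dtype=float)
N_BINS = FREQ_BINS.size
#: Entropy of the uniform 45-bin distribution, the attainable maximum.
MAX_ENTROPY_BITS = math.log2(N_BINS)


class ZeroPowerError(ValueError):
    """A window carries no power in the analysis band."""


@dataclass(frozen=True)
class BandTable:
    """Named frequency bands partitioning the 4-48 Hz analysis range.

    Edges are half-open ``[low, high)`` except that the top band also
    includes its upper edge, so bin 48 belongs to Gamma.
    """

    bands: tuple[tuple[str, float, float], ...] = (
        ("Theta", 4.0, 8.0),
        ("Alpha", 8.0, 13.0),
        ("L-Beta", 13.0, 20.0),
        ("H-Beta", 20.0, 30.0),
        ("Gamma", 30.0, 48.0),
    )

    def __post_init__(self) -> None:
        lows = [b[1] for b in self.bands]
        highs = [b[2] for b in self.bands]
        if lows[0] != FREQ_BINS[0] or highs[-1] != FREQ_BINS[-1]:
            raise ValueError("bands must span the 4-48 Hz analysis range")
        for (_, _, hi), (_, lo, _) in zip(self.bands[:-1], self.bands[1:]):
            if hi != lo:
                raise ValueError("bands must tile the range without gaps or overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def membership(self, freqs: np.ndarray = FREQ_BINS) -> np.ndarray:
        """Band index of every frequency bin."""
        idx = np.empty(freqs.size, dtype=int)
        for k, (_, lo, hi) in enumerate(self.bands):
            last = k == len(self.bands) - 1
            mask = (freqs >= lo) & ((freqs <= hi) if last else (freqs < hi))
            idx[mask] = k
        return idx


DEFAULT_BANDS = BandTable()


# ---------------------------------------------------------------------------
# spectrum estimation


def window_psd_batch(segments: np.ndarray, fs: float) -> np.ndarray:
    """Periodogram band powers for a stack of equal-length windows.

    ``segments`` may have any leading shape; the last axis is time.  Returns
    powers on the 4-48 Hz 1 Hz grid with matching leading shape.  Windows are
    Hann-tapered and zero-padded to a full second (1 Hz native resolution).
    """
    segments = np.asarray(segments, dtype=float)
    nfft = int(round(fs))  # 1 Hz spacing
    nper = segments.shape[-1]
    if nper > nfft:
        raise ValueError("window longer than 1 s is not supported by the 1 Hz grid")
    # one-sided Hann periodogram (matches scipy.signal.periodogram exactly)
    taper = sps.get_window("hann", nper)
    spec = np.fft.rfft(segments * taper, n=nfft, axis=-1)
    pxx = np.abs(spec) ** 2 / (fs * (taper**2).sum())
    pxx[..., 1:-1] *= 2.0
    freqs = np.arange(pxx.shape[-1], dtype=float) * fs / nfft
    lo = int(np.searchsorted(freqs, FREQ_BINS[0]))
    hi = int(np.searchsorted(freqs, FREQ_BINS[-1]))
    out = pxx[..., lo : hi + 1]
    if out.shape[-1] != N_BINS or freqs[lo] != FREQ_BINS[0]:
        raise ValueError("sampling rate incompatible with the 1 Hz analysis grid")
    return out


def window_psd(segment: np.ndarray, fs: float) -> np.ndarray:
    """Band powers of a single window; errors on an all-zero segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("window_psd expects a single-channel segment")
    powers = window_psd_batch(segment, fs)
    if not np.any(powers > 0):
        raise ZeroPowerError("zero total power in analysis band")
    return powers


# ---------------------------------------------------------------------------
# indices on one spectrum


def spectrum_to_distribution(powers: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize band powers into an empirical probability distribution.

    Returns ``(p, TP)`` with ``p_i = PW_i / TP`` and ``TP = sum PW_i``.
    """
    powers = np.asarray(powers, dtype=float)
    if np.any(powers < 0):
        raise ValueError("negative band power")
    tp = float(powers.sum())
    if tp == 0.0:
        raise ZeroPowerError("zero total power")
    return powers / tp, tp


def shannon_entropy(probs: np.ndarray) -> float:
    """Shannon entropy in bits, with the 0 * log 0 := 0 convention."""
    p = np.asarray(probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def pearson_skewness(probs: np.ndarray, bin_freqs: np.ndarray = FREQ_BINS) -> float:
    """|mean - mode| / SD of the spectral distribution over frequency.

    Mean and SD are probability-weighted frequency moments; the mode is the
    frequency of the maximum-probability bin (ties to the lowest frequency).
    A degenerate single-bin distribution has SD 0 and returns 0 by
    convention (its mean necessarily equals its mode).
    """
    p = np.asarray(probs, dtype=float)
    f = np.asarray(bin_freqs, dtype=float)
    mean = float((f * p).sum())
    sd = float(np.sqrt((p * (f - mean) ** 2).sum()))
    if sd == 0.0:
        return 0.0
    mode = float(f[int(np.argmax(p))])
    return abs(mean - mode) / sd


def dominant_frequency_and_band(
    powers: np.ndarray,
    bands: BandTable = DEFAULT_BANDS,
    bin_freqs: np.ndarray = FREQ_BINS,
) -> tuple[float, str]:
    """Dominant frequency (max-power bin) and dominant band (max summed power).

    Ties break toward the lowest frequency / lowest band.
    """
    powers = np.asarray(powers, dtype=float)
    df = float(bin_freqs[int(np.argmax(powers))])
    member = bands.membership(np.asarray(bin_freqs, dtype=float))
    sums = np.bincount(member, weights=powers, minlength=len(bands.bands))
    band = bands.names[int(np.argmax(sums))]
    return df, band


def band_dominance_time(
    band_labels: Sequence[str],
    window_ms: float = 500.0,
    bands: BandTable = DEFAULT_BANDS,
) -> dict[str, float]:
    """Total seconds each band spent as the dominant band."""
    labels = list(band_labels)
    if not labels:
        raise ValueError("no dominant-band frames supplied")
    secs = window_ms / 1000.0
    out = {name: 0.0 for name in bands.names}
    for lab in labels:
        if lab not in out:
            raise ValueError(f"unknown band label {lab!r}")
        out[lab] += secs
    return out


def mean_mode_per_electrode(modes: Sequence[float]) -> float:
    """Mean of an electrode's per-window dominant frequencies (Hz)."""
    arr = np.asarray(list(modes), dtype=float)
    if arr.size == 0:
        raise ValueError("no windows")
    return float(arr.mean())


def dfs_index(mean_modes: Sequence[float]) -> float:
    """Spatial dispersion of spectral peaks: sample SD (n-1 divisor) across
    electrodes of the per-electrode mean dominant frequency."""
    arr = np.asarray(list(mean_modes), dtype=float)
    if arr.size < 2:
        raise ValueError("DFs needs at least 2 electrodes")
    return float(arr.std(ddof=1))


# ---------------------------------------------------------------------------
# full frame


def compute_index_frame(
    wrec: WindowedRecording, bands: BandTable = DEFAULT_BANDS
) -> tuple[pd.DataFrame, float, int]:
    """All four indices for every (electrode, window) of a windowed recording.

    Returns ``(frame, DFs, n_flagged)`` where ``frame`` has one row per valid
    (electrode, window) with columns electrode, window, H, PSk, TP, DF, band,
    and ``DFs`` is the recording-level spatial dispersion of dominant
    frequencies.  Zero-power windows are flagged and excluded; more than 50%
    flagged windows aborts with an error.
    """
    powers = window_psd_batch(wrec.windows, wrec.fs)  # (n_ch, n_win, 45)
    n_ch, n_win, _ = powers.shape
    tp = powers.sum(axis=-1)
    valid = tp > 0
    n_flagged = int((~valid).sum())
    if n_flagged > 0.5 * valid.size:
        raise ValueError(
            f"degenerate recording: {n_flagged}/{valid.size} zero-power windows"
        )

    safe_tp = np.where(valid, tp, 1.0)
    p = powers / safe_tp[..., None]

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -(p * logp).sum(axis=-1)

    f = FREQ_BINS
    mean = (p * f).sum(axis=-1)
    sd = np.sqrt((p * (f - mean[..., None]) ** 2).sum(axis=-1))
    mode_idx = powers.argmax(axis=-1)
    mode = f[mode_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        psk = np.where(sd > 0, np.abs(mean - mode) / np.where(sd > 0, sd, 1.0), 0.0)

    member = bands.membership(f)
    band_power = np.stack(
        [powers[..., member == k].sum(axis=-1) for k in range(len(bands.bands))],
        axis=-1,
    )
    band_idx = band_power.argmax(axis=-1)
    band_names = np.asarray(bands.names)

    ch_ids = np.repeat(np.asarray(wrec.channels), n_win)
    win_ids = np.tile(np.arange(n_win), n_ch)
    flat_valid = valid.ravel()
    frame = pd.DataFrame(
        {
            "electrode": ch_ids[flat_valid],
            "window": win_ids[flat_valid],
            "H": h.ravel()[flat_valid],
            "PSk": psk.ravel()[flat_valid],
            "TP": tp.ravel()[flat_valid],
            "DF": mode.ravel()[flat_valid],
            "band": band_names[band_idx.ravel()[flat_valid]],
        }
    )

    # per-electrode mean DF over valid windows, then spatial SD
    mean_modes = []
    for c in range(n_ch):
        v = valid[c]
        if v.any():
            mean_modes.append(mode[c, v].mean())
    dfs = dfs_index(mean_modes) if len(mean_modes) >= 2 else float("nan")
    return frame, dfs, n_flagged
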