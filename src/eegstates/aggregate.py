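"""Hierarchical averaging of index frames and spatial landscape matrices.

Index values are averaged level by level — windows within an electrode,
electrodes within a participant, participants within a group — mirroring
how per-window values are chained into group summaries.  Because levels are
averaged in turn (not pooled), unbalanced window counts never let one
electrode dominate a participant mean.

Group summaries carry a two-sided t-based confidence interval,
``mean ± t_{1-α/2, n-1} · SD / sqrt(n)``.

For cross-modality comparison indices are normalized to [0, 1]: entropy by
its attainable maximum log2(45), the remaining indices by the maximum over
the compared collection (so the largest value maps to 1).  The method used
is recorded with the output so normalized values can be inverted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .layout import SensorLayout, map_to_grid
from .spectral import MAX_ENTROPY_BITS

__all__ = [
    "INDEX_COLUMNS",
    "GroupSummary",
    "Normalization",
    "hierarchical_means",
    "group_summary",
    "normalize_index",
    "landscape_matrix",
]

INDEX_COLUMNS = ("H", "PSk", "TP", "DF")


def hierarchical_means(
    frames: pd.DataFrame, index_cols: Sequence[str] = INDEX_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window -> electrode -> participant means of each index column.

    ``frames`` needs columns participant, modality, group, electrode plus the
    index columns (flagged windows are assumed already absent).  Returns
    ``(electrode_summary, participant_summary)``; the participant summary
    averages the per-electrode means, one value per electrode.
    """
    if frames.empty:
        raise ValueError("empty index frame table")
    index_cols = [c for c in index_cols if c in frames.columns]
    keys = ["participant", "modality", "group"]
    electrode = (
        frames.groupby(keys + ["electrode"], observed=True, sort=True)[index_cols]
        .mean()
        .reset_index()
    )
    participant = (
        electrode.groupby(keys, observed=True, sort=True)[index_cols]
        .mean()
        .reset_index()
    )
    return electrode, participant


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and t-based CI half-width of per-participant values."""

    mean: float
    sd: float
    n: int
    alpha: float
    ci_half_width: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.mean - self.ci_half_width, self.mean + self.ci_half_width)


def group_summary(values: Sequence[float], alpha: float = 0.05) -> GroupSummary:
    """Summarize one group x modality x index across participants.

    The CI half-width is ``t_{1-α/2, n-1} · SD / sqrt(n)`` with the sample
    (n-1) standard deviation; requires at least two participants.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("group summary needs at least 2 participants")
    sd = float(arr.std(ddof=1))
    tq = float(sstats.t.ppf(1 - alpha / 2, df=n - 1))
    return GroupSummary(
        mean=float(arr.mean()),
        sd=sd,
        n=n,
        alpha=alpha,
        ci_half_width=tq * sd / np.sqrt(n),
    )


@dataclass(frozen=True)
class Normalization:
    """Record of how a collection of values was scaled to [0, 1]."""

    method: str  # "entropy-ratio" or "max"
    factor: float

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        return np.asarray(normalized, dtype=float) * self.factor


def normalize_index(
    values: Sequence[float], kind: str, method: str | None = None
) -> tuple[np.ndarray, Normalization]:
    """Scale index values into [0, 1] for cross-modality comparison.

    Entropy uses the fixed ratio to its maximum ``log2(45)``; the other
    indices are scaled by the maximum of the supplied collection.  Pass
    ``method`` explicitly to override the per-kind default.
    """
    arr = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values cannot be normalized")
    if method is None:
        method = "entropy-ratio" if kind == "H" else "max"
    if method == "entropy-ratio":
        factor = MAX_ENTROPY_BITS
    elif method == "max":
        factor = float(arr.max())
        if factor <= 0:
            raise ValueError("max-scaling needs a positive maximum")
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return arr / factor, Normalization(method=method, factor=factor)


def landscape_matrix(
    electrode_means: Mapping[int, float] | pd.DataFrame,
    layout: SensorLayout,
    index: str | None = None,
) -> np.ndarray:
    """12 x 12 scalp map of per-electrode index means.

    Accepts either a channel -> value mapping or an electrode-summary frame
    (then ``index`` selects the column).  Empty reference cells stay NaN.
    """
    if isinstance(electrode_means, pd.DataFrame):
        if index is None:
            raise ValueError("index column required with a summary frame")
        values = dict(
            zip(electrode_means["electrode"].astype(int), electrode_means[index])
        )
    else:
        values = dict(electrode_means)
    return map_to_grid(values, layout)
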