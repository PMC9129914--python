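"""Robust per-position outlier statistics over windows of RT-stop counts.

Two metrics quantify how strongly a position's cDNA-end count stands out
from its local background:

* modified Z-score — the count at the test position against the mean and
  population standard deviation of a centered window, with the test position
  itself excluded from mean and deviation.  Suited to mRNA, where a window
  rarely holds more than one strong stop.
* MAD score — the count against the window median, scaled by the median
  absolute deviation about that median (center included).  Robust to the
  multiple strong stops typical of heavily modified, structured ncRNA, but
  needs ends mapped to more than half the window for a non-zero denominator.

Both are computed over a window of ``window_size`` positions centered on the
test position (default 101, i.e. center ± 50); windows are truncated, never
padded, at transcript ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tracks import EndCountTrack

__all__ = [
    "WindowStats",
    "ScoreRecord",
    "window_counts",
    "window_stats",
    "modified_z",
    "mad_score",
    "score_track",
    "score_library",
]

DEFAULT_WINDOW = 101
DEFAULT_COVERAGE_MIN = 50


@dataclass(frozen=True)
class WindowStats:
    position: int
    window_sum: int
    mean_excl: float
    stdev_excl: float
    median_w: float
    mad_w: float
    window_len: int


@dataclass(frozen=True)
class ScoreRecord:
    position: int
    zscore: float | None
    madscore: float | None
    window_sum: int
    window_len: int
    pass_coverage: bool
    pass_median: bool


def _as_counts(track) -> np.ndarray:
    if isinstance(track, EndCountTrack):
        return np.asarray(track.counts, dtype=np.float64)
    return np.asarray(track, dtype=np.float64)


def window_counts(track, position: int, window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Counts in the window centered on ``position``; truncated at ends."""
    counts = _as_counts(track)
    L = counts.shape[0]
    if window_size % 2 != 1:
        raise ValueError(f"window_size must be odd, got {window_size}")
    if not 0 <= position < L:
        raise IndexError(f"position {position} outside [0, {L})")
    h = (window_size - 1) // 2
    return counts[max(0, position - h): min(L, position + h + 1)]


def window_stats(track, position: int, window_size: int = DEFAULT_WINDOW) -> WindowStats:
    counts = _as_counts(track)
    win = window_counts(counts, position, window_size)
    h = (window_size - 1) // 2
    center = counts[position]
    flank = np.delete(win, position - max(0, position - h))
    mean_excl = float(flank.mean()) if flank.size else float("nan")
    stdev_excl = float(np.sqrt(((flank - mean_excl) ** 2).mean())) if flank.size else float("nan")
    median_w = float(np.median(win))
    mad_w = float(np.median(np.abs(win - median_w)))
    return WindowStats(position, int(win.sum()), mean_excl, stdev_excl,
                       median_w, mad_w, int(win.size))


def modified_z(track, position: int, window_size: int = DEFAULT_WINDOW,
               *, exclude_center: bool = True) -> float | None:
    """Modified Z-score; None when the window has zero spread (unscorable).

    The test position is excluded from the mean and (population) standard
    deviation by default; the toggle is exposed for comparison."""
    counts = _as_counts(track)
    win = window_counts(counts, position, window_size)
    if win.size < 3:
        raise ValueError("window must hold at least 2 non-center positions")
    h = (window_size - 1) // 2
    ref = np.delete(win, position - max(0, position - h)) if exclude_center else win
    mean = float(ref.mean())
    stdev = float(np.sqrt(((ref - mean) ** 2).mean()))
    if stdev == 0:
        return None
    return (float(counts[position]) - mean) / stdev


def mad_score(track, position: int, window_size: int = DEFAULT_WINDOW,
              *, exclude_center: bool = False) -> tuple[float | None, bool]:
    """(MAD score, pass_median).  Score is None when the window MAD is zero;
    pass_median records the window-median-above-zero requirement applied to
    ncRNA calling.  The window median and MAD include the test position by
    default (the toggle mirrors the Z-score's center exclusion)."""
    counts = _as_counts(track)
    win = window_counts(counts, position, window_size)
    h = (window_size - 1) // 2
    ref = np.delete(win, position - max(0, position - h)) if exclude_center else win
    median_w = float(np.median(ref))
    mad_w = float(np.median(np.abs(ref - median_w)))
    pass_median = median_w > 0
    if mad_w == 0:
        return None, pass_median
    return (float(counts[position]) - median_w) / mad_w, pass_median


def _score_full_windows(counts: np.ndarray, w: int) -> pd.DataFrame:
    """Vectorized scores for all positions whose window is untruncated."""
    from numpy.lib.stride_tricks import sliding_window_view

    L = counts.shape[0]
    h = (w - 1) // 2
    win = sliding_window_view(counts, w)          # (L-w+1, w)
    center = counts[h:L - h]
    wsum = win.sum(axis=1)
    # integer counts in float64: sums are exact
    mean_excl = (wsum - center) / (w - 1)
    ssq = (win ** 2).sum(axis=1)
    var_excl = (ssq - center ** 2) / (w - 1) - mean_excl ** 2
    var_excl = np.maximum(var_excl, 0.0)
    std_excl = np.sqrt(var_excl)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std_excl > 0, (center - mean_excl) / std_excl, np.nan)
    med = np.median(win, axis=1)
    mad = np.median(np.abs(win - med[:, None]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(mad > 0, (center - med) / mad, np.nan)
    return pd.DataFrame({
        "position": np.arange(h, L - h),
        "zscore": z,
        "madscore": m,
        "window_sum": wsum.astype(np.int64),
        "window_len": np.full(L - w + 1, w),
        "pass_median": med > 0,
    })


def score_track(track, *, window_size: int = DEFAULT_WINDOW,
                coverage_min: int = DEFAULT_COVERAGE_MIN) -> pd.DataFrame:
    """Score every position of one track.

    Returns a DataFrame with one row per transcript position: both metrics
    (NaN where the denominator vanishes), window_sum, actual window length,
    pass_coverage (window_sum >= coverage_min, boundary inclusive) and
    pass_median (window median > 0).
    """
    counts = _as_counts(track)
    L = counts.shape[0]
    h = (window_size - 1) // 2
    if L >= window_size:
        df = _score_full_windows(counts, window_size)
        edge_positions = list(range(0, h)) + list(range(L - h, L))
    else:
        df = None
        edge_positions = list(range(L))
    rows = []
    for p in edge_positions:
        ws = window_stats(counts, p, window_size)
        z = np.nan if (ws.window_len < 3 or ws.stdev_excl == 0) \
            else (counts[p] - ws.mean_excl) / ws.stdev_excl
        m = np.nan if ws.mad_w == 0 else (counts[p] - ws.median_w) / ws.mad_w
        rows.append((p, z, m, ws.window_sum, ws.window_len, ws.median_w > 0))
    edge = pd.DataFrame(rows, columns=["position", "zscore", "madscore",
                                       "window_sum", "window_len", "pass_median"])
    df = edge if df is None else pd.concat([df, edge], ignore_index=True)
    df = df.sort_values("position", ignore_index=True)
    df["pass_coverage"] = df["window_sum"] >= coverage_min
    return df


def score_library(tracks_by_library: Mapping[str, Mapping[str, EndCountTrack]], *,
                  window_size: int = DEFAULT_WINDOW,
                  coverage_min: int = DEFAULT_COVERAGE_MIN,
                  ) -> dict[str, dict[str, pd.DataFrame]]:
    """Score every position of every transcript in every library.

    Input maps library_id -> {transcript_id: track}; output mirrors the
    nesting with a score DataFrame per transcript.  These tables are the
    sole input to site calling.
    """
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for lib, tracks in tracks_by_library.items():
        out[lib] = {tid: score_track(t, window_size=window_size,
                                     coverage_min=coverage_min)
                    for tid, t in tracks.items()}
    return out


def scores_to_table(scores: Mapping[str, Mapping[str, pd.DataFrame]],
                    strands: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Flatten nested score tables to one long DataFrame for TSV output."""
    frames = []
    for lib, per_tid in scores.items():
        for tid, df in per_tid.items():
            d = df.copy()
            d.insert(0, "library_id", lib)
            d.insert(1, "transcript_id", tid)
            d.insert(2, "strand", (strands or {}).get(tid, "+"))
            frames.append(d)
    return pd.concat(frames, ignore_index=True)
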