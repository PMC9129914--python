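"""DMS-reactivity meta-profiles around called D sites.

Dimethyl sulfate methylates the Watson–Crick face of unpaired A and C;
mutational-profiling sequencing reads this out as a per-base mutation rate
(mutations / coverage), high at flexible, unpaired bases and low at paired
ones.  To ask whether D sites sit in flexible regions, reactivities are
pooled at each offset in a 25-nt window centered on the D coordinate, the
per-offset median is compared to size-matched random draws from the
background of interrogated-but-uncalled positions (for visualization), and
per-offset two-sided Mann–Whitney U tests against the *full* background set
provide significance.

Filters follow the meta-analysis convention: a position contributes only
when its coverage exceeds ``min_coverage`` (strictly, default 350) and its
base is A or C.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaProfile",
    "load_reactivity_table",
    "filter_reactivities",
    "meta_profile",
    "sample_background",
    "positionwise_test",
    "mann_whitney_u",
    "run_meta_analysis",
    "plot_meta_profile",
]

DEFAULT_MIN_COVERAGE = 350
DEFAULT_BASES = ("A", "C")
DEFAULT_HALF_WINDOW = 12
DEFAULT_N_DRAWS = 70
EXACT_MAX_N = 8


@dataclass
class MetaProfile:
    offsets: np.ndarray            # -half_window .. +half_window
    d_median: np.ndarray           # per-offset median over pooled site flanks
    n_per_offset: np.ndarray       # pool sizes
    bg_medians: np.ndarray | None = None   # (n_draws, n_offsets)
    pvalues: np.ndarray | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets, "d_median": self.d_median,
                           "n": self.n_per_offset})
        if self.bg_medians is not None:
            df["bg_median_q25"] = np.nanquantile(self.bg_medians, 0.25, axis=0)
            df["bg_median_q50"] = np.nanquantile(self.bg_medians, 0.50, axis=0)
            df["bg_median_q75"] = np.nanquantile(self.bg_medians, 0.75, axis=0)
        if self.pvalues is not None:
            df["pvalue"] = self.pvalues
        return df


# ---------------------------------------------------------------------------
# table handling
# ---------------------------------------------------------------------------

def load_reactivity_table(path) -> pd.DataFrame:
    """Read a tab-delimited table (transcript, position, base, mutations,
    coverage); adds the reactivity column and validates mutations <= coverage."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"transcript": str, "position": np.int64,
                            "base": str, "mutations": np.int64,
                            "coverage": np.int64})
    required = {"transcript", "position", "base", "mutations", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reactivity table missing columns {sorted(missing)}")
    return _prepare(df)


def _prepare(df: pd.DataFrame) -> pd.DataFrame:
    if (df["mutations"] < 0).any() or (df["coverage"] < 0).any():
        raise ValueError("mutations and coverage must be non-negative")
    if (df["mutations"] > df["coverage"]).any():
        raise ValueError("mutations must not exceed coverage")
    df = df.copy()
    df["base"] = df["base"].str.upper().str.replace("T", "U")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["reactivity"] = np.where(df["coverage"] > 0,
                                    df["mutations"] / df["coverage"], np.nan)
    return df


def filter_reactivities(table: pd.DataFrame,
                        min_coverage: int = DEFAULT_MIN_COVERAGE,
                        allowed_bases: Sequence[str] = DEFAULT_BASES,
                        ) -> pd.DataFrame:
    """Keep positions with coverage strictly greater than ``min_coverage``
    and base in ``allowed_bases`` (DMS reports only A and C)."""
    if "reactivity" not in table.columns:
        table = _prepare(table)
    bases = {b.upper().replace("T", "U") for b in allowed_bases}
    keep = (table["coverage"] > min_coverage) & table["base"].isin(bases)
    return table.loc[keep].reset_index(drop=True)


def _lookup(table: pd.DataFrame) -> dict[tuple[str, int], float]:
    return {(t, int(p)): float(r) for t, p, r in
            zip(table["transcript"], table["position"], table["reactivity"])}


def _pool(sites: Iterable[tuple[str, int]], lut: Mapping[tuple[str, int], float],
          half_window: int) -> list[list[float]]:
    """Per-offset pooled reactivities over all sites (offset index 0 is
    -half_window)."""
    pools: list[list[float]] = [[] for _ in range(2 * half_window + 1)]
    for tid, pos in sites:
        for i, o in enumerate(range(-half_window, half_window + 1)):
            v = lut.get((tid, pos + o))
            if v is not None and np.isfinite(v):
                pools[i].append(v)
    return pools


# ---------------------------------------------------------------------------
# meta-profile and background
# ---------------------------------------------------------------------------

def meta_profile(sites: Sequence[tuple[str, int]], table: pd.DataFrame,
                 half_window: int = DEFAULT_HALF_WINDOW) -> MetaProfile:
    """Median reactivity at each offset in [-half_window, half_window]
    relative to the D coordinate, pooled over sites.  Offsets with an empty
    pool are NaN (plotted as gaps, never interpolated)."""
    lut = _lookup(table)
    pools = _pool(sites, lut, half_window)
    if not any(pools):
        raise ValueError("no site contributes a filtered reactivity at any offset")
    med = np.array([np.median(p) if p else np.nan for p in pools])
    n = np.array([len(p) for p in pools])
    return MetaProfile(offsets=np.arange(-half_window, half_window + 1),
                       d_median=med, n_per_offset=n)


def sample_background(background_sites: Sequence[tuple[str, int]],
                      table: pd.DataFrame, *, n_draws: int = DEFAULT_N_DRAWS,
                      draw_size: int, seed: int,
                      half_window: int = DEFAULT_HALF_WINDOW) -> np.ndarray:
    """Median-reactivity vectors for ``n_draws`` random draws of
    ``draw_size`` background positions.

    Each draw samples without replacement (draws are independent of one
    another); the background population should be the interrogated positions
    that fell below both score cutoffs in treated and control.  Returns an
    (n_draws, 2*half_window+1) array of medians.
    """
    background_sites = list(background_sites)
    if len(background_sites) < draw_size:
        raise ValueError(f"background population ({len(background_sites)}) "
                         f"smaller than draw size ({draw_size})")
    rng = np.random.default_rng(seed)
    lut = _lookup(table)
    out = np.full((n_draws, 2 * half_window + 1), np.nan)
    for d in range(n_draws):
        idx = rng.choice(len(background_sites), size=draw_size, replace=False)
        pools = _pool([background_sites[i] for i in idx], lut, half_window)
        out[d] = [np.median(p) if p else np.nan for p in pools]
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_stat(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x via pairwise comparisons (ties count one half)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration over all group assignments (tie-aware) when both
    samples have at most 8 observations; otherwise the normal approximation
    with tie correction.  Returns (U of the first sample, p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_stat(x, y)
    n1, n2 = x.size, y.size
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        all_idx = frozenset(range(n1 + n2))
        for idx in combinations(range(n1 + n2), n1):
            xs = pooled[list(idx)]
            ys = pooled[list(all_idx - set(idx))]
            total += 1
            if abs(_u_stat(xs, ys) - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def positionwise_test(sites: Sequence[tuple[str, int]],
                      background_sites: Sequence[tuple[str, int]],
                      table: pd.DataFrame,
                      half_window: int = DEFAULT_HALF_WINDOW) -> np.ndarray:
    """Per-offset two-sided Mann–Whitney p-values, D-flank pool vs the pool
    around the *full* background set (not the visualization draws).  NaN
    where either pool is empty."""
    lut = _lookup(table)
    site_pools = _pool(sites, lut, half_window)
    bg_pools = _pool(background_sites, lut, half_window)
    out = np.full(2 * half_window + 1, np.nan)
    for i, (sp, bp) in enumerate(zip(site_pools, bg_pools)):
        if sp and bp:
            out[i] = mann_whitney_u(np.array(sp), np.array(bp))[1]
    return out


def run_meta_analysis(sites: Sequence[tuple[str, int]],
                      background_sites: Sequence[tuple[str, int]],
                      table: pd.DataFrame, *, seed: int,
                      min_coverage: int = DEFAULT_MIN_COVERAGE,
                      allowed_bases: Sequence[str] = DEFAULT_BASES,
                      n_draws: int = DEFAULT_N_DRAWS,
                      half_window: int = DEFAULT_HALF_WINDOW) -> MetaProfile:
    """Filter, profile, resample and test in one pass."""
    filtered = filter_reactivities(table, min_coverage, allowed_bases)
    prof = meta_profile(sites, filtered, half_window)
    prof.bg_medians = sample_background(background_sites, filtered,
                                        n_draws=n_draws, draw_size=len(sites),
                                        seed=seed, half_window=half_window)
    prof.pvalues = positionwise_test(sites, background_sites, filtered, half_window)
    prof.seed = seed
    return prof


def plot_meta_profile(profile: MetaProfile, path) -> None:
    """Diagnostic plot: D-flank median trace, background draw medians and
    per-offset p-values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if profile.bg_medians is not None:
        for row in profile.bg_medians:
            ax.plot(profile.offsets, row, ".", color="0.6", ms=2, alpha=0.5)
    ax.plot(profile.offsets, profile.d_median, "r-", lw=2, label="D-flank median")
    ax.set_xlabel("offset from D (nt)")
    ax.set_ylabel("median DMS reactivity")
    if profile.pvalues is not None:
        ax2 = ax.twinx()
        ax2.plot(profile.offsets, profile.pvalues, "b-", lw=1, label="p-value")
        ax2.set_yscale("log")
        ax2.set_ylabel("Mann-Whitney p")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
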