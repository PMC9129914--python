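"""Replicate-consensus dihydrouridine site calling.

A transcript position is called a D site when, in every library, the window
coverage filter passes and the score is defined, every treated (WT)
replicate scores strictly above ``treated_min``, and every knockout-control
replicate scores strictly below ``control_max``.  The RT stop piles up one
nucleotide 3' of the modified base, so the inferred D coordinate is the peak
position minus one.

Published class defaults (tRNA MAD 40/40, snRNA MAD 12/8, mRNA Z 10/7,
window coverage 50) ship in the package's versioned defaults file; the
empirical cutoff machinery (inverse-CDF survival curves, divergence-point
suggestion) is advisory and never overrides them unless asked.

The false-discovery rate of a call set is estimated by inverting the
analysis — demanding high scores in the knockout controls and low scores in
the treated replicates — and counting the "sites" that survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import NONCODING, TranscriptModel

__all__ = [
    "CutoffConfig",
    "DSiteCall",
    "FdrEstimate",
    "class_cutoffs",
    "score_survival_curves",
    "suggest_cutoffs",
    "call_sites",
    "assign_d_position",
    "annotate_shadows",
    "estimate_fdr",
    "annotate_features",
    "interrogated_positions",
    "calls_to_bed",
    "calls_to_table",
]

DEFAULT_SHADOW_RANGE = 80  # nt; upper bound of the 70-80 nt RNA size selection


@dataclass(frozen=True)
class CutoffConfig:
    """Score thresholds for one RNA class.

    Every treated replicate must score > treated_min and every control
    replicate < control_max (strict inequalities)."""

    metric: str  # "z" or "mad"
    treated_min: float
    control_max: float
    coverage_min: int = 50
    rna_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.metric not in ("z", "mad"):
            raise ValueError(f"metric must be 'z' or 'mad', got {self.metric!r}")
        if self.treated_min < self.control_max:
            raise ValueError("treated_min must be >= control_max")


def class_cutoffs(rna_class: str) -> CutoffConfig:
    """Published per-class default cutoffs from the shipped defaults file."""
    from .config import load_defaults

    d = load_defaults()["cutoffs"]
    key = rna_class.lower().replace("-", "")
    if key not in d:
        raise KeyError(f"no default cutoffs for RNA class {rna_class!r}")
    c = d[key]
    return CutoffConfig(metric=c["metric"], treated_min=float(c["treated_min"]),
                        control_max=float(c["control_max"]),
                        coverage_min=int(c.get("coverage_min", 50)),
                        rna_class=rna_class)


@dataclass
class DSiteCall:
    transcript_id: str
    peak_position: int
    d_position: int | None = None
    chrom: str | None = None
    strand: str | None = None
    genomic_d: int | None = None
    genomic_peak: int | None = None
    treated_scores: dict[str, float] = field(default_factory=dict)
    control_scores: dict[str, float] = field(default_factory=dict)
    feature: str | None = None
    shadow_flag: bool = False
    shadow_source: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def min_treated_score(self) -> float:
        return min(self.treated_scores.values())

    @property
    def max_control_score(self) -> float:
        return max(self.control_scores.values())


@dataclass(frozen=True)
class FdrEstimate:
    n_forward: int
    n_inverted: int

    @property
    def fdr(self) -> float | None:
        if self.n_forward == 0:
            return None
        return self.n_inverted / self.n_forward

    @property
    def percent(self) -> float | None:
        return None if self.fdr is None else 100.0 * self.fdr

    def __str__(self) -> str:
        if self.fdr is None:
            return (f"FDR not applicable (0 forward calls, "
                    f"{self.n_inverted} inverted)")
        return (f"FDR {self.percent:.1f}% ({self.n_inverted} inverted / "
                f"{self.n_forward} forward calls)")


# ---------------------------------------------------------------------------
# empirical cutoff derivation
# ---------------------------------------------------------------------------

def _pool_scores(per_tid, metric: str) -> np.ndarray:
    if not isinstance(per_tid, Mapping):  # a bare array of scores
        pooled = np.asarray(per_tid, dtype=float)
    else:
        col = "zscore" if metric == "z" else "madscore"
        vals = [df.loc[df["pass_coverage"], col].to_numpy() for df in per_tid.values()]
        pooled = np.concatenate(vals) if vals else np.array([])
    return pooled[np.isfinite(pooled)]


def score_survival_curves(scores: Mapping[str, Mapping[str, pd.DataFrame]],
                          metric: str = "z",
                          grid: np.ndarray | None = None) -> pd.DataFrame:
    """Inverse CDF of scorable position scores per library.

    Returns a DataFrame indexed by the shared score grid with one column per
    library holding the fraction of scorable positions with score >= s
    (monotone non-increasing).  The default grid is the sorted union of the
    observed scores.
    """
    pooled = {lib: _pool_scores(per_tid, metric) for lib, per_tid in scores.items()}
    for lib, v in pooled.items():
        if v.size == 0:
            raise ValueError(f"library {lib!r} has no scorable positions")
    if grid is None:
        grid = np.unique(np.concatenate(list(pooled.values())))
    grid = np.asarray(grid, dtype=float)
    out = {}
    for lib, v in pooled.items():
        v = np.sort(v)
        # fraction with score >= s
        out[lib] = 1.0 - np.searchsorted(v, grid, side="left") / v.size
    return pd.DataFrame(out, index=pd.Index(grid, name="score"))


def suggest_cutoffs(treated_curves: pd.DataFrame, control_curves: pd.DataFrame,
                    divergence_fraction: float = 0.1, *,
                    metric: str = "z", coverage_min: int = 50,
                    rna_class: str = "mRNA") -> CutoffConfig | None:
    """Suggest a treated_min as the smallest grid score where the mean
    control survival fraction drops to ``divergence_fraction`` times the
    mean treated fraction.

    Advisory only: the published class defaults always apply unless the user
    opts into the suggestion.  Returns None (with a warning) when the curves
    never diverge at the requested fraction.
    """
    if not treated_curves.index.equals(control_curves.index):
        raise ValueError("curves must share a score grid")
    mt = treated_curves.mean(axis=1).to_numpy()
    mc = control_curves.mean(axis=1).to_numpy()
    grid = treated_curves.index.to_numpy()
    ok = (mt > 0) & (mc <= divergence_fraction * mt)
    if not ok.any():
        warnings.warn("treated and control score distributions never diverge "
                      f"at fraction {divergence_fraction}; no cutoff suggested")
        return None
    s_star = float(grid[ok][0])
    return CutoffConfig(metric=metric, treated_min=s_star, control_max=s_star,
                        coverage_min=coverage_min, rna_class=rna_class)


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def _stack_library_tables(scores: Mapping[str, Mapping[str, pd.DataFrame]],
                          tid: str, metric: str,
                          ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    col = "zscore" if metric == "z" else "madscore"
    libs = sorted(scores)
    mats, covs, meds = [], [], []
    for lib in libs:
        df = scores[lib][tid]
        mats.append(df[col].to_numpy())
        covs.append(df["pass_coverage"].to_numpy())
        meds.append(df["pass_median"].to_numpy())
    return libs, np.vstack(mats), np.vstack(covs), np.vstack(meds)


def call_sites(scores: Mapping[str, Mapping[str, pd.DataFrame]],
               conditions: Mapping[str, str],
               cutoffs: CutoffConfig,
               *, control_rule: str = "each") -> list[DSiteCall]:
    """Apply the replicate-consensus rule to per-library score tables.

    ``scores`` maps library_id -> {transcript_id: score DataFrame} (from
    :func:`dseq.scoring.score_library`); ``conditions`` maps library_id ->
    'treated'/'control'.  A position is called iff, at that position,

    1. the coverage filter passes in every library (and the window-median
       filter too, for the MAD metric),
    2. the score is defined in every library,
    3. every treated replicate scores > treated_min,
    4. every control replicate scores < control_max (``control_rule='mean'``
       relaxes this to the mean of the control replicates).
    """
    if control_rule not in ("each", "mean"):
        raise ValueError(f"control_rule must be 'each' or 'mean', got {control_rule!r}")
    libs = sorted(scores)
    if set(conditions) != set(libs):
        raise ValueError("conditions must cover exactly the scored libraries")
    treated = [l for l in libs if conditions[l] == "treated"]
    control = [l for l in libs if conditions[l] == "control"]
    if not treated or not control:
        raise ValueError("need at least one treated and one control library")
    tids = set(scores[libs[0]])
    for lib in libs:
        if set(scores[lib]) != tids:
            raise ValueError("libraries must cover the same transcript set")

    calls: list[DSiteCall] = []
    for tid in sorted(tids):
        all_libs, mat, cov, med = _stack_library_tables(scores, tid, cutoffs.metric)
        idx = {l: i for i, l in enumerate(all_libs)}
        t_rows = [idx[l] for l in treated]
        c_rows = [idx[l] for l in control]
        defined = np.isfinite(mat).all(axis=0)
        passing = cov.all(axis=0)
        if cutoffs.metric == "mad":
            passing &= med.all(axis=0)
        hi = (mat[t_rows] > cutoffs.treated_min).all(axis=0)
        if control_rule == "each":
            lo = (mat[c_rows] < cutoffs.control_max).all(axis=0)
        else:
            lo = mat[c_rows].mean(axis=0) < cutoffs.control_max
        hit = defined & passing & hi & lo
        for p in np.flatnonzero(hit):
            calls.append(DSiteCall(
                transcript_id=tid, peak_position=int(p),
                treated_scores={l: float(mat[idx[l], p]) for l in treated},
                control_scores={l: float(mat[idx[l], p]) for l in control},
            ))
    return calls


def assign_d_position(call: DSiteCall,
                      model: TranscriptModel | None = None) -> DSiteCall:
    """Infer the modified base: the RT stops one nucleotide 3' of the D, so
    the D coordinate is the peak minus one (transcript 5'->3').  With a
    transcript model, genomic coordinates are filled in through the exon
    projection (on the minus strand the genomic D coordinate is the genomic
    peak coordinate + 1)."""
    if call.peak_position < 1:
        call.d_position = None
        if "no_d_position" not in call.flags:
            call.flags.append("no_d_position")
        return call
    call.d_position = call.peak_position - 1
    if model is not None:
        call.chrom = model.chrom
        call.strand = model.strand
        call.genomic_peak = model.transcript_to_genomic(call.peak_position)
        call.genomic_d = model.transcript_to_genomic(call.d_position)
    return call


def annotate_shadows(calls: Sequence[DSiteCall],
                     candidates: Iterable[tuple[str, int]] = (),
                     shadow_range: int = DEFAULT_SHADOW_RANGE,
                     ) -> tuple[list[DSiteCall], list[tuple[str, int, int]]]:
    """Flag shadowing relationships.

    A strong RT stop consumes the cDNAs that would otherwise have reported a
    site on its 5' side (within roughly the retained-fragment length), so:

    * a called site within ``shadow_range`` nt 5' of a *stronger* called
      site gets ``shadow_flag`` (possible shadow artifact), and
    * any candidate position (e.g. a known site that was not detected) with
      a called site within ``shadow_range`` nt on its 3' side is returned as
      potentially shadowed, explaining its non-detection.

    Purely annotative; no call is ever removed.
    """
    calls = list(calls)
    by_tid: dict[str, list[DSiteCall]] = {}
    for c in calls:
        by_tid.setdefault(c.transcript_id, []).append(c)
    for tid, group in by_tid.items():
        group.sort(key=lambda c: c.peak_position)
        for c in group:
            for other in group:
                if other is c:
                    continue
                dist = other.peak_position - c.peak_position
                if 0 < dist <= shadow_range and \
                        other.min_treated_score > c.min_treated_score:
                    c.shadow_flag = True
                    c.shadow_source = other.peak_position
                    break
    shadowed_candidates: list[tuple[str, int, int]] = []
    for tid, pos in candidates:
        for other in by_tid.get(tid, []):
            dist = other.peak_position - pos
            if 0 < dist <= shadow_range:
                shadowed_candidates.append((tid, pos, other.peak_position))
                break
    return calls, shadowed_candidates


def estimate_fdr(scores: Mapping[str, Mapping[str, pd.DataFrame]],
                 conditions: Mapping[str, str],
                 cutoffs: CutoffConfig,
                 *, control_rule: str = "each") -> FdrEstimate:
    """Inverted-analysis FDR: swap the treated/control roles (controls must
    exceed treated_min, treated must stay below control_max) and take the
    ratio of surviving inverted "sites" to forward calls."""
    n_forward = len(call_sites(scores, conditions, cutoffs, control_rule=control_rule))
    swapped = {lib: ("control" if c == "treated" else "treated")
               for lib, c in conditions.items()}
    n_inverted = len(call_sites(scores, swapped, cutoffs, control_rule=control_rule))
    return FdrEstimate(n_forward=n_forward, n_inverted=n_inverted)


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

def interrogated_positions(scores: Mapping[str, Mapping[str, pd.DataFrame]],
                           metric: str = "z") -> dict[str, np.ndarray]:
    """Boolean mask per transcript of positions that passed coverage (and,
    for MAD, the median filter) with a defined score in *all* libraries —
    the background of positions actually surveyed for D."""
    col = "zscore" if metric == "z" else "madscore"
    tids = set(next(iter(scores.values())))
    out = {}
    for tid in tids:
        mask = None
        for lib in scores:
            df = scores[lib][tid]
            ok = df["pass_coverage"].to_numpy() & np.isfinite(df[col].to_numpy())
            if metric == "mad":
                ok &= df["pass_median"].to_numpy()
            mask = ok if mask is None else (mask & ok)
        out[tid] = mask
    return out


def annotate_features(calls: Sequence[DSiteCall],
                      models: Mapping[str, TranscriptModel],
                      interrogated: Mapping[str, np.ndarray] | None = None,
                      ) -> tuple[list[DSiteCall], dict[str, float]]:
    """Label each call with the feature segment containing its D coordinate
    and, when the interrogated-position masks are given, return the feature
    distribution of all surveyed positions (the background against which the
    call distribution is compared)."""
    calls = list(calls)
    for c in calls:
        pos = c.d_position if c.d_position is not None else c.peak_position
        model = models.get(c.transcript_id)
        if model is None or not 0 <= pos < model.length:
            c.feature = NONCODING
            c.flags.append("feature_out_of_range")
            continue
        c.feature = model.feature_at(pos)
    background: dict[str, float] = {}
    if interrogated is not None:
        totals: dict[str, int] = {}
        for tid, mask in interrogated.items():
            model = models.get(tid)
            if model is None:
                continue
            for p in np.flatnonzero(mask):
                seg = model.feature_at(int(p))
                totals[seg] = totals.get(seg, 0) + 1
        grand = sum(totals.values())
        if grand:
            background = {seg: n / grand for seg, n in sorted(totals.items())}
    return calls, background


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def calls_to_table(calls: Sequence[DSiteCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "transcript_id": c.transcript_id,
            "peak_position": c.peak_position,
            "d_position": c.d_position,
            "chrom": c.chrom,
            "strand": c.strand,
            "genomic_d": c.genomic_d,
            "min_treated_score": c.min_treated_score,
            "max_control_score": c.max_control_score,
            "feature": c.feature,
            "shadow_flag": c.shadow_flag,
            "shadow_source": c.shadow_source,
        }
        for lib, s in c.treated_scores.items():
            row[f"score_{lib}"] = s
        for lib, s in c.control_scores.items():
            row[f"score_{lib}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_bed(calls: Sequence[DSiteCall]) -> str:
    """BED6 of D coordinates; name = transcript:position, score = min
    treated score.  Uses genomic coordinates when assigned, else transcript
    coordinates with the transcript id as chrom."""
    lines = []
    for c in calls:
        pos = c.d_position if c.d_position is not None else c.peak_position
        if c.genomic_d is not None:
            chrom, start, strand = c.chrom, c.genomic_d, c.strand
        else:
            chrom, start, strand = c.transcript_id, pos, "+"
        lines.append(f"{chrom}\t{start}\t{start + 1}\t"
                     f"{c.transcript_id}:{pos}\t{c.min_treated_score:.3f}\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")
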