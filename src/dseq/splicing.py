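"""Intron-retention comparison via the intron/exon mapping-read ratio.

For a gene whose pre-mRNA splicing may depend on an intronic modification,
the fraction of reads mapping to the intron relative to exonic reads is a
simple retention index.  Ratios are computed per replicate and compared
between conditions with a two-sample Student's t test (equal variance, as
named; Welch available via flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import INTRON, TranscriptModel

__all__ = ["SpliceRatio", "intron_exon_ratio", "count_intron_exon_reads",
           "splice_ratios", "compare_conditions"]


@dataclass
class SpliceRatio:
    gene_id: str
    ratios_a: dict[str, float] = field(default_factory=dict)
    ratios_b: dict[str, float] = field(default_factory=dict)
    t_statistic: float | None = None
    p_value: float | None = None

    @property
    def mean_a(self) -> float:
        return float(np.mean(list(self.ratios_a.values())))

    @property
    def mean_b(self) -> float:
        return float(np.mean(list(self.ratios_b.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": self.gene_id, "group": g, "library": lib, "ratio": r}
                for g, d in (("A", self.ratios_a), ("B", self.ratios_b))
                for lib, r in d.items()]
        return pd.DataFrame(rows)


def _segment_counts(counts: np.ndarray, model: TranscriptModel) -> tuple[int, int]:
    intron = exon = 0
    for seg, (a, b) in model.features:
        s = int(np.sum(counts[a:b]))
        if seg == INTRON:
            intron += s
        else:
            exon += s
    return intron, exon


def intron_exon_ratio(track_or_counts, model: TranscriptModel) -> float:
    """Intron reads / exon reads for one replicate, assigning each counted
    position to the feature segment containing it.  NaN (with a warning)
    when no exonic reads are present."""
    if not any(seg == INTRON for seg, _ in model.features):
        raise ValueError(f"model {model.transcript_id!r} has no intron")
    counts = np.asarray(getattr(track_or_counts, "counts", track_or_counts))
    if counts.shape[0] != model.length:
        raise ValueError("counts length does not match the transcript model")
    intron, exon = _segment_counts(counts, model)
    if exon == 0:
        warnings.warn(f"{model.transcript_id}: zero exonic reads; ratio undefined")
        return float("nan")
    return intron / exon


def count_intron_exon_reads(alignments, model: TranscriptModel, *,
                            min_mapq: int = 10,
                            junction_policy: str = "intron") -> tuple[int, int]:
    """Count whole alignments over one gene's intron vs exon segments.

    Reads spanning an exon–intron junction are evidence of an unspliced
    molecule and count as intronic by default (``junction_policy='exon'``
    flips this).  The model must be unspliced (genome-contiguous)."""
    import pysam

    if junction_policy not in ("intron", "exon"):
        raise ValueError(f"junction_policy must be 'intron' or 'exon'")
    if len(model.exons) != 1:
        raise ValueError("read-level counting needs an unspliced (single-span) model")
    if not any(seg == INTRON for seg, _ in model.features):
        raise ValueError(f"model {model.transcript_id!r} has no intron")
    own = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments)
        own = True
    span = model.span
    intron_spans = []
    for seg, (a, b) in model.features:
        if seg == INTRON:
            ga = model.transcript_to_genomic(a)
            gb = model.transcript_to_genomic(b - 1)
            intron_spans.append((min(ga, gb), max(ga, gb) + 1))
    n_intron = n_exon = 0
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq or read.reference_name != model.chrom:
                continue
            s, e = read.reference_start, read.reference_end
            if e <= span[0] or s >= span[1]:
                continue
            in_intron = any(s < ib and e > ia for ia, ib in intron_spans)
            in_exon = not all(ia <= s and e <= ib for ia, ib in intron_spans) and (
                any(not (ia <= s and e <= ib) for ia, ib in intron_spans)
                if intron_spans else True)
            fully_intronic = any(ia <= s and e <= ib for ia, ib in intron_spans)
            if fully_intronic:
                n_intron += 1
            elif in_intron:  # junction-spanning
                if junction_policy == "intron":
                    n_intron += 1
                else:
                    n_exon += 1
            else:
                n_exon += 1
    finally:
        if own:
            alignments.close()
    return n_intron, n_exon


def splice_ratios(tracks_a: Mapping[str, object], tracks_b: Mapping[str, object],
                  model: TranscriptModel, *, equal_var: bool = True) -> SpliceRatio:
    """Per-replicate ratios for two conditions plus the between-condition
    Student's t test.  Replicates with undefined ratios are excluded with a
    warning; the test requires at least two finite ratios per condition."""
    res = SpliceRatio(gene_id=model.transcript_id)
    for out, tracks in ((res.ratios_a, tracks_a), (res.ratios_b, tracks_b)):
        for lib, t in tracks.items():
            r = intron_exon_ratio(t, model)
            if np.isfinite(r):
                out[lib] = r
    res.t_statistic, res.p_value = compare_conditions(
        list(res.ratios_a.values()), list(res.ratios_b.values()),
        equal_var=equal_var)
    return res


def compare_conditions(ratios_a: Sequence[float], ratios_b: Sequence[float],
                       *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-sided t test on per-replicate ratios (df = nA+nB-2
    for the equal-variance form).  Degenerate zero-variance inputs with
    equal means give (0, 1)."""
    a = np.asarray([r for r in ratios_a if np.isfinite(r)], dtype=float)
    b = np.asarray([r for r in ratios_b if np.isfinite(r)], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite ratios per condition")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
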