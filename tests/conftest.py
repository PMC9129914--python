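"""Shared fixtures: tiny transcript models, synthetic SAM writers, and
score-table builders used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dseq import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def plus_model():
    # single-exon plus-strand transcript: genomic 1000..1200 on chrI
    return TranscriptModel("tplus", "chrI", "+", ((1000, 1200),))


@pytest.fixture
def minus_model():
    return TranscriptModel("tminus", "chrI", "-", ((5000, 5200),))


def write_sam(path, reads, references=(("chrI", 10000),)):
    """Minimal coordinate-sorted SAM.  ``reads`` are (name, flag, chrom,
    pos0, mapq, read_length) tuples; CIGAR is all-match."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in references:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for name, flag, chrom, pos0, mapq, rlen in sorted(reads, key=lambda r: (r[2], r[3])):
        seq = "A" * rlen
        lines.append(f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{rlen}M\t*\t0\t0\t"
                     f"{seq}\t{'I' * rlen}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def make_score_df(values, *, coverage=True, median=True, length=None,
                  metric_col="zscore"):
    """Score table with full flag control; the other metric column mirrors
    the given one so either metric can be used."""
    values = np.asarray(values, dtype=float)
    n = length or len(values)
    df = pd.DataFrame({
        "position": np.arange(n),
        "zscore": values,
        "madscore": values,
        "window_sum": np.full(n, 1000),
        "window_len": np.full(n, 101),
        "pass_median": np.broadcast_to(np.asarray(median), (n,)).copy(),
        "pass_coverage": np.broadcast_to(np.asarray(coverage), (n,)).copy(),
    })
    if metric_col == "madscore":
        df["zscore"] = np.nan
    return df
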