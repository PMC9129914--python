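"""Transcript models and strand-specific cDNA-end count tracks.

The central objects of the pipeline are per-position counts of reverse
transcription (RT) stop events: each truncated cDNA contributes one count at
the transcript position of its 3' terminus.  This module defines the
transcript coordinate system (0-based, half-open, 5'->3' on the RNA), the
count-track containers, and readers/writers for SAM/BAM, bedGraph, wig,
BED12, GFF3 and FASTA pseudo-genomes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "TranscriptModel",
    "EndCountTrack",
    "LibraryInfo",
    "LibrarySet",
    "ExtractionStats",
    "TranscriptIndex",
    "extract_end_counts",
    "read_count_track",
    "write_count_track",
    "read_bed12_models",
    "read_gff3_models",
    "models_from_fasta",
]

# feature segment labels
FIVE_PRIME_UTR = "five_prime_utr"
CDS = "cds"
INTRON = "intron"
THREE_PRIME_UTR = "three_prime_utr"
NONCODING = "noncoding"

SEGMENT_TYPES = (FIVE_PRIME_UTR, CDS, INTRON, THREE_PRIME_UTR, NONCODING)

RNA_CLASSES = ("tRNA", "snoRNA", "snRNA", "mRNA", "rRNA", "other")


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of genomic exon blocks plus a feature
    segmentation of its own coordinate system.

    ``exons`` are genomic, 0-based, half-open, sorted by genomic start and
    non-overlapping.  Transcript coordinates run 5'->3' on the RNA, so for a
    minus-strand transcript position 0 is the genomically *rightmost* exon
    base.  ``features`` partition [0, length) into labelled segments in
    transcript coordinates.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    features: tuple[tuple[str, tuple[int, int]], ...] = ()
    rna_class: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        if not exons:
            raise ValueError("transcript needs at least one exon")
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"empty or inverted exon {(a, b)}")
        for (_, a), (b, _) in zip(exons, exons[1:]):
            if b < a:
                raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", exons)
        length = sum(b - a for a, b in exons)
        feats = tuple(self.features) or ((NONCODING, (0, length)),)
        pos = 0
        for seg, (a, b) in feats:
            if seg not in SEGMENT_TYPES:
                raise ValueError(f"unknown segment type {seg!r}")
            if a != pos or b <= a:
                raise ValueError("features must tile [0, length) contiguously")
            pos = b
        if pos != length:
            raise ValueError("features must cover the full transcript length")
        object.__setattr__(self, "features", feats)

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    # -- coordinate projection ------------------------------------------------

    def _cum_starts(self) -> list[int]:
        out, c = [], 0
        for a, b in self.exons:
            out.append(c)
            c += b - a
        return out

    def genomic_to_transcript(self, g: int) -> int | None:
        """Project a genomic base to a transcript position, or None if the
        base is not exonic."""
        c = 0
        for a, b in self.exons:
            if a <= g < b:
                t_plus = c + (g - a)
                return t_plus if self.strand == "+" else self.length - 1 - t_plus
            c += b - a
        return None

    def transcript_to_genomic(self, t: int) -> int:
        if not 0 <= t < self.length:
            raise IndexError(f"transcript position {t} outside [0, {self.length})")
        t_plus = t if self.strand == "+" else self.length - 1 - t
        for (a, b), c in zip(self.exons, self._cum_starts()):
            if c <= t_plus < c + (b - a):
                return a + (t_plus - c)
        raise AssertionError("unreachable")

    def feature_at(self, t: int) -> str:
        if not 0 <= t < self.length:
            raise IndexError(f"transcript position {t} outside [0, {self.length})")
        for seg, (a, b) in self.features:
            if a <= t < b:
                return seg
        return NONCODING

    def feature_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seg, (a, b) in self.features:
            out[seg] = out.get(seg, 0) + (b - a)
        return out

    # -- constructors ---------------------------------------------------------

    @classmethod
    def single_block(cls, transcript_id: str, length: int, *, chrom: str | None = None,
                     strand: str = "+", start: int = 0, rna_class: str = "other",
                     features: Sequence[tuple[str, tuple[int, int]]] = ()) -> "TranscriptModel":
        """One-exon transcript; chrom defaults to the transcript id (the
        pseudo-genome convention used for tRNA analysis)."""
        return cls(transcript_id, chrom or transcript_id, strand,
                   ((start, start + length),), tuple(features), rna_class)

    @classmethod
    def spliced(cls, transcript_id: str, chrom: str, strand: str,
                exons: Sequence[tuple[int, int]], *, cds: tuple[int, int] | None = None,
                rna_class: str = "mRNA") -> "TranscriptModel":
        """Spliced transcript whose coordinate system excludes introns; the
        feature segmentation is UTR/CDS derived from a genomic CDS span."""
        exons = tuple(sorted((int(a), int(b)) for a, b in exons))
        length = sum(b - a for a, b in exons)
        if cds is None:
            feats: tuple[tuple[str, tuple[int, int]], ...] = ()
        else:
            tmp = cls(transcript_id, chrom, strand, exons, (), rna_class)
            tpos = sorted(t for g in range(cds[0], cds[1])
                          if (t := tmp.genomic_to_transcript(g)) is not None)
            if not tpos:
                feats = ()
            else:
                t0, t1 = tpos[0], tpos[-1] + 1
                parts = []
                if t0 > 0:
                    parts.append((FIVE_PRIME_UTR, (0, t0)))
                parts.append((CDS, (t0, t1)))
                if t1 < length:
                    parts.append((THREE_PRIME_UTR, (t1, length)))
                feats = tuple(parts)
        return cls(transcript_id, chrom, strand, exons, feats, rna_class)

    @classmethod
    def unspliced(cls, transcript_id: str, chrom: str, strand: str,
                  exon_blocks: Sequence[tuple[int, int]], *,
                  cds: tuple[int, int] | None = None,
                  rna_class: str = "mRNA") -> "TranscriptModel":
        """Pre-mRNA model: the coordinate system is the contiguous genomic
        span and introns (gaps between exon blocks) are feature segments.
        This is the natural model for genome-space end counting, where RT
        stops in retained introns are observable."""
        blocks = sorted((int(a), int(b)) for a, b in exon_blocks)
        span = (blocks[0][0], blocks[-1][1])
        labels = np.full(span[1] - span[0], -1, dtype=np.int8)
        seg_idx = {s: i for i, s in enumerate(SEGMENT_TYPES)}
        for a, b in blocks:
            lab = NONCODING if cds is None else None
            for g in range(a, b):
                if cds is not None:
                    if cds[0] <= g < cds[1]:
                        lab = CDS
                    elif (g < cds[0]) == (strand == "+"):
                        lab = FIVE_PRIME_UTR
                    else:
                        lab = THREE_PRIME_UTR
                labels[g - span[0]] = seg_idx[lab]
        labels[labels == -1] = seg_idx[INTRON]
        if strand == "-":
            labels = labels[::-1]
        feats, start = [], 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                feats.append((SEGMENT_TYPES[labels[start]], (start, i)))
                start = i
        return cls(transcript_id, chrom, strand, (span,), tuple(feats), rna_class)


class TranscriptIndex:
    """Interval lookup of transcripts by (chrom, genomic position, strand)."""

    def __init__(self, models: Iterable[TranscriptModel]):
        from intervaltree import IntervalTree

        self.models: dict[str, TranscriptModel] = {}
        self._trees: dict[str, "IntervalTree"] = {}
        for m in models:
            if m.transcript_id in self.models:
                raise ValueError(f"duplicate transcript id {m.transcript_id!r}")
            self.models[m.transcript_id] = m
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            a, b = m.span
            tree[a:b] = m

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.models.values())

    def __len__(self) -> int:
        return len(self.models)

    def find(self, chrom: str, g: int, strand: str | None = None
             ) -> list[tuple[TranscriptModel, int]]:
        """Transcripts whose exons contain genomic base ``g``, with the
        projected transcript position; sorted by transcript id."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree[g]:
            m = iv.data
            if strand is not None and m.strand != strand:
                continue
            t = m.genomic_to_transcript(g)
            if t is not None:
                hits.append((m, t))
        hits.sort(key=lambda mt: mt[0].transcript_id)
        return hits


# ---------------------------------------------------------------------------
# count tracks
# ---------------------------------------------------------------------------

@dataclass
class EndCountTrack:
    """Per-position counts of cDNA 3'-terminus (RT stop) events on one
    transcript; ``counts[i]`` is the number of truncated cDNAs whose stop
    maps to transcript position i."""

    transcript_id: str
    counts: np.ndarray
    library_id: str = ""
    condition: str = "treated"
    replicate: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.condition not in ("treated", "control"):
            raise ValueError(f"condition must be treated/control, got {self.condition!r}")

    @property
    def length(self) -> int:
        return int(self.counts.shape[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class LibraryInfo:
    condition: str
    replicate: int
    total_mapped: int | None = None


@dataclass
class LibrarySet:
    """Replicate x condition collection of per-transcript count tracks.

    ``treated``/``control`` hold one ``{transcript_id: EndCountTrack}`` dict
    per replicate; ``metadata`` maps library_id -> LibraryInfo (RPM scaling
    uses total_mapped)."""

    treated: list[dict[str, EndCountTrack]]
    control: list[dict[str, EndCountTrack]]
    metadata: dict[str, LibraryInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.treated or not self.control:
            raise ValueError("need at least one replicate per condition")
        tids = set(self.treated[0])
        for coll in list(self.treated) + list(self.control):
            if set(coll) != tids:
                raise ValueError("all libraries must cover the same transcript set")
        ids = [t.library_id for coll in self.libraries().values() for t in [next(iter(coll.values()))]]
        if len(ids) != len(set(ids)):
            raise ValueError("library ids must be unique")

    def libraries(self) -> dict[str, dict[str, EndCountTrack]]:
        """library_id -> track collection, treated replicates first."""
        out: dict[str, dict[str, EndCountTrack]] = {}
        for coll in list(self.treated) + list(self.control):
            lib = next(iter(coll.values())).library_id
            out[lib] = coll
        return out

    def conditions(self) -> dict[str, str]:
        """library_id -> condition."""
        return {lib: next(iter(coll.values())).condition
                for lib, coll in self.libraries().items()}

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.treated[0])


# ---------------------------------------------------------------------------
# SAM/BAM end extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractionStats:
    accepted: int = 0
    spill: int = 0
    strand_skipped: int = 0
    filtered: int = 0

    @property
    def counted(self) -> int:
        return self.accepted - self.spill


def _stop_position(read, end_convention: str) -> int:
    """Genomic coordinate of the RT stop for one alignment.

    The default convention takes the read base that abuts the 5' sequencing
    adapter of the cDNA — the 5' end of the read on the transcript strand —
    as the cDNA 3' terminus."""
    if end_convention not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown end_convention {end_convention!r}")
    five = read.reference_end - 1 if read.is_reverse else read.reference_start
    three = read.reference_start if read.is_reverse else read.reference_end - 1
    return five if end_convention == "five_prime" else three


def extract_end_counts(alignments, models: Iterable[TranscriptModel] | TranscriptIndex,
                       *, end_convention: str = "five_prime", min_mapq: int = 10,
                       library_id: str = "", condition: str = "treated",
                       replicate: int = 1,
                       ) -> tuple[dict[str, EndCountTrack], ExtractionStats]:
    """Stream a coordinate-sorted SAM/BAM and histogram RT-stop positions
    onto transcripts.

    Only primary alignments at or above ``min_mapq`` are used (multi-mapping
    reads typically carry low mapping quality and are excluded by default).
    Each accepted read increments exactly one transcript position; stops that
    fall outside any transcript exon (or on a transcript of the wrong strand)
    go to the spill bucket.  Reads on the strand opposite every local
    transcript are tallied separately, since in a strand-specific library
    they indicate an orientation problem.

    Returns (tracks keyed by transcript id, extraction statistics) with the
    conservation property sum(counts) + spill == accepted.
    """
    import pysam

    index = models if isinstance(models, TranscriptIndex) else TranscriptIndex(models)
    own = False
    if isinstance(alignments, (str, os.PathLike)):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        hd = alignments.header.to_dict().get("HD", {})
        if hd.get("SO") != "coordinate":
            raise ValueError("alignments must be coordinate-sorted (HD SO:coordinate)")
        tracks = {m.transcript_id: np.zeros(m.length, dtype=np.int64) for m in index}
        stats = ExtractionStats()
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                stats.filtered += 1
                continue
            if read.mapping_quality < min_mapq:
                stats.filtered += 1
                continue
            if read.is_paired and read.is_read2:
                stats.filtered += 1
                continue
            strand = "-" if read.is_reverse else "+"
            g = _stop_position(read, end_convention)
            chrom = read.reference_name
            hits = index.find(chrom, g, strand=strand)
            if not hits:
                # distinguish wrong-strand from genuinely untracked stops
                if index.find(chrom, g, strand="-" if strand == "+" else "+"):
                    stats.strand_skipped += 1
                    continue
                stats.accepted += 1
                stats.spill += 1
                continue
            m, t = hits[0]
            tracks[m.transcript_id][t] += 1
            stats.accepted += 1
    finally:
        if own:
            alignments.close()
    out = {tid: EndCountTrack(tid, arr, library_id=library_id,
                              condition=condition, replicate=replicate)
           for tid, arr in tracks.items()}
    return out, stats


# ---------------------------------------------------------------------------
# bedGraph / wig
# ---------------------------------------------------------------------------

def _parse_value(tok: str, lineno: int, path: str) -> float:
    try:
        v = float(tok)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: non-numeric value {tok!r}") from None
    if v < 0:
        raise ValueError(f"{path}:{lineno}: negative value {tok!r}")
    return v


def read_count_track(path: str | os.PathLike, models: Iterable[TranscriptModel] | TranscriptIndex,
                     *, fmt: str | None = None, strand: str | None = None,
                     library_id: str = "", condition: str = "treated",
                     replicate: int = 1) -> dict[str, EndCountTrack]:
    """Read a bedGraph or wig coverage file into per-transcript count arrays.

    Positions absent from the file are zero.  ``fmt`` is inferred from the
    extension when not given; ``strand`` restricts which transcripts receive
    counts (bedGraph/wig carry no strand of their own, so stranded data is
    conventionally split across two files)."""
    path = str(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "wig" if ext == ".wig" else "bedgraph"
    index = models if isinstance(models, TranscriptIndex) else TranscriptIndex(models)
    arrays = {m.transcript_id: np.zeros(m.length, dtype=np.float64) for m in index}

    def deposit(chrom: str, g: int, value: float) -> None:
        for m, t in index.find(chrom, g, strand=strand):
            arrays[m.transcript_id][t] += value

    with open(path) as fh:
        if fmt == "bedgraph":
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                v = _parse_value(parts[3], lineno, path)
                for g in range(start, end):
                    deposit(chrom, g, v)
        elif fmt == "wig":
            chrom, step_mode, pos, step, span = None, None, 0, 1, 1
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                if line.startswith("variableStep") or line.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in line.split()[1:])
                    chrom = kv["chrom"]
                    span = int(kv.get("span", 1))
                    if line.startswith("fixedStep"):
                        step_mode = "fixed"
                        pos = int(kv["start"]) - 1  # wig is 1-based
                        step = int(kv.get("step", 1))
                    else:
                        step_mode = "variable"
                    continue
                if chrom is None:
                    raise ValueError(f"{path}:{lineno}: data before step declaration")
                parts = line.split()
                if step_mode == "variable":
                    g0 = int(parts[0]) - 1
                    v = _parse_value(parts[1], lineno, path)
                else:
                    g0 = pos
                    pos += step
                    v = _parse_value(parts[0], lineno, path)
                for g in range(g0, g0 + span):
                    deposit(chrom, g, v)
        else:
            raise ValueError(f"unknown track format {fmt!r}")

    out = {}
    for tid, arr in arrays.items():
        counts = np.rint(arr)
        if np.allclose(arr, counts):
            counts = counts.astype(np.int64)
        else:
            counts = arr  # RPM-scaled input stays float
        out[tid] = EndCountTrack(tid, counts, library_id=library_id,
                                 condition=condition, replicate=replicate)
    return out


def write_count_track(tracks: Mapping[str, EndCountTrack], path: str | os.PathLike,
                      *, scale: str = "raw", total_mapped: int | None = None,
                      models: Mapping[str, TranscriptModel] | None = None,
                      fmt: str | None = None) -> None:
    """Write tracks as bedGraph (default) or wig.

    With ``models`` the output is in genomic coordinates; otherwise the
    transcript id is used as the chrom name and coordinates are transcript
    positions (the pseudo-genome convention).  ``scale='rpm'`` emits
    count * 1e6 / total_mapped.  Zero positions are omitted (sparse); raw
    integer output round-trips losslessly through :func:`read_count_track`.
    """
    path = str(path)
    if fmt is None:
        fmt = "wig" if os.path.splitext(path)[1].lower() == ".wig" else "bedgraph"
    if scale not in ("raw", "rpm"):
        raise ValueError(f"scale must be 'raw' or 'rpm', got {scale!r}")
    if scale == "rpm" and not total_mapped:
        raise ValueError("RPM scaling requires total mapped reads")

    def fmt_val(c: float) -> str:
        if scale == "rpm":
            return repr(float(c) * 1e6 / total_mapped)
        return str(int(c)) if float(c).is_integer() else repr(float(c))

    with open(path, "w") as fh:
        for tid in sorted(tracks):
            track = tracks[tid]
            model = models.get(tid) if models else None
            entries = []  # (chrom, genomic pos, value)
            for t in np.flatnonzero(track.counts):
                c = track.counts[t]
                if model is not None:
                    entries.append((model.chrom, model.transcript_to_genomic(int(t)), c))
                else:
                    entries.append((tid, int(t), c))
            entries.sort()
            if fmt == "bedgraph":
                for chrom, g, c in entries:
                    fh.write(f"{chrom}\t{g}\t{g + 1}\t{fmt_val(c)}\n")
            else:
                cur = None
                for chrom, g, c in entries:
                    if chrom != cur:
                        fh.write(f"variableStep chrom={chrom}\n")
                        cur = chrom
                    fh.write(f"{g + 1}\t{fmt_val(c)}\n")


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def read_bed12_models(path: str | os.PathLike, *, rna_class: str = "mRNA",
                      ) -> list[TranscriptModel]:
    """BED12 -> spliced transcript models (thickStart/thickEnd define the CDS)."""
    out = []
    with open(str(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            thick = (int(f[6]), int(f[7]))
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            cds = thick if thick[1] > thick[0] else None
            out.append(TranscriptModel.spliced(name, chrom, strand, exons,
                                               cds=cds, rna_class=rna_class))
    return out


_GFF_CLASS = {"tRNA": "tRNA", "tRNA_gene": "tRNA", "snoRNA": "snoRNA",
              "snoRNA_gene": "snoRNA", "snRNA": "snRNA", "snRNA_gene": "snRNA",
              "rRNA": "rRNA", "rRNA_gene": "rRNA", "mRNA": "mRNA"}


def read_gff3_models(path: str | os.PathLike, *, unspliced: bool = True,
                     ) -> list[TranscriptModel]:
    """GFF3 -> transcript models via gffutils.

    mRNAs become pre-mRNA (unspliced) models by default so that intronic RT
    stops are observable in genome-space analysis; set ``unspliced=False``
    for spliced coordinates.  ncRNA feature types become single-block models
    with the appropriate rna_class.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for ftype, rna_class in _GFF_CLASS.items():
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            continue
        for tr in feats:
            tid = tr.id
            if rna_class == "mRNA":
                exons = [(e.start - 1, e.end) for e in db.children(tr, featuretype="exon")]
                cds_parts = [(c.start - 1, c.end) for c in db.children(tr, featuretype="CDS")]
                if not exons:
                    exons = [(tr.start - 1, tr.end)]
                cds = (min(a for a, _ in cds_parts), max(b for _, b in cds_parts)) \
                    if cds_parts else None
                if unspliced:
                    out.append(TranscriptModel.unspliced(tid, tr.seqid, tr.strand,
                                                         exons, cds=cds, rna_class="mRNA"))
                else:
                    out.append(TranscriptModel.spliced(tid, tr.seqid, tr.strand,
                                                       exons, cds=cds, rna_class="mRNA"))
            else:
                out.append(TranscriptModel.single_block(
                    tid, tr.end - (tr.start - 1), chrom=tr.seqid, strand=tr.strand,
                    start=tr.start - 1, rna_class=rna_class))
    return out


def models_from_fasta(path: str | os.PathLike, *, rna_class: str = "tRNA",
                      ) -> list[TranscriptModel]:
    """Pseudo-genome FASTA (one record per unique RNA sequence) -> plus-strand
    single-exon models, the convention used for tRNA alignment."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), build_index=True, rebuild=True)
    return [TranscriptModel.single_block(name, len(fa[name]), rna_class=rna_class)
            for name in fa.keys()]
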