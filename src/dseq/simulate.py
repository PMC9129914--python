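"""Generative simulator of RT-stop sequencing libraries with ground truth.

The model follows the library design: transcripts are fragmented, fragments
are size-selected (70–80 nt), each fragment is reverse transcribed from its
3' end, and the RT walks 5'-ward copying one nucleotide at a time.  At every
copied nucleotide it terminates with a small background probability ``b``;
when it is about to copy a reduced dihydrouridine (a planted site that is
modified on this molecule — probability ``stoichiometry`` — in a treated
library) it terminates with probability ``stop_efficiency``, leaving the
cDNA 3' terminus exactly one nucleotide 3' of the site.  Truncated cDNAs
are retained when their length falls in the cDNA size-selection window
(50–80 nt) and contribute one end count at the stop position; cDNAs that
run off the fragment 5' end are full-length and tracked separately (they
model the matched RNA-seq control libraries when emitted).

Control libraries (the knockout condition) run the identical process with
all stop efficiencies forced to zero, so their background stop counts are
identical in distribution to the treated libraries.

Shadowing emerges from the model rather than being scripted: a penetrant 3'
stop consumes the fragments that would otherwise have reported a 5' site.
The expected retained stop count at a site has the closed form
``N_cover_in_retention_range * s * e * prod(1 - b)`` along the RT path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import EndCountTrack, LibraryInfo, LibrarySet

__all__ = [
    "PlantedSite",
    "SimConfig",
    "SimTruth",
    "FragmentResult",
    "simulate_fragment",
    "simulate_library",
    "simulate_experiment",
    "truth_report",
]


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    position: int           # transcript coordinate of the D itself
    stoichiometry: float = 1.0   # fraction of molecules modified
    stop_efficiency: float = 0.5  # P(stop | modified and reduced)

    def __post_init__(self) -> None:
        if not 0 <= self.stoichiometry <= 1:
            raise ValueError("stoichiometry must be in [0, 1]")
        if not 0 <= self.stop_efficiency <= 1:
            raise ValueError("stop_efficiency must be in [0, 1]")

    @property
    def expected_stop_position(self) -> int:
        return self.position + 1


@dataclass(frozen=True)
class SimConfig:
    """Study design for one simulated experiment.

    Defaults mirror the library protocol: RNA fragments 70–80 nt, truncated
    cDNA retention 50–80 nt, 3 treated + 3 control replicates.  The
    background stop probability per copied nucleotide is not something the
    protocol pins down; the default 0.003 gives realistically sparse noise
    and is fully configurable."""

    transcripts: Mapping[str, int]          # transcript_id -> length (nt)
    copy_numbers: Mapping[str, float] | None = None
    n_fragments: int = 65_000               # per library
    fragment_len: tuple[int, int] = (70, 80)
    background_stop_prob: float = 0.003
    sites: tuple[PlantedSite, ...] = ()
    n_treated: int = 3
    n_control: int = 3
    cdna_len: tuple[int, int] = (50, 80)
    emit_runoff: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_stop_prob < 1:
            raise ValueError("background_stop_prob must be in [0, 1)")
        if self.fragment_len[0] > self.fragment_len[1] or self.fragment_len[0] < 1:
            raise ValueError("invalid fragment length range")
        for tid, L in self.transcripts.items():
            if L < self.fragment_len[1]:
                raise ValueError(f"transcript {tid!r} shorter than the longest fragment")
        for s in self.sites:
            if s.transcript_id not in self.transcripts:
                raise ValueError(f"planted site on unknown transcript {s.transcript_id!r}")
            if not 0 <= s.position < self.transcripts[s.transcript_id] - 1:
                raise ValueError("planted site must leave room for a stop 1 nt 3' of it")
        object.__setattr__(self, "sites", tuple(self.sites))


@dataclass
class SimTruth:
    """Ground truth emitted alongside the tracks: per planted site and
    library, the fragments covering the site and how they resolved (stop at
    site+1 / stopped 3' of it / read through), plus the retained stop count
    that actually lands in the count track."""

    sites: pd.DataFrame
    library_totals: dict[str, int]
    run_id: str
    config: SimConfig

    def per_site_stops(self) -> pd.DataFrame:
        """Retained stop counts pivoted site x library."""
        if self.sites.empty:
            return pd.DataFrame()
        return self.sites.pivot_table(index=["transcript_id", "position"],
                                      columns="library_id",
                                      values="n_stop_retained")


@dataclass(frozen=True)
class FragmentResult:
    f5: int
    f3: int
    end: int
    kind: str       # "truncated" | "runoff"
    retained: bool


def _library_rng(seed: int, condition_index: int, replicate: int) -> np.random.Generator:
    # per-library substream: adding replicates never perturbs existing ones
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(condition_index, replicate)))


def simulate_fragment(transcript_length: int, sites: Sequence[PlantedSite],
                      config: SimConfig, rng: np.random.Generator,
                      *, treated: bool = True) -> FragmentResult:
    """Sequential reference implementation of one fragment's fate.

    Draws fragment length and placement, then walks the RT 5'-ward checking
    the background stop after each copied nucleotide and the D stop before
    copying a planted site.  Returned ``end`` is the transcript position of
    the cDNA 3' terminus."""
    fl0, fl1 = config.fragment_len
    b = config.background_stop_prob
    flen = int(rng.integers(fl0, fl1 + 1))
    f3 = int(rng.integers(0, transcript_length - flen + 1)) + flen - 1
    f5 = f3 - flen + 1
    site_at = {s.position: s for s in sites}
    p = f3
    end, kind = f5, "runoff"
    while True:
        if b > 0 and rng.random() < b:
            end, kind = p, "truncated"
            break
        if p == f5:
            break
        st = site_at.get(p - 1)
        if st is not None:
            modified = rng.random() < st.stoichiometry
            stops = rng.random() < st.stop_efficiency
            if treated and modified and stops:
                end, kind = p, "truncated"   # terminus 1 nt 3' of the site
                break
        p -= 1
    length = f3 - end + 1
    retained = (config.cdna_len[0] <= length <= config.cdna_len[1]) \
        if kind == "truncated" else True
    return FragmentResult(f5=f5, f3=f3, end=end, kind=kind, retained=retained)


def _simulate_library_arrays(config: SimConfig, rng: np.random.Generator,
                             treated: bool,
                             ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray],
                                        list[dict], int]:
    """Vectorized library simulation (equivalent in distribution to the
    sequential reference: the background stop offset is geometric and each
    planted site fires an independent Bernoulli; the realized stop is the
    3'-most firing event)."""
    tids = sorted(config.transcripts)
    lengths = np.array([config.transcripts[t] for t in tids], dtype=float)
    copies = np.array([(config.copy_numbers or {}).get(t, 1.0) for t in tids])
    w = lengths * copies
    alloc = rng.multinomial(config.n_fragments, w / w.sum())
    fl0, fl1 = config.fragment_len
    c0, c1 = config.cdna_len
    b = config.background_stop_prob
    counts = {t: np.zeros(config.transcripts[t], dtype=np.int64) for t in tids}
    runoff = {t: np.zeros(config.transcripts[t], dtype=np.int64) for t in tids}
    truth_rows: list[dict] = []
    retained_total = 0
    NO_STOP = -(10 ** 9)
    for tid, n in zip(tids, alloc):
        L = config.transcripts[tid]
        n = int(n)
        if n == 0:
            continue
        flen = rng.integers(fl0, fl1 + 1, size=n)
        f3 = rng.integers(0, L - flen + 1) + flen - 1
        f5 = f3 - flen + 1
        best = np.full(n, NO_STOP, dtype=np.int64)
        if b > 0:
            K = rng.geometric(b, size=n)
            q_bg = f3 - (K - 1)
            best = np.where(K <= flen, q_bg, NO_STOP)
        site_masks = []
        for s in config.sites:
            if s.transcript_id != tid:
                continue
            covering = (s.position >= f5) & (s.position <= f3 - 1)
            modified = rng.random(n) < s.stoichiometry
            stops = rng.random(n) < s.stop_efficiency
            fire = covering & modified & stops & treated
            best = np.maximum(best, np.where(fire, s.position + 1, NO_STOP))
            site_masks.append((s, covering))
        truncated = best > NO_STOP
        end = np.where(truncated, best, f5)
        length = f3 - end + 1
        retained = truncated & (length >= c0) & (length <= c1)
        np.add.at(counts[tid], end[retained], 1)
        retained_total += int(retained.sum())
        np.add.at(runoff[tid], f5[~truncated], 1)
        for s, covering in site_masks:
            stop_here = covering & (end == s.position + 1)
            truth_rows.append({
                "transcript_id": tid, "position": s.position,
                "stoichiometry": s.stoichiometry,
                "stop_efficiency": s.stop_efficiency,
                "n_cover": int(covering.sum()),
                "n_stop": int(stop_here.sum()),
                "n_stop_retained": int((stop_here & retained).sum()),
                "n_upstream": int((covering & (end > s.position + 1)).sum()),
                "n_readthrough": int((covering & (end < s.position + 1)).sum()),
            })
    return counts, runoff, truth_rows, retained_total


def simulate_library(config: SimConfig, rng: np.random.Generator, *,
                     treated: bool = True, library_id: str = "",
                     replicate: int = 1,
                     ) -> tuple[dict[str, EndCountTrack], list[dict], int]:
    counts, _, truth_rows, retained = _simulate_library_arrays(config, rng, treated)
    condition = "treated" if treated else "control"
    tracks = {tid: EndCountTrack(tid, arr, library_id=library_id,
                                 condition=condition, replicate=replicate)
              for tid, arr in counts.items()}
    for row in truth_rows:
        row["library_id"] = library_id
        row["condition"] = condition
        row["replicate"] = replicate
    return tracks, truth_rows, retained


def simulate_experiment(config: SimConfig) -> tuple[LibrarySet, SimTruth]:
    """Full replicate x condition design.

    Deterministic given the config seed; each library draws from its own
    substream keyed by (condition, replicate)."""
    treated_colls, control_colls = [], []
    metadata: dict[str, LibraryInfo] = {}
    truth_rows: list[dict] = []
    totals: dict[str, int] = {}
    for cond_idx, (cond, n_rep, colls) in enumerate(
            (("treated", config.n_treated, treated_colls),
             ("control", config.n_control, control_colls))):
        for rep in range(1, n_rep + 1):
            lib = f"{'wt' if cond == 'treated' else 'dusko'}_{rep}"
            rng = _library_rng(config.seed, cond_idx, rep)
            tracks, rows, retained = simulate_library(
                config, rng, treated=(cond == "treated"),
                library_id=lib, replicate=rep)
            colls.append(tracks)
            metadata[lib] = LibraryInfo(condition=cond, replicate=rep,
                                        total_mapped=retained)
            totals[lib] = retained
            truth_rows.extend(rows)
    libset = LibrarySet(treated=treated_colls, control=control_colls,
                        metadata=metadata)
    cols = ["transcript_id", "position", "stoichiometry", "stop_efficiency",
            "library_id", "condition", "replicate", "n_cover", "n_stop",
            "n_stop_retained", "n_upstream", "n_readthrough"]
    truth = SimTruth(sites=pd.DataFrame(truth_rows, columns=cols),
                     library_totals=totals, run_id=f"sim-seed-{config.seed}",
                     config=config)
    return libset, truth


def truth_report(calls, truth: SimTruth, *,
                 interrogated: Mapping[str, np.ndarray] | None = None,
                 run_id: str | None = None) -> dict:
    """Compare a call set with the simulator's ground truth.

    Sensitivity is recovered planted sites over planted sites with
    sufficient coverage (``interrogated`` masks index the *peak* position,
    site + 1); a call matches truth when its inferred D coordinate equals a
    planted position exactly.  Empirical FDR is the fraction of calls not
    matching any planted site (None when there are no calls).
    """
    if run_id is not None and run_id != truth.run_id:
        raise ValueError(f"call set from run {run_id!r} does not match "
                         f"truth from {truth.run_id!r}")
    planted = {(s.transcript_id, s.position) for s in truth.config.sites}
    if interrogated is not None:
        eligible = {(t, p) for (t, p) in planted
                    if t in interrogated and p + 1 < len(interrogated[t])
                    and bool(interrogated[t][p + 1])}
    else:
        eligible = set(planted)
    called = {(c.transcript_id, c.d_position) for c in calls
              if c.d_position is not None}
    recovered = called & eligible
    n_calls = len(calls)
    false_calls = len(called - planted)
    rows = [{"transcript_id": t, "position": p, "eligible": (t, p) in eligible,
             "detected": (t, p) in called} for t, p in sorted(planted)]
    return {
        "sensitivity": len(recovered) / len(eligible) if eligible else float("nan"),
        "empirical_fdr": false_calls / n_calls if n_calls else None,
        "n_calls": n_calls,
        "n_planted": len(planted),
        "n_eligible": len(eligible),
        "n_recovered": len(recovered),
        "detection_table": pd.DataFrame(rows),
    }
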