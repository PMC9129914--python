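"""Consensus calling, cutoff derivation, FDR inversion, shadows, features."""

import numpy as np
import pandas as pd
import pytest

import dseq
from dseq import calling

from conftest import make_score_df


def nested(per_lib_values, **kw):
    """library -> {'t': score DataFrame} from per-library value arrays."""
    return {lib: {"t": make_score_df(v, **kw)} for lib, v in per_lib_values.items()}


CONDS = {"wt_1": "treated", "wt_2": "treated", "wt_3": "treated",
         "ko_1": "control", "ko_2": "control", "ko_3": "control"}
MRNA = dseq.class_cutoffs("mrna")


class TestSurvivalCurves:
    def test_fraction_at_midpoint(self):
        curves = calling.score_survival_curves({"a": [1, 2, 3, 4]},
                                               grid=np.array([2.5]))
        assert curves.loc[2.5, "a"] == 0.5

    def test_below_minimum_is_one(self):
        curves = calling.score_survival_curves({"a": [1, 2, 3, 4]},
                                               grid=np.array([0.0]))
        assert curves.loc[0.0, "a"] == 1.0

    def test_matches_brute_force_on_random_scores(self, rng):
        scores = rng.normal(size=500)
        curves = calling.score_survival_curves({"a": scores})
        for s in curves.index[::37]:
            assert curves.loc[s, "a"] == pytest.approx(np.mean(scores >= s))

    def test_monotone_non_increasing(self, rng):
        curves = calling.score_survival_curves({"a": rng.normal(size=200)})
        assert (np.diff(curves["a"].to_numpy()) <= 0).all()

    def test_empty_scores_error(self):
        with pytest.raises(ValueError, match="no scorable"):
            calling.score_survival_curves({"a": []})


class TestSuggestCutoffs:
    def test_identical_curves_never_diverge(self, rng):
        s = rng.normal(size=300)
        t = calling.score_survival_curves({"a": s})
        with pytest.warns(UserWarning, match="never diverge"):
            assert calling.suggest_cutoffs(t, t, 0.5) is None

    def test_zero_control_diverges_at_smallest_positive_score(self):
        grid = np.array([-1.0, 0.0, 1.0, 2.0, 5.0])
        t = calling.score_survival_curves({"a": [1.0, 2.0, 5.0]}, grid=grid)
        c = calling.score_survival_curves({"a": [0.0, 0.0, 0.0]}, grid=grid)
        got = calling.suggest_cutoffs(t, c, 0.1)
        assert got.treated_min == 1.0

    def test_separates_simulated_spikes_from_background(self):
        cfg = dseq.SimConfig(transcripts={"t1": 2000}, n_fragments=65000,
                             sites=(dseq.PlantedSite("t1", 500, 1.0, 0.5),
                                    dseq.PlantedSite("t1", 1200, 1.0, 0.5)),
                             seed=5)
        libset, _ = dseq.simulate_experiment(cfg)
        scores = dseq.score_library(libset.libraries())
        conds = libset.conditions()
        t = calling.score_survival_curves(
            {l: scores[l] for l in scores if conds[l] == "treated"})
        c = calling.score_survival_curves(
            {l: scores[l] for l in scores if conds[l] == "control"},
            grid=t.index.to_numpy())
        sug = calling.suggest_cutoffs(t, c, 0.01)
        # exhaustive check: the suggestion separates spiked positions from
        # every background position in the treated libraries
        spikes = {501, 1201}
        for lib, cond in conds.items():
            if cond != "treated":
                continue
            df = scores[lib]["t1"]
            z = df.zscore.to_numpy()
            assert all(z[p] >= sug.treated_min for p in spikes)
            bg = [z[p] for p in range(100, 1900)
                  if p not in spikes and np.isfinite(z[p])]
            assert np.mean(np.array(bg) >= sug.treated_min) < 0.01


class TestCallSites:
    def test_worked_consensus_example(self):
        vals = {"wt_1": [0, 11.0], "wt_2": [0, 12.0], "wt_3": [0, 13.0],
                "ko_1": [0, 0.0], "ko_2": [0, 1.0], "ko_3": [0, 2.0]}
        calls = calling.call_sites(nested(vals), CONDS, MRNA)
        assert [(c.transcript_id, c.peak_position) for c in calls] == [("t", 1)]
        assert calls[0].min_treated_score == 11.0
        assert calls[0].max_control_score == 2.0

    def test_three_of_three_rule(self):
        vals = {"wt_1": [11.0], "wt_2": [12.0], "wt_3": [9.9],
                "ko_1": [0.0], "ko_2": [0.0], "ko_3": [0.0]}
        assert calling.call_sites(nested(vals), CONDS, MRNA) == []

    def test_failed_coverage_disqualifies(self):
        vals = {l: [20.0] if c == "treated" else [0.0]
                for l, c in CONDS.items()}
        tables = nested(vals)
        tables["ko_2"]["t"].loc[0, "pass_coverage"] = False
        assert calling.call_sites(tables, CONDS, MRNA) == []

    def test_undefined_score_disqualifies(self):
        vals = {l: [20.0] if c == "treated" else [0.0]
                for l, c in CONDS.items()}
        tables = nested(vals)
        tables["wt_3"]["t"].loc[0, "zscore"] = np.nan
        assert calling.call_sites(tables, CONDS, MRNA) == []

    def test_median_rule_applies_only_to_mad_metric(self):
        vals = {l: [50.0] if c == "treated" else [0.0]
                for l, c in CONDS.items()}
        tables = nested(vals, median=False)
        assert len(calling.call_sites(tables, CONDS, MRNA)) == 1  # z metric
        trna = dseq.class_cutoffs("trna")
        assert calling.call_sites(tables, CONDS, trna) == []

    def test_monotone_in_cutoffs(self, rng):
        vals = {l: rng.normal(5, 5, size=60) for l in CONDS}
        tables = nested(vals)
        loose = calling.CutoffConfig("z", 4.0, 4.0)
        tight = calling.CutoffConfig("z", 8.0, 2.0)
        got_loose = {c.peak_position for c in calling.call_sites(tables, CONDS, loose)}
        got_tight = {c.peak_position for c in calling.call_sites(tables, CONDS, tight)}
        assert got_tight <= got_loose

    def test_matches_brute_force_on_simulation(self):
        cfg = dseq.SimConfig(transcripts={"t1": 1200}, n_fragments=40000,
                             sites=(dseq.PlantedSite("t1", 400, 1.0, 0.4),
                                    dseq.PlantedSite("t1", 800, 1.0, 0.6)),
                             seed=9)
        libset, _ = dseq.simulate_experiment(cfg)
        scores = dseq.score_library(libset.libraries())
        conds = libset.conditions()
        calls = calling.call_sites(scores, conds, MRNA)
        got = {c.peak_position for c in calls}
        # independent position-by-position application of the rule
        brute = set()
        for p in range(1200):
            ok = True
            for lib, cond in conds.items():
                row = scores[lib]["t1"].iloc[p]
                if not row.pass_coverage or not np.isfinite(row.zscore):
                    ok = False
                    break
                if cond == "treated" and not row.zscore > MRNA.treated_min:
                    ok = False
                    break
                if cond == "control" and not row.zscore < MRNA.control_max:
                    ok = False
                    break
            if ok:
                brute.add(p)
        assert got == brute


class TestDPosition:
    def test_plus_strand(self, plus_model):
        c = dseq.DSiteCall("tplus", 50, treated_scores={"w": 12.0},
                           control_scores={"k": 0.0})
        calling.assign_d_position(c, plus_model)
        assert c.d_position == 49
        assert c.genomic_d == 1049

    def test_minus_strand_genomic_d_is_peak_plus_one(self, minus_model):
        c = dseq.DSiteCall("tminus", 50, treated_scores={"w": 12.0},
                           control_scores={"k": 0.0})
        calling.assign_d_position(c, minus_model)
        assert c.d_position == 49
        assert c.genomic_d == c.genomic_peak + 1

    def test_peak_at_zero_flagged(self):
        c = dseq.DSiteCall("t", 0, treated_scores={"w": 12.0},
                           control_scores={"k": 0.0})
        calling.assign_d_position(c)
        assert c.d_position is None and "no_d_position" in c.flags


class TestShadows:
    def _call(self, pos, score):
        return dseq.DSiteCall("t", pos, treated_scores={"w": score},
                              control_scores={"k": 0.0})

    def test_candidate_within_range_flagged(self):
        calls, shadowed = calling.annotate_shadows([self._call(100, 20.0)],
                                                   candidates=[("t", 60)])
        assert shadowed == [("t", 60, 100)]

    def test_candidate_beyond_range_not_flagged(self):
        _, shadowed = calling.annotate_shadows([self._call(100, 20.0)],
                                               candidates=[("t", 10)])
        assert shadowed == []

    def test_weaker_called_site_upstream_of_stronger_flagged(self):
        weak, strong = self._call(70, 11.0), self._call(100, 30.0)
        calls, _ = calling.annotate_shadows([weak, strong])
        assert weak.shadow_flag and weak.shadow_source == 100
        assert not strong.shadow_flag


class TestFdr:
    def test_worked_example(self):
        est = dseq.FdrEstimate(n_forward=130, n_inverted=5)
        assert round(est.percent, 1) == 3.8
        assert "3.8%" in str(est)

    def test_zero_inverted_gives_zero(self):
        assert dseq.FdrEstimate(10, 0).fdr == 0.0

    def test_zero_forward_not_applicable(self):
        assert dseq.FdrEstimate(0, 3).fdr is None

    def test_label_swap_symmetry(self, rng):
        vals = {l: rng.normal(5, 5, size=80) for l in CONDS}
        tables = nested(vals)
        cut = calling.CutoffConfig("z", 6.0, 6.0)
        fwd = calling.estimate_fdr(tables, CONDS, cut)
        swapped = {l: ("control" if c == "treated" else "treated")
                   for l, c in CONDS.items()}
        rev = calling.estimate_fdr(tables, swapped, cut)
        assert (fwd.n_forward, fwd.n_inverted) == (rev.n_inverted, rev.n_forward)


class TestFeatures:
    def toy_model(self):
        feats = (("five_prime_utr", (0, 10)), ("cds", (10, 40)),
                 ("three_prime_utr", (40, 50)))
        return dseq.TranscriptModel("t", "chrI", "+", ((0, 50),), feats)

    def test_intron_label(self):
        m = dseq.TranscriptModel("t", "chrI", "+", ((0, 30),),
                                 (("cds", (0, 10)), ("intron", (10, 20)),
                                  ("cds", (20, 30))))
        c = dseq.DSiteCall("t", 16, d_position=15, treated_scores={"w": 12.0},
                           control_scores={"k": 0.0})
        calls, _ = calling.annotate_features([c], {"t": m})
        assert calls[0].feature == "intron"

    def test_background_proportions_on_toy_model(self):
        m = self.toy_model()
        interrogated = {"t": np.ones(50, dtype=bool)}
        _, bg = calling.annotate_features([], {"t": m}, interrogated)
        assert bg == {"cds": pytest.approx(0.6),
                      "five_prime_utr": pytest.approx(0.2),
                      "three_prime_utr": pytest.approx(0.2)}

    def test_background_proportions_sum_to_one(self, rng):
        m = self.toy_model()
        interrogated = {"t": rng.random(50) < 0.5}
        _, bg = calling.annotate_features([], {"t": m}, interrogated)
        assert sum(bg.values()) == pytest.approx(1.0)
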