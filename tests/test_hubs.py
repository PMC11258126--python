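"""Elbow hub calling and enrichment models."""

import numpy as np
import pandas as pd
import pytest

from methlink import hubs as hmod


def pot_frame(values):
    return pd.DataFrame({"cluster_id": [f"cl{i}" for i in range(len(values))],
                         "potential": values})


class TestCallHubs:
    def test_two_regime_curve(self):
        vals = [10.0, 9.5, 9.0] + list(np.linspace(0.1, 0.01, 7))
        calls = hmod.call_hubs(pot_frame(vals))
        assert sorted(calls.table.loc[calls.table["is_hub"], "potential"]) == [9.0, 9.5, 10.0]

    def test_all_equal_no_hubs(self):
        with pytest.warns(UserWarning, match="no hubs"):
            calls = hmod.call_hubs(pot_frame([1.0] * 12))
        assert not calls.table["is_hub"].any()

    def test_linear_ramp_low_confidence(self):
        with pytest.warns(UserWarning):
            calls = hmod.call_hubs(pot_frame(list(np.linspace(0, 10, 21))))
        assert calls.low_confidence
        assert abs(calls.threshold - 5.0) <= 2.5  # near the midpoint

    def test_threshold_invariant_to_low_tail(self):
        vals = [10.0, 9.5, 9.0] + list(np.linspace(0.1, 0.01, 7))
        base = hmod.call_hubs(pot_frame(vals))
        extended = hmod.call_hubs(pot_frame(vals + [-1.0, -2.0, 0.0]))
        assert extended.threshold == base.threshold

    def test_too_few_elements(self):
        with pytest.raises(ValueError):
            hmod.call_hubs(pot_frame([1, 2, 3]))

    def test_recovers_planted_hubs(self):
        rng = np.random.default_rng(0)
        vals = list(rng.normal(0, 0.5, 500)) + [8.0, 9.0, 10.0, 11.0, 12.0]
        calls = hmod.call_hubs(pot_frame(vals))
        hubs = set(calls.hub_ids)
        planted = {f"cl{i}" for i in range(500, 505)}
        assert len(hubs & planted) >= 4


def track_tiling(labels, win=1000, chrom="chr1", length=100_000, seed=0):
    rng = np.random.default_rng(seed)
    starts = np.arange(0, length, win)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + win,
                         "label": rng.choice(labels, len(starts))})


def clusters_at(positions, chrom="chr1"):
    return pd.DataFrame(
        {"cluster_id": [f"cl{i}" for i in range(len(positions))], "chrom": chrom,
         "start": positions, "end": [p + 10 for p in positions],
         "midpoint": [p + 5 for p in positions]}
    )


class TestAssignState:
    def test_largest_overlap_wins(self):
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 300],
             "label": ["A", "B"]}
        )
        clusters = pd.DataFrame(
            {"cluster_id": ["c1"], "chrom": ["chr1"], "start": [80], "end": [200],
             "midpoint": [140]}
        )
        assert hmod.assign_state(clusters, track)["c1"] == "B"  # overlap 100 vs 21

    def test_tie_goes_to_earlier_interval(self):
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200],
             "label": ["A", "B"]}
        )
        clusters = pd.DataFrame(
            {"cluster_id": ["c1"], "chrom": ["chr1"], "start": [50], "end": [149],
             "midpoint": [100]}
        )
        assert hmod.assign_state(clusters, track)["c1"] == "A"


class TestEnrichPotentialByState:
    def test_recovery_and_balanced_equivalence(self):
        rng = np.random.default_rng(4)
        n = 200
        states = pd.Series(
            ["Low Signal"] * n + ["Enhancer"] * n,
            index=[f"cl{i}" for i in range(2 * n)],
        )
        pot = pot_frame(np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)]))
        res = hmod.enrich_potential_by_state(pot, states)
        eff = res.set_index("term").loc["Enhancer"]
        assert eff["ci_low"] < 2.0 < eff["ci_high"]
        # balanced design: effect equals direct group-mean difference
        direct = (
            pot.set_index("cluster_id")["potential"].groupby(states).mean()
        )
        assert eff["effect"] == pytest.approx(direct["Enhancer"] - direct["Low Signal"])

    def test_missing_reference_raises(self):
        states = pd.Series(["A"] * 10, index=[f"cl{i}" for i in range(10)])
        with pytest.raises(ValueError):
            hmod.enrich_potential_by_state(pot_frame(np.ones(10)), states)

    def test_all_reference_empty_result(self):
        states = pd.Series(["Low Signal"] * 10, index=[f"cl{i}" for i in range(10)])
        res = hmod.enrich_potential_by_state(pot_frame(np.ones(10)), states)
        assert res.empty


class TestEnrichPotentialByFactor:
    def test_single_factor_recovery(self):
        rng = np.random.default_rng(5)
        n = 400
        bound = rng.random(n) < 0.3
        pot = pot_frame(rng.normal(0, 1, n) + 1.5 * bound)
        mem = pd.DataFrame({"TF1": bound}, index=pot["cluster_id"])
        res = hmod.enrich_potential_by_factor(pot, mem).set_index("term")
        assert res.loc["TF1", "ci_low"] < 1.5 < res.loc["TF1", "ci_high"]

    def test_nested_factor_dropped(self):
        rng = np.random.default_rng(6)
        n = 100
        bound = rng.random(n) < 0.5
        pot = pot_frame(rng.normal(0, 1, n))
        mem = pd.DataFrame({"TF1": bound, "TF2": bound}, index=pot["cluster_id"])
        with pytest.warns(UserWarning, match="collinear"):
            res = hmod.enrich_potential_by_factor(pot, mem)
        assert list(res["term"]) == ["TF1"]

    def test_two_independent_factors(self):
        rng = np.random.default_rng(7)
        n = 600
        f1 = rng.random(n) < 0.4
        f2 = rng.random(n) < 0.4
        pot = pot_frame(rng.normal(0, 1, n) + 1.0 * f1 - 0.5 * f2)
        mem = pd.DataFrame({"TF1": f1, "TF2": f2}, index=pot["cluster_id"])
        res = hmod.enrich_potential_by_factor(pot, mem).set_index("term")
        assert res.loc["TF1", "ci_low"] < 1.0 < res.loc["TF1", "ci_high"]
        assert res.loc["TF2", "ci_low"] < -0.5 < res.loc["TF2", "ci_high"]


class TestLoopCountEnrichment:
    def test_binning(self):
        assert hmod.loop_count_group(0) == "0"
        assert hmod.loop_count_group(1) == "1"
        assert hmod.loop_count_group(2) == "[2,4)"
        assert hmod.loop_count_group(3) == "[2,4)"
        assert hmod.loop_count_group(4) == "[4,13)"
        assert hmod.loop_count_group(12) == "[4,13)"
        assert hmod.loop_count_group(13) == "[13,209)"
        assert hmod.loop_count_group(500) == "[13,209)"  # clamped to top group

    def test_partition(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 300, 200)
        groups = [hmod.loop_count_group(int(c)) for c in counts]
        assert set(groups) <= {"0", "1", "[2,4)", "[4,13)", "[13,209)"}

    def test_cluster_anchor_counting(self):
        clusters = clusters_at([100, 5_000])
        loops = pd.DataFrame(
            {
                "chrom1": ["chr1", "chr1"], "start1": [0, 90], "end1": [200, 150],
                "chrom2": ["chr1", "chr1"], "start2": [4_000, 9_000],
                "end2": [6_000, 9_500],
            }
        )
        counts = hmod.count_loops_per_cluster(clusters, loops)
        assert counts["cl0"] == 2 and counts["cl1"] == 1

    def test_planted_relation_monotone(self):
        rng = np.random.default_rng(9)
        n = 500
        counts = rng.integers(0, 20, n)
        clusters = clusters_at(list(range(0, n * 100, 100)))
        pot = pot_frame(0.3 * counts + rng.normal(0, 0.5, n))
        # fabricate loops so cluster i gets counts[i] anchors
        rows = []
        for i, c in enumerate(counts):
            for _ in range(int(c)):
                rows.append({"chrom1": "chr1", "start1": i * 100, "end1": i * 100 + 10,
                             "chrom2": "chr2", "start2": 0, "end2": 10})
        loops = pd.DataFrame(rows)
        prom = pd.Series(False, index=clusters["cluster_id"])
        res = hmod.enrich_by_loop_count(pot, clusters, loops, prom)
        effects = res.set_index("term")["effect"]
        ordered = [effects.get("1"), effects.get("[2,4)"), effects.get("[4,13)"),
                   effects.get("[13,209)")]
        ordered = [e for e in ordered if e is not None]
        assert all(a <= b for a, b in zip(ordered, ordered[1:]))

    def test_no_loops_no_contrasts(self):
        clusters = clusters_at([100, 200, 300])
        pot = pot_frame([1.0, 2.0, 3.0])
        prom = pd.Series(False, index=clusters["cluster_id"])
        with pytest.warns(UserWarning):
            res = hmod.enrich_by_loop_count(
                pot, clusters, pd.DataFrame(columns=["chrom1", "start1", "end1",
                                                     "chrom2", "start2", "end2"]), prom
            )
        assert res.empty


class TestEnrichHubness:
    def make_calls(self, potentials, is_hub):
        tab = pot_frame(potentials)
        tab["is_hub"] = is_hub
        return hmod.HubCalls(tab, threshold=0.0)

    def test_planted_odds_ratio_recovered(self):
        rng = np.random.default_rng(10)
        n = 2000
        in_state = rng.random(n) < 0.5
        base_p = 0.1
        odds = base_p / (1 - base_p) * np.where(in_state, 4.0, 1.0)
        p = odds / (1 + odds)
        is_hub = rng.random(n) < p
        pot = np.abs(rng.normal(1, 0.5, n))  # all positive potential
        calls = self.make_calls(pot, is_hub)
        grouping = pd.Series(np.where(in_state, "S", "ref"),
                             index=calls.table["cluster_id"])
        res = hmod.enrich_hubness(calls, grouping, reference="ref").set_index("term")
        assert res.loc["S", "ci_low"] < np.log(4) < res.loc["S", "ci_high"]

    def test_null_covers_zero(self):
        rng = np.random.default_rng(11)
        cover = 0
        reps = 20
        for rep in range(reps):
            n = 400
            is_hub = rng.random(n) < 0.15
            grp = rng.random(n) < 0.5
            calls = self.make_calls(np.abs(rng.normal(1, 0.5, n)), is_hub)
            grouping = pd.Series(np.where(grp, "S", "ref"), index=calls.table["cluster_id"])
            res = hmod.enrich_hubness(calls, grouping, reference="ref").set_index("term")
            if res.loc["S", "ci_low"] <= 0 <= res.loc["S", "ci_high"]:
                cover += 1
        assert cover >= 0.9 * reps - 2

    def test_separation_fallback(self):
        is_hub = [True] * 20 + [False] * 20
        grp = ["S"] * 20 + ["ref"] * 20
        calls = self.make_calls(np.abs(np.random.default_rng(1).normal(1, 0.2, 40)), is_hub)
        grouping = pd.Series(grp, index=calls.table["cluster_id"])
        with pytest.warns(UserWarning, match="separation|penalized"):
            res = hmod.enrich_hubness(calls, grouping, reference="ref")
        assert np.isfinite(res.set_index("term").loc["S", "effect"])
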