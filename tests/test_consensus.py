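"""Consensus aggregation, contribution scores, distance detrending and
regulatory potential."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from methlink import consensus as cmod
from methlink.expression import CancerNetwork, GeneModelFit


def fit(gene, coefs, r2, cancer="c0", k_g=None):
    s = pd.Series(coefs, dtype=float)
    s.index.name = "cluster_id"
    return GeneModelFit(gene, cancer, s, {}, 0.1, 0.5, r2, k_g or len(s))


def net(cancer, fits):
    return CancerNetwork(cancer, fits)


def adjacency_for(consensus_edges, k_g_map):
    rows = []
    for g, k in k_g_map.items():
        for i in range(k):
            rows.append({"gene_id": g, "cluster_id": f"{g}_cand{i}", "abs_distance": 1000 * (i + 1),
                         "signed_distance": 1000 * (i + 1), "overlaps_gene_body": False,
                         "overlaps_promoter": False})
    adj = pd.DataFrame(rows)
    # make sure consensus clusters are present as candidates
    extra = consensus_edges[~consensus_edges["cluster_id"].isin(adj["cluster_id"])]
    return adj


class TestBuildConsensus:
    def test_single_cohort_identity(self):
        n = net("c0", [fit("g1", {"a": -2.0, "b": 0.0, "c": 1.0}, 0.5)])
        cons = cmod.build_consensus([n]).set_index("cluster_id")
        assert set(cons.index) == {"a", "c"}
        assert cons.loc["a", "consensus_coef"] == -2.0
        assert cons.loc["a", "robustness"] == 1
        assert cons.loc["a", "direction"] == "activating"
        assert cons.loc["c", "direction"] == "repressing"

    def test_weighted_mean_arithmetic(self):
        n1 = net("c0", [fit("g1", {"a": -2.0}, 0.5, "c0")])
        n2 = net("c1", [fit("g1", {"a": 0.0, "b": 1.0}, 0.5, "c1")])
        cons = cmod.build_consensus([n1, n2]).set_index("cluster_id")
        assert cons.loc["a", "consensus_coef"] == pytest.approx(-1.0)
        assert cons.loc["a", "robustness"] == 1

    def test_negative_r2_clipped(self):
        n1 = net("c0", [fit("g1", {"a": -2.0}, -0.3, "c0")])
        n2 = net("c1", [fit("g1", {"a": -1.0}, 0.5, "c1")])
        cons = cmod.build_consensus([n1, n2]).set_index("cluster_id")
        assert cons.loc["a", "consensus_coef"] == pytest.approx(-1.0)  # weight 0 for cohort 0

    def test_absent_gene_treated_missing(self):
        n1 = net("c0", [fit("g1", {"a": -2.0}, 0.5, "c0")])
        n2 = net("c1", [fit("g2", {"z": 1.0}, 0.5, "c1")])
        cons = cmod.build_consensus([n1, n2]).set_index("cluster_id")
        assert cons.loc["a", "consensus_coef"] == pytest.approx(-2.0)

    def test_core_edges_more_robust(self, small_study):
        from methlink.expression import fit_cancer_network

        nets = [
            fit_cancer_network(ds, small_study["adjacency"], seed=1)
            for ds in small_study["datasets"]
        ]
        cons = cmod.build_consensus(nets)
        truth = small_study["truth"].edges
        merged = cons.merge(truth, on=["gene_id", "cluster_id"])
        core = merged.loc[merged["scope"] == "core", "robustness"]
        spec = merged.loc[merged["scope"] != "core", "robustness"]
        assert core.median() > spec.median()


class TestComputeScores:
    def kg_adj(self, gene, k):
        return pd.DataFrame(
            {
                "gene_id": gene,
                "cluster_id": [f"cand{i}" for i in range(k)],
                "abs_distance": np.arange(k) + 1,
                "signed_distance": np.arange(k) + 1,
                "overlaps_gene_body": False,
                "overlaps_promoter": False,
            }
        )

    def test_single_association_log_kg(self):
        cons = pd.DataFrame(
            {"gene_id": ["g1"], "cluster_id": ["cand0"], "consensus_coef": [-0.8],
             "robustness": [1]}
        )
        scored = cmod.compute_scores(cons, self.kg_adj("g1", 400))
        assert scored["score"].iloc[0] == pytest.approx(np.log(400), abs=1e-12)

    def test_equal_contributions_score_zero(self):
        k = 7
        cons = pd.DataFrame(
            {"gene_id": "g1", "cluster_id": [f"cand{i}" for i in range(k)],
             "consensus_coef": [0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5], "robustness": 1}
        )
        scored = cmod.compute_scores(cons, self.kg_adj("g1", k))
        np.testing.assert_allclose(scored["score"], 0.0, atol=1e-12)

    def test_hand_arithmetic(self):
        # |b| = 0.3 of a 1.0 total, k_g = 10 -> ln 3
        cons = pd.DataFrame(
            {"gene_id": "g1", "cluster_id": ["cand0", "cand1"],
             "consensus_coef": [0.3, -0.7], "robustness": 1}
        )
        scored = cmod.compute_scores(cons, self.kg_adj("g1", 10)).set_index("cluster_id")
        assert scored.loc["cand0", "score"] == pytest.approx(np.log(3), abs=1e-12)

    def test_share_identity_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        k = 20
        coefs = rng.normal(0, 1, 8)
        cons = pd.DataFrame(
            {"gene_id": "g1", "cluster_id": [f"cand{i}" for i in range(8)],
             "consensus_coef": coefs, "robustness": 1}
        )
        adj = self.kg_adj("g1", k)
        scored = cmod.compute_scores(cons, adj)
        # sum of relative shares exp(b - ln k_g) is 1
        assert np.exp(scored["score"] - np.log(k)).sum() == pytest.approx(1.0)
        cons2 = cons.assign(consensus_coef=coefs * 7.3)
        scored2 = cmod.compute_scores(cons2, adj)
        np.testing.assert_allclose(scored["score"], scored2["score"], atol=1e-12)


def synth_scored(n=400, decay=None, seed=0, frac_flagged=0.1):
    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 1_000_000, n)
    b = rng.normal(0, 1, n)
    if decay is not None:
        b = b + decay(d)
    flagged = rng.random(n) < frac_flagged
    return pd.DataFrame(
        {
            "gene_id": [f"g{i % 20}" for i in range(n)],
            "cluster_id": [f"cl{i}" for i in range(n)],
            "score": b,
            "abs_distance": d,
            "overlaps_gene_body": flagged,
            "overlaps_promoter": False,
        }
    )


class TestDistanceTrend:
    def test_flat_scores_give_constant_trend(self):
        scored = synth_scored(seed=1)
        f, out = cmod.fit_distance_trend(scored)
        train = out[~out["overlaps_gene_body"] & ~out["overlaps_promoter"]]
        sd = train["score"].std()
        assert (train["trend"] - train["score"].mean()).abs().max() < 0.15 * sd
        # training residuals centered
        assert abs(train["residual"].mean()) < 1e-6 * sd

    def test_planted_decay_removed(self):
        scored = synth_scored(n=600, decay=lambda d: 3 - d / 500_000, seed=2)
        f, out = cmod.fit_distance_trend(scored)
        train = out[~out["overlaps_gene_body"] & ~out["overlaps_promoter"]]
        rho = spearmanr(train["residual"], train["abs_distance"]).statistic
        assert abs(rho) < 0.05
        # trend decreasing over the bulk
        grid = np.linspace(50_000, 950_000, 10)
        fv = f(grid)
        assert fv[0] > fv[-1]

    def test_excluded_edges_still_detrended(self):
        scored = synth_scored(n=300, seed=3, frac_flagged=0.3)
        _, out = cmod.fit_distance_trend(scored)
        assert out["residual"].notna().all()
        flagged = out[out["overlaps_gene_body"]]
        np.testing.assert_allclose(
            flagged["residual"], flagged["score"] - flagged["trend"], atol=1e-12
        )

    def test_few_edges_constant_fallback(self):
        scored = synth_scored(n=20, seed=4, frac_flagged=0.0)
        with pytest.warns(UserWarning, match="constant"):
            f, out = cmod.fit_distance_trend(scored)
        assert np.allclose(out["trend"], out["score"].mean())


class TestPotential:
    def test_sums_and_linearity(self):
        scored = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "cluster_id": ["a", "a", "b"],
             "residual": [1.0, 2.0, 0.0]}
        )
        pot = cmod.compute_potential(scored).set_index("cluster_id")
        assert pot.loc["a", "potential"] == pytest.approx(3.0)
        assert pot.loc["a", "n_assoc"] == 2
        assert pot.loc["b", "potential"] == 0.0

    def test_brute_force_recomputation(self):
        scored = synth_scored(n=500, seed=6)
        _, out = cmod.fit_distance_trend(scored)
        out["cluster_id"] = [f"cl{i % 40}" for i in range(len(out))]
        pot = cmod.compute_potential(out).set_index("cluster_id")
        for cid in pot.index:
            expected = out.loc[out["cluster_id"] == cid, "residual"].sum()
            assert pot.loc[cid, "potential"] == pytest.approx(expected, abs=1e-9)


class TestRankProfile:
    def test_hand_toy(self, small_study):
        cm = small_study["cluster_map"]
        adj = small_study["adjacency"]
        gene = adj["gene_id"].iloc[0]
        sub = adj[(adj["gene_id"] == gene) & adj["rank"].notna()].head(4)
        cons = pd.DataFrame(
            {
                "gene_id": gene,
                "cluster_id": sub["cluster_id"].to_numpy(),
                "consensus_coef": [-1.0, 0.0, 2.0, 0.0][: len(sub)],
                "robustness": 1,
            }
        )
        cons = cons[cons["consensus_coef"] != 0]
        prof = cmod.distance_rank_profile(cons, adj[adj["gene_id"] == gene], cm)
        in_cgi = cm.clusters.set_index("cluster_id")["in_cgi"]
        for _, row in prof.iterrows():
            grp = adj[(adj["gene_id"] == gene) & (adj["rank"] == row["rank"])]
            grp = grp[grp["cluster_id"].map(in_cgi).map(
                {True: "island", False: "non-island"}) == row["category"]]
            coefs = [
                float(cons.loc[cons["cluster_id"] == c, "consensus_coef"].sum())
                for c in grp["cluster_id"]
            ]
            assert row["mean_coefficient"] == pytest.approx(np.mean(coefs))
            assert row["probability"] == pytest.approx(np.mean([c != 0 for c in coefs]))
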