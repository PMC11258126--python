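"""Consensus network, contribution scores, distance detrending, and
per-element regulatory potential.

The per-cohort networks are averaged into a consensus with weights equal to
each cohort model's cross-validated R^2 (clipped at zero).  Each retained
edge then gets a contribution score

    b_gc = ln(|beta_gc| / sum_c |beta_gc|) - ln(1 / k_g)

i.e. the log excess of the edge's relative coefficient share over the
uniform 1/k_g share of a null model in which all k_g candidate neighbours
of the gene contribute equally.  Distance acts on every element alike, so
its trend f(d) is estimated with a penalized-spline GAM of b_gc on the
absolute TSS-cluster distance (gene-body and promoter edges excluded from
the fit, which would otherwise confound it) and removed.  The regulatory
potential of an element is the sum of its distance-adjusted scores,

    b_c = sum_g (b_gc - f(d_gc)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

MIN_TREND_EDGES = 50


def build_consensus(networks: list) -> pd.DataFrame:
    """R^2-weighted average of per-cohort coefficients.

    For each edge, cohorts in which the gene was modelled contribute their
    coefficient (zero when the cluster was not selected) with weight
    max(cv_r2, 0); cohorts where the gene failed the variance filter are
    treated as missing.  Edges nonzero in no cohort are dropped.
    Returns columns ``gene_id, cluster_id, consensus_coef, robustness,
    direction``.
    """
    if not networks:
        raise ValueError("need at least one cohort network")
    # per-cohort lookup: gene -> (weight, coefficient Series over nonzero clusters)
    per_cohort = []
    for net in networks:
        d = {f.gene_id: (max(f.cv_r2, 0.0), f.nonzero) for f in net.fits}
        per_cohort.append(d)

    genes = sorted({g for d in per_cohort for g in d})
    rows = []
    for g in genes:
        present = [d[g] for d in per_cohort if g in d]
        edge_ids = sorted({c for _, nz in present for c in nz.index})
        if not edge_ids:
            continue
        W = np.array([w for w, _ in present])
        B = np.array([[nz.get(c, 0.0) for c in edge_ids] for _, nz in present])
        if W.sum() == 0:
            warnings.warn(f"gene {g}: all cohort weights zero, using unweighted mean", stacklevel=2)
            coef = B.mean(axis=0)
        else:
            coef = (W[:, None] * B).sum(axis=0) / W.sum()
        robust = (B != 0).sum(axis=0)
        for c, v, r in zip(edge_ids, coef, robust):
            if r > 0:
                rows.append({"gene_id": g, "cluster_id": c, "consensus_coef": v, "robustness": int(r)})
    out = pd.DataFrame(rows, columns=["gene_id", "cluster_id", "consensus_coef", "robustness"])
    out["direction"] = np.where(out["consensus_coef"] < 0, "activating", "repressing")
    return out


def compute_scores(consensus: pd.DataFrame, adjacency: pd.DataFrame) -> pd.DataFrame:
    """Contribution score b_gc for every consensus edge.

    k_g is the gene's full candidate count from the adjacency network; the
    normalizing sum runs over the gene's retained consensus edges.  Genes
    whose coefficients all vanished are skipped.
    """
    k_g = adjacency.groupby("gene_id")["cluster_id"].size()
    scored = consensus.copy()
    absb = scored["consensus_coef"].abs()
    # opposite-sign cohorts can cancel to an exactly-zero consensus
    # coefficient; such edges carry no effect size and are not scored
    total = absb.groupby(scored["gene_id"]).transform("sum")
    keep = (total > 0) & (absb > 0)
    scored = scored[keep].copy()
    scored["score"] = np.log(absb[keep] / total[keep]) + np.log(
        scored["gene_id"].map(k_g).astype(float)
    )
    flags = adjacency.set_index(["gene_id", "cluster_id"])
    idx = pd.MultiIndex.from_frame(scored[["gene_id", "cluster_id"]])
    for col in ("abs_distance", "signed_distance", "overlaps_gene_body", "overlaps_promoter"):
        if col in flags.columns:
            scored[col] = flags[col].reindex(idx).to_numpy()
    return scored.reset_index(drop=True)


def fit_distance_trend(scored: pd.DataFrame, df_spline: int = 20):
    """Fit and remove the distance trend f(d) from the scores.

    A Gaussian GAM with a penalized cubic B-spline basis (up to
    ``df_spline`` functions, penalty weight chosen by generalized cross
    validation) is trained on edges overlapping neither the gene body nor a
    promoter.  f is evaluated for *all* edges, clamped to its boundary
    values outside the training distance range, and the residual
    ``score - f(d)`` is the distance-adjusted score.

    Returns ``(predict_f, scored)`` where ``predict_f`` maps distances to
    trend values and ``scored`` has ``trend`` and ``residual`` columns.
    """
    train = scored[
        ~scored["overlaps_gene_body"]
        & ~scored["overlaps_promoter"]
        & np.isfinite(scored["score"])
    ]
    y = train["score"].to_numpy(dtype=float)
    d = train["abs_distance"].to_numpy(dtype=float)

    if len(train) < MIN_TREND_EDGES or np.ptp(d) == 0:
        warnings.warn(
            f"only {len(train)} training edges for the distance trend; using constant f",
            stacklevel=2,
        )
        const = float(y.mean()) if len(y) else 0.0

        def predict_f(dist):
            return np.full(np.shape(np.atleast_1d(dist)), const)

    else:
        lo, hi = float(d.min()), float(d.max())
        # normalize distance to [0, 1]: the curvature penalty scales with
        # the cube of the predictor range, so raw base-pair units would push
        # the GCV optimum to astronomically large penalty weights
        du = (d - lo) / (hi - lo)
        df_use = int(min(df_spline, max(5, len(train) // 10)))
        smoother = BSplines(du[:, None], df=[df_use], degree=[3])
        gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=smoother)
        try:
            gam.fit()  # initializes scale before the penalty-weight search
            alpha = float(np.squeeze(gam.select_penweight(criterion="gcv")[0]))
        except Exception:  # optimizer hiccup: fall back to a mild penalty
            alpha = 1.0
        alpha = float(np.clip(alpha, 1e-10, 1e10))
        res = GLMGam(y, exog=np.ones((len(y), 1)), smoother=smoother, alpha=alpha).fit()

        def _raw(dist):
            dist = np.clip(np.asarray(dist, dtype=float), lo, hi)
            u = (dist - lo) / (hi - lo)
            return np.asarray(
                res.predict(np.ones((u.size, 1)), exog_smooth=u.reshape(-1, 1))
            )

        # re-center so the training residuals average exactly zero
        offset = float(np.mean(y - _raw(d)))

        def predict_f(dist):
            return _raw(dist) + offset

    out = scored.copy()
    out["trend"] = predict_f(out["abs_distance"].to_numpy(dtype=float))
    out["residual"] = out["score"] - out["trend"]
    return predict_f, out


def compute_potential(scored: pd.DataFrame, cluster_beta_variance: pd.Series | None = None) -> pd.DataFrame:
    """Regulatory potential per element: the sum of its residual scores.

    Returns ``cluster_id, potential, n_assoc`` (+ ``beta_variance`` when a
    per-cluster cross-cohort methylation variance Series is supplied).
    """
    grp = scored.groupby("cluster_id")["residual"]
    out = pd.DataFrame({"potential": grp.sum(), "n_assoc": grp.size()}).reset_index()
    if cluster_beta_variance is not None:
        out["beta_variance"] = out["cluster_id"].map(cluster_beta_variance)
    return out


def distance_rank_profile(consensus: pd.DataFrame, adjacency: pd.DataFrame, cluster_map) -> pd.DataFrame:
    """Mean distance, mean coefficient and association probability per
    (island-category, distance-rank) group.

    All candidate edges count: a candidate with no consensus edge enters
    with coefficient zero, so the probability column is the fraction of
    candidates that carry a nonzero consensus coefficient.
    """
    adj = adjacency.copy()
    in_cgi = cluster_map.clusters.set_index("cluster_id")["in_cgi"]
    adj["category"] = np.where(adj["cluster_id"].map(in_cgi).astype(bool), "island", "non-island")
    coef = consensus.set_index(["gene_id", "cluster_id"])["consensus_coef"]
    idx = pd.MultiIndex.from_frame(adj[["gene_id", "cluster_id"]])
    adj["coef"] = coef.reindex(idx).fillna(0.0).to_numpy()
    adj = adj[adj["rank"].notna()]
    rows = []
    for (cat, rank), grp in adj.groupby(["category", "rank"]):
        rows.append(
            {
                "category": cat,
                "rank": int(rank),
                "mean_distance": float(grp["abs_distance"].mean()),
                "mean_coefficient": float(grp["coef"].mean()),
                "probability": float((grp["coef"] != 0).mean()),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows).sort_values(["category", "rank"]).reset_index(drop=True)
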