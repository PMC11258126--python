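"""Regulatory-hub calling and enrichment of potential across chromatin
annotations, factor binding and loop connectivity.

Hubs are elements in the long right tail of the potential distribution,
found with an elbow rule on the sorted-potential curve.  Enrichments are
ordinary linear models of potential on annotation indicators (logistic for
hub-vs-non-hub), reported as effect +/- stderr with 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree

DEFAULT_LOOP_GROUPS = ((0, 1), (1, 2), (2, 4), (4, 13), (13, 209))
ENRICH_COLUMNS = ["term", "effect", "stderr", "ci_low", "ci_high", "n"]


@dataclass
class HubCalls:
    table: pd.DataFrame  # cluster_id, potential, is_hub
    threshold: float
    method: str = "elbow"
    low_confidence: bool = False

    @property
    def hub_ids(self) -> list:
        return list(self.table.loc[self.table["is_hub"], "cluster_id"])


def call_hubs(potentials: pd.DataFrame) -> HubCalls:
    """Elbow-threshold hub calling on the sorted potential curve.

    Potentials are sorted descending; the threshold sits at the point of
    maximum perpendicular distance from the chord joining the curve's
    endpoints (ties broken toward the stricter, higher threshold).
    Elements strictly above the threshold are hubs.
    """
    if len(potentials) < 10:
        raise ValueError("need at least 10 elements to call hubs")
    p = np.sort(potentials["potential"].to_numpy(dtype=float))[::-1]
    n = len(p)
    if p[0] == p[-1]:
        warnings.warn("all potentials equal; no hubs called", stacklevel=2)
        thr = float(p[0])
        tab = potentials.copy()
        tab["is_hub"] = False
        return HubCalls(tab, thr, low_confidence=True)
    x = np.arange(n, dtype=float)
    # perpendicular distance of each curve point from the endpoint chord
    dx, dy = x[-1] - x[0], p[-1] - p[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (p - p[0])) / norm
    elbow = int(np.argmax(dist))  # argmax takes the first (stricter) tie
    low_conf = dist[elbow] < 0.01 * norm
    if dist[elbow] <= 1e-9 * norm:
        # exactly linear curve: no elbow exists; fall back to the midpoint
        elbow = n // 2
    thr = float(p[elbow])
    if low_conf:
        warnings.warn("weak elbow: hub threshold is low-confidence", stacklevel=2)
    tab = potentials.copy()
    tab["is_hub"] = tab["potential"] > thr
    return HubCalls(tab, thr, low_confidence=low_conf)


def _interval_tree(track: pd.DataFrame) -> dict:
    trees: dict = {}
    for i, row in track.reset_index(drop=True).iterrows():
        if row["end"] <= row["start"]:
            continue
        trees.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], (i, row["label"]))
    return trees


def assign_state(clusters: pd.DataFrame, track: pd.DataFrame, default: str | None = None) -> pd.Series:
    """Label each cluster with the annotation state of largest overlap.

    ``track`` has half-open intervals with columns ``chrom, start, end,
    label``.  Ties go to the earlier interval in track order; clusters with
    no overlap get ``default`` (or raise when default is None).
    """
    trees = _interval_tree(track)
    labels = {}
    for _, c in clusters.iterrows():
        tree = trees.get(c["chrom"])
        hits = tree.overlap(c["start"], c["end"] + 1) if tree is not None else set()
        if not hits:
            if default is None:
                raise KeyError(f"cluster {c['cluster_id']} overlaps no annotation interval")
            labels[c["cluster_id"]] = default
            continue
        best = max(
            hits,
            key=lambda iv: (
                min(iv.end, c["end"] + 1) - max(iv.begin, c["start"]),
                -iv.data[0],
            ),
        )
        labels[c["cluster_id"]] = best.data[1]
    return pd.Series(labels, name="state")


def _ols_results(model_res, terms, n_per_term) -> pd.DataFrame:
    ci = model_res.conf_int()
    rows = []
    for t in terms:
        rows.append(
            {
                "term": t,
                "effect": float(model_res.params[t]),
                "stderr": float(model_res.bse[t]),
                "ci_low": float(ci.loc[t, 0]),
                "ci_high": float(ci.loc[t, 1]),
                "n": int(n_per_term.get(t, 0)),
            }
        )
    return pd.DataFrame(rows, columns=ENRICH_COLUMNS)


def enrich_potential_by_state(
    potentials: pd.DataFrame, states: pd.Series, reference_label: str = "Low Signal"
) -> pd.DataFrame:
    """Mean potential difference of each annotation state vs the reference.

    Fits potential ~ state indicators with the reference state as baseline;
    on a balanced design the effects equal direct group-mean differences.
    """
    df = potentials.copy()
    df["state"] = df["cluster_id"].map(states)
    if reference_label not in set(df["state"]):
        raise ValueError(f"reference label {reference_label!r} absent")
    others = sorted(set(df["state"]) - {reference_label})
    if not others:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    X = pd.DataFrame({t: (df["state"] == t).astype(float) for t in others})
    X = sm.add_constant(X)
    res = sm.OLS(df["potential"].to_numpy(dtype=float), X).fit()
    return _ols_results(res, others, df["state"].value_counts())


def enrich_potential_by_factor(potentials: pd.DataFrame, memberships: pd.DataFrame) -> pd.DataFrame:
    """Joint regression of potential on overlapping factor-binding indicators.

    ``memberships`` is clusters x factors boolean; the baseline is unbound
    chromatin and each factor's effect is its partial mean shift.  Perfectly
    collinear factor columns are dropped with a warning.
    """
    mem = memberships.reindex(potentials["cluster_id"]).fillna(False).astype(float)
    keep = []
    seen = {}
    for col in mem.columns:
        key = tuple(mem[col].to_numpy())
        if mem[col].std() == 0:
            warnings.warn(f"factor {col!r} constant; dropped", stacklevel=2)
            continue
        if key in seen:
            warnings.warn(f"factor {col!r} collinear with {seen[key]!r}; dropped", stacklevel=2)
            continue
        seen[key] = col
        keep.append(col)
    if not keep:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    X = sm.add_constant(mem[keep])
    res = sm.OLS(potentials["potential"].to_numpy(dtype=float), X).fit()
    return _ols_results(res, keep, mem[keep].sum())


def count_loops_per_cluster(clusters: pd.DataFrame, loops: pd.DataFrame) -> pd.Series:
    """Number of loops with >= 1 anchor overlapping each cluster interval."""
    counts = pd.Series(0, index=clusters["cluster_id"], dtype=int)
    trees: dict = {}
    for _, c in clusters.iterrows():
        trees.setdefault(c["chrom"], IntervalTree()).addi(
            int(c["start"]), int(c["end"]) + 1, c["cluster_id"]
        )
    for _, lp in loops.iterrows():
        hit_ids = set()
        for chrom, s, e in (
            (lp["chrom1"], lp["start1"], lp["end1"]),
            (lp["chrom2"], lp["start2"], lp["end2"]),
        ):
            tree = trees.get(chrom)
            if tree is not None:
                hit_ids |= {iv.data for iv in tree.overlap(int(s), int(e))}
        for cid in hit_ids:
            counts[cid] += 1
    return counts


def loop_count_group(count: int, groups=DEFAULT_LOOP_GROUPS) -> str:
    """Bin a loop count into its connectivity group (top group open-ended)."""
    lo_top = groups[-1][0]
    if count >= lo_top:
        return f"[{groups[-1][0]},{groups[-1][1]})"
    for lo, hi in groups[:-1]:
        if lo <= count < hi:
            return str(lo) if hi == lo + 1 else f"[{lo},{hi})"
    raise ValueError(f"negative loop count {count}")


def enrich_by_loop_count(
    potentials: pd.DataFrame,
    clusters: pd.DataFrame,
    loops: pd.DataFrame,
    promoter_flags: pd.Series,
    groups=DEFAULT_LOOP_GROUPS,
) -> pd.DataFrame:
    """Potential as a function of loop-connectivity group.

    Promoter-overlapping elements are removed first (the analysis targets
    enhancer-like elements); the zero-loop group is the model intercept and
    is not reported as a contrast.
    """
    keep = ~potentials["cluster_id"].map(promoter_flags).astype(bool)
    pot = potentials[keep].copy()
    counts = count_loops_per_cluster(clusters[clusters["cluster_id"].isin(pot["cluster_id"])], loops)
    pot["group"] = pot["cluster_id"].map(counts).fillna(0).astype(int).map(
        lambda k: loop_count_group(k, groups)
    )
    terms = [loop_count_group(g[0], groups) for g in groups[1:]]
    present = [t for t in terms if (pot["group"] == t).any()]
    for t in set(terms) - set(present):
        warnings.warn(f"loop group {t} empty; omitted", stacklevel=2)
    if not present:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    X = sm.add_constant(pd.DataFrame({t: (pot["group"] == t).astype(float) for t in present}))
    res = sm.OLS(pot["potential"].to_numpy(dtype=float), X).fit()
    return _ols_results(res, present, pot["group"].value_counts())


def enrich_hubness(hub_calls: HubCalls, grouping: pd.Series, reference: str | None = None) -> pd.DataFrame:
    """Log-odds of being a hub per annotation group, among elements with
    positive potential.

    Logistic regression of is_hub on group indicators; under complete
    separation a ridge-penalized fit is reported with a warning.
    """
    df = hub_calls.table[hub_calls.table["potential"] > 0].copy()
    df["group"] = df["cluster_id"].map(grouping)
    levels = sorted(df["group"].dropna().unique())
    if reference is None:
        reference = levels[0]
    terms = [g for g in levels if g != reference]
    if not terms:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    X = sm.add_constant(pd.DataFrame({t: (df["group"] == t).astype(float) for t in terms}))
    y = df["is_hub"].astype(float).to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0)
        if not np.isfinite(res.bse).all() or (np.abs(res.params) > 15).any():
            raise np.linalg.LinAlgError("separation")
        return _ols_results(res, terms, df["group"].value_counts())
    except Exception:
        warnings.warn(
            "separation or non-convergence in hubness model; penalized fallback", stacklevel=2
        )
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        ci = pd.DataFrame(
            {0: res.params - 1.96, 1: res.params + 1.96}, index=res.params.index
        )
        rows = [
            {
                "term": t,
                "effect": float(res.params[t]),
                "stderr": float("nan"),
                "ci_low": float(ci.loc[t, 0]),
                "ci_high": float(ci.loc[t, 1]),
                "n": int((df["group"] == t).sum()),
            }
            for t in terms
        ]
        return pd.DataFrame(rows, columns=ENRICH_COLUMNS)
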