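"""Concordance of methylation-derived associations with chromatin loops.

Loops arrive as BEDPE anchor pairs at a fixed resolution (5 kb by default).
An association overlaps a loop when one anchor intersects the regulatory
element and the other intersects the gene promoter (TSS +/- the anchor
resolution); only associations spanning at least twice the anchor
resolution (10 kb) are informative and shorter ones are dropped.  Bin-level
potential (sum of element potentials per genomic bin) is evaluated as a
predictor of multi-loop "chromatin hubs" with ROC/AUC sweeps over the
loop-count threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
DEFAULT_ANCHOR_RESOLUTION = 5_000
DEFAULT_MIN_LENGTH = 10_000
DEFAULT_LOOP_THRESHOLDS = (1, 2, 3, 5, 8)


@dataclass
class LoopSet:
    """Chromatin loops with two half-open anchors per record."""

    loops: pd.DataFrame
    anchor_resolution: int = DEFAULT_ANCHOR_RESOLUTION

    def __post_init__(self):
        missing = set(BEDPE_COLUMNS) - set(self.loops.columns)
        if missing:
            raise ValueError(f"loop table missing columns {sorted(missing)}")
        bad = (self.loops["end1"] <= self.loops["start1"]) | (
            self.loops["end2"] <= self.loops["start2"]
        )
        if bad.any():
            raise ValueError("degenerate loop anchors")
        if "source" not in self.loops.columns:
            self.loops = self.loops.assign(source="loops")

    @property
    def intra(self) -> pd.DataFrame:
        return self.loops[self.loops["chrom1"] == self.loops["chrom2"]]

    @staticmethod
    def union(parts: list["LoopSet"]) -> "LoopSet":
        res = parts[0].anchor_resolution
        return LoopSet(pd.concat([p.loops for p in parts], ignore_index=True), res)


def _anchor_trees(loops: pd.DataFrame):
    t1: dict = {}
    t2: dict = {}
    for i, lp in loops.reset_index(drop=True).iterrows():
        t1.setdefault(lp["chrom1"], IntervalTree()).addi(int(lp["start1"]), int(lp["end1"]), i)
        t2.setdefault(lp["chrom2"], IntervalTree()).addi(int(lp["start2"]), int(lp["end2"]), i)
    return t1, t2


def _hits(trees, chrom, start, end):
    tree = trees.get(chrom)
    if tree is None or end <= start:
        return set()
    return {iv.data for iv in tree.overlap(start, end)}


def overlap_associations(
    scored: pd.DataFrame,
    cluster_map,
    genes: pd.DataFrame,
    loops: LoopSet,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Flag each association (>= ``min_len`` bp) as loop-supported or not.

    A loop supports an association when one anchor intersects the cluster
    interval and the other intersects the gene promoter window
    (TSS +/- anchor resolution); anchor order does not matter.
    """
    table = scored[scored["abs_distance"] >= min_len].copy()
    lp = loops.intra.reset_index(drop=True)
    t1, t2 = _anchor_trees(lp)
    cl = cluster_map.clusters.set_index("cluster_id")
    ge = genes.set_index("gene_id")
    res = loops.anchor_resolution

    flags = []
    for _, row in table.iterrows():
        c = cl.loc[row["cluster_id"]]
        g = ge.loc[row["gene_id"]]
        c_iv = (c["chrom"], int(c["start"]), int(c["end"]) + 1)
        g_iv = (g["chrom"], int(g["tss"]) - res, int(g["tss"]) + res)
        a1c, a2c = _hits(t1, *c_iv), _hits(t2, *c_iv)
        a1g, a2g = _hits(t1, *g_iv), _hits(t2, *g_iv)
        flags.append(bool((a1c & a2g) or (a2c & a1g)))
    table["overlaps_loop"] = flags
    return table


def binned_overlap_probability(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Loop-overlap probability per score-quantile bin.

    Associations are binned by score deciles (by default) and a saturated
    logistic model of the overlap flag on bin indicators gives the per-bin
    probability with a 95% CI; single-class bins fall back to a Wilson
    interval.
    """
    tab = table.copy()
    tab["bin"] = pd.qcut(tab["score"].rank(method="first"), n_bins, labels=False)
    present = sorted(tab["bin"].unique())
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty score bins")
    rows = []
    for b in present:
        sub = tab[tab["bin"] == b]
        k, n = int(sub["overlaps_loop"].sum()), len(sub)
        if k == 0 or k == n:
            warnings.warn(f"bin {b} has a single outcome class; Wilson interval", stacklevel=2)
            lo, hi = proportion_confint(k, n, method="wilson")
            rows.append({"bin": int(b), "mean_score": float(sub["score"].mean()),
                         "probability": k / n, "ci_low": float(lo), "ci_high": float(hi), "n": n})
        else:
            X = np.ones((n, 1))
            fit = sm.Logit(sub["overlaps_loop"].astype(float).to_numpy(), X).fit(disp=0)
            ci = fit.conf_int()
            expit = lambda v: 1.0 / (1.0 + np.exp(-v))
            rows.append(
                {
                    "bin": int(b),
                    "mean_score": float(sub["score"].mean()),
                    "probability": float(expit(fit.params[0])),
                    "ci_low": float(expit(ci[0, 0])),
                    "ci_high": float(expit(ci[0, 1])),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def tile_bins(genes: pd.DataFrame, cluster_map, bin_size: int) -> pd.DataFrame:
    """Fixed-width genome tiling covering every gene and cluster."""
    rows = []
    spans: dict = {}
    for _, g in genes.iterrows():
        lo, hi = sorted((int(g["tss"]), int(g["tes"])))
        cur = spans.setdefault(g["chrom"], [lo, hi])
        cur[0], cur[1] = min(cur[0], lo), max(cur[1], hi)
    for _, c in cluster_map.clusters.iterrows():
        cur = spans.setdefault(c["chrom"], [int(c["start"]), int(c["end"])])
        cur[0], cur[1] = min(cur[0], int(c["start"])), max(cur[1], int(c["end"]))
    for chrom, (lo, hi) in sorted(spans.items()):
        start = (lo // bin_size) * bin_size
        for s in range(start, hi + 1, bin_size):
            rows.append({"chrom": chrom, "start": s, "end": s + bin_size})
    bins = pd.DataFrame(rows)
    bins["bin_id"] = bins["chrom"] + ":" + bins["start"].astype(str)
    return bins


def hub_prediction_auc(
    potentials: pd.DataFrame,
    cluster_map,
    genes: pd.DataFrame,
    loops: LoopSet,
    bin_size: int = DEFAULT_ANCHOR_RESOLUTION,
    loop_thresholds=DEFAULT_LOOP_THRESHOLDS,
    promoter_only: bool = False,
    min_positives: int = 5,
):
    """ROC/AUC of bin potential as a predictor of multi-loop bins.

    The genome is tiled into ``bin_size`` bins; each bin's potential is the
    sum of potentials of clusters whose midpoint falls in it, and its loop
    count is the number of loops with an anchor overlapping it.  For each
    threshold T, bins with >= T loops are the positive class.
    ``promoter_only`` restricts scoring to bins containing a TSS (capture
    designs enrich promoter-anchored contacts).  Returns ``(auc_table,
    roc_points)``.
    """
    bins = tile_bins(genes, cluster_map, bin_size)
    cl = cluster_map.clusters.merge(potentials, on="cluster_id", how="inner")
    cl["bin_start"] = (cl["midpoint"] // bin_size) * bin_size
    cl["bin_id"] = cl["chrom"] + ":" + cl["bin_start"].astype(str)
    bin_pot = cl.groupby("bin_id")["potential"].sum()
    bins["potential"] = bins["bin_id"].map(bin_pot).fillna(0.0)

    counts = pd.Series(0, index=bins["bin_id"], dtype=int)
    trees: dict = {}
    for _, b in bins.iterrows():
        trees.setdefault(b["chrom"], IntervalTree()).addi(b["start"], b["end"], b["bin_id"])
    for _, lp in loops.intra.iterrows():
        ids = _hits_ids(trees, lp)
        for bid in ids:
            counts[bid] += 1
    bins["loop_count"] = bins["bin_id"].map(counts).astype(int)

    tss_bins = set(
        genes["chrom"] + ":" + ((genes["tss"] // bin_size) * bin_size).astype(str)
    )
    bins["is_promoter_bin"] = bins["bin_id"].isin(tss_bins)
    eval_bins = bins[bins["is_promoter_bin"]] if promoter_only else bins

    auc_rows, roc_rows = [], []
    for t in loop_thresholds:
        y = (eval_bins["loop_count"] >= t).astype(int).to_numpy()
        if y.sum() < min_positives or y.sum() == len(y):
            warnings.warn(f"threshold {t}: too few class members; omitted", stacklevel=2)
            continue
        score = eval_bins["potential"].to_numpy()
        auc = float(roc_auc_score(y, score))
        fpr, tpr, _ = roc_curve(y, score)
        auc_rows.append({"threshold": int(t), "auc": auc, "n_pos": int(y.sum()), "n": len(y)})
        roc_rows.extend(
            {"threshold": int(t), "fpr": float(f), "tpr": float(p)} for f, p in zip(fpr, tpr)
        )
    return pd.DataFrame(auc_rows), pd.DataFrame(roc_rows), bins


def _hits_ids(trees, lp) -> set:
    ids = set()
    for chrom, s, e in (
        (lp["chrom1"], int(lp["start1"]), int(lp["end1"])),
        (lp["chrom2"], int(lp["start2"]), int(lp["end2"])),
    ):
        tree = trees.get(chrom)
        if tree is not None:
            ids |= {iv.data for iv in tree.overlap(s, e)}
    return ids
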