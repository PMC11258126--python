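"""Genomic scaffold: CpG probe clustering, beta aggregation, and the
gene--cluster candidate adjacency network.

Coordinates are 0-based internally.  Probe manifests follow the Illumina
1-based convention on disk and are converted on ingest (see :mod:`methlink.io`).
A *cluster* is a maximal group of CpG probes whose pairwise span does not
exceed a fixed diameter (complete linkage, 200 bp by default); its anchor
point for all distance computations is the midpoint (floor of the mean) of
its member probe positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

GENE_COLUMNS = ["gene_id", "chrom", "tss", "tes", "strand", "is_protein_coding"]

DEFAULT_DIAMETER = 200
DEFAULT_RADIUS = 1_000_000
DEFAULT_PROMOTER_HALFWIDTH = 2_000


def make_gene_table(records) -> pd.DataFrame:
    """Build a validated gene annotation table.

    Each record supplies ``gene_id, chrom, tss, tes, strand,
    is_protein_coding``.  For ``+`` genes tss < tes; for ``-`` genes the TSS
    is the larger genomic coordinate.
    """
    df = pd.DataFrame(list(records), columns=GENE_COLUMNS)
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    bad = df["tss"] == df["tes"]
    if bad.any():
        raise ValueError(f"genes with tss == tes: {df.loc[bad, 'gene_id'].tolist()}")
    plus = df["strand"] == "+"
    if (df.loc[plus, "tss"] >= df.loc[plus, "tes"]).any():
        raise ValueError("+ strand gene with tss >= tes")
    if (df.loc[~plus, "tss"] <= df.loc[~plus, "tes"]).any():
        raise ValueError("- strand gene with tss <= tes")
    return df.reset_index(drop=True)


@dataclass
class ClusterMap:
    """Partition of the probe set into CpG clusters.

    Attributes
    ----------
    clusters : DataFrame with columns ``cluster_id, chrom, start, end,
        midpoint, in_cgi, n_probes``.
    members : DataFrame with columns ``probe_id, cluster_id``.
    """

    clusters: pd.DataFrame
    members: pd.DataFrame

    def __post_init__(self):
        if self.members["probe_id"].duplicated().any():
            raise ValueError("a probe is assigned to more than one cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_positions(self, manifest: pd.DataFrame) -> pd.DataFrame:
        pos = manifest.set_index("probe_id")["pos"]
        out = self.members.copy()
        out["pos"] = out["probe_id"].map(pos)
        return out


def cluster_probes(manifest: pd.DataFrame, diameter: int = DEFAULT_DIAMETER) -> ClusterMap:
    """Collapse CpG probes into clusters of diameter <= ``diameter`` bp.

    Complete-linkage agglomeration per chromosome: the closest pair of
    clusters merges first, and merging stops when no merge keeps the maximum
    pairwise probe span within ``diameter`` (inclusive).  Returns a partition
    of the probe set.

    Parameters
    ----------
    manifest : DataFrame with columns ``probe_id, chrom, pos, in_cgi``
        (positions 0-based).  Sorted internally if needed.
    diameter : maximum pairwise span within a cluster, bp.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cols = ["cluster_id", "chrom", "start", "end", "midpoint", "in_cgi", "n_probes"]
    if len(manifest) == 0:
        return ClusterMap(
            clusters=pd.DataFrame(columns=cols),
            members=pd.DataFrame(columns=["probe_id", "cluster_id"]),
        )
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    cluster_rows = []
    member_rows = []
    counter = 0
    for chrom, grp in manifest.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=float)
        if len(grp) == 1:
            labels = np.array([1])
        else:
            # complete linkage on 1-D positions; cutting the dendrogram at
            # `diameter` yields exactly the merge-closest-first partition
            # with inclusive maximum pairwise span.
            Z = linkage(pos[:, None], method="complete")
            labels = fcluster(Z, t=diameter, criterion="distance")
        for lab in np.unique(labels):
            mask = labels == lab
            p = grp.loc[mask]
            counter += 1
            cid = f"cl{counter:06d}"
            cluster_rows.append(
                {
                    "cluster_id": cid,
                    "chrom": chrom,
                    "start": int(p["pos"].min()),
                    "end": int(p["pos"].max()),
                    "midpoint": int(np.floor(p["pos"].mean())),
                    "in_cgi": bool(p["in_cgi"].any()),
                    "n_probes": int(mask.sum()),
                }
            )
            member_rows.extend({"probe_id": pid, "cluster_id": cid} for pid in p["probe_id"])
    clusters = pd.DataFrame(cluster_rows, columns=cols)
    clusters = clusters.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return ClusterMap(clusters=clusters, members=pd.DataFrame(member_rows))


def aggregate_beta(cluster_map: ClusterMap, probe_beta: pd.DataFrame) -> pd.DataFrame:
    """Average probe beta values into cluster beta values per sample.

    ``probe_beta`` is probes x samples with values in [0, 1] or NaN.  A cell
    with all member probes missing stays NaN; downstream model fitting drops
    samples carrying any missing value.
    """
    missing = set(cluster_map.members["probe_id"]) - set(probe_beta.index)
    if missing:
        raise KeyError(f"probes absent from beta matrix: {sorted(missing)[:5]} ...")
    assign = cluster_map.members.set_index("probe_id")["cluster_id"]
    out = probe_beta.groupby(assign.reindex(probe_beta.index)).mean()
    out = out.reindex(cluster_map.clusters["cluster_id"])
    out.index.name = "cluster_id"
    return out


def build_adjacency(
    genes: pd.DataFrame,
    cluster_map: ClusterMap,
    radius: int = DEFAULT_RADIUS,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> pd.DataFrame:
    """Candidate gene--cluster edges within ``radius`` bp of each TSS.

    An edge (g, c) exists iff the gene and cluster share a chromosome and
    ``|TSS_g - midpoint_c| <= radius`` (inclusive).  The signed distance is
    strand-oriented: negative means the cluster lies 5' (upstream) of the
    promoter.  ``overlaps_gene_body`` marks clusters intersecting the gene
    span; ``overlaps_promoter`` marks clusters within ``promoter_halfwidth``
    of *any* gene's TSS.

    Genes should be restricted to protein-coding before this call; promoter
    flags still consider every TSS passed in.
    """
    cl = cluster_map.clusters
    edges = []
    all_tss = np.sort(genes["tss"].to_numpy())
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")}

    for chrom, cgrp in cl.groupby("chrom"):
        mids = cgrp["midpoint"].to_numpy()
        order = np.argsort(mids)
        mids_sorted = mids[order]
        cgrp_sorted = cgrp.iloc[order]
        gsub = genes[genes["chrom"] == chrom]
        for _, g in gsub.iterrows():
            lo = np.searchsorted(mids_sorted, g["tss"] - radius, side="left")
            hi = np.searchsorted(mids_sorted, g["tss"] + radius, side="right")
            if lo == hi:
                continue
            hit = cgrp_sorted.iloc[lo:hi]
            d = hit["midpoint"].to_numpy() - int(g["tss"])
            if g["strand"] == "-":
                d = -d
            gmin, gmax = sorted((int(g["tss"]), int(g["tes"])))
            body = (hit["start"].to_numpy() <= gmax) & (hit["end"].to_numpy() >= gmin)
            for (_, c), sd, b in zip(hit.iterrows(), d, body):
                edges.append(
                    {
                        "gene_id": g["gene_id"],
                        "cluster_id": c["cluster_id"],
                        "signed_distance": int(sd),
                        "abs_distance": int(abs(sd)),
                        "overlaps_gene_body": bool(b),
                    }
                )
    no_edge = set(genes["gene_id"]) - {e["gene_id"] for e in edges}
    if no_edge:
        warnings.warn(f"{len(no_edge)} gene(s) have no candidate clusters", stacklevel=2)
    adj = pd.DataFrame(
        edges,
        columns=["gene_id", "cluster_id", "signed_distance", "abs_distance", "overlaps_gene_body"],
    )

    # promoter flag is a property of the cluster (vs ANY TSS), computed once
    prom = {}
    for _, c in cl.iterrows():
        tss_arr = tss_by_chrom.get(c["chrom"])
        if tss_arr is None or len(tss_arr) == 0:
            prom[c["cluster_id"]] = False
            continue
        i = np.searchsorted(tss_arr, c["start"])
        dist = min(
            abs(int(tss_arr[j]) - x)
            for j in (max(i - 1, 0), min(i, len(tss_arr) - 1))
            for x in (int(c["start"]), int(c["end"]))
        )
        # a TSS inside the cluster interval is distance 0
        inside = ((tss_arr >= c["start"]) & (tss_arr <= c["end"])).any()
        prom[c["cluster_id"]] = bool(inside or dist <= promoter_halfwidth)
    adj["overlaps_promoter"] = adj["cluster_id"].map(prom).astype(bool)
    adj["rank"] = pd.array([pd.NA] * len(adj), dtype="Int64")
    return adj


def annotate_distance_ranks(
    adjacency: pd.DataFrame, cluster_map: ClusterMap, genes: pd.DataFrame
) -> pd.DataFrame:
    """Assign per-gene distance ranks, separately for island and non-island
    clusters.

    Upstream-of-promoter clusters get ranks -1, -2, ... by increasing
    distance from the TSS; clusters downstream of the TES get +1, +2, ... by
    increasing distance from the TES.  Clusters overlapping the gene body,
    or lying between TSS and TES without overlapping it, stay unranked.
    """
    adj = adjacency.copy()
    in_cgi = cluster_map.clusters.set_index("cluster_id")["in_cgi"]
    adj["_cgi"] = adj["cluster_id"].map(in_cgi).astype(bool)
    mid = cluster_map.clusters.set_index("cluster_id")["midpoint"]
    adj["_mid"] = adj["cluster_id"].map(mid)
    gtab = genes.set_index("gene_id")

    ranks = pd.array([pd.NA] * len(adj), dtype="Int64")
    for gene_id, grp in adj.groupby("gene_id"):
        g = gtab.loc[gene_id]
        span = abs(int(g["tes"]) - int(g["tss"]))
        eligible = ~grp["overlaps_gene_body"]
        up = eligible & (grp["signed_distance"] < 0)
        # oriented distance downstream of the TES
        down_dist = grp["signed_distance"] - span
        down = eligible & (down_dist > 0)
        for cat in (True, False):
            sel_up = grp.index[up & (grp["_cgi"] == cat)]
            order = grp.loc[sel_up, "signed_distance"].abs().sort_values(kind="mergesort").index
            for r, idx in enumerate(order, start=1):
                ranks[adj.index.get_loc(idx)] = -r
            sel_dn = grp.index[down & (grp["_cgi"] == cat)]
            order = down_dist.loc[sel_dn].sort_values(kind="mergesort").index
            for r, idx in enumerate(order, start=1):
                ranks[adj.index.get_loc(idx)] = r
    adj["rank"] = ranks
    return adj.drop(columns=["_cgi", "_mid"])
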