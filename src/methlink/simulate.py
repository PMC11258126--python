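"""Seeded synthetic data with the statistical structure the pipeline
assumes, so every stage is testable without external downloads.

The generator plants a sparse linear methylation->expression network with
distance-decaying edge probability (P(edge) ~ exp(-d / scale)), a shared
core of edges present in every cohort plus cohort-specific edges, bimodal
beta values, tumor/normal intercept shifts and Gaussian noise; designated
hub clusters regulate many nearby genes.  Downstream fixtures follow the
same ground truth: chromatin loops preferentially anchored at strong
planted edges, survival times with a proportional-hazards link to hub
methylation, and multi-guide single-cell perturbation data with planted
knockdown of each region's target genes.

Each sub-generator draws from its own RNG stream split from the master
seed, so e.g. adding loops never perturbs the cohort draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import genome as gmod
from .expression import CancerDataset
from .hic import LoopSet

_STREAMS = {"genome": 0, "cohorts": 1, "loops": 2, "survival": 3, "perturb": 4}


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline (desk scale)."""

    seed: int = 0
    n_genes: int = 40
    n_clusters: int = 600
    genome_length: int = 20_000_000
    n_cohorts: int = 3
    samples_per_cohort: int = 150
    tumor_fraction: float = 0.8
    # edge structure
    edge_prob_decay: float = 200_000.0  # P(edge) = edge_prob_base * exp(-d/decay)
    edge_prob_base: float = 0.25
    core_edge_fraction: float = 0.5
    effect_size_range: tuple = (1.0, 2.0)
    activating_fraction: float = 0.7  # fraction of edges with negative coefficient
    noise_sd: float = 0.5
    tumor_shift: float = 2.0
    island_fraction: float = 0.3
    hub_spec: tuple = (5, 6)  # (n_hubs, targets_per_hub)
    # survival
    survival_baseline_rate: float = 0.001  # events per day
    survival_hazard_slope: float = 1.0
    # loops
    n_loops: int = 300
    loop_enrichment: float = 0.8
    anchor_resolution: int = 5_000
    # perturb-seq
    n_regions: int = 20
    cells_per_guide: int = 25
    guides_per_region: int = 3
    n_nt_guides: int = 4
    knockdown_fraction: float = 0.3
    multi_guide_rate: float = 0.3
    perturb_expr_sd: float = 0.3

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth aligned with the emitted matrices."""

    edges: pd.DataFrame  # gene_id, cluster_id, beta, scope ('core' or a cohort id)
    hub_ids: list
    loop_backed: pd.DataFrame = None  # gene_id, cluster_id rows a loop was placed on
    perturb_effects: pd.DataFrame = None  # region, gene, log_fold_change


def simulate_genome(config: SimConfig):
    """Place genes and CpG probes on one synthetic chromosome.

    Probes come in well-separated groups (gap >> cluster diameter) of 1-3
    probes spanning < 200 bp, so the probe-clustering stage has an
    unambiguous planted partition.  Returns ``(genes, probes)`` tables.
    """
    rng = config.rng("genome")
    L = config.genome_length
    slot = 1_000
    n_slots = L // slot - 1
    if config.n_clusters > n_slots:
        raise ValueError("genome too short for the requested cluster count")
    if config.n_genes == 0:
        genes = pd.DataFrame(columns=gmod.GENE_COLUMNS)
    else:
        tss = np.sort(rng.choice(np.arange(int(L * 0.05), int(L * 0.95)), config.n_genes, replace=False))
        rows = []
        for i, t in enumerate(tss):
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(5_000, 50_000))
            tes = t + length if strand == "+" else t - length
            if tes < 0:
                strand, tes = "+", t + length
            rows.append(
                {
                    "gene_id": f"g{i:04d}",
                    "chrom": "chr1",
                    "tss": int(t),
                    "tes": int(tes),
                    "strand": strand,
                    "is_protein_coding": True,
                }
            )
        genes = gmod.make_gene_table(rows)

    probe_rows = []
    if config.n_clusters > 0:
        seeds = np.sort(rng.choice(n_slots, config.n_clusters, replace=False)) * slot
        for j, s in enumerate(seeds):
            n_p = int(rng.integers(1, 4))
            offs = np.sort(rng.choice(180, n_p, replace=False))
            cgi = bool(rng.random() < config.island_fraction)
            for k, o in enumerate(offs):
                probe_rows.append(
                    {"probe_id": f"p{j:05d}_{k}", "chrom": "chr1", "pos": int(s + o), "in_cgi": cgi}
                )
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos", "in_cgi"])
    return genes, probes


def plant_network(config: SimConfig, adjacency: pd.DataFrame, rng=None) -> SimTruth:
    """Sample the true sparse network on the candidate adjacency.

    Each candidate edge is true with probability
    ``edge_prob_base * exp(-d / edge_prob_decay)``; true edges are 'core'
    (all cohorts) with probability ``core_edge_fraction``, otherwise
    specific to one cohort.  Hub clusters additionally get core edges to
    their nearest ``targets_per_hub`` candidate genes with effect sizes at
    the top of the range.
    """
    rng = rng or config.rng("cohorts")
    lo, hi = config.effect_size_range
    p_edge = config.edge_prob_base * np.exp(
        -adjacency["abs_distance"].to_numpy() / config.edge_prob_decay
    )
    chosen = rng.random(len(adjacency)) < p_edge
    rows = []
    for _, e in adjacency[chosen].iterrows():
        mag = rng.uniform(lo, hi)
        sign = -1.0 if rng.random() < config.activating_fraction else 1.0
        scope = (
            "core"
            if rng.random() < config.core_edge_fraction
            else f"cohort{int(rng.integers(config.n_cohorts))}"
        )
        rows.append(
            {"gene_id": e["gene_id"], "cluster_id": e["cluster_id"], "beta": sign * mag, "scope": scope}
        )

    n_hubs, per_hub = config.hub_spec
    deg = adjacency.groupby("cluster_id")["gene_id"].nunique()
    eligible = deg[deg >= per_hub].index.to_numpy()
    hub_ids = sorted(rng.choice(eligible, min(n_hubs, len(eligible)), replace=False))
    for h in hub_ids:
        cand = adjacency[adjacency["cluster_id"] == h].nsmallest(per_hub, "abs_distance")
        for _, e in cand.iterrows():
            mag = rng.uniform((lo + hi) / 2, hi)
            sign = -1.0 if rng.random() < config.activating_fraction else 1.0
            rows.append(
                {"gene_id": e["gene_id"], "cluster_id": h, "beta": sign * mag, "scope": "core"}
            )
    edges = pd.DataFrame(rows, columns=["gene_id", "cluster_id", "beta", "scope"])
    edges = edges.drop_duplicates(subset=["gene_id", "cluster_id"], keep="last").reset_index(drop=True)
    return SimTruth(edges=edges, hub_ids=list(hub_ids))


def simulate_cohorts(config: SimConfig, cluster_map, adjacency: pd.DataFrame):
    """Paired beta/expression matrices per cohort from the planted network.

    Beta values follow a bimodal per-cluster mixture (low Beta(1,10) vs high
    Beta(10,1) states, cluster-specific state probability) and expression
    follows the planted linear model plus noise and a tumor intercept
    shift.  Returns ``(datasets, truth)``.
    """
    rng = config.rng("cohorts")
    truth = plant_network(config, adjacency, rng=rng)
    cluster_ids = list(cluster_map.clusters["cluster_id"])
    gene_ids = sorted(adjacency["gene_id"].unique())
    state_prob = pd.Series(rng.uniform(0.2, 0.8, len(cluster_ids)), index=cluster_ids)
    base_expr = pd.Series(rng.normal(5.0, 0.5, len(gene_ids)), index=gene_ids)

    edge_by_scope = {}
    for _, e in truth.edges.iterrows():
        edge_by_scope.setdefault(e["scope"], []).append((e["gene_id"], e["cluster_id"], e["beta"]))

    datasets = []
    for k in range(config.n_cohorts):
        cid = f"cohort{k}"
        n = config.samples_per_cohort
        samples = [f"{cid}_s{i:03d}" for i in range(n)]
        tumor = rng.random(n) < config.tumor_fraction
        stype = pd.Series(np.where(tumor, "tumor", "normal"), index=samples)

        high = rng.random((len(cluster_ids), n)) < state_prob.to_numpy()[:, None]
        beta_low = rng.beta(1, 10, size=(len(cluster_ids), n))
        beta_high = rng.beta(10, 1, size=(len(cluster_ids), n))
        beta = np.where(high, beta_high, beta_low)
        beta_df = pd.DataFrame(beta, index=cluster_ids, columns=samples)
        beta_df.index.name = "cluster_id"

        expr = np.tile(base_expr.to_numpy()[:, None], (1, n)).astype(float)
        expr += config.tumor_shift * tumor[None, :]
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        active = edge_by_scope.get("core", []) + edge_by_scope.get(cid, [])
        for g, c, b in active:
            expr[gene_pos[g]] += b * beta_df.loc[c].to_numpy()
        expr += rng.normal(0, config.noise_sd, size=expr.shape)
        expr_df = pd.DataFrame(expr, index=gene_ids, columns=samples)
        expr_df.index.name = "gene_id"
        datasets.append(CancerDataset(cid, expr_df, beta_df, stype))
    return datasets, truth


def simulate_loops(config: SimConfig, truth: SimTruth, cluster_map, genes: pd.DataFrame, adjacency: pd.DataFrame) -> LoopSet:
    """Chromatin loops enriched at strong planted edges.

    With probability ``loop_enrichment`` a loop is anchored on a planted
    edge of length >= 2 x anchor resolution (element bin <-> promoter bin);
    otherwise both anchors are random candidate pairs.
    """
    rng = config.rng("loops")
    res = config.anchor_resolution
    mid = cluster_map.clusters.set_index("cluster_id")["midpoint"]
    tss = genes.set_index("gene_id")["tss"]
    dist = adjacency.set_index(["gene_id", "cluster_id"])["abs_distance"]

    idx = pd.MultiIndex.from_frame(truth.edges[["gene_id", "cluster_id"]])
    tedges = truth.edges.assign(abs_distance=dist.reindex(idx).to_numpy())
    strong = tedges[
        (tedges["abs_distance"] >= 2 * res)
        & (tedges["beta"].abs() >= tedges["beta"].abs().median())
    ]
    rows, backed = [], []
    for _ in range(config.n_loops):
        if len(strong) and rng.random() < config.loop_enrichment:
            e = strong.iloc[int(rng.integers(len(strong)))]
            a1 = (int(mid[e["cluster_id"]]) // res) * res
            a2 = (int(tss[e["gene_id"]]) // res) * res
            backed.append({"gene_id": e["gene_id"], "cluster_id": e["cluster_id"]})
        else:
            a1 = (int(mid.iloc[int(rng.integers(len(mid)))]) // res) * res
            a2 = (int(tss.iloc[int(rng.integers(len(tss)))]) // res) * res
        rows.append(
            {
                "chrom1": "chr1", "start1": a1, "end1": a1 + res,
                "chrom2": "chr1", "start2": a2, "end2": a2 + res,
                "source": "sim",
            }
        )
    truth.loop_backed = pd.DataFrame(backed, columns=["gene_id", "cluster_id"]).drop_duplicates()
    return LoopSet(pd.DataFrame(rows), anchor_resolution=res)


def simulate_survival(config: SimConfig, truth: SimTruth, datasets: list) -> pd.DataFrame:
    """Overall-survival table with a proportional-hazards link to hub
    methylation.

    Hazard rate per sample: ``baseline * exp(slope * (hub_beta - 0.5))``
    with hub_beta the sample's mean methylation over planted hub clusters;
    independent exponential censoring at half the baseline rate.
    """
    rng = config.rng("survival")
    rows = []
    for ds in datasets:
        hub_beta = (
            ds.cluster_beta.loc[[h for h in truth.hub_ids if h in ds.cluster_beta.index]].mean(axis=0)
            if truth.hub_ids
            else pd.Series(0.5, index=ds.sample_ids)
        )
        for s in ds.sample_ids:
            rate = config.survival_baseline_rate * np.exp(
                config.survival_hazard_slope * (float(hub_beta[s]) - 0.5)
            )
            t_event = rng.exponential(1.0 / rate)
            t_cens = rng.exponential(2.0 / config.survival_baseline_rate)
            rows.append(
                {
                    "sample_id": s,
                    "cancer_id": ds.cancer_id,
                    "os_time": float(max(min(t_event, t_cens), 1e-3)),
                    "os_event": bool(t_event <= t_cens),
                }
            )
    return pd.DataFrame(rows)


def simulate_perturb(config: SimConfig, truth: SimTruth, cluster_map, genes: pd.DataFrame):
    """Single-cell CRISPRi screen over planted regulatory regions.

    Targeted regions are hub clusters plus further planted-edge clusters;
    each region gets ``guides_per_region`` guides, each guide
    ``cells_per_guide`` cells, and a ``multi_guide_rate`` fraction of cells
    carry one extra random guide.  Cells with a region's guide have that
    region's planted target genes knocked down by ``knockdown_fraction``
    in normalized expression.
    """
    rng = config.rng("perturb")
    deg = truth.edges.groupby("cluster_id").size().sort_values(ascending=False)
    region_pool = list(dict.fromkeys(list(truth.hub_ids) + list(deg.index)))
    regions = region_pool[: config.n_regions]
    region_targets = {
        r: sorted(truth.edges.loc[truth.edges["cluster_id"] == r, "gene_id"].unique())
        for r in regions
    }
    gene_ids = sorted({g for ts in region_targets.values() for g in ts})
    # distractor genes with no planted effect
    extra = [g for g in genes["gene_id"] if g not in gene_ids][:10]
    gene_ids = gene_ids + extra

    guides, guide_to_region = [], {}
    for r in regions:
        for j in range(config.guides_per_region):
            gname = f"{r}_sg{j}"
            guides.append(gname)
            guide_to_region[gname] = r
    nt = [f"NT_sg{j}" for j in range(config.n_nt_guides)]
    guides_all = guides + nt

    n_cells = len(guides_all) * config.cells_per_guide
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    X = np.zeros((n_cells, len(guides_all)), dtype=int)
    primary = np.repeat(np.arange(len(guides_all)), config.cells_per_guide)
    X[np.arange(n_cells), primary] = 1
    extra_mask = rng.random(n_cells) < config.multi_guide_rate
    for i in np.flatnonzero(extra_mask):
        j = int(rng.integers(len(guides_all)))
        X[i, j] = 1

    mu = pd.Series(rng.normal(1.5, 0.2, len(gene_ids)), index=gene_ids)
    Y = np.tile(mu.to_numpy()[None, :], (n_cells, 1))
    lfc = np.log(1.0 - config.knockdown_fraction)
    effect_rows = []
    for gname, r in guide_to_region.items():
        col = guides_all.index(gname)
        carriers = X[:, col] == 1
        for t in region_targets[r]:
            Y[carriers, gene_ids.index(t)] += lfc
    for r in regions:
        for t in region_targets[r]:
            effect_rows.append({"region": r, "gene": t, "log_fold_change": lfc})
    Y += rng.normal(0, config.perturb_expr_sd, size=Y.shape)
    Y = np.maximum(Y, 0.0)

    from .perturb import PerturbDataset

    expr = pd.DataFrame(Y, index=cells, columns=gene_ids)
    Xdf = pd.DataFrame(X, index=cells, columns=guides_all)
    truth.perturb_effects = pd.DataFrame(effect_rows, columns=["region", "gene", "log_fold_change"])
    ds = PerturbDataset(
        expr=expr,
        X=Xdf,
        guide_to_region=guide_to_region,
        region_targets=region_targets,
        non_targeting=set(nt),
    )
    return ds, regions
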