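"""File-based pipeline stages and the end-to-end runner.

Each stage reads its inputs from a workspace directory written by earlier
stages and writes its outputs back, stamped with the config hash, so a run
is fully reproducible from ``config.yaml`` + seed.  ``run_all`` chains
every stage on one configuration; the run log records element counts at
each boundary.
"""

from __future__ import annotations

import json
import time
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cmod
from . import expression as emod
from . import genome as gmod
from . import hic as hicmod
from . import hubs as hmod
from . import io as iomod
from . import perturb as pmod
from . import simulate as smod
from . import survival as survmod

STATE_LABELS = ("Low Signal", "Enhancer", "Heterochromatin")


def _config(workdir) -> smod.SimConfig:
    raw = iomod.read_config(Path(workdir) / "config.yaml")
    known = {f.name for f in fields(smod.SimConfig)}
    cfg = smod.SimConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.extra = {k: v for k, v in raw.items() if k not in known}
    return cfg


def _log(workdir, msg, cfg=None):
    stamp = iomod.config_hash(cfg.to_dict()) if cfg is not None else "-"
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} config_hash={stamp} {msg}\n"
    with open(Path(workdir) / "run.log", "a") as fh:
        fh.write(line)


def _cohort_ids(cfg) -> list[str]:
    return [f"cohort{k}" for k in range(cfg.n_cohorts)]


def stage_simulate(workdir, config: smod.SimConfig | None = None) -> None:
    """Generate every input the downstream stages consume."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg = config or _config(workdir)
    iomod.write_config(cfg.to_dict(), workdir / "config.yaml")
    c = cfg.to_dict()

    genes, probes = smod.simulate_genome(cfg)
    iomod.write_gene_bed(genes, workdir / "genes.bed", c, cfg.seed)
    iomod.write_probe_manifest(probes, workdir / "probes.csv", c, cfg.seed)

    cluster_map = gmod.cluster_probes(probes)
    adjacency = gmod.build_adjacency(genes, cluster_map)
    datasets, truth = smod.simulate_cohorts(cfg, cluster_map, adjacency)
    for ds in datasets:
        # probe-level betas: each member probe carries its cluster's value
        assign = cluster_map.members.set_index("probe_id")["cluster_id"]
        probe_beta = ds.cluster_beta.loc[assign.to_numpy()]
        probe_beta.index = assign.index
        iomod.write_matrix(probe_beta, workdir / f"beta_probe_{ds.cancer_id}.tsv", c, cfg.seed)
        iomod.write_matrix(ds.expression, workdir / f"expr_{ds.cancer_id}.tsv", c, cfg.seed)
        iomod.write_table(
            ds.sample_type.rename("sample_type").rename_axis("sample_id").reset_index(),
            workdir / f"samples_{ds.cancer_id}.tsv", c, cfg.seed, sep="\t",
        )

    loops = smod.simulate_loops(cfg, truth, cluster_map, genes, adjacency)
    iomod.write_bedpe(loops, workdir / "loops.bedpe", c, cfg.seed)
    clinical = smod.simulate_survival(cfg, truth, datasets)
    iomod.write_table(clinical, workdir / "clinical.tsv", c, cfg.seed, sep="\t")

    pds, regions = smod.simulate_perturb(cfg, truth, cluster_map, genes)
    iomod.write_mtx(pds.expr, workdir / "perturb")
    long = pds.X.stack()
    det = long[long == 1].reset_index()
    det.columns = ["cell", "guide", "detected"]
    iomod.write_table(det[["cell", "guide"]], workdir / "guide_detection.tsv", c, cfg.seed, sep="\t")
    iomod.write_table(
        pd.DataFrame(
            {"guide": list(pds.guide_to_region) + sorted(pds.non_targeting),
             "region": list(pds.guide_to_region.values()) + ["non-targeting"] * len(pds.non_targeting)}
        ),
        workdir / "guide_map.tsv", c, cfg.seed, sep="\t",
    )
    iomod.write_table(
        pd.DataFrame(
            [(r, g) for r, ts in pds.region_targets.items() for g in ts],
            columns=["region", "gene"],
        ),
        workdir / "region_targets.tsv", c, cfg.seed, sep="\t",
    )

    # synthetic chromatin-state segmentation covering the genome
    rng = np.random.default_rng([cfg.seed % (2**31), 7])
    win = 10_000
    starts = np.arange(0, cfg.genome_length, win)
    track = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + win,
            "label": rng.choice(STATE_LABELS, len(starts), p=(0.6, 0.2, 0.2)),
        }
    )
    iomod.write_table(track, workdir / "state_track.bed", c, cfg.seed, sep="\t")

    truth.edges.to_csv(workdir / "truth_edges.csv", index=False)
    with open(workdir / "truth_hubs.json", "w") as fh:
        json.dump({"hub_ids": truth.hub_ids, "regions": regions}, fh)
    _log(workdir, f"simulate: {len(genes)} genes, {len(probes)} probes, "
                  f"{len(truth.edges)} true edges", cfg)


def load_genome(workdir):
    genes = iomod.read_gene_annotation(Path(workdir) / "genes.bed")
    probes = iomod.read_probe_manifest(Path(workdir) / "probes.csv")
    return genes, probes


def stage_cluster(workdir) -> gmod.ClusterMap:
    cfg = _config(workdir)
    genes, probes = load_genome(workdir)
    iomod.check_chromosomes(genes, probes)
    cluster_map = gmod.cluster_probes(probes)
    iomod.write_cluster_map(cluster_map, Path(workdir) / "clusters.bed",
                            Path(workdir) / "clusters.members.tsv", cfg.to_dict(), cfg.seed)
    for cid in _cohort_ids(cfg):
        probe_beta = iomod.read_matrix(Path(workdir) / f"beta_probe_{cid}.tsv")
        cb = gmod.aggregate_beta(cluster_map, probe_beta)
        iomod.write_matrix(cb, Path(workdir) / f"beta_cluster_{cid}.tsv", cfg.to_dict(), cfg.seed)
    _log(workdir, f"cluster: {cluster_map.n_clusters} clusters", cfg)
    return cluster_map


def _load_dataset(workdir, cid) -> emod.CancerDataset:
    expr = iomod.read_matrix(Path(workdir) / f"expr_{cid}.tsv")
    beta = iomod.read_matrix(Path(workdir) / f"beta_cluster_{cid}.tsv")
    stypes = iomod.read_table(Path(workdir) / f"samples_{cid}.tsv", sep="\t").set_index("sample_id")[
        "sample_type"
    ]
    return emod.CancerDataset(cid, expr, beta, stypes)


def _load_scaffold(workdir):
    genes, _ = load_genome(workdir)
    cluster_map = iomod.read_cluster_map(Path(workdir) / "clusters.bed",
                                         Path(workdir) / "clusters.members.tsv")
    adjacency = gmod.build_adjacency(genes, cluster_map)
    adjacency = gmod.annotate_distance_ranks(adjacency, cluster_map, genes)
    return genes, cluster_map, adjacency


def stage_fit(workdir) -> list:
    cfg = _config(workdir)
    _, _, adjacency = _load_scaffold(workdir)
    networks = []
    for cid in _cohort_ids(cfg):
        ds = _load_dataset(workdir, cid)
        min_size = int(cfg.extra.get("min_cohort_size", 100)) if hasattr(cfg, "extra") else 100
        try:
            net = emod.fit_cancer_network(ds, adjacency, seed=cfg.seed,
                                          min_cohort_size=min_size)
        except ValueError as err:
            _log(workdir, f"fit: cohort {cid} skipped ({err})", cfg)
            continue
        iomod.write_table(net.edges, Path(workdir) / f"edges_{cid}.csv", cfg.to_dict(), cfg.seed)
        iomod.write_table(net.fit_table(), Path(workdir) / f"fits_{cid}.csv", cfg.to_dict(), cfg.seed)
        _log(workdir, f"fit: cohort {cid}: {len(net.fits)} genes, {len(net.edges)} edges", cfg)
        networks.append(net)
    return networks


def _reload_networks(workdir) -> list:
    cfg = _config(workdir)
    networks = []
    for cid in _cohort_ids(cfg):
        epath = Path(workdir) / f"edges_{cid}.csv"
        if not epath.exists():
            continue
        edges = iomod.read_table(epath)
        fits_meta = iomod.read_table(Path(workdir) / f"fits_{cid}.csv")
        fits = []
        for _, m in fits_meta.iterrows():
            nz = edges[edges["gene_id"] == m["gene_id"]]
            coefs = pd.Series(nz["coefficient"].to_numpy(), index=nz["cluster_id"])
            fits.append(
                emod.GeneModelFit(m["gene_id"], cid, coefs, {}, m["lambda"], m["alpha"],
                                  m["cv_r2"], int(m["k_g"]))
            )
        networks.append(emod.CancerNetwork(cid, fits))
    return networks


def stage_consensus(workdir) -> pd.DataFrame:
    cfg = _config(workdir)
    networks = _reload_networks(workdir)
    cons = cmod.build_consensus(networks)
    iomod.write_table(cons, Path(workdir) / "consensus_edges.csv", cfg.to_dict(), cfg.seed)
    _log(workdir, f"consensus: {len(cons)} edges", cfg)
    return cons


def stage_score(workdir) -> pd.DataFrame:
    cfg = _config(workdir)
    cons = iomod.read_table(Path(workdir) / "consensus_edges.csv")
    genes, cluster_map, adjacency = _load_scaffold(workdir)
    scored = cmod.compute_scores(cons, adjacency)
    _, scored = cmod.fit_distance_trend(scored)

    # cross-cohort methylation variance: variance over cohorts of the
    # per-cohort mean beta of each cluster
    means = []
    for cid in _cohort_ids(cfg):
        cb = iomod.read_matrix(Path(workdir) / f"beta_cluster_{cid}.tsv")
        means.append(cb.mean(axis=1))
    beta_var = pd.concat(means, axis=1).var(axis=1, ddof=1)

    potentials = cmod.compute_potential(scored, beta_var)
    profile = cmod.distance_rank_profile(cons, adjacency, cluster_map)

    iomod.write_table(scored, Path(workdir) / "associations.csv", cfg.to_dict(), cfg.seed)
    cl = cluster_map.clusters.set_index("cluster_id")
    out = potentials.copy()
    for col in ("chrom", "start", "end"):
        out[col] = out["cluster_id"].map(cl[col])
    iomod.write_table(out, Path(workdir) / "cluster_score.csv", cfg.to_dict(), cfg.seed)
    iomod.write_table(profile, Path(workdir) / "rank_profile.csv", cfg.to_dict(), cfg.seed)
    _log(workdir, f"score: {len(potentials)} scored clusters", cfg)
    return scored


def stage_hubs(workdir) -> hmod.HubCalls:
    cfg = _config(workdir)
    potentials = iomod.read_table(Path(workdir) / "cluster_score.csv")
    calls = hmod.call_hubs(potentials)
    out = potentials.merge(calls.table[["cluster_id", "is_hub"]], on="cluster_id")
    iomod.write_table(out, Path(workdir) / "cluster_score.csv", cfg.to_dict(), cfg.seed)
    _log(workdir, f"hubs: {int(out['is_hub'].sum())} hubs at threshold {calls.threshold:.3f}", cfg)
    return calls


def stage_enrich(workdir) -> dict:
    cfg = _config(workdir)
    genes, cluster_map, adjacency = _load_scaffold(workdir)
    potentials = iomod.read_table(Path(workdir) / "cluster_score.csv")
    track = iomod.read_table(Path(workdir) / "state_track.bed", sep="\t")
    states = hmod.assign_state(cluster_map.clusters, track)
    res_state = hmod.enrich_potential_by_state(potentials, states)
    iomod.write_table(res_state, Path(workdir) / "enrichment_state.tsv", cfg.to_dict(), cfg.seed, sep="\t")

    loops = iomod.read_bedpe(Path(workdir) / "loops.bedpe", cfg.anchor_resolution)
    prom = adjacency.drop_duplicates("cluster_id").set_index("cluster_id")["overlaps_promoter"]
    prom = prom.reindex(potentials["cluster_id"]).fillna(False)
    res_loops = hmod.enrich_by_loop_count(potentials, cluster_map.clusters, loops.loops, prom)
    iomod.write_table(res_loops, Path(workdir) / "enrichment_loops.tsv", cfg.to_dict(), cfg.seed, sep="\t")

    calls = hmod.HubCalls(
        potentials.rename(columns={"is_hub": "is_hub"}), threshold=float("nan")
    )
    res_hub = hmod.enrich_hubness(calls, states)
    iomod.write_table(res_hub, Path(workdir) / "enrichment_hubness.tsv", cfg.to_dict(), cfg.seed, sep="\t")
    _log(workdir, "enrich: state/loop/hubness tables written", cfg)
    return {"state": res_state, "loops": res_loops, "hubness": res_hub}


def stage_survival(workdir, n_random: int = 40, max_elements: int = 60) -> pd.DataFrame:
    cfg = _config(workdir)
    clinical = iomod.read_table(Path(workdir) / "clinical.tsv", sep="\t")
    potentials = iomod.read_table(Path(workdir) / "cluster_score.csv")
    hub_ids = list(potentials.loc[potentials["is_hub"], "cluster_id"])
    selected = survmod.select_survival_elements(potentials, hub_ids, n_random, cfg.seed)
    selected = selected[:max_elements]
    betas = pd.concat(
        [iomod.read_matrix(Path(workdir) / f"beta_cluster_{cid}.tsv") for cid in _cohort_ids(cfg)],
        axis=1,
    )
    effects = [
        survmod.fit_stratified_cox(c, clinical, betas.loc[c]) for c in selected if c in betas.index
    ]
    tab = survmod.adjust_p_values(effects)
    tab["is_hub"] = tab["cluster_id"].isin(set(hub_ids))
    iomod.write_table(tab, Path(workdir) / "survival_effects.tsv", cfg.to_dict(), cfg.seed, sep="\t")
    try:
        stat, p = survmod.compare_hub_survival(effects, hub_ids)
        with open(Path(workdir) / "survival_test.json", "w") as fh:
            json.dump({"wilcoxon_statistic": stat, "p_value": p}, fh)
    except ValueError:
        p = float("nan")
    _log(workdir, f"survival: {len(effects)} elements, hub-vs-non-hub p={p:.3g}", cfg)
    return tab


def stage_hic(workdir) -> pd.DataFrame:
    cfg = _config(workdir)
    genes, cluster_map, _ = _load_scaffold(workdir)
    scored = iomod.read_table(Path(workdir) / "associations.csv")
    potentials = iomod.read_table(Path(workdir) / "cluster_score.csv")
    loops = iomod.read_bedpe(Path(workdir) / "loops.bedpe", cfg.anchor_resolution)
    table = hicmod.overlap_associations(scored, cluster_map, genes, loops)
    prob = hicmod.binned_overlap_probability(table, n_bins=min(10, max(2, len(table) // 20)))
    iomod.write_table(prob, Path(workdir) / "hic_bin_prob.tsv", cfg.to_dict(), cfg.seed, sep="\t")
    auc, roc, _ = hicmod.hub_prediction_auc(
        potentials[["cluster_id", "potential"]], cluster_map, genes, loops
    )
    iomod.write_table(auc, Path(workdir) / "hic_auc.tsv", cfg.to_dict(), cfg.seed, sep="\t")
    iomod.write_table(roc, Path(workdir) / "hic_roc.csv", cfg.to_dict(), cfg.seed)
    _log(workdir, f"hic: {len(table)} associations, {len(auc)} AUC thresholds", cfg)
    return auc


def load_perturb(workdir) -> pmod.PerturbDataset:
    workdir = Path(workdir)
    expr = iomod.read_mtx(workdir / "perturb")
    det = iomod.read_table(workdir / "guide_detection.tsv", sep="\t")
    X = pd.crosstab(det["cell"], det["guide"]).reindex(expr.index).fillna(0).astype(int)
    gmap = iomod.read_table(workdir / "guide_map.tsv", sep="\t")
    nt = set(gmap.loc[gmap["region"] == "non-targeting", "guide"])
    g2r = dict(zip(gmap.loc[~gmap["guide"].isin(nt), "guide"],
                   gmap.loc[~gmap["guide"].isin(nt), "region"]))
    rt = iomod.read_table(workdir / "region_targets.tsv", sep="\t")
    region_targets = rt.groupby("region")["gene"].apply(list).to_dict()
    return pmod.PerturbDataset(expr, X, g2r, region_targets, nt)


def stage_perturb(workdir, B: int | None = None) -> dict:
    cfg = _config(workdir)
    ds = load_perturb(workdir)
    genes = list(ds.expr.columns)
    calls = pmod.fit_guide_effects(ds, genes)
    iomod.write_table(calls, Path(workdir) / "interaction_calls.csv", cfg.to_dict(), cfg.seed)
    count, detail = pmod.count_validated_regions(calls, ds)
    B = B if B is not None else int(getattr(cfg, "extra", {}).get("bootstrap_B", 200))
    boot = pmod.bootstrap_null(ds, genes, B=B, seed=cfg.seed)
    iomod.write_table(
        pd.Series(boot.null_counts, name="null_validated").to_frame(),
        Path(workdir) / "bootstrap_null.csv", cfg.to_dict(), cfg.seed,
    )
    with open(Path(workdir) / "perturb_summary.json", "w") as fh:
        json.dump(
            {"validated_regions": count, "n_regions": len(ds.regions), "bootstrap_p": boot.p,
             "B": B},
            fh,
        )
    _log(workdir, f"perturb: {count}/{len(ds.regions)} regions validated, p={boot.p:.4g}", cfg)
    return {"validated": count, "p": boot.p, "detail": detail}


def run_all(workdir, config: smod.SimConfig | None = None) -> None:
    """simulate -> cluster -> fit -> consensus -> hubs -> enrich ->
    survival -> hic -> perturb, on one configuration."""
    stage_simulate(workdir, config)
    stage_cluster(workdir)
    stage_fit(workdir)
    stage_consensus(workdir)
    stage_score(workdir)
    stage_hubs(workdir)
    stage_enrich(workdir)
    stage_survival(workdir)
    stage_hic(workdir)
    stage_perturb(workdir)
    _log(workdir, "run-all: complete")
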