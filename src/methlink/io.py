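"""Readers and writers for the external text formats.

Conventions: internal coordinates are 0-based; probe manifests are 1-based
on disk (Illumina convention) and converted on ingest; BED/BEDPE intervals
are half-open.  Every table the pipeline writes starts with a ``#`` comment
line carrying the config hash and seed, so any artifact can be traced to
the run that produced it; all readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

from . import genome as gmod
from .hic import BEDPE_COLUMNS, LoopSet


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(config: dict | None, seed=None) -> str:
    h = config_hash(config) if config is not None else "none"
    return f"# methlink config_hash={h} seed={seed}\n"


def write_table(df: pd.DataFrame, path, config: dict | None = None, seed=None, sep=",",
                index=False, header=True):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_stamp(config, seed))
        df.to_csv(fh, sep=sep, index=index, header=header)


def read_table(path, sep=",", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# --- gene annotation -------------------------------------------------------

def read_gene_annotation(path) -> pd.DataFrame:
    """Read genes from GTF (gene records) or 6-column BED.

    BED: gene_id in the name column; TSS is the strand-dependent end of the
    half-open interval.  GTF: 1-based inclusive; records with
    ``feature == gene``; ``gene_id`` and optional ``gene_biotype`` parsed
    from the attributes.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                    for kv in f[8].rstrip(";").split(";")
                    if " " in kv.strip()
                )
                start0, end0 = int(f[3]) - 1, int(f[4])  # to 0-based half-open
                strand = f[6]
                tss, tes = (start0, end0 - 1) if strand == "+" else (end0 - 1, start0)
                rows.append(
                    {
                        "gene_id": attrs.get("gene_id", f"gene{len(rows)}"),
                        "chrom": f[0],
                        "tss": tss,
                        "tes": tes,
                        "strand": strand,
                        "is_protein_coding": attrs.get("gene_biotype", "protein_coding")
                        == "protein_coding",
                    }
                )
        return gmod.make_gene_table(rows)
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[:6]
            start, end = int(start), int(end)
            tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
            rows.append(
                {
                    "gene_id": name,
                    "chrom": chrom,
                    "tss": tss,
                    "tes": tes,
                    "strand": strand,
                    "is_protein_coding": True,
                }
            )
    return gmod.make_gene_table(rows)


def write_gene_bed(genes: pd.DataFrame, path, config=None, seed=None):
    rows = []
    for _, g in genes.iterrows():
        lo, hi = sorted((int(g["tss"]), int(g["tes"])))
        rows.append(
            {"chrom": g["chrom"], "start": lo, "end": hi + 1, "name": g["gene_id"],
             "score": 0, "strand": g["strand"]}
        )
    write_table(pd.DataFrame(rows), path, config, seed, sep="\t", header=False)


# --- probe manifest --------------------------------------------------------

def read_probe_manifest(path) -> pd.DataFrame:
    """CSV with columns probe_id, chrom, pos (1-based), cgi_flag."""
    df = pd.read_csv(path, comment="#")
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int) - 1,  # 1-based on disk -> 0-based internal
            "in_cgi": df["cgi_flag"].astype(bool),
        }
    )
    if out["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in manifest")
    return out


def write_probe_manifest(probes: pd.DataFrame, path, config=None, seed=None):
    df = pd.DataFrame(
        {
            "probe_id": probes["probe_id"],
            "chrom": probes["chrom"],
            "pos": probes["pos"].astype(int) + 1,
            "cgi_flag": probes["in_cgi"].astype(bool),
        }
    )
    write_table(df, path, config, seed)


# --- cluster map -----------------------------------------------------------

def write_cluster_map(cluster_map, bed_path, members_path, config=None, seed=None):
    cl = cluster_map.clusters
    bed = pd.DataFrame(
        {"chrom": cl["chrom"], "start": cl["start"], "end": cl["end"] + 1,
         "name": cl["cluster_id"]}
    )
    write_table(bed, bed_path, config, seed, sep="\t", header=False)
    write_table(cluster_map.members, members_path, config, seed, sep="\t")
    meta = cl[["cluster_id", "midpoint", "in_cgi", "n_probes"]]
    write_table(meta, str(bed_path) + ".meta.tsv", config, seed, sep="\t")


def read_cluster_map(bed_path, members_path):
    bed = pd.read_csv(bed_path, sep="\t", comment="#", header=None,
                      names=["chrom", "start", "end", "name"])
    members = read_table(members_path, sep="\t")
    meta = read_table(str(bed_path) + ".meta.tsv", sep="\t").set_index("cluster_id")
    clusters = pd.DataFrame(
        {
            "cluster_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int) - 1,
            "midpoint": bed["name"].map(meta["midpoint"]).astype(int),
            "in_cgi": bed["name"].map(meta["in_cgi"]).astype(bool),
            "n_probes": bed["name"].map(meta["n_probes"]).astype(int),
        }
    )
    return gmod.ClusterMap(clusters=clusters, members=members)


# --- matrices --------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path, config=None, seed=None):
    """Feature x sample TSV with a header row of sample ids."""
    write_table(df.reset_index(), path, config, seed, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(df.columns[0])


def write_mtx(expr: pd.DataFrame, prefix):
    """Dense cells x genes frame -> MTX triplet + barcodes/features TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sp.csr_matrix(expr.to_numpy()))
    pd.Series(expr.index).to_csv(str(prefix) + ".barcodes.tsv", index=False, header=False)
    pd.Series(expr.columns).to_csv(str(prefix) + ".features.tsv", index=False, header=False)


def read_mtx(prefix) -> pd.DataFrame:
    m = spio.mmread(str(prefix) + ".mtx").toarray()
    cells = pd.read_csv(str(prefix) + ".barcodes.tsv", header=None)[0]
    genes = pd.read_csv(str(prefix) + ".features.tsv", header=None)[0]
    return pd.DataFrame(m, index=cells, columns=genes)


# --- BEDPE -----------------------------------------------------------------

def read_bedpe(path, anchor_resolution: int = 5_000) -> LoopSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    cols = BEDPE_COLUMNS + (["source"] if df.shape[1] >= 7 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return LoopSet(df, anchor_resolution=anchor_resolution)


def write_bedpe(loops: LoopSet, path, config=None, seed=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = BEDPE_COLUMNS + (["source"] if "source" in loops.loops.columns else [])
    with open(path, "w") as fh:
        fh.write(_stamp(config, seed))
        loops.loops[cols].to_csv(fh, sep="\t", index=False, header=False)


# --- config ----------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def check_chromosomes(*tables) -> None:
    """Raise when inputs disagree on chromosome naming (chr1 vs 1)."""
    seen = [set(t["chrom"].unique()) for t in tables if "chrom" in getattr(t, "columns", [])]
    if not seen:
        return
    stripped = [{c.removeprefix("chr") for c in s} for s in seen]
    union = set().union(*seen)
    if len({c.startswith("chr") for c in union}) > 1 and len(set().union(*stripped)) < len(union):
        raise ValueError(f"inconsistent chromosome naming across inputs: {sorted(union)}")
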