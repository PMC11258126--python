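"""Deconvolution of per-guide effects from multi-guide CRISPRi perturb-seq.

Because cells frequently carry more than one guide, per-guide effects are
estimated jointly: for each gene, log-normalized expression is regressed on
the full binary cell x guide detection matrix (plus an intercept), so a
guide's coefficient is its expression shift net of every co-occurring
guide.  Per-coefficient t-tests use empirical-Bayes moderation of the
residual variances across genes (scaled inverse-chi-squared shrinkage
toward a pooled prior); Benjamini-Hochberg adjustment runs over all tested
(guide, gene) pairs and calls are made at adjusted p < 0.05.  A targeted
region is *validated* when at least one of its guides has a significant
call on one of the region's predicted target genes.  Significance of the
validated-region count is assessed with a label-shuffle bootstrap null that
permutes each guide column of the detection matrix independently,
preserving per-guide detection totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
DEFAULT_MIN_MEAN_EXPR = 0.0002
DEFAULT_RADIUS = 1_000_000


@dataclass
class PerturbDataset:
    """Single-cell expression with guide detection and region maps.

    ``expr``: cells x genes log-normalized expression.
    ``X``: cells x guides binary detection matrix.
    ``guide_to_region``: targeting guide -> CRE region id.
    ``region_targets``: region id -> list of predicted target genes.
    ``non_targeting``: guide ids of non-targeting controls.
    """

    expr: pd.DataFrame
    X: pd.DataFrame
    guide_to_region: dict
    region_targets: dict
    non_targeting: set = field(default_factory=set)

    def __post_init__(self):
        if list(self.expr.index) != list(self.X.index):
            raise ValueError("expr and X must share the cell index")
        vals = self.X.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("guide detection matrix must be binary")
        targeting = set(self.X.columns) - set(self.non_targeting)
        unmapped = targeting - set(self.guide_to_region)
        if unmapped:
            raise ValueError(f"targeting guides without a region: {sorted(unmapped)[:5]}")

    @property
    def regions(self) -> list:
        return sorted(set(self.guide_to_region.values()))


def filter_testable_genes(
    dataset: PerturbDataset,
    gene_coords: pd.DataFrame,
    region_coords: pd.DataFrame,
    radius: int = DEFAULT_RADIUS,
    min_mean_expr: float = DEFAULT_MIN_MEAN_EXPR,
) -> list[str]:
    """Genes within ``radius`` of a targeted region and expressed above the
    mean-normalized-expression floor (strictly above).

    ``gene_coords`` has ``gene_id, chrom, tss``; ``region_coords`` has
    ``region, chrom, start, end``.  Mean normalized expression is recovered
    from the log-normalized matrix as mean(expm1(.)).
    """
    mean_norm = np.expm1(dataset.expr).mean(axis=0)
    near = set()
    for _, g in gene_coords.iterrows():
        sub = region_coords[region_coords["chrom"] == g["chrom"]]
        d = np.minimum(
            np.abs(sub["start"].to_numpy() - g["tss"]), np.abs(sub["end"].to_numpy() - g["tss"])
        )
        inside = (sub["start"].to_numpy() <= g["tss"]) & (g["tss"] <= sub["end"].to_numpy())
        if len(sub) and (inside | (d <= radius)).any():
            near.add(g["gene_id"])
    return [
        g for g in dataset.expr.columns
        if g in near and float(mean_norm.get(g, 0.0)) > min_mean_expr
    ]


def _squeeze_var(s2: np.ndarray, df: int):
    """Smyth-style moment estimation of the scaled inverse-chi-squared prior
    for residual variances, returning (moderated variances, total df)."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2 or df < 1:
        return s2, np.full_like(s2, float(df))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = max(e.var(ddof=1) - special.polygamma(1, df / 2.0), 1e-12)

    # solve trigamma(d0/2) = evar for d0 by Newton iteration on x = d0/2
    x = 1.0 / evar + 0.5
    for _ in range(50):
        f = special.polygamma(1, x) - evar
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * abs(x):
            x = x_new
            break
        x = x_new
    d0 = 2.0 * x
    s0_sq = np.exp(emean + special.digamma(x) - np.log(x))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, np.full_like(s2, df + d0)


def fit_guide_effects(
    dataset: PerturbDataset, genes: list[str], moderation: bool = True
) -> pd.DataFrame:
    """Joint per-gene regression of expression on all guide indicators.

    Returns one row per tested (guide, gene) pair with columns ``guide,
    gene, effect, p, p_adj, significant, predicted``.  All-zero guide
    columns are excluded with a warning; a rank-deficient design gets the
    least-norm solution with a warning.  With ``moderation=False`` plain
    per-gene OLS t-tests are used (handy as an oracle on disjoint designs).
    """
    X = dataset.X.copy()
    empty = [g for g in X.columns if X[g].sum() == 0]
    if empty:
        warnings.warn(f"guides never detected, excluded: {empty}", stacklevel=2)
        X = X.drop(columns=empty)
    guides = list(X.columns)
    Y = dataset.expr[genes].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    calls = _fit_design(design, Y, guides, genes, moderation)
    pred = {
        (g, t): True
        for g, r in dataset.guide_to_region.items()
        for t in dataset.region_targets.get(r, [])
    }
    calls["predicted"] = [
        pred.get((g, t), False) for g, t in zip(calls["guide"], calls["gene"])
    ]
    return calls


def _fit_design(design: np.ndarray, Y: np.ndarray, guides, genes, moderation: bool) -> pd.DataFrame:
    n, p = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        warnings.warn("collinear guide columns; least-norm solution", stacklevel=2)
    pinv = np.linalg.pinv(design)
    coef = pinv @ Y  # p x n_genes
    resid = Y - design @ coef
    dof = max(n - rank, 1)
    s2 = (resid**2).sum(axis=0) / dof
    if moderation:
        s2_use, df_use = _squeeze_var(s2, dof)
    else:
        s2_use, df_use = s2, np.full_like(s2, float(dof))
    xtx_inv_diag = np.sum(pinv**2, axis=1)  # diag of pinv pinv'
    se = np.sqrt(np.outer(xtx_inv_diag, s2_use))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = coef / se
    rows = []
    for j, guide in enumerate(guides, start=1):  # column 0 is the intercept
        pvals = 2.0 * stats.t.sf(np.abs(tval[j]), df_use)
        for k, gene in enumerate(genes):
            rows.append(
                {"guide": guide, "gene": gene, "effect": float(coef[j, k]), "p": float(pvals[k])}
            )
    out = pd.DataFrame(rows)
    out["p"] = out["p"].fillna(1.0)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < FDR_THRESHOLD
    return out


def count_validated_regions(
    calls: pd.DataFrame, dataset: PerturbDataset, restrict_to_predicted: bool = True
):
    """Regions with >= 1 significant call from one of their guides.

    With ``restrict_to_predicted`` the significant call must hit one of the
    region's predicted target genes.  Non-targeting guides never validate a
    region.  Returns ``(count, per-region detail table)``.
    """
    sig = calls[calls["significant"]]
    sig = sig[~sig["guide"].isin(dataset.non_targeting)]
    detail = []
    validated = set()
    for _, row in sig.iterrows():
        region = dataset.guide_to_region.get(row["guide"])
        if region is None:
            continue
        if restrict_to_predicted and row["gene"] not in set(dataset.region_targets.get(region, [])):
            continue
        validated.add(region)
        detail.append({"region": region, "guide": row["guide"], "gene": row["gene"],
                       "effect": row["effect"], "p_adj": row["p_adj"]})
    return len(validated), pd.DataFrame(detail, columns=["region", "guide", "gene", "effect", "p_adj"])


@dataclass
class BootstrapResult:
    observed_validated: int
    null_counts: list
    p: float


def bootstrap_null(
    dataset: PerturbDataset,
    genes: list[str],
    B: int = 20_000,
    seed: int = 0,
    moderation: bool = True,
    restrict_to_predicted: bool = True,
) -> BootstrapResult:
    """Label-shuffle null for the validated-region count.

    Each replicate permutes every guide column of X independently (per-guide
    detection totals preserved), refits the deconvolution model, and
    recounts validated regions;

        p = (1 + #{null >= observed}) / (1 + B).
    """
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates gives an unstable p-value", stacklevel=2)
    calls = fit_guide_effects(dataset, genes, moderation=moderation)
    observed, _ = count_validated_regions(calls, dataset, restrict_to_predicted)

    rng = np.random.default_rng(seed)
    Xobs = dataset.X.copy()
    guides = list(Xobs.columns)
    Yg = dataset.expr[genes].to_numpy(dtype=float)
    nulls = []
    for _ in range(B):
        Xb = Xobs.to_numpy().copy()
        for j in range(Xb.shape[1]):
            Xb[:, j] = rng.permutation(Xb[:, j])
        keep = Xb.sum(axis=0) > 0
        design = np.column_stack([np.ones(len(Xb)), Xb[:, keep].astype(float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls_b = _fit_design(
                design, Yg, [g for g, k in zip(guides, keep) if k], genes, moderation
            )
        cnt, _ = count_validated_regions(calls_b, dataset, restrict_to_predicted)
        nulls.append(cnt)
    p = (1 + sum(c >= observed for c in nulls)) / (1 + B)
    return BootstrapResult(observed, nulls, float(p))
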