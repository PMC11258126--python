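"""Per-gene, per-cohort penalized models of expression on neighborhood
methylation.

For gene g in cohort k the model is

    y_gi = beta_g0(z_i) + sum_c beta_gc x_ic + eps_gi

with y the log-normalized expression, x the cluster beta values in [0, 1],
z the sample type (tumor/metastatic vs normal), and an elastic-net penalty
lambda * (alpha * |beta| + (1 - alpha) * beta^2) on the cluster coefficients
only.  The sample-type intercepts are unpenalized; minimizing over them
reduces the problem to an elastic net on group-centered y and X, which is
how the fit is carried out here.  Predictors are standardized internally for
the penalty and coefficients are reported on the original beta-value scale,
so beta_gc is the expression shift for a change from completely
unmethylated to completely methylated.

(lambda, alpha) are tuned by seeded k-fold cross validation (stratified by
sample type when present), choosing the pair minimizing mean CV error over
an alpha grid of 0.1, 0.2, ..., 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, StratifiedKFold

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
DEFAULT_MIN_SD = 1.0
DEFAULT_CV_FOLDS = 10
DEFAULT_MIN_COHORT_SIZE = 100


@dataclass
class CancerDataset:
    """Aligned expression / methylation matrices for one cohort.

    ``expression``: genes x samples, log-normalized.
    ``cluster_beta``: clusters x samples, beta values in [0, 1].
    ``sample_type``: per-sample label, e.g. "tumor" / "normal".
    """

    cancer_id: str
    expression: pd.DataFrame
    cluster_beta: pd.DataFrame
    sample_type: pd.Series

    def __post_init__(self):
        if list(self.expression.columns) != list(self.cluster_beta.columns):
            raise ValueError("expression and cluster_beta sample columns differ")
        self.sample_type = self.sample_type.reindex(self.expression.columns)
        if self.sample_type.isna().any():
            raise ValueError("sample_type missing for some samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def drop_incomplete_samples(self) -> "CancerDataset":
        """Drop samples with any missing expression or beta value."""
        ok = self.expression.notna().all(axis=0) & self.cluster_beta.notna().all(axis=0)
        keep = [s for s, good in ok.items() if good]
        return CancerDataset(
            self.cancer_id,
            self.expression[keep],
            self.cluster_beta[keep],
            self.sample_type.loc[keep],
        )


@dataclass
class GeneModelFit:
    gene_id: str
    cancer_id: str
    coefficients: pd.Series  # indexed by cluster_id over all candidates; exact zeros kept
    intercepts: dict  # sample type -> unpenalized intercept
    lam: float
    alpha: float
    cv_r2: float
    k_g: int

    @property
    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]


@dataclass
class CancerNetwork:
    cancer_id: str
    fits: list
    edges: pd.DataFrame = field(default=None)  # gene_id, cluster_id, coefficient

    def __post_init__(self):
        if self.edges is None:
            rows = [
                {"gene_id": f.gene_id, "cluster_id": c, "coefficient": v}
                for f in self.fits
                for c, v in f.nonzero.items()
            ]
            self.edges = pd.DataFrame(rows, columns=["gene_id", "cluster_id", "coefficient"])

    def fit_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [f.gene_id for f in self.fits],
                "lambda": [f.lam for f in self.fits],
                "alpha": [f.alpha for f in self.fits],
                "cv_r2": [f.cv_r2 for f in self.fits],
                "k_g": [f.k_g for f in self.fits],
            }
        )


def filter_genes(dataset: CancerDataset, min_sd: float = DEFAULT_MIN_SD) -> list[str]:
    """Genes whose per-cohort expression standard deviation is >= ``min_sd``.

    Low-variance genes carry no usable signal for association modelling and
    are dropped per cohort (sample sd, ddof=1; boundary inclusive).
    """
    sd = dataset.expression.std(axis=1, ddof=1)
    return list(sd.index[sd >= min_sd])


def _cv_folds(sample_type: pd.Series, n_folds: int, seed: int):
    y = sample_type.to_numpy()
    if len(np.unique(y)) > 1 and np.min(np.bincount(pd.factorize(y)[0])) >= n_folds:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(len(y)), y))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(len(y))))


def _group_center(v: np.ndarray, groups: np.ndarray) -> np.ndarray:
    out = v.astype(float).copy()
    for g in np.unique(groups):
        m = groups == g
        out[m] = out[m] - out[m].mean(axis=0)
    return out


def fit_gene_model(
    gene_id: str,
    dataset: CancerDataset,
    candidates: list[str],
    cv_folds: int = DEFAULT_CV_FOLDS,
    alpha_grid=DEFAULT_ALPHA_GRID,
    seed: int = 0,
    n_lambdas: int = 30,
) -> GeneModelFit:
    """Fit the elastic-net model for one gene.

    ``candidates`` are the gene's adjacency neighbours.  Raises if there are
    fewer samples than CV folds.  A fully degenerate design (every candidate
    constant) returns an intercept-only fit with all-zero coefficients.
    """
    n = dataset.n_samples
    if n < cv_folds:
        raise ValueError(f"{n} samples < {cv_folds} CV folds")
    y = dataset.expression.loc[gene_id].to_numpy(dtype=float)
    X = dataset.cluster_beta.loc[candidates].to_numpy(dtype=float).T  # samples x clusters
    groups = dataset.sample_type.to_numpy()
    k_g = len(candidates)

    yc = _group_center(y, groups)
    Xc = _group_center(X, groups)
    col_sd = Xc.std(axis=0, ddof=0)
    active = col_sd > 0
    if not active.any():
        coefs = pd.Series(0.0, index=pd.Index(candidates, name="cluster_id"))
        intercepts = {g: float(y[groups == g].mean()) for g in np.unique(groups)}
        return GeneModelFit(gene_id, dataset.cancer_id, coefs, intercepts, 0.0, 1.0, 0.0, k_g)

    Xs = Xc[:, active] / col_sd[active]
    folds = _cv_folds(dataset.sample_type, cv_folds, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNetCV(
            l1_ratio=list(alpha_grid),
            alphas=n_lambdas,  # length of the automatic lambda path
            cv=folds,
            fit_intercept=False,
            max_iter=3000,
        )
        model.fit(Xs, yc)
    beta_std = model.coef_
    beta = np.zeros(k_g)
    beta[active] = beta_std / col_sd[active]
    coefs = pd.Series(beta, index=pd.Index(candidates, name="cluster_id"))

    resid_lin = y - X @ beta
    intercepts = {g: float(resid_lin[groups == g].mean()) for g in np.unique(groups)}

    # out-of-fold R^2 at the selected (lambda, alpha)
    mse_path = np.asarray(model.mse_path_)  # (n_l1, n_alpha, n_folds)
    cv_mse = float(mse_path.mean(axis=-1).min())
    var_y = float(yc.var(ddof=0))
    cv_r2 = 1.0 - cv_mse / var_y if var_y > 0 else 0.0

    return GeneModelFit(
        gene_id,
        dataset.cancer_id,
        coefs,
        intercepts,
        float(model.alpha_),
        float(np.squeeze(model.l1_ratio_)),
        float(cv_r2),
        k_g,
    )


def fit_cancer_network(
    dataset: CancerDataset,
    adjacency: pd.DataFrame,
    seed: int = 0,
    min_sd: float = DEFAULT_MIN_SD,
    cv_folds: int = DEFAULT_CV_FOLDS,
    min_cohort_size: int = DEFAULT_MIN_COHORT_SIZE,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_lambdas: int = 30,
) -> CancerNetwork:
    """Fit the per-gene models for one cohort and collect the network.

    The cohort must meet the minimum paired-sample size.  Genes failing the
    expression-variance filter are skipped; each retained gene is fitted
    independently with the same seeded CV fold assignment, so results match
    per-gene calls to :func:`fit_gene_model`.
    """
    dataset = dataset.drop_incomplete_samples()
    if dataset.n_samples < min_cohort_size:
        raise ValueError(
            f"cohort {dataset.cancer_id}: {dataset.n_samples} samples "
            f"< minimum {min_cohort_size}"
        )
    genes = [g for g in filter_genes(dataset, min_sd) if g in set(adjacency["gene_id"])]
    if not genes:
        warnings.warn(f"cohort {dataset.cancer_id}: no genes pass the sd filter", stacklevel=2)
        return CancerNetwork(dataset.cancer_id, [])
    nbrs = adjacency.groupby("gene_id")["cluster_id"].apply(list)
    fits = []
    for g in genes:
        cands = [c for c in nbrs.get(g, []) if c in dataset.cluster_beta.index]
        if not cands:
            continue
        fits.append(
            fit_gene_model(
                g, dataset, cands, cv_folds=cv_folds, alpha_grid=alpha_grid, seed=seed,
                n_lambdas=n_lambdas,
            )
        )
    return CancerNetwork(dataset.cancer_id, fits)
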