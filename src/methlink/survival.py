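"""Overall-survival impact of element methylation.

Per element, a Cox proportional-hazards model with cohort-stratified
baseline hazard and a varying slope:

    h_i(t) = h0_{cohort(i)}(t) * exp(beta_shared * x_i + dev_{cohort(i)} * x_i)

where x_i is the sample's methylation beta value at the element.  The
cohort deviations are sum-to-zero coded so ``beta_shared`` is the mean
methylation effect across cohorts and the per-cohort effects are
``beta_shared + dev_k``.  Ties are handled with the Efron approximation
(the lifelines default).  A positive shared slope means higher methylation
increases hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

DEFAULT_VARIANCE_QUANTILE = 0.25


@dataclass
class SurvivalEffect:
    cluster_id: str
    mean_effect: float
    mean_se: float
    p_value: float
    cancer_effects: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def z(self) -> float:
        return self.mean_effect / self.mean_se if self.mean_se > 0 else float("nan")


def select_survival_elements(
    potentials: pd.DataFrame,
    hub_ids: list,
    n_random: int,
    seed: int,
    variance_quantile: float = DEFAULT_VARIANCE_QUANTILE,
) -> list:
    """Analysis set: hubs plus a random draw of non-hubs, excluding
    low-variance elements.

    Elements in the bottom ``variance_quantile`` of cross-cohort methylation
    variance are removed first; all surviving hubs are kept and ``n_random``
    non-hubs are sampled with a seeded RNG.
    """
    if "beta_variance" not in potentials:
        raise KeyError("potentials must carry a beta_variance column")
    cut = potentials["beta_variance"].quantile(variance_quantile)
    pool = potentials[potentials["beta_variance"] > cut]
    hubs = [c for c in pool["cluster_id"] if c in set(hub_ids)]
    non_hubs = [c for c in pool["cluster_id"] if c not in set(hub_ids)]
    rng = np.random.default_rng(seed)
    if n_random > len(non_hubs):
        warnings.warn(
            f"requested {n_random} random non-hubs but only {len(non_hubs)} available",
            stacklevel=2,
        )
        chosen = non_hubs
    else:
        chosen = list(rng.choice(non_hubs, size=n_random, replace=False))
    return hubs + sorted(chosen)


def fit_stratified_cox(cluster_id: str, clinical: pd.DataFrame, beta: pd.Series) -> SurvivalEffect:
    """Cohort-stratified varying-slope Cox fit for one element.

    ``clinical`` has columns ``sample_id, cancer_id, os_time, os_event``;
    ``beta`` maps sample_id to the element's methylation.  Cohorts without
    events or without methylation variation are dropped.  With a single
    usable cohort the model reduces to an unstratified Cox slope.
    """
    df = clinical.copy()
    df["beta"] = df["sample_id"].map(beta)
    df = df.dropna(subset=["beta", "os_time", "os_event"])
    usable = []
    for k, grp in df.groupby("cancer_id"):
        if grp["os_event"].sum() == 0:
            warnings.warn(f"cohort {k}: no events, dropped", stacklevel=2)
        elif grp["beta"].std() == 0:
            warnings.warn(f"cohort {k}: constant methylation, dropped", stacklevel=2)
        else:
            usable.append(k)
    df = df[df["cancer_id"].isin(usable)].reset_index(drop=True)
    if df.empty:
        return SurvivalEffect(cluster_id, np.nan, np.nan, np.nan, converged=False)

    cohorts = sorted(usable)
    data = pd.DataFrame(
        {"os_time": df["os_time"].astype(float), "os_event": df["os_event"].astype(int),
         "beta": df["beta"].astype(float)}
    )
    # sum-to-zero coded beta x cohort deviations; last cohort = -sum(others)
    dev_cols = []
    for k in cohorts[:-1]:
        col = f"dev_{k}"
        contrast = np.where(
            df["cancer_id"] == k, 1.0, np.where(df["cancer_id"] == cohorts[-1], -1.0, 0.0)
        )
        data[col] = contrast * df["beta"].to_numpy()
        dev_cols.append(col)
    strata = df["cancer_id"] if len(cohorts) > 1 else None
    if strata is not None:
        data["cancer_id"] = strata

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                data,
                duration_col="os_time",
                event_col="os_event",
                strata=["cancer_id"] if strata is not None else None,
            )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return SurvivalEffect(cluster_id, np.nan, np.nan, np.nan, converged=False)

    shared = float(cph.params_["beta"])
    se = float(cph.standard_errors_["beta"])
    p = float(cph.summary.loc["beta", "p"])
    devs = {k: float(cph.params_.get(f"dev_{k}", 0.0)) for k in cohorts[:-1]}
    if len(cohorts) > 1:
        devs[cohorts[-1]] = -sum(devs.values())
    effects = {k: shared + devs.get(k, 0.0) for k in cohorts}
    return SurvivalEffect(cluster_id, shared, se, p, cancer_effects=effects)


def adjust_p_values(effects: list) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of per-element shared-slope p-values."""
    tab = pd.DataFrame(
        {
            "cluster_id": [e.cluster_id for e in effects],
            "mean_effect": [e.mean_effect for e in effects],
            "se": [e.mean_se for e in effects],
            "p": [e.p_value for e in effects],
            "converged": [e.converged for e in effects],
        }
    )
    ok = tab["converged"] & tab["p"].notna()
    tab["p_adj"] = np.nan
    if ok.any():
        tab.loc[ok, "p_adj"] = multipletests(tab.loc[ok, "p"], method="fdr_bh")[1]
    return tab


def compare_hub_survival(effects: list, hub_ids) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (continuity-corrected) comparison of
    |mean effect| between hub and non-hub elements.

    Returns ``(U statistic for the hub group, p value)``.
    """
    hub_set = set(hub_ids)
    hub_vals = [abs(e.mean_effect) for e in effects if e.cluster_id in hub_set and e.converged]
    other = [abs(e.mean_effect) for e in effects if e.cluster_id not in hub_set and e.converged]
    if len(hub_vals) < 3 or len(other) < 3:
        raise ValueError("need at least 3 elements per group")
    res = mannwhitneyu(hub_vals, other, alternative="two-sided", use_continuity=True, method="asymptotic")
    return float(res.statistic), float(res.pvalue)
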