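"""Impute-then-select orchestration and reporting.

Runs the spike-and-slab sampler independently on every completed dataset of
an :class:`~fcselect.impute.ImputationSet`, pools marginal inclusion
probabilities (MIPs) and model-averaged coefficients by arithmetic mean
across imputations, applies the selection cutoff (default 0.5, with a
near-threshold band flagged just below it), and builds the
with/without-covariate comparison used to probe specificity against a
comorbid confounder such as depression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impute import ImputationSet
from .ssvs import SsvsConfig, gibbs_ssvs, standardize

__all__ = [
    "PooledResult",
    "ModelComparison",
    "impute_then_select",
    "pool_results",
    "select_predictors",
    "mip_plot_data",
    "compare_models",
]

#: width of the flagged band just below the cutoff ("just sub-threshold")
NEAR_THRESHOLD_BAND = 0.05


@dataclass
class PooledResult:
    """Imputation-averaged selection quantities."""

    table: pd.DataFrame  # per predictor: pooled_mip, pooled_beta, mip_sd, ...
    m: int
    cutoff: float
    ssvs_config: SsvsConfig

    def __post_init__(self) -> None:
        mips = self.table["pooled_mip"].to_numpy()
        if ((mips < 0) | (mips > 1)).any():
            raise ValueError("pooled MIPs must lie in [0, 1]")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")

    @property
    def predictors(self) -> list[str]:
        return list(self.table.index)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclass
class ModelComparison:
    """Selection changes between models without and with one covariate."""

    covariate: str
    table: pd.DataFrame  # per predictor: mip/beta under A and B + category


def pool_results(
    per_imputation: list[pd.DataFrame], cutoff: float, config: SsvsConfig
) -> PooledResult:
    """Average per-imputation result tables (columns mip, avg_beta).

    Pooling is the arithmetic mean across imputations, exactly; the
    across-imputation sd of the MIP is reported as a stability diagnostic.
    """
    if not per_imputation:
        raise ValueError("need at least one per-imputation result")
    index = per_imputation[0].index
    for i, t in enumerate(per_imputation[1:], start=1):
        if not t.index.equals(index):
            raise ValueError(f"imputation {i} has a different predictor roster")
    mips = np.vstack([t["mip"].to_numpy(float) for t in per_imputation])
    betas = np.vstack([t["avg_beta"].to_numpy(float) for t in per_imputation])
    m = len(per_imputation)
    pooled_mip = mips.mean(axis=0)
    table = pd.DataFrame(
        {
            "pooled_mip": pooled_mip,
            "pooled_beta": betas.mean(axis=0),
            "mip_sd": mips.std(axis=0, ddof=1) if m > 1 else np.zeros(len(index)),
            "beta_sd": betas.std(axis=0, ddof=1) if m > 1 else np.zeros(len(index)),
            "selected": pooled_mip >= cutoff,
        },
        index=index,
    )
    return PooledResult(table=table, m=m, cutoff=cutoff, ssvs_config=config)


def impute_then_select(
    imputations: ImputationSet,
    outcome,
    ssvs_config: SsvsConfig = SsvsConfig(),
    *,
    cutoff: float = 0.5,
    drop_cols: list[str] | None = None,
) -> PooledResult:
    """Run SSVS on each completed dataset and pool across imputations.

    The sampler seed for imputation i is ``ssvs_config.seed + i``, recorded
    so the whole run is reproducible from one master seed. ``drop_cols``
    removes non-predictor columns from the completed tables (defaults to the
    imputation set's recorded outcome column, if any).
    """
    if drop_cols is None:
        drop_cols = [imputations.outcome_col] if imputations.outcome_col else []
    outcome = np.asarray(outcome, float).ravel()
    per_imp = []
    for i, completed in enumerate(imputations.tables):
        design_table = completed.drop(columns=drop_cols, errors="raise")
        if len(design_table) != outcome.size:
            raise ValueError("outcome length does not match imputed tables")
        cfg_i = dataclasses.replace(ssvs_config, seed=ssvs_config.seed + i)
        try:
            result = gibbs_ssvs(standardize(design_table, outcome), cfg_i)
        except Exception as exc:
            raise RuntimeError(f"SSVS failed on imputation {i}: {exc}") from exc
        per_imp.append(result.to_frame()[["mip", "avg_beta"]])
    return pool_results(per_imp, cutoff, ssvs_config)


def select_predictors(pooled: PooledResult, cutoff: float | None = None) -> pd.DataFrame:
    """Selection table at the cutoff, sorted by descending pooled MIP.

    Predictors with pooled MIP >= cutoff are selected (ties at the cutoff
    included); those within ``NEAR_THRESHOLD_BAND`` below it are flagged
    ``near_threshold``, mirroring just-sub-threshold annotations in selection
    reports.
    """
    cutoff = pooled.cutoff if cutoff is None else cutoff
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie strictly in (0, 1)")
    t = pooled.table.copy()
    t["selected"] = t["pooled_mip"] >= cutoff
    t["near_threshold"] = (~t["selected"]) & (
        t["pooled_mip"] >= cutoff - NEAR_THRESHOLD_BAND
    )
    # descending MIP, deterministic tie-break by predictor name
    t = (
        t.assign(_name=t.index.astype(str))
        .sort_values(["pooled_mip", "_name"], ascending=[False, True], kind="mergesort")
        .drop(columns="_name")
    )
    return t[t["selected"] | t["near_threshold"]][
        ["pooled_mip", "pooled_beta", "mip_sd", "selected", "near_threshold"]
    ]


def mip_plot_data(pooled: PooledResult) -> pd.DataFrame:
    """Sorted MIP table for graphical cutoff (elbow) inspection.

    Rows are ordered by descending pooled MIP (ties broken by predictor
    name); ``gap`` is the drop to the next-ranked predictor and ``rank`` the
    cumulative count, so a natural cutoff shows as a large gap.
    """
    t = pooled.table[["pooled_mip", "pooled_beta"]].copy()
    if t.empty:
        return t.assign(rank=pd.Series(dtype=int), gap=pd.Series(dtype=float))
    t = (
        t.assign(_name=t.index.astype(str))
        .sort_values(["pooled_mip", "_name"], ascending=[False, True], kind="mergesort")
        .drop(columns="_name")
    )
    mips = t["pooled_mip"].to_numpy()
    t["rank"] = np.arange(1, len(t) + 1)
    t["gap"] = np.concatenate([mips[:-1] - mips[1:], [np.nan]])
    return t


def compare_models(
    pooled_without: PooledResult,
    pooled_with: PooledResult,
    covariate: str,
) -> ModelComparison:
    """Per-predictor selection changes after adding one covariate.

    Categories: ``retained`` (selected in both), ``dropped`` (selected only
    without the covariate), ``newly_selected`` (selected only with it),
    ``unselected`` (neither). The covariate's own row comes first.
    """
    without_names = set(pooled_without.predictors)
    with_names = set(pooled_with.predictors)
    if covariate not in with_names:
        raise ValueError(f"covariate {covariate!r} not in the with-covariate roster")
    extra = with_names - without_names - {covariate}
    lost = without_names - with_names
    if extra or lost:
        raise ValueError(
            "rosters differ beyond the covariate: "
            f"unexpected {sorted(extra)}, missing {sorted(lost)}"
        )
    rows = []
    order = [covariate] + pooled_without.predictors
    for name in order:
        in_a = name in without_names
        a = pooled_without.table.loc[name] if in_a else None
        b = pooled_with.table.loc[name]
        sel_a = bool(a["selected"]) if in_a else False
        sel_b = bool(b["selected"])
        if name == covariate:
            category = "covariate"
        elif sel_a and sel_b:
            category = "retained"
        elif sel_a and not sel_b:
            category = "dropped"
        elif sel_b and not sel_a:
            category = "newly_selected"
        else:
            category = "unselected"
        rows.append(
            {
                "predictor": name,
                "mip_without": float(a["pooled_mip"]) if in_a else np.nan,
                "beta_without": float(a["pooled_beta"]) if in_a else np.nan,
                "mip_with": float(b["pooled_mip"]),
                "beta_with": float(b["pooled_beta"]),
                "category": category,
            }
        )
    table = pd.DataFrame(rows).set_index("predictor")
    return ModelComparison(covariate=covariate, table=table)
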