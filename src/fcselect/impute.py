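"""Multiple imputation by fully conditional specification (FCS).

Missing self-report entries are filled m times by cycling variable-by-variable
conditional models: Bayesian linear regression with proper parameter draws
for continuous variables (posterior draw of the residual variance, then the
coefficients, then noise-added predictions) and logistic regression with an
approximate posterior coefficient draw for binary variables. The m streams
differ only by a seed offset, so observed cells are bit-identical across
imputations and reruns are exactly reproducible.

Downstream, selection is run on each completed dataset and pooled
("impute, then select").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "MissingDataMatrix",
    "MiConfig",
    "ImputationSet",
    "missingness_report",
    "fcs_impute",
]


@dataclass
class MissingDataMatrix:
    """A predictor table with missing entries and an imputation roster.

    Columns not listed in ``imputable`` (functional-connectivity edges, the
    outcome, demographics) are required to be complete and serve only as
    predictors in the conditional models.
    """

    table: pd.DataFrame
    imputable: list[str]
    var_types: dict = field(default_factory=dict)  # name -> continuous|binary
    #: variables imputed on a log1p scale and back-transformed (heavy skew)
    log1p_vars: frozenset = frozenset()
    outcome_col: str | None = None

    def __post_init__(self) -> None:
        missing_cols = [v for v in self.imputable if v not in self.table.columns]
        if missing_cols:
            raise ValueError(f"imputable variables not in table: {missing_cols}")
        for v in self.imputable:
            self.var_types.setdefault(v, "continuous")
            if self.var_types[v] not in ("continuous", "binary"):
                raise ValueError(f"{v}: type must be continuous or binary")
            if self.var_types[v] == "binary":
                vals = self.table[v].dropna().unique()
                if not set(np.asarray(vals)) <= {0.0, 1.0}:
                    raise ValueError(f"binary variable {v!r} has values outside {{0,1}}")
        complete_cols = [c for c in self.table.columns if c not in self.imputable]
        bad = [c for c in complete_cols if self.table[c].isna().any()]
        if bad:
            raise ValueError(f"non-imputable columns contain missing values: {bad}")

    @property
    def mask(self) -> pd.DataFrame:
        """True where observed."""
        return self.table.notna()


@dataclass(frozen=True)
class MiConfig:
    m: int = 50
    fcs_cycles: int = 20
    seed: int = 0
    include_outcome_in_models: bool = True

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2 for pooling")
        if self.fcs_cycles < 1:
            raise ValueError("fcs_cycles must be >= 1")


@dataclass
class ImputationSet:
    """m completed copies of one table, sharing a single missingness mask."""

    tables: list[pd.DataFrame]
    mask: pd.DataFrame
    config: MiConfig
    #: per imputable variable: mean across missing cells of the variance of
    #: the m imputed values (> 0 for proper imputation)
    between_variance: pd.Series
    outcome_col: str | None = None

    def __post_init__(self) -> None:
        if len(self.tables) != self.config.m:
            raise ValueError("number of tables does not match config.m")
        for i, t in enumerate(self.tables):
            if t.isna().any().any():
                raise ValueError(f"imputation {i} still contains missing values")

    @property
    def m(self) -> int:
        return len(self.tables)


def missingness_report(
    data: MissingDataMatrix, age_col: str | None = None
) -> pd.DataFrame:
    """Per-variable missingness summary.

    Returns one row per table column with observed/missing counts and rates.
    When ``age_col`` is given, a variable whose missing subjects are strictly
    older than every observed subject is flagged as a by-design block with
    the threshold at the youngest missing subject's age. The frame's
    ``attrs`` carry the average missing rate and the complete-case count.
    """
    mask = data.mask
    n = len(data.table)
    rows = []
    age = data.table[age_col] if age_col is not None else None
    for col in data.table.columns:
        obs = mask[col]
        n_obs = int(obs.sum())
        by_design = False
        threshold = np.nan
        if age is not None and n_obs not in (0, n) and col != age_col:
            missing_ages = age[~obs].dropna()
            observed_ages = age[obs].dropna()
            if len(missing_ages) and len(observed_ages):
                if missing_ages.min() > observed_ages.max():
                    by_design = True
                    threshold = float(missing_ages.min())
        rows.append(
            {
                "variable": col,
                "n_observed": n_obs,
                "n_missing": n - n_obs,
                "missing_rate": (n - n_obs) / n,
                "by_design": by_design,
                "by_design_threshold": threshold,
            }
        )
    report = pd.DataFrame(rows).set_index("variable")
    report.attrs["average_missing_rate"] = float(report["missing_rate"].mean())
    report.attrs["n_complete_cases"] = int(mask.all(axis=1).sum())
    return report


def _design(df: pd.DataFrame, cols: list[str], rows: np.ndarray | slice) -> np.ndarray:
    x = df.loc[rows, cols].to_numpy(float) if not isinstance(rows, slice) else df[cols].to_numpy(float)
    return np.column_stack([np.ones(x.shape[0]), x])


def _check_rank(z: np.ndarray, cols: list[str], target: str) -> None:
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError(
            f"imputation model for {target!r} is perfectly collinear; "
            f"predictors: {cols}"
        )


def _draw_continuous(
    rng: np.random.Generator,
    z_obs: np.ndarray,
    w_obs: np.ndarray,
    z_mis: np.ndarray,
) -> np.ndarray:
    """Proper Bayesian linear-regression imputation draw (flat prior)."""
    n_obs, k = z_obs.shape
    df_resid = n_obs - k
    if df_resid < 1:
        raise np.linalg.LinAlgError("too few observed cases for the linear model")
    beta_hat, _, rank, _ = np.linalg.lstsq(z_obs, w_obs, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = w_obs - z_obs @ beta_hat
    rss = float(resid @ resid)
    sigma2 = max(rss, 1e-12) / rng.chisquare(df_resid)
    ztz = z_obs.T @ z_obs
    chol = np.linalg.cholesky(ztz)
    # beta | sigma2 ~ N(beta_hat, sigma2 (Z'Z)^-1)
    beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(chol.T, rng.standard_normal(k))
    return z_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=z_mis.shape[0])


def _draw_binary(
    rng: np.random.Generator,
    z_obs: np.ndarray,
    w_obs: np.ndarray,
    z_mis: np.ndarray,
    target: str,
) -> np.ndarray:
    """Logistic imputation with an approximate posterior coefficient draw.

    On non-convergence or separation, falls back to observed-marginal
    Bernoulli draws with a logged warning.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(w_obs, z_obs).fit(disp=0, maxiter=50)
        if not np.all(np.isfinite(fit.params)) or not np.all(
            np.isfinite(fit.cov_params())
        ):
            raise np.linalg.LinAlgError("non-finite logistic fit")
        cov = np.asarray(fit.cov_params())
        beta = rng.multivariate_normal(np.asarray(fit.params), cov, method="cholesky")
        p = 1.0 / (1.0 + np.exp(-(z_mis @ beta)))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError, ValueError):
        logger.warning(
            "logistic imputation model for %r did not converge; "
            "falling back to observed-marginal draws", target,
        )
        p = np.full(z_mis.shape[0], float(np.mean(w_obs)))
    return (rng.random(z_mis.shape[0]) < p).astype(float)


def fcs_impute(data: MissingDataMatrix, config: MiConfig = MiConfig()) -> ImputationSet:
    """Generate m completed tables by chained conditional imputation.

    Each stream initializes missing entries with random draws from the
    observed marginals, then cycles ``fcs_cycles`` times over the imputable
    roster in fixed order, refitting each variable's conditional model on the
    currently completed data and redrawing its missing entries. Predictors in
    each conditional model are all other table columns (optionally excluding
    the outcome).
    """
    mask = data.mask
    missing_by_var = {
        v: (~mask[v]).to_numpy() for v in data.imputable if (~mask[v]).any()
    }
    for v in data.imputable:
        n_obs = int(mask[v].sum())
        if n_obs < 10:
            raise ValueError(f"variable {v!r} has only {n_obs} observed cases (need >= 10)")

    tables: list[pd.DataFrame] = []
    for i in range(config.m):
        rng = np.random.default_rng(config.seed + i)
        df = data.table.copy()
        # initialization: observed-marginal draws
        for v, mis in missing_by_var.items():
            observed = data.table.loc[mask[v], v].to_numpy()
            df.loc[mis, v] = rng.choice(observed, size=int(mis.sum()), replace=True)
        for _cycle in range(config.fcs_cycles):
            for v, mis in missing_by_var.items():
                pred_cols = [
                    c
                    for c in df.columns
                    if c != v
                    and (config.include_outcome_in_models or c != data.outcome_col)
                ]
                z_obs = _design(df, pred_cols, mask[v].to_numpy())
                z_mis = _design(df, pred_cols, mis)
                w = data.table.loc[mask[v], v].to_numpy(float)
                if data.var_types[v] == "binary":
                    df.loc[mis, v] = _draw_binary(rng, z_obs, w, z_mis, v)
                else:
                    if v in data.log1p_vars:
                        w = np.log1p(w)
                    try:
                        draw = _draw_continuous(rng, z_obs, np.asarray(w, float), z_mis)
                    except np.linalg.LinAlgError:
                        _check_rank(z_obs, pred_cols, v)
                        raise
                    if v in data.log1p_vars:
                        draw = np.maximum(np.expm1(draw), 0.0)
                    df.loc[mis, v] = draw
        tables.append(df)

    between = {}
    for v in data.imputable:
        mis = ~mask[v].to_numpy()
        if mis.any():
            stacked = np.vstack([t.loc[mis, v].to_numpy(float) for t in tables])
            between[v] = float(stacked.var(axis=0, ddof=1).mean())
        else:
            between[v] = 0.0
    return ImputationSet(
        tables=tables,
        mask=mask,
        config=config,
        between_variance=pd.Series(between, name="between_imputation_variance"),
        outcome_col=data.outcome_col,
    )
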