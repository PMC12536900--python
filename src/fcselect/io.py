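"""Delimited-text input/output for every pipeline artifact.

All on-disk formats are plain text: per-subject time-series matrices
(CSV, header = atlas label IDs), the predictor table (empty field =
missing), the edge-feature table, imputation-set directories with a YAML
manifest, and result tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityFeatures, RoiTimeSeriesPanel
from .impute import ImputationSet, MiConfig, MissingDataMatrix

__all__ = [
    "write_panel",
    "read_panel",
    "write_features",
    "read_features",
    "write_predictor_table",
    "read_predictor_table",
    "write_imputation_set",
    "read_imputation_set",
]


def write_panel(panel: RoiTimeSeriesPanel, directory) -> None:
    """One ``<subject>.csv`` (timepoints x labels) per subject."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [str(c) for c in panel.label_ids]
    for sid in panel.subjects:
        pd.DataFrame(panel.data[sid], columns=cols).to_csv(
            directory / f"{sid}.csv", index=False
        )


def read_panel(directory) -> RoiTimeSeriesPanel:
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no per-subject CSV files in {directory}")
    subjects, data = [], {}
    label_ids: list | None = None
    for f in files:
        df = pd.read_csv(f)
        ids = [int(c) if c.isdigit() else c for c in df.columns]
        if label_ids is None:
            label_ids = ids
        elif ids != label_ids:
            raise ValueError(f"{f.name}: label columns differ from first subject")
        subjects.append(f.stem)
        data[f.stem] = df.to_numpy(float)
    return RoiTimeSeriesPanel(subjects=subjects, data=data, label_ids=label_ids)


def write_features(features: ConnectivityFeatures, path) -> None:
    features.to_frame().to_csv(path)


def read_features(path) -> ConnectivityFeatures:
    df = pd.read_csv(path, index_col="subject")
    return ConnectivityFeatures(
        subjects=list(df.index), edge_labels=list(df.columns), values=df.to_numpy(float)
    )


def write_predictor_table(table: pd.DataFrame, path) -> None:
    """Delimited text; empty field marks a missing entry."""
    table.to_csv(path)


def read_predictor_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_imputation_set(imps: ImputationSet, directory) -> None:
    """A directory of m completed tables plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(imps.tables):
        t.to_csv(directory / f"imp_{i:03d}.csv")
    imps.mask.to_csv(directory / "mask.csv")
    manifest = {
        "m": imps.m,
        "outcome_col": imps.outcome_col,
        "config": dataclasses.asdict(imps.config),
        "between_variance": {
            str(k): float(v) for k, v in imps.between_variance.items()
        },
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_imputation_set(directory) -> ImputationSet:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = MiConfig(**manifest["config"])
    tables = [
        pd.read_csv(directory / f"imp_{i:03d}.csv", index_col=0)
        for i in range(manifest["m"])
    ]
    mask = pd.read_csv(directory / "mask.csv", index_col=0).astype(bool)
    return ImputationSet(
        tables=tables,
        mask=mask,
        config=config,
        between_variance=pd.Series(manifest["between_variance"], dtype=float),
        outcome_col=manifest.get("outcome_col"),
    )


def build_missing_data_matrix(
    table: pd.DataFrame,
    imputable: list[str],
    *,
    binary_vars: list[str] | None = None,
    log1p_vars: list[str] | None = None,
    outcome_col: str | None = None,
) -> MissingDataMatrix:
    """Convenience constructor from a raw table and a roster."""
    var_types = {v: "continuous" for v in imputable}
    for v in binary_vars or []:
        var_types[v] = "binary"
    return MissingDataMatrix(
        table=table,
        imputable=list(imputable),
        var_types=var_types,
        log1p_vars=frozenset(log1p_vars or []),
        outcome_col=outcome_col,
    )
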