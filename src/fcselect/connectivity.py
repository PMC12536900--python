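"""Functional-connectivity edge features from ROI time series.

The pipeline from cleaned BOLD time series to predictors: average atlas-label
series into regions, correlate region series within subject, Fisher
z-transform the correlations, and vectorize the upper triangle into a
subject x edge feature table with deterministic edge labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionMap

__all__ = [
    "RoiTimeSeriesPanel",
    "ConnectivityFeatures",
    "aggregate_regions",
    "fc_matrix",
    "fisher_z",
    "vectorize_edges",
    "connectivity_features",
]

# |r| at and beyond which correlations are clamped before arctanh; finite
# samples can produce |r| = 1 exactly in degenerate cases.
_CLAMP = 1.0 - 1e-7


@dataclass
class RoiTimeSeriesPanel:
    """Per-subject (timepoints x labels) matrices with a shared column order.

    ``label_ids`` may hold atlas label IDs (ints) or region codes (strings)
    after aggregation.
    """

    subjects: list
    data: dict  # subject -> ndarray (timepoints x labels)
    label_ids: list

    def __post_init__(self) -> None:
        ncols = len(self.label_ids)
        for sid in self.subjects:
            mat = np.asarray(self.data[sid], dtype=float)
            if mat.ndim != 2 or mat.shape[1] != ncols:
                raise ValueError(
                    f"subject {sid!r}: expected 2-D matrix with {ncols} columns, "
                    f"got shape {mat.shape}"
                )
            if mat.shape[0] < 2:
                raise ValueError(f"subject {sid!r}: needs >= 2 timepoints")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"subject {sid!r}: non-finite timepoints")
            self.data[sid] = mat

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class ConnectivityFeatures:
    """Subject x edge table of Fisher-z correlations."""

    subjects: list
    edge_labels: list[str]
    values: np.ndarray  # n_subjects x n_edges

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.edge_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.edge_labels)} edges"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite edge values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subjects, name="subject"),
            columns=self.edge_labels,
        )


def aggregate_regions(panel: RoiTimeSeriesPanel, region_map: RegionMap) -> RoiTimeSeriesPanel:
    """Average atlas-label series into region series, per timepoint.

    Each output column is the unweighted mean of that region's constituent
    label series; column order follows the region map.
    """
    col_of = {lab: i for i, lab in enumerate(panel.label_ids)}
    missing = [lab for lab in region_map.all_labels if lab not in col_of]
    if missing:
        raise ValueError(f"panel is missing atlas labels: {missing}")
    index_sets = [
        [col_of[lab] for lab in labels] for _, labels in region_map.regions
    ]
    out = {
        sid: np.column_stack([mat[:, idx].mean(axis=1) for idx in index_sets])
        for sid, mat in ((s, panel.data[s]) for s in panel.subjects)
    }
    return RoiTimeSeriesPanel(
        subjects=list(panel.subjects), data=out, label_ids=region_map.region_names
    )


def fc_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a (timepoints x regions) array."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 3:
        raise ValueError("need a 2-D array with >= 3 timepoints")
    sd = series.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance series at column(s) {zero.tolist()}")
    r = np.corrcoef(series, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher z-transformation, ``arctanh(r)``.

    Values with ``|r| >= 1 - 1e-7`` are clamped to the open interval so the
    transform stays finite on degenerate finite-sample correlations.
    """
    r = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(r, -_CLAMP, _CLAMP))
    return out if out.ndim else float(out)


def vectorize_edges(matrices: dict, region_map: RegionMap) -> ConnectivityFeatures:
    """Upper-triangle Fisher-z edges from per-subject correlation matrices.

    ``matrices`` maps subject -> symmetric (k x k) correlation matrix with k
    equal to the region count; edge order is (i, j) with i < j in region-map
    order, for every subject identically.
    """
    k = region_map.n_regions
    iu = np.triu_indices(k, k=1)
    subjects = list(matrices)
    rows = []
    for sid in subjects:
        mat = np.asarray(matrices[sid], dtype=float)
        if mat.shape != (k, k):
            raise ValueError(
                f"subject {sid!r}: matrix shape {mat.shape}, expected ({k}, {k})"
            )
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError(f"subject {sid!r}: correlation matrix not symmetric")
        rows.append(fisher_z(mat[iu]))
    values = np.vstack(rows) if rows else np.empty((0, k * (k - 1) // 2))
    return ConnectivityFeatures(
        subjects=subjects, edge_labels=region_map.edge_labels(), values=values
    )


def connectivity_features(
    panel: RoiTimeSeriesPanel,
    region_map: RegionMap,
    *,
    aggregate: bool = True,
) -> ConnectivityFeatures:
    """Full label-panel -> edge-feature pipeline.

    With ``aggregate=True`` (default) label series are averaged into regions
    before correlating, giving k(k-1)/2 region-level edges. With
    ``aggregate=False`` correlations are computed at label level and then
    averaged over each region pair's label pairs on the Fisher-z scale — the
    alternative construction when region aggregation before correlation is
    not wanted.
    """
    if aggregate:
        region_panel = aggregate_regions(panel, region_map)
        mats = {sid: fc_matrix(region_panel.data[sid]) for sid in region_panel.subjects}
        return vectorize_edges(mats, region_map)

    col_of = {lab: i for i, lab in enumerate(panel.label_ids)}
    missing = [lab for lab in region_map.all_labels if lab not in col_of]
    if missing:
        raise ValueError(f"panel is missing atlas labels: {missing}")
    index_sets = [
        np.array([col_of[lab] for lab in labels]) for _, labels in region_map.regions
    ]
    k = region_map.n_regions
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    values = np.empty((panel.n_subjects, len(pairs)))
    for s, sid in enumerate(panel.subjects):
        r = fc_matrix(panel.data[sid])
        z = fisher_z(r)
        for e, (i, j) in enumerate(pairs):
            values[s, e] = z[np.ix_(index_sets[i], index_sets[j])].mean()
    return ConnectivityFeatures(
        subjects=list(panel.subjects),
        edge_labels=region_map.edge_labels(),
        values=values,
    )
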