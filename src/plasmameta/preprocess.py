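"""Per-cohort preprocessing of expression matrices.

Standardized handling of one study at a time: log2 transformation, quantile
normalization across samples, collapsing of platform probes to gene symbols
by averaging, and PCA-based exploratory QC on the samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Matrices whose maximum exceeds this are treated as linear-scale
#: (un-logged) intensities.  Log2 microarray data essentially never exceeds
#: ~20, linear intensities essentially always do.
LOG_DETECTION_MAX = 50.0


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with a known scale.

    Parameters
    ----------
    data :
        DataFrame indexed by feature (probe or gene) identifier with one
        column per sample.
    scale :
        Either ``"raw"`` (linear intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicated feature identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicated sample identifier: {dup!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortDataset:
    """One study's expression matrix plus control/treated sample labels."""

    matrix: ExpressionMatrix
    groups: Mapping[str, str]
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        for sid in self.matrix.sample_ids:
            if sid not in self.groups:
                raise ValueError(
                    f"sample {sid!r} in cohort {self.cohort_id!r} has no group label"
                )
        labels = {self.groups[s] for s in self.matrix.sample_ids}
        bad = labels - {"control", "treated"}
        if bad:
            raise ValueError(f"unknown group label(s) {sorted(bad)}; expected control/treated")
        if labels != {"control", "treated"}:
            raise ValueError(
                f"cohort {self.cohort_id!r} needs at least one sample per group"
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.matrix.sample_ids if self.groups[s] == group]

    def arm_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix (features x samples) for one arm."""
        return self.matrix.data[self.samples_in(group)]


def looks_raw(matrix: ExpressionMatrix) -> bool:
    """Heuristic scale check: a maximum above ``LOG_DETECTION_MAX`` marks
    linear-scale data (standard GEO convention for microarray series)."""
    return float(np.nanmax(matrix.data.to_numpy())) > LOG_DETECTION_MAX


def ensure_log2(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return the matrix on log2 scale, applying ``log2(x + offset)`` if raw.

    A matrix already flagged ``log2`` is returned unchanged (idempotent).
    Negative raw values are rejected: intensities must be non-negative.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if matrix.scale == "log2":
        return matrix
    vals = matrix.data.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("raw-scale matrix contains negative values; cannot log-transform")
    out = pd.DataFrame(
        np.log2(vals + offset), index=matrix.data.index, columns=matrix.data.columns
    )
    return ExpressionMatrix(out, scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the mean distribution of order statistics.

    After normalization every column has the same sorted value vector: the
    across-column mean of the k-th order statistics.  Ties within a column
    receive the mean of the reference values over their tied ranks, so the
    map stays well defined and rank order is preserved up to ties.

    A single-sample matrix is returned unchanged with a warning — there is
    nothing to normalize against.
    """
    vals = matrix.data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix (no NaN)")
    if vals.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization skipped", stacklevel=2)
        return matrix
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        out[order, j] = reference
        # average the assigned reference values over tie groups
        assigned = pd.Series(out[:, j])
        out[:, j] = assigned.groupby(col).transform("mean").to_numpy()
    frame = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, scale=matrix.scale)


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by the arithmetic mean on log2 scale.

    Probes absent from the map are dropped (their count is logged).  The
    output has one row per distinct mapped gene.
    """
    genes = pd.Series(
        [probe_map.get(p) for p in matrix.data.index], index=matrix.data.index
    )
    keep = genes.notna()
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no probe in the matrix is covered by the probe map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    collapsed = matrix.data.loc[keep].groupby(genes[keep]).mean()
    collapsed.index.name = matrix.data.index.name
    return ExpressionMatrix(collapsed, scale=matrix.scale)


def pca_explained(matrix: ExpressionMatrix, n_components: int = 2) -> np.ndarray:
    """Fractions of variance explained by the leading principal components.

    Samples are the observations and genes the variables; gene rows are
    mean-centered (no scaling) before decomposition, the usual convention
    for log-expression QC.
    """
    X = matrix.data.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_features = X.shape
    max_rank = min(n_samples - 1, n_features)
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound "
            f"min(samples-1, features)={max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return pca.explained_variance_ratio_


def preprocess_cohort(
    cohort: CohortDataset,
    probe_map: Mapping[str, str] | None = None,
    offset: float = 1.0,
) -> CohortDataset:
    """Full standardized preprocessing for one cohort.

    log2 transform (if needed, by the scale heuristic) → quantile
    normalization → probe-to-gene collapsing (if a map is given).
    Deterministic: the same input always yields the same output.
    """
    m = cohort.matrix
    if m.scale == "raw" or (m.scale == "log2" and looks_raw(m)):
        m = ExpressionMatrix(m.data, scale="raw") if m.scale != "raw" else m
        m = ensure_log2(m, offset=offset)
    m = quantile_normalize(m)
    if probe_map is not None:
        m = collapse_probes(m, probe_map)
    return CohortDataset(matrix=m, groups=dict(cohort.groups), cohort_id=cohort.cohort_id)
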