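"""Morphometric similarity network construction.

A subject's MSN is built from a table of 360 cortical regions × 7
surface-based grey-matter features (grey matter volume, surface area,
cortical thickness, intrinsic curvature, mean curvature, curved index,
folding index).  Feature columns are z-scored across regions, every pair of
regions is scored by the Pearson correlation of its two 7-feature vectors,
and self- and negative correlations are removed.  The weighted undirected
matrix is then proportionally thresholded to a target edge density and
normalized by its maximum retained weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from msnpipe.errors import DegenerateInputError, EmptyNetworkError, ValidationError

logger = logging.getLogger(__name__)

#: The 7 regional cortical grey-matter features, in canonical column order.
FEATURES = (
    "gm_volume",
    "surface_area",
    "cortical_thickness",
    "intrinsic_curvature",
    "mean_curvature",
    "curved_index",
    "folding_index",
)


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURES if c not in table.columns]
    if missing:
        raise ValidationError(f"morphometric table missing feature columns: {missing}")
    x = table[list(FEATURES)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("morphometric table contains missing values")
    return x


def standardize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column across regions (mean 0, sample SD 1).

    Raw features have incommensurate units (mm³, mm², mm, dimensionless
    indices); standardizing puts them on a common scale before regions are
    correlated.  Raises :class:`DegenerateInputError` naming any constant
    column.
    """
    x = _feature_matrix(table)
    sd = x.std(axis=0, ddof=1)
    degenerate = [FEATURES[j] for j in np.nonzero(sd == 0)[0]]
    if degenerate:
        raise DegenerateInputError(f"zero-variance feature column(s): {degenerate}")
    out = table.copy()
    out[list(FEATURES)] = (x - x.mean(axis=0)) / sd
    return out


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric region × region similarity matrix with zeroed diagonal.

    Entries are Pearson correlations clamped below at 0, so all weights lie
    in [0, 1].
    """

    weights: np.ndarray = field(repr=False)
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if len(self.node_ids) != w.shape[0]:
            raise ValidationError("node_ids length must match matrix size")
        if not np.isfinite(w).all():
            raise ValidationError("similarity matrix contains non-finite values")
        if not np.allclose(w, w.T):
            raise ValidationError("similarity matrix must be symmetric")
        if np.diagonal(w).any():
            raise ValidationError("similarity matrix diagonal must be zero")
        if (w < 0).any() or (w > 1).any():
            raise ValidationError("similarity weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def build_msn(table: pd.DataFrame, standardize: bool = True) -> SimilarityMatrix:
    """Build one subject's MSN from its regional morphometric table.

    Parameters
    ----------
    table
        Long-format table with ``region_id`` plus the 7 feature columns,
        one row per region.
    standardize
        Z-score feature columns across regions first (default).  Disable
        only for inputs that are already standardized.

    Notes
    -----
    A region whose 7-feature vector has zero variance has undefined
    correlations; its similarities are set to 0 with a logged warning
    rather than failing the whole subject.
    """
    if "region_id" not in table.columns:
        raise ValidationError("morphometric table must have a region_id column")
    if len(table) < 3:
        raise ValidationError("need at least 3 regions to build an MSN")
    if table["region_id"].duplicated().any():
        raise ValidationError("duplicate region_id in morphometric table")
    if standardize:
        table = standardize_features(table)
    x = _feature_matrix(table)

    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    # relative tolerance: catches constant rows up to float rounding
    flat = norms <= 1e-12 * (1.0 + np.abs(x).max(axis=1))
    if flat.any():
        ids = table["region_id"].to_numpy()[flat].tolist()
        logger.warning(
            "region feature vector(s) with zero variance; similarities set to 0: %s", ids
        )
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, 0.0, 1.0, out=corr)
    np.fill_diagonal(corr, 0.0)
    corr = (corr + corr.T) / 2.0
    return SimilarityMatrix(corr, tuple(table["region_id"]))


def extract_subnetwork(matrix: SimilarityMatrix, nodes: Sequence[int]) -> SimilarityMatrix:
    """Induced submatrix on ``nodes`` (0-based indices), preserving order."""
    idx = np.asarray(list(nodes), dtype=int)
    if len(idx) != len(set(idx.tolist())):
        raise IndexError("node indices must be unique")
    if idx.size and (idx.min() < 0 or idx.max() >= matrix.n):
        raise IndexError(f"node index out of range for {matrix.n}-node matrix")
    sub = matrix.weights[np.ix_(idx, idx)].copy()
    ids = tuple(matrix.node_ids[i] for i in idx)
    return SimilarityMatrix(sub, ids)


def expected_edge_count(n: int, density: float) -> int:
    """Edge count contract: round-half-up of density · n(n−1)/2."""
    return int(math.floor(density * n * (n - 1) / 2 + 0.5))


@dataclass(frozen=True)
class ThresholdedNetwork:
    """A density-thresholded, max-normalized weighted network."""

    weights: np.ndarray = field(repr=False)
    node_ids: tuple[str, ...]
    density: float
    retained_edges: int

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def threshold_density(matrix: SimilarityMatrix, density: float) -> ThresholdedNetwork:
    """Retain the ``round(density · n(n−1)/2)`` strongest edges, then normalize.

    Ties in weight are broken by ascending (i, j) lexicographic node-index
    order so that thresholding is bit-reproducible.  Retained weights are
    divided by the retained maximum, so the strongest surviving edge has
    weight exactly 1.  If fewer positive edges exist than the target count,
    all positive edges are kept with a logged warning.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = matrix.n
    k = expected_edge_count(n, density)
    if k == 0:
        raise EmptyNetworkError(f"density {density} retains 0 edges on a {n}-node network")
    iu, ju = np.triu_indices(n, k=1)
    w = matrix.weights[iu, ju]
    # Sort by (-weight, i, j): strongest first, lexicographic tie-break.
    order = np.lexsort((ju, iu, -w))
    positive = order[w[order] > 0]
    if positive.size < k:
        logger.warning(
            "density %.2f requests %d edges but only %d positive edges exist; keeping all",
            density,
            k,
            positive.size,
        )
    keep = positive[:k]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    retained = int(keep.size)
    if retained:
        out /= out.max()
    return ThresholdedNetwork(out, matrix.node_ids, float(density), retained)


def save_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write a square matrix as tab-delimited text with node_id header row/column."""
    df = pd.DataFrame(matrix.weights, index=matrix.node_ids, columns=matrix.node_ids)
    df.to_csv(path, sep="\t", index_label="region_id", float_format="%.10g")


def load_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(df.to_numpy(dtype=float), tuple(df.columns))
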