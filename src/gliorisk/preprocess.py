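"""Count normalization, marker-based cell typing, moving-average CNV score.

The CNV score follows the classic expression-based strategy: subtract a
reference (non-malignant) baseline per gene, order genes along each
chromosome, and smooth with a centered moving average so that broad
chromosomal dosage changes emerge above gene-level noise.  The per-cell
"burden" (mean squared smoothed score) separates cells carrying arm-level
events from diploid reference cells.  Only this moving-average relative
expression score is implemented; HMM segmentation and subclustering as done
by full CNV-inference tools are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import CELL_TYPE_MARKERS

__all__ = [
    "NormalizedMatrix",
    "CnvProfile",
    "default_marker_table",
    "normalize_counts",
    "CellTypeAnnotator",
    "annotate_cell_types",
    "MovingAverageCNV",
    "cnv_moving_average",
]


@dataclass
class NormalizedMatrix:
    """Log-scale library-size-normalized expression.

    ``values[c, g] = log1p(scale * counts[c, g] / library_size[c])``; cells
    with zero total counts are dropped before normalization and counted in
    ``n_dropped``.
    """

    values: pd.DataFrame
    library_sizes: pd.Series
    n_dropped: int = 0


@dataclass
class CnvProfile:
    """Reference-relative smoothed CNV scores and per-cell burden."""

    scores: pd.DataFrame
    burden: pd.Series


def default_marker_table() -> dict[str, list[str]]:
    table = {t: list(g) for t, g in CELL_TYPE_MARKERS.items()}
    table["endothelial"] = ["PECAM1"]
    return table


def normalize_counts(counts: pd.DataFrame, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize and log-transform a cells x genes count matrix."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(np.asarray(counts))
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    lib = values.sum(axis=1)
    keep = lib > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} all-zero cell(s) before normalization")
    values = values[keep]
    lib = lib[keep]
    norm = np.log1p(scale * values / lib[:, None])
    idx = counts.index[keep]
    return NormalizedMatrix(
        values=pd.DataFrame(norm, index=idx, columns=counts.columns),
        library_sizes=pd.Series(lib, index=idx, name="library_size"),
        n_dropped=n_dropped,
    )


class CellTypeAnnotator(BaseEstimator):
    """Assign canonical cell types from marker-gene expression.

    Each type is scored per cell as the mean normalized expression of its
    marker genes; the argmax type is assigned when it beats the runner-up
    by at least ``min_margin`` (log-scale units), otherwise the cell is
    'unassigned'.
    """

    def __init__(self, markers: dict[str, list[str]] | None = None,
                 min_margin: float = 0.1):
        self.markers = markers
        self.min_margin = min_margin

    def fit(self, X: pd.DataFrame, y=None) -> "CellTypeAnnotator":
        markers = self.markers if self.markers is not None else default_marker_table()
        if not markers:
            raise ValueError("marker table is empty")
        seen: dict[str, str] = {}
        for t, genes in markers.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"marker {g} assigned to both {seen[g]} and {t}")
                seen[g] = t
        self.markers_ = {}
        for t, genes in markers.items():
            present = [g for g in genes if g in X.columns]
            missing = set(genes) - set(present)
            if missing:
                warnings.warn(f"markers missing for {t}, skipped: {sorted(missing)}")
            if present:
                self.markers_[t] = present
        if not self.markers_:
            raise ValueError("no marker genes present in the matrix")
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        types = list(self.markers_)
        scores = np.column_stack(
            [X[self.markers_[t]].to_numpy(dtype=float).mean(axis=1) for t in types]
        )
        order = np.argsort(scores, axis=1)
        best = order[:, -1]
        margin = scores[np.arange(len(X)), best] - scores[
            np.arange(len(X)), order[:, -2]
        ] if len(types) > 1 else np.full(len(X), np.inf)
        labels = np.where(
            margin >= self.min_margin,
            np.asarray(types, dtype=object)[best],
            "unassigned",
        )
        return pd.Series(labels, index=X.index, name="cell_type")


def annotate_cell_types(
    norm: NormalizedMatrix | pd.DataFrame,
    markers: dict[str, list[str]] | None = None,
    min_margin: float = 0.1,
) -> pd.Series:
    X = norm.values if isinstance(norm, NormalizedMatrix) else norm
    return CellTypeAnnotator(markers, min_margin).fit(X).predict(X)


def _smooth_chromosome(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, truncated at block ends."""
    if window == 1:
        return block
    n = block.shape[1]
    half = window // 2
    csum = np.cumsum(block, axis=1)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)


class MovingAverageCNV(BaseEstimator, TransformerMixin):
    """Reference-relative moving-average CNV score.

    ``fit`` learns the per-gene baseline from reference cells; ``transform``
    subtracts it, orders genes by chromosomal position and smooths each
    chromosome with a centered moving average of width ``window``
    (truncated at chromosome ends).
    """

    def __init__(self, window: int = 101):
        self.window = window

    def fit(self, X: pd.DataFrame, y=None, *, positions: pd.DataFrame) -> "MovingAverageCNV":
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        if len(X) == 0:
            raise ValueError("reference cell set is empty")
        shared = [g for g in X.columns if g in positions.index]
        dropped = set(X.columns) - set(shared)
        if dropped:
            warnings.warn(
                f"{len(dropped)} gene(s) without position excluded from CNV scoring"
            )
        if not shared:
            raise ValueError("no gene has a chromosomal position")
        pos = positions.loc[shared]
        self.gene_order_ = (
            pos.sort_values(["chrom", "start"], kind="stable").index.to_list()
        )
        self.chrom_ = pos.loc[self.gene_order_, "chrom"].to_numpy()
        self.reference_mean_ = X[self.gene_order_].mean(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rel = X[self.gene_order_].to_numpy(dtype=float) - self.reference_mean_.to_numpy()
        out = np.empty_like(rel)
        for chrom in pd.unique(self.chrom_):
            cols = np.flatnonzero(self.chrom_ == chrom)
            out[:, cols] = _smooth_chromosome(rel[:, cols], self.window)
        return pd.DataFrame(out, index=X.index, columns=self.gene_order_)

    def burden(self, scores: pd.DataFrame) -> pd.Series:
        """Per-cell mean squared smoothed score."""
        return (scores ** 2).mean(axis=1).rename("cnv_burden")


def cnv_moving_average(
    norm: NormalizedMatrix | pd.DataFrame,
    positions: pd.DataFrame,
    reference_cells,
    window: int = 101,
) -> CnvProfile:
    """Compute the reference-relative moving-average CNV profile.

    ``reference_cells`` indexes the rows used as the normal-karyotype
    baseline (immune/stromal cells in practice).
    """
    X = norm.values if isinstance(norm, NormalizedMatrix) else norm
    ref = X.loc[reference_cells]
    est = MovingAverageCNV(window=window).fit(ref, positions=positions)
    scores = est.transform(X)
    return CnvProfile(scores=scores, burden=est.burden(scores))
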