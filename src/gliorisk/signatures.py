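"""Rank-based per-cell gene-signature scoring and group comparison.

The score is a Mann-Whitney-U statistic on the within-cell expression ranks
of the signature genes, with a rank ceiling so that the score reflects only
the top of each cell's transcriptome (the convention of rank-based
single-cell signature scorers).  Scores live in [0, 1] and are invariant to
any strictly monotone transform of a cell's expression vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GeneSignature",
    "HYPOXIA15",
    "hypoxia15_signature",
    "UCellScorer",
    "signature_score",
    "compare_signature_by_group",
]

# 15-gene expression signature classifying hypoxia status.
HYPOXIA15: tuple[str, ...] = (
    "ACOT7", "ADM", "ALDOA", "CDKN3", "ENO1", "LDHA", "MIF", "MRPS17",
    "NDRG1", "P4HA1", "PGAM1", "SLC2A1", "TPI1", "TUBB6", "VEGFA",
)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


def hypoxia15_signature() -> GeneSignature:
    """The packaged 15-gene hypoxia signature."""
    return GeneSignature("hypoxia15", HYPOXIA15)


class UCellScorer(BaseEstimator, TransformerMixin):
    """Per-cell rank-based signature activity score.

    For each cell, genes are ranked by descending expression (ties get the
    average rank) and ranks beyond ``max_rank`` are capped at
    ``max_rank + 1``.  With U the Mann-Whitney U of the signature genes'
    capped ranks, the score is ``1 - U / (n_sig * max_rank)``, clipped to
    [0, 1]: 1 when the signature occupies the very top ranks, ~0 when it is
    entirely below the ceiling.

    Parameters
    ----------
    signature:
        The gene set to score.
    max_rank:
        Rank ceiling; genes ranked below it contribute as if tied just
        beyond it.
    """

    def __init__(self, signature: GeneSignature, max_rank: int = 1500):
        self.signature = signature
        self.max_rank = max_rank

    def fit(self, X: pd.DataFrame, y=None) -> "UCellScorer":
        X = _as_frame(X)
        present = [g for g in self.signature.genes if g in X.columns]
        missing = [g for g in self.signature.genes if g not in X.columns]
        if not present:
            raise ValueError(
                f"signature '{self.signature.name}' entirely absent from the matrix"
            )
        if missing:
            warnings.warn(
                f"{len(missing)} signature gene(s) missing and skipped: {missing}"
            )
        self.genes_ = present
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        X = _as_frame(X)
        values = X.to_numpy(dtype=float)
        # descending ranks, average for ties, computed per cell
        ranks = stats.rankdata(-values, axis=1, method="average")
        capped = np.minimum(ranks, self.max_rank + 1)
        sig_idx = [X.columns.get_loc(g) for g in self.genes_]
        n_sig = len(sig_idx)
        r_sum = capped[:, sig_idx].sum(axis=1)
        u = r_sum - n_sig * (n_sig + 1) / 2.0
        score = 1.0 - u / (n_sig * self.max_rank)
        return pd.Series(np.clip(score, 0.0, 1.0), index=X.index, name=self.signature.name)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X))


def signature_score(
    norm: pd.DataFrame, signature: GeneSignature, max_rank: int = 1500
) -> pd.Series:
    """Score ``signature`` in every row (cell) of ``norm``; see
    :class:`UCellScorer`."""
    return UCellScorer(signature, max_rank=max_rank).fit(norm).transform(norm)


def compare_signature_by_group(
    scores: pd.Series, groups: pd.Series | np.ndarray, min_group_size: int = 3
):
    """Compare signature scores across groups.

    Two groups are compared with a two-sided Mann-Whitney test, three or
    more with Kruskal-Wallis.  Returns ``(per-group means, statistic, p)``.
    """
    groups = pd.Series(np.asarray(groups), index=scores.index)
    by = scores.groupby(groups)
    sizes = by.size()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    small = sizes[sizes < min_group_size]
    if len(small):
        raise ValueError(
            f"groups below the size floor ({min_group_size}): {list(small.index)}"
        )
    samples = [np.asarray(v) for _, v in by]
    if len(samples) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    else:
        stat, p = stats.kruskal(*samples)
    return by.mean(), float(stat), float(p)
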