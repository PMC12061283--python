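"""Reference-based bulk deconvolution and cluster-marker selection.

Subpopulation proportions in bulk samples are estimated by non-negative
least squares against mean single-cell reference profiles, renormalized to
the simplex — a deliberately simple estimator with the same contract as
Bayesian deconvolution tools (per-sample simplex proportions plus a
reconstruction residual), which is all the downstream marker-selection and
survival stages consume.

Marker selection follows an exclusivity-then-correlation scheme: candidate
markers of the target biological cluster are the top genes of its member
programs that appear in no other cluster's programs; candidates are then
ranked by the correlation of their bulk expression with the target
cluster's estimated proportion across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .programs import ExpressionProgram

__all__ = [
    "DeconvolutionResult",
    "MarkerRanking",
    "build_reference",
    "ReferenceDeconvolver",
    "deconvolve",
    "select_markers",
]


@dataclass
class DeconvolutionResult:
    """Simplex proportions per sample plus reconstruction residual."""

    proportions: pd.DataFrame
    residual: pd.Series


@dataclass
class MarkerRanking:
    """Exclusive candidate genes of the target cluster, ranked by
    correlation with its estimated proportion."""

    candidates: list[str]
    correlation: pd.Series
    ranked: list[str]
    selected: list[str]


def build_reference(
    norm_linear: pd.DataFrame,
    subpopulation: pd.Series,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Mean linear-scale normalized profile per subpopulation.

    ``norm_linear`` is cells x genes on a linear (library-size-normalized)
    scale; ``subpopulation`` labels each cell (cell types, with glioma
    split by biological cluster).  Subpopulations with fewer than
    ``min_cells`` cells are dropped with a warning.
    """
    subpopulation = pd.Series(np.asarray(subpopulation), index=norm_linear.index)
    sizes = subpopulation.value_counts()
    small = sizes[sizes < min_cells]
    if len(small):
        warnings.warn(
            f"subpopulations below {min_cells} cells dropped: {dict(small)}"
        )
    keep = subpopulation.isin(sizes[sizes >= min_cells].index)
    df = norm_linear.loc[keep].copy()
    prof = df.groupby(subpopulation[keep]).mean()
    prof.index.name = None
    return prof


class ReferenceDeconvolver(BaseEstimator, TransformerMixin):
    """Estimate subpopulation proportions in bulk samples by NNLS.

    ``fit`` takes the reference profile matrix (subpopulations x genes) and
    checks it is usable (>= 2 subpopulations, no collinear pair);
    ``transform`` fits each bulk sample as a non-negative combination of
    the profiles over the shared genes and renormalizes the weights to the
    simplex.  The residual is the relative L2 reconstruction error.
    """

    def __init__(self, min_shared_genes: int = 200):
        self.min_shared_genes = min_shared_genes

    def fit(self, reference: pd.DataFrame, y=None) -> "ReferenceDeconvolver":
        if len(reference) < 2:
            raise ValueError("need at least two reference subpopulations")
        R = reference.to_numpy(dtype=float)
        norms = np.linalg.norm(R, axis=1)
        if (norms == 0).any():
            zero = reference.index[norms == 0].tolist()
            raise ValueError(f"all-zero reference profile(s): {zero}")
        cosine = (R / norms[:, None]) @ (R / norms[:, None]).T
        np.fill_diagonal(cosine, 0.0)
        i, j = np.unravel_index(np.argmax(cosine), cosine.shape)
        if cosine[i, j] > 1.0 - 1e-10:
            raise ValueError(
                "reference is rank-deficient: profiles "
                f"'{reference.index[i]}' and '{reference.index[j]}' are collinear"
            )
        self.reference_ = reference
        return self

    def transform(self, bulk: pd.DataFrame) -> DeconvolutionResult:
        shared = [g for g in self.reference_.columns if g in bulk.columns]
        if len(shared) < self.min_shared_genes:
            raise ValueError(
                f"only {len(shared)} genes shared with the reference "
                f"(need >= {self.min_shared_genes})"
            )
        R = self.reference_[shared].to_numpy(dtype=float).T  # genes x subpops
        B = bulk[shared].to_numpy(dtype=float)
        props = np.zeros((len(bulk), R.shape[1]))
        resid = np.zeros(len(bulk))
        for s in range(len(bulk)):
            w, rnorm = nnls(R, B[s])
            total = w.sum()
            if total <= 0:
                warnings.warn(f"sample {bulk.index[s]} fit with all-zero weights")
                props[s] = 1.0 / R.shape[1]
            else:
                props[s] = w / total
            bnorm = np.linalg.norm(B[s])
            resid[s] = rnorm / bnorm if bnorm > 0 else 0.0
        return DeconvolutionResult(
            proportions=pd.DataFrame(
                props, index=bulk.index, columns=self.reference_.index
            ),
            residual=pd.Series(resid, index=bulk.index, name="residual"),
        )


def deconvolve(bulk: pd.DataFrame, reference: pd.DataFrame) -> DeconvolutionResult:
    """NNLS deconvolution of bulk samples against reference profiles."""
    return ReferenceDeconvolver().fit(reference).transform(bulk)


def select_markers(
    target_programs: list[ExpressionProgram],
    other_programs: list[ExpressionProgram],
    bulk: pd.DataFrame,
    proportions: pd.Series,
    m: int = 3,
    method: str = "pearson",
    min_recurrence: int = 1,
) -> MarkerRanking:
    """Select the target cluster's marker genes.

    Candidates are the union of the target programs' top genes minus the
    top genes of the other programs (exclusivity); each candidate's log1p
    bulk expression is correlated with the target-cluster proportion across
    samples, and the top ``m`` by descending correlation are selected.
    Zero-variance candidates are excluded with a warning.

    ``min_recurrence`` controls how many other programs a gene must appear
    in before it is excluded.  The default (1) excludes on any occurrence;
    2 requires the gene to recur, which makes the filter robust to the
    noisy tail of individual factors' top-gene lists (genuinely shared
    structure recurs across programs, single-factor noise does not).
    """
    target = set()
    for p in target_programs:
        target.update(p.top_genes)
    occurrences: dict[str, int] = {}
    for p in other_programs:
        for g in set(p.top_genes):
            occurrences[g] = occurrences.get(g, 0) + 1
    excluded = {g for g, c in occurrences.items() if c >= min_recurrence}
    candidates = sorted((target - excluded) & set(bulk.columns))
    if not candidates:
        raise ValueError("no candidate gene survives the exclusivity filter")

    prop = np.asarray(proportions, dtype=float)
    corr: dict[str, float] = {}
    dropped = []
    for g in candidates:
        x = np.log1p(bulk[g].to_numpy(dtype=float))
        if np.ptp(x) == 0 or np.ptp(prop) == 0:
            dropped.append(g)
            continue
        if method == "pearson":
            r = stats.pearsonr(x, prop).statistic
        elif method == "spearman":
            r = stats.spearmanr(x, prop).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        corr[g] = float(r)
    if dropped:
        warnings.warn(f"zero-variance candidate(s) excluded: {dropped}")
    if not corr:
        raise ValueError("all candidates had zero variance")
    series = pd.Series(corr).sort_values(ascending=False, kind="stable")
    ranked = series.index.to_list()
    return MarkerRanking(
        candidates=[g for g in candidates if g not in dropped],
        correlation=series,
        ranked=ranked,
        selected=ranked[:m],
    )
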