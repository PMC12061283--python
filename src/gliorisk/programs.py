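"""Per-tumor NMF expression programs and Jaccard meta-clustering.

Intra-tumor co-expression programs are learned tumor by tumor: the
normalized glioma-cell submatrix is centered per gene, negative values are
clipped to zero, and the result is factorized by NMF at a fixed rank (10 by
default, best of several random restarts).  Each factor yields one program,
summarized by its 100 highest-weight genes.  Programs from all tumors are
then compared by the Jaccard index of their top-gene sets and grouped by
average-linkage hierarchical clustering into biological clusters shared
across tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF

__all__ = [
    "ExpressionProgram",
    "ProgramSimilarity",
    "BioClusterSet",
    "prepare_nmf_input",
    "NMFProgramExtractor",
    "extract_programs",
    "jaccard_index",
    "program_similarity",
    "ProgramClusterer",
    "cluster_programs",
    "assign_cells",
]


@dataclass
class ExpressionProgram:
    """One NMF program: its tumor of origin and ranked gene weights."""

    tumor_id: str
    program_index: int
    gene_weights: pd.Series
    top_genes: list[str]
    usage: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.tumor_id}_P{self.program_index}"

    @property
    def top_gene_set(self) -> frozenset:
        return frozenset(self.top_genes)


@dataclass
class ProgramSimilarity:
    matrix: pd.DataFrame
    method: str = "jaccard"


@dataclass
class BioClusterSet:
    """Partition of programs into shared biological clusters."""

    cluster_of_program: dict[str, int]
    consensus_genes: dict[int, list[str]]
    n_clusters: int
    programs: list[ExpressionProgram] = field(default_factory=list)

    def members(self, cluster: int) -> list[ExpressionProgram]:
        return [p for p in self.programs if self.cluster_of_program[p.name] == cluster]


def prepare_nmf_input(
    norm: pd.DataFrame, tumor_cells=None, min_cells: int = 50
) -> pd.DataFrame:
    """Per-gene centering of a tumor's normalized glioma submatrix, negatives
    clipped to zero (the standard trick to feed centered expression to NMF)."""
    X = norm if tumor_cells is None else norm.loc[tumor_cells]
    if len(X) < min_cells:
        raise ValueError(
            f"only {len(X)} cells; need >= {min_cells} for a stable factorization"
        )
    centered = X - X.mean(axis=0)
    return centered.clip(lower=0.0)


class NMFProgramExtractor(BaseEstimator):
    """Extract ranked expression programs from one tumor by NMF.

    Factorizes the non-negative matrix at rank ``n_programs`` (Frobenius
    loss, best of ``n_restarts`` random initializations by reconstruction
    error).  Programs are ranked by total usage — the sum over cells of the
    factor's loadings times the sum of its gene weights — and each is
    summarized by its ``n_top_genes`` highest-weight genes.  All-zero gene
    columns are excluded from the factorization and from top genes.
    """

    def __init__(self, n_programs: int = 10, n_top_genes: int = 100,
                 n_restarts: int = 5, random_state: int = 0,
                 max_iter: int = 1000):
        self.n_programs = n_programs
        self.n_top_genes = n_top_genes
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None, tumor_id: str = "tumor") -> "NMFProgramExtractor":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        values = X.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("NMF input must be non-negative")
        nonzero = values.sum(axis=0) > 0
        if not nonzero.any():
            raise ValueError("all-zero matrix cannot be factorized")
        if self.n_programs >= min(values.shape[0], int(nonzero.sum())):
            raise ValueError("n_programs must be below min(cells, nonzero genes)")
        values = values[:, nonzero]
        genes = X.columns[nonzero]

        best = None
        best_err = np.inf
        # first restart uses the deterministic SVD-based init, the rest are
        # random; the best fit by reconstruction error wins
        for r in range(self.n_restarts):
            model = NMF(
                n_components=self.n_programs,
                init="nndsvda" if r == 0 else "random",
                solver="cd",
                max_iter=self.max_iter,
                random_state=self.random_state + r,
                tol=1e-5,
            )
            W = model.fit_transform(values)
            if model.reconstruction_err_ < best_err:
                best_err = model.reconstruction_err_
                best = (W, model.components_)
        W, H = best
        self.reconstruction_err_ = float(best_err)

        usage = W.sum(axis=0) * H.sum(axis=1)
        # rank by descending usage; ties broken by original factor index
        order = np.lexsort((np.arange(len(usage)), -usage))
        programs: list[ExpressionProgram] = []
        for rank, k in enumerate(order, start=1):
            weights = pd.Series(H[k], index=genes).sort_values(
                ascending=False, kind="stable"
            )
            programs.append(
                ExpressionProgram(
                    tumor_id=tumor_id,
                    program_index=rank,
                    gene_weights=weights,
                    top_genes=weights.index[: self.n_top_genes].to_list(),
                    usage=float(usage[k]),
                )
            )
        self.programs_ = programs
        return self


def extract_programs(
    matrix: pd.DataFrame,
    n_programs: int = 10,
    n_top_genes: int = 100,
    n_restarts: int = 5,
    seed: int = 0,
    tumor_id: str = "tumor",
) -> list[ExpressionProgram]:
    """Factorize one tumor's prepared matrix into ranked expression programs."""
    est = NMFProgramExtractor(
        n_programs=n_programs,
        n_top_genes=n_top_genes,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(matrix, tumor_id=tumor_id)
    return est.programs_


def jaccard_index(a, b) -> float:
    """|A n B| / |A u B| for two gene sets."""
    A, B = set(a), set(b)
    if not A and not B:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(A & B) / len(A | B)


def program_similarity(programs: list[ExpressionProgram]) -> ProgramSimilarity:
    """Pairwise Jaccard similarity of the programs' top-gene sets."""
    names = [p.name for p in programs]
    sets = [p.top_gene_set for p in programs]
    n = len(sets)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard_index(sets[i], sets[j])
    return ProgramSimilarity(pd.DataFrame(mat, index=names, columns=names))


class ProgramClusterer(BaseEstimator):
    """Average-linkage hierarchical clustering of programs on 1 - Jaccard.

    Cut at ``n_clusters`` when given, else at distance ``threshold``.
    Cluster ids are ordered by descending member count.  Each cluster's
    consensus signature is the set of genes appearing in at least half of
    the member programs' top-gene lists, completed to at least
    ``min_consensus_genes`` genes by mean weight rank across members.
    """

    def __init__(self, n_clusters: int | None = 8, threshold: float | None = None,
                 min_consensus_genes: int = 30):
        self.n_clusters = n_clusters
        self.threshold = threshold
        self.min_consensus_genes = min_consensus_genes

    def fit(self, programs: list[ExpressionProgram], y=None) -> "ProgramClusterer":
        sim = program_similarity(programs)
        n = len(programs)
        if self.n_clusters is not None and self.n_clusters > n:
            raise ValueError("n_clusters exceeds the number of programs")
        dist = 1.0 - sim.matrix.to_numpy()
        np.fill_diagonal(dist, 0.0)
        if n == 1:
            raw = np.array([1])
        else:
            Z = linkage(squareform(dist, checks=False), method="average")
            if self.n_clusters is not None:
                raw = fcluster(Z, t=self.n_clusters, criterion="maxclust")
            else:
                if self.threshold is None:
                    raise ValueError("either n_clusters or threshold must be set")
                raw = fcluster(Z, t=self.threshold, criterion="distance")
        # relabel clusters by descending member count (ties: first seen)
        counts = pd.Series(raw).value_counts()
        relabel = {old: i + 1 for i, old in enumerate(counts.index)}
        labels = [relabel[r] for r in raw]

        cluster_of_program = {p.name: c for p, c in zip(programs, labels)}
        consensus: dict[int, list[str]] = {}
        for c in sorted(set(labels)):
            members = [p for p, l in zip(programs, labels) if l == c]
            consensus[c] = self._consensus(members)
        self.similarity_ = sim
        self.labels_ = np.asarray(labels)
        self.clusters_ = BioClusterSet(
            cluster_of_program=cluster_of_program,
            consensus_genes=consensus,
            n_clusters=len(consensus),
            programs=list(programs),
        )
        return self

    def _consensus(self, members: list[ExpressionProgram]) -> list[str]:
        counts: dict[str, int] = {}
        for p in members:
            for g in p.top_genes:
                counts[g] = counts.get(g, 0) + 1
        need = len(members) / 2.0
        core = [g for g, c in counts.items() if c >= need]
        if len(core) >= self.min_consensus_genes:
            return sorted(core)
        # complete by mean weight rank across member programs
        rank_sum: dict[str, float] = {}
        for p in members:
            for r, g in enumerate(p.top_genes):
                rank_sum[g] = rank_sum.get(g, 0.0) + r
            # genes absent from a member's top list count as rank beyond it
            for g in counts:
                if g not in p.top_genes:
                    rank_sum[g] = rank_sum.get(g, 0.0) + len(p.top_genes)
        extras = sorted(
            (g for g in counts if g not in core),
            key=lambda g: (rank_sum[g], g),
        )
        out = list(core) + extras[: self.min_consensus_genes - len(core)]
        return sorted(out)


def cluster_programs(
    programs: list[ExpressionProgram],
    n_clusters: int | None = 8,
    threshold: float | None = None,
) -> BioClusterSet:
    """Group programs into shared biological clusters; see
    :class:`ProgramClusterer`."""
    est = ProgramClusterer(n_clusters=n_clusters, threshold=threshold)
    return est.fit(programs).clusters_


def assign_cells(
    norm: pd.DataFrame, clusters: BioClusterSet, min_score: float = 0.1
) -> pd.Series:
    """Assign each (glioma) cell to the biological cluster whose consensus
    signature it expresses most, relative to the cell's global mean.

    The score of cluster k in cell c is the mean normalized expression of
    k's consensus genes minus c's mean over all genes; the argmax cluster is
    assigned when its score exceeds ``min_score``, else the cell gets
    ``-1`` (none).
    """
    for c, genes in clusters.consensus_genes.items():
        if not genes:
            raise ValueError(f"cluster {c} has an empty consensus gene set")
    global_mean = norm.mean(axis=1).to_numpy()
    ids = sorted(clusters.consensus_genes)
    scores = np.column_stack(
        [
            norm[[g for g in clusters.consensus_genes[c] if g in norm.columns]]
            .to_numpy(dtype=float)
            .mean(axis=1)
            - global_mean
            for c in ids
        ]
    )
    best = np.argmax(scores, axis=1)
    best_score = scores[np.arange(len(norm)), best]
    labels = np.where(best_score > min_score, np.asarray(ids)[best], -1)
    return pd.Series(labels, index=norm.index, name="bio_cluster")
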