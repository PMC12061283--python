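"""End-to-end analysis: programs -> clusters -> deconvolution -> risk model.

`run_pipeline` wires the stages together on a single-cell cohort plus one
or more bulk cohorts: per-tumor NMF programs, Jaccard meta-clustering into
biological clusters, per-cell cluster assignment, reference construction,
bulk deconvolution, survival-based identification of the high-risk cluster,
exclusivity/correlation marker selection, marker-based risk stratification
and hypoxia signature comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .deconvolution import (
    DeconvolutionResult,
    MarkerRanking,
    build_reference,
    deconvolve,
    select_markers,
)
from .preprocess import annotate_cell_types, normalize_counts
from .programs import (
    BioClusterSet,
    ExpressionProgram,
    assign_cells,
    cluster_programs,
    extract_programs,
    prepare_nmf_input,
)
from .signatures import compare_signature_by_group, hypoxia15_signature, signature_score
from .simulate import BulkCohort
from .survival import RiskModel, RiskStratifier, optimal_cutpoint

__all__ = ["PipelineResult", "discover_programs", "identify_highrisk_cluster",
           "shared_programs", "run_pipeline"]


@dataclass
class PipelineResult:
    programs: list[ExpressionProgram]
    clusters: BioClusterSet
    cell_assignment: pd.Series
    highrisk_cluster: int
    deconvolution: dict[str, DeconvolutionResult]
    markers: dict[str, MarkerRanking]
    risk_models: dict[str, RiskModel]
    hypoxia: dict[str, object] = field(default_factory=dict)


def discover_programs(
    norm: pd.DataFrame,
    patient: pd.Series,
    cell_type: pd.Series,
    n_programs: int = 10,
    n_top_genes: int = 100,
    n_restarts: int = 5,
    seed: int = 0,
) -> list[ExpressionProgram]:
    """Per-tumor NMF programs over the glioma cells of every patient."""
    programs: list[ExpressionProgram] = []
    for tumor in pd.unique(patient):
        cells = norm.index[(patient == tumor) & (cell_type == "glioma")]
        prepared = prepare_nmf_input(norm, cells)
        programs.extend(
            extract_programs(
                prepared,
                n_programs=n_programs,
                n_top_genes=n_top_genes,
                n_restarts=n_restarts,
                seed=seed,
                tumor_id=str(tumor),
            )
        )
    return programs


def shared_programs(
    programs: list[ExpressionProgram], min_jaccard: float = 0.1
) -> list[ExpressionProgram]:
    """Programs shared across tumors: top-gene Jaccard of at least
    ``min_jaccard`` with some program of another tumor.

    Biological clusters are by definition shared by multiple tumors; a
    factor with no counterpart in any other tumor is tumor-specific
    residual structure and carries no cross-cohort signal, so it is kept
    out of the marker exclusivity filter.
    """
    from .programs import jaccard_index

    out = []
    for p in programs:
        best = max(
            (
                jaccard_index(p.top_gene_set, q.top_gene_set)
                for q in programs
                if q.tumor_id != p.tumor_id
            ),
            default=0.0,
        )
        if best >= min_jaccard:
            out.append(p)
    return out


def identify_highrisk_cluster(
    deconv: DeconvolutionResult,
    clinical: pd.DataFrame,
    cluster_columns: list[str],
) -> tuple[str, pd.Series]:
    """Pick the biological cluster whose estimated proportion best separates
    survival with the high-proportion group doing worse.

    For each cluster column, samples are split at the optimal-cutpoint
    log-rank scan on the proportion; the cluster with the smallest p among
    those where the high-proportion group has the worse outcome (smaller
    restricted mean survival) is returned.
    """
    from .survival import km_estimate, logrank_test

    times = clinical["time"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=int)

    def rmst(mask, horizon):
        curve = km_estimate(times[mask], events[mask])
        t = np.append(curve["time"].to_numpy(), horizon)
        s = np.append(1.0, curve["survival"].to_numpy())
        t = np.clip(t, None, horizon)
        return float(np.sum(np.diff(np.append(0.0, t)) * s))

    pvals = {}
    for col in cluster_columns:
        prop = deconv.proportions[col].to_numpy()
        if np.ptp(prop) == 0:
            continue
        try:
            cut, groups = optimal_cutpoint(prop, times, events)
        except ValueError:
            continue
        _, p = logrank_test(times, events, groups)
        high = groups == "high"
        horizon = times.max()
        worse = rmst(high, horizon) < rmst(~high, horizon)
        pvals[col] = (p if worse else 1.0, p)
    if not pvals:
        raise ValueError("no cluster proportion admits a survival split")
    best = min(pvals, key=lambda c: pvals[c][0])
    return best, pd.Series({c: v[1] for c, v in pvals.items()}, name="logrank_p")


def run_pipeline(
    sc: ad.AnnData,
    bulks: dict[str, BulkCohort],
    n_programs: int = 10,
    n_top_genes: int = 100,
    n_clusters: int = 8,
    n_markers: int = 3,
    seed: int = 0,
) -> PipelineResult:
    """Run the full discovery-to-stratification analysis.

    The high-risk cluster is identified on the first bulk cohort and the
    marker ranking plus risk model are computed per cohort.
    """
    counts = pd.DataFrame(
        np.asarray(sc.X), index=sc.obs_names, columns=sc.var_names
    )
    norm = normalize_counts(counts)
    labels = annotate_cell_types(norm)

    programs = discover_programs(
        norm.values,
        sc.obs["patient"].reindex(norm.values.index),
        labels,
        n_programs=n_programs,
        n_top_genes=n_top_genes,
        seed=seed,
    )
    clusters = cluster_programs(programs, n_clusters=n_clusters)

    glioma_cells = norm.values.index[labels == "glioma"]
    cell_assignment = assign_cells(norm.values.loc[glioma_cells], clusters)

    # linear-scale reference split by cluster for glioma, cell type otherwise
    linear = pd.DataFrame(
        np.expm1(norm.values.to_numpy()),
        index=norm.values.index,
        columns=norm.values.columns,
    )
    subpop = labels.copy().astype(object)
    for cell in glioma_cells:
        c = cell_assignment.loc[cell]
        subpop.loc[cell] = f"glioma_C{c}" if c != -1 else "glioma_unresolved"
    subpop = subpop[subpop != "unassigned"]
    reference = build_reference(linear.loc[subpop.index], subpop)

    deconv = {name: deconvolve(b.expression, reference) for name, b in bulks.items()}

    cluster_cols = [c for c in reference.index if c.startswith("glioma_C")]
    first = next(iter(bulks))
    hr_col, cluster_pvals = identify_highrisk_cluster(
        deconv[first], bulks[first].clinical, cluster_cols
    )
    hr_cluster = int(hr_col.removeprefix("glioma_C"))

    shared = shared_programs(programs)
    target = [p for p in shared if clusters.cluster_of_program[p.name] == hr_cluster]
    others = [p for p in shared if clusters.cluster_of_program[p.name] != hr_cluster]
    markers = {
        name: select_markers(
            target, others, b.expression, deconv[name].proportions[hr_col],
            m=n_markers, min_recurrence=2,
        )
        for name, b in bulks.items()
    }

    risk_models = {}
    for name, b in bulks.items():
        cov = pd.DataFrame(
            {
                "grade3": (b.clinical["grade"] == 3).astype(float),
                "idh_wild": (b.clinical["idh"] == "wild").astype(float),
            },
            index=b.clinical.index,
        )
        est = RiskStratifier(markers[name].selected).fit(
            b.expression, b.clinical, covariates=cov
        )
        risk_models[name] = est.model_

    # hypoxia signature in glioma cells: high-risk cluster vs the rest
    hyp_scores = signature_score(norm.values.loc[glioma_cells], hypoxia15_signature())
    grp = np.where(cell_assignment == hr_cluster, "highrisk", "other")
    hyp_means, hyp_stat, hyp_p = compare_signature_by_group(hyp_scores, grp)
    hypoxia = {
        "scores": hyp_scores,
        "group_means": hyp_means,
        "statistic": hyp_stat,
        "p": hyp_p,
        "cluster_pvals": cluster_pvals,
    }

    return PipelineResult(
        programs=programs,
        clusters=clusters,
        cell_assignment=cell_assignment,
        highrisk_cluster=hr_cluster,
        deconvolution=deconv,
        markers=markers,
        risk_models=risk_models,
        hypoxia=hypoxia,
    )
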