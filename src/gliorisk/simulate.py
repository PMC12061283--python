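"""Synthetic single-cell and bulk glioma cohorts with planted structure.

The generator emulates the statistical shape of a small multi-patient LGG
study: a handful of patients profiled by scRNA-seq, whose glioma cells carry
shared co-expression programs, and bulk cohorts built as mixtures of those
subpopulations with survival times driven by the abundance of one high-risk
program.  All planted parameters are recorded so downstream stages
(program discovery, deconvolution, marker selection, survival modelling)
can be tested for recovery without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .signatures import HYPOXIA15

__all__ = [
    "SimConfig",
    "BulkCohort",
    "DEFAULT_CELL_TYPE_FRACTIONS",
    "CELL_TYPE_MARKERS",
    "generate_sc_cohort",
    "generate_bulk_cohort",
]

# Canonical marker panel used both to plant cell identities and (in
# sc_preprocess) to call them back.
CELL_TYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "glioma": ("GFAP", "PTPRZ1"),
    "oligodendrocyte": ("MOG",),
    "pericyte": ("RGS5",),
    "T": ("CD3D", "CD3E"),
    "macrophage": ("CD68",),
}

DEFAULT_CELL_TYPE_FRACTIONS: dict[str, float] = {
    "glioma": 0.6,
    "T": 0.1,
    "oligodendrocyte": 0.1,
    "macrophage": 0.1,
    "pericyte": 0.1,
}

# Canonical markers are planted as truly specific genes: a low ectopic
# baseline everywhere and a strong induction in their own cell type.
MARKER_BASELINE = 0.05
MARKER_FOLD = 200.0
# Planted arm-level gain carried by all glioma cells (one extra copy of one
# chromosome arm, i.e. 3/2 dosage), used to test the CNV moving average.
CNV_GAIN = 1.5
CNV_GAIN_CHROM = "chr7"
N_CHROMOSOMES = 22


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted single-cell cohort.

    Defaults mirror the study design being emulated: 4 patients, five
    canonical cell types, eight disjoint glioma co-expression programs of
    100 genes each, one of which is a high-risk program carrying three
    designated exclusive marker genes and elevated hypoxia-signature
    activity.
    """

    n_patients: int = 4
    n_cells_per_patient: int = 500
    n_genes: int = 2000
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPE_FRACTIONS)
    )
    n_planted_programs: int = 8
    program_size: int = 100
    highrisk_marker_genes: tuple[str, str, str] = ("CDC20", "KIF20A", "PTTG1")
    highrisk_fraction: float = 0.15
    program_effect: float = 3.0
    marker_boost: float = 3.0
    baseline_dispersion: float = 0.5
    hypoxia_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"cell_type_fractions must sum to 1 (got {total!r})"
            )
        if min(self.cell_type_fractions.values()) < 0:
            raise ValueError("cell_type_fractions must be non-negative")
        for name in ("n_patients", "n_cells_per_patient", "n_genes",
                     "n_planted_programs", "program_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.highrisk_fraction <= 1.0:
            raise ValueError("highrisk_fraction must lie in [0, 1]")
        if self.program_effect <= 1.0:
            raise ValueError("program_effect must exceed 1")
        if len(set(self.highrisk_marker_genes)) != 3:
            raise ValueError("highrisk_marker_genes must be three distinct genes")
        n_special = (
            sum(len(v) for v in CELL_TYPE_MARKERS.values())
            + len(HYPOXIA15)
            + 3
        )
        if self.n_planted_programs * self.program_size + n_special > self.n_genes:
            raise ValueError(
                "planted program gene sets exceed n_genes: "
                f"{self.n_planted_programs} x {self.program_size} programs plus "
                f"{n_special} reserved genes do not fit in {self.n_genes} genes"
            )


@dataclass
class BulkCohort:
    """Bulk expression cohort with survival metadata.

    ``expression`` is samples x genes (non-negative, linear scale);
    ``clinical`` has columns ``time`` (days), ``event`` (0/1), ``grade``
    (2/3) and ``idh`` ('mutant'/'wild'); ``true_proportions`` records the
    planted mixing weights (rows on the simplex) when synthetic.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    true_proportions: pd.DataFrame | None = None
    highrisk_column: str | None = None

    def __post_init__(self) -> None:
        if self.true_proportions is not None:
            rowsum = self.true_proportions.sum(axis=1).to_numpy()
            if np.abs(rowsum - 1.0).max() > 1e-6:
                raise ValueError("true_proportions rows must sum to 1")
        if (self.clinical["time"] <= 0).any():
            raise ValueError("survival_time must be positive")
        if not set(self.clinical["event"].unique()) <= {0, 1}:
            raise ValueError("event must be 0/1")


def _gene_names(config: SimConfig) -> list[str]:
    special: list[str] = []
    for genes in CELL_TYPE_MARKERS.values():
        special.extend(genes)
    special.append("PECAM1")  # endothelial marker kept in the panel namespace
    special.extend(HYPOXIA15)
    special.extend(config.highrisk_marker_genes)
    generic = [f"G{i:04d}" for i in range(config.n_genes - len(special))]
    return special + generic


def _gene_positions(genes: list[str]) -> pd.DataFrame:
    """Bin genes uniformly into 22 synthetic chromosomes in index order."""
    n = len(genes)
    per_chrom = int(np.ceil(n / N_CHROMOSOMES))
    chrom = [f"chr{i // per_chrom + 1}" for i in range(n)]
    start = [(i % per_chrom) * 100_000 + 1 for i in range(n)]
    return pd.DataFrame({"chrom": chrom, "start": start}, index=genes)


def _plant_programs(config: SimConfig, genes: list[str],
                    rng: np.random.Generator) -> dict[str, list[str]]:
    """Disjoint program gene sets; the last program is the high-risk one and
    is the only program containing the designated marker genes."""
    reserved = set()
    for ms in CELL_TYPE_MARKERS.values():
        reserved.update(ms)
    reserved.add("PECAM1")
    reserved.update(HYPOXIA15)
    reserved.update(config.highrisk_marker_genes)
    pool = [g for g in genes if g not in reserved]
    need = config.n_planted_programs * config.program_size - 3
    picked = rng.choice(len(pool), size=need, replace=False)
    picked_genes = [pool[i] for i in picked]
    programs: dict[str, list[str]] = {}
    at = 0
    for k in range(config.n_planted_programs - 1):
        programs[f"prog{k + 1}"] = picked_genes[at:at + config.program_size]
        at += config.program_size
    hr = list(config.highrisk_marker_genes) + picked_genes[at:at + config.program_size - 3]
    programs[f"prog{config.n_planted_programs}"] = hr
    return programs


def generate_sc_cohort(config: SimConfig | None = None) -> ad.AnnData:
    """Generate the planted single-cell cohort.

    Returns an :class:`~anndata.AnnData` with integer counts in ``X``,
    per-cell ``obs`` columns ``patient``, ``cell_type`` and ``program``
    (program label only on glioma cells, '' otherwise), per-gene ``var``
    columns ``chrom`` and ``start``, and the full planted ground truth in
    ``uns['truth']``.

    Counts follow a negative-binomial model (gamma-Poisson mixture) with
    gene-specific lognormal baseline means; each cell type over-expresses
    its canonical markers, each glioma cell carries exactly one planted
    program whose genes are scaled by ``program_effect`` (the three
    designated markers by ``program_effect * marker_boost`` in high-risk
    cells), high-risk cells additionally scale the 15 hypoxia-signature
    genes by ``hypoxia_effect``, and all glioma cells carry a planted
    arm-level gain on one chromosome.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    positions = _gene_positions(genes)
    programs = _plant_programs(config, genes, rng)
    hr_program = f"prog{config.n_planted_programs}"

    gene_index = {g: i for i, g in enumerate(genes)}
    n_cells = config.n_patients * config.n_cells_per_patient

    # gene-specific baseline means, lognormal across genes
    mu = rng.lognormal(mean=np.log(0.2), sigma=1.0, size=config.n_genes)
    # the designated high-risk markers emulate strongly state-restricted
    # genes (cell-cycle/mitosis class): a well-measured moderate baseline,
    # induced marker_boost-fold beyond the program effect in carrier cells
    for g in config.highrisk_marker_genes:
        mu[genes.index(g)] = 0.5
    # cell-type markers are specific: near-silent outside their own type
    for ms in CELL_TYPE_MARKERS.values():
        for g in ms:
            mu[genes.index(g)] = MARKER_BASELINE
    mu[genes.index("PECAM1")] = MARKER_BASELINE

    # per-cell labels
    types = list(config.cell_type_fractions)
    type_p = np.array([config.cell_type_fractions[t] for t in types])
    patient = np.repeat(
        [f"P{i + 1}" for i in range(config.n_patients)],
        config.n_cells_per_patient,
    )
    cell_type = np.empty(n_cells, dtype=object)
    program_of_cell = np.full(n_cells, "", dtype=object)

    prog_names = list(programs)
    other = [p for p in prog_names if p != hr_program]
    if config.highrisk_fraction < 1.0 and other:
        p_other = (1.0 - config.highrisk_fraction) / len(other)
    else:
        p_other = 0.0
    prog_p = np.array(
        [config.highrisk_fraction if p == hr_program else p_other
         for p in prog_names]
    )
    prog_p = prog_p / prog_p.sum()

    mean = np.empty((n_cells, config.n_genes))
    cnv_genes = np.asarray(positions["chrom"] == CNV_GAIN_CHROM)
    hyp_idx = [gene_index[g] for g in HYPOXIA15]
    marker_idx = {t: [gene_index[g] for g in ms]
                  for t, ms in CELL_TYPE_MARKERS.items()}
    prog_idx = {p: [gene_index[g] for g in gs] for p, gs in programs.items()}
    hr_marker_idx = [gene_index[g] for g in config.highrisk_marker_genes]

    for p in range(config.n_patients):
        lo = p * config.n_cells_per_patient
        hi = lo + config.n_cells_per_patient
        ct = rng.choice(types, size=hi - lo, p=type_p)
        cell_type[lo:hi] = ct
        glioma = np.flatnonzero(ct == "glioma")
        assigned = rng.choice(prog_names, size=glioma.size, p=prog_p)
        program_of_cell[lo + glioma] = assigned

    for c in range(n_cells):
        m = mu.copy()
        t = cell_type[c]
        m[marker_idx[t]] *= MARKER_FOLD
        if t == "glioma":
            m[cnv_genes] *= CNV_GAIN
            prog = program_of_cell[c]
            if prog:
                m[prog_idx[prog]] *= config.program_effect
                if prog == hr_program:
                    m[hr_marker_idx] *= config.marker_boost
                    m[hyp_idx] *= config.hypoxia_effect
        mean[c] = m

    alpha = config.baseline_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int32)

    obs = pd.DataFrame(
        {
            "patient": patient,
            "cell_type": cell_type,
            "program": program_of_cell,
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = positions.copy()
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["truth"] = {
        "programs": {k: list(v) for k, v in programs.items()},
        "highrisk_program": hr_program,
        "highrisk_markers": list(config.highrisk_marker_genes),
        "hypoxia_genes": list(HYPOXIA15),
        "cnv_gain_chrom": CNV_GAIN_CHROM,
        "cnv_gain": CNV_GAIN,
        "config": dataclasses.asdict(config),
    }
    return adata


def _subpopulation_label(cell_type: str, program: str) -> str:
    if cell_type == "glioma" and program:
        return f"glioma_{program}"
    return cell_type


def subpopulation_profiles(sc: ad.AnnData, scale: float = 1e4) -> pd.DataFrame:
    """Mean library-size-normalized (linear, counts-per-``scale``) profile of
    every planted subpopulation: non-glioma cell types plus glioma split by
    planted program."""
    counts = np.asarray(sc.X, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    keep = lib[:, 0] > 0
    cp10k = scale * counts[keep] / lib[keep]
    labels = [
        _subpopulation_label(t, p)
        for t, p in zip(sc.obs["cell_type"][keep], sc.obs["program"][keep])
    ]
    df = pd.DataFrame(cp10k, columns=sc.var_names)
    df["__subpop"] = labels
    prof = df.groupby("__subpop").mean()
    prof.index.name = None
    return prof


def generate_bulk_cohort(
    sc: ad.AnnData,
    n_samples: int,
    survival_params: dict | None = None,
    seed: int = 0,
    noise_sigma: float = 0.2,
    concentration: float = 10.0,
) -> BulkCohort:
    """Generate a bulk cohort as convex mixtures of the single-cell
    subpopulation profiles, with survival driven by the high-risk fraction.

    Each sample's expression is ``weights @ profiles`` with multiplicative
    lognormal noise of scale ``noise_sigma`` (set 0 for exact mixtures).
    Mixing weights are Dirichlet with mean equal to the cohort-wide
    subpopulation composition and the given ``concentration``.  Survival
    times are exponential with log-hazard linear in the high-risk program
    proportion; censoring is independent exponential calibrated so that
    about ``censor_rate`` of baseline-hazard samples are censored.  Tumor
    grade (2/3) and IDH status covariates are drawn with probabilities that
    shift with the high-risk proportion, mimicking the clinical enrichment
    of aggressive features in high-risk cases.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10 (cutpoint scan undefined below)")
    params = {
        "baseline_hazard": 1e-3,
        "log_hazard_per_unit_highrisk": 4.0,
        "censor_rate": 0.3,
    }
    if survival_params:
        params.update(survival_params)
    rng = np.random.default_rng(seed)

    prof = subpopulation_profiles(sc)
    subpops = list(prof.index)
    for s in subpops:
        if not (
            (sc.obs["cell_type"] == s).any()
            or s.startswith("glioma_")
        ):
            raise ValueError(f"subpopulation {s} has no cells")

    # cohort-wide composition as the Dirichlet mean
    labels = [
        _subpopulation_label(t, p)
        for t, p in zip(sc.obs["cell_type"], sc.obs["program"])
    ]
    comp = pd.Series(labels).value_counts(normalize=True).reindex(subpops)
    alpha = comp.to_numpy() * concentration
    weights = rng.dirichlet(alpha, size=n_samples)

    expr = weights @ prof.to_numpy()
    if noise_sigma > 0:
        expr = expr * rng.lognormal(0.0, noise_sigma, size=expr.shape)

    hr_program = sc.uns["truth"]["highrisk_program"]
    hr_col = f"glioma_{hr_program}"
    w_hr = weights[:, subpops.index(hr_col)]

    lam0 = params["baseline_hazard"]
    beta = params["log_hazard_per_unit_highrisk"]
    rate = lam0 * np.exp(beta * w_hr)
    t_event = rng.exponential(1.0 / rate)
    cr = params["censor_rate"]
    if cr > 0:
        c_rate = lam0 * cr / (1.0 - cr)
        t_cens = rng.exponential(1.0 / c_rate, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)

    # clinical covariates enriched with the high-risk fraction
    z = (w_hr - w_hr.mean()) / (w_hr.std() + 1e-12)
    p_grade3 = 1.0 / (1.0 + np.exp(-(-0.4 + 1.0 * z)))
    p_wild = 1.0 / (1.0 + np.exp(-(-0.6 + 1.0 * z)))
    grade = np.where(rng.random(n_samples) < p_grade3, 3, 2)
    idh = np.where(rng.random(n_samples) < p_wild, "wild", "mutant")

    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    expression = pd.DataFrame(expr, index=samples, columns=prof.columns)
    clinical = pd.DataFrame(
        {"time": time, "event": event, "grade": grade, "idh": idh},
        index=samples,
    )
    props = pd.DataFrame(weights, index=samples, columns=subpops)
    return BulkCohort(
        expression=expression,
        clinical=clinical,
        true_proportions=props,
        highrisk_column=hr_col,
    )
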