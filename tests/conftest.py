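import warnings

import numpy as np
import pandas as pd
import pytest

import gliorisk as gr

# the default planted cohort and everything derived from it are expensive;
# build once per session
COHORT_SEED = 0


@pytest.fixture(scope="session")
def sc_cohort():
    return gr.generate_sc_cohort(gr.SimConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def norm(sc_cohort):
    counts = pd.DataFrame(
        np.asarray(sc_cohort.X),
        index=sc_cohort.obs_names,
        columns=sc_cohort.var_names,
    )
    return gr.normalize_counts(counts)


@pytest.fixture(scope="session")
def cell_labels(norm):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gr.annotate_cell_types(norm)


@pytest.fixture(scope="session")
def programs(sc_cohort, norm, cell_labels):
    return gr.discover_programs(
        norm.values,
        sc_cohort.obs["patient"].reindex(norm.values.index),
        cell_labels,
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def clusters(programs):
    return gr.cluster_programs(programs, n_clusters=8)


@pytest.fixture(scope="session")
def bulk_cohorts(sc_cohort):
    return {
        "c2": gr.generate_bulk_cohort(sc_cohort, 500, seed=11),
        "c3": gr.generate_bulk_cohort(sc_cohort, 420, seed=22),
    }


@pytest.fixture(scope="session")
def pipeline_result(sc_cohort, bulk_cohorts):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gr.run_pipeline(sc_cohort, bulk_cohorts, seed=COHORT_SEED)


@pytest.fixture()
def tiny_config():
    # small cohort for fast I/O and CLI checks
    return gr.SimConfig(
        n_patients=2,
        n_cells_per_patient=120,
        n_genes=400,
        n_planted_programs=3,
        program_size=30,
        seed=7,
    )
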