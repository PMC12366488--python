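import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from screpsim import DESpec, EmpiricalDataset, RescueParams, simulate_dataset


def make_params(rng=None, **overrides) -> RescueParams:
    """Small but realistic simulator parameters for tests."""
    rng = rng or np.random.default_rng(0)
    defaults = dict(
        n_genes=300,
        n_subjects=4,
        n_timepoints=2,
        cells_per_sample=50,
        mu_a=-2.0,
        sigma_a=0.5,
        mu_b=-2.5,
        sigma_b=0.5,
        mu_lib=8.0,
        sigma_lib=0.3,
        lib_concentration=100.0,
    )
    defaults.update(overrides)
    g = defaults["n_genes"]
    defaults.setdefault("gene_means", np.exp(rng.normal(0.0, 1.5, g)))
    defaults.setdefault("dispersions", np.full(g, 0.4))
    return RescueParams(**defaults)


@pytest.fixture
def small_params():
    return make_params()


@pytest.fixture
def small_sim(small_params):
    return simulate_dataset(small_params, seed=42)


@pytest.fixture
def de_params():
    return make_params(de_spec=DESpec(proportion_de=0.2, log2fc=1.0))


def build_dataset(counts, subjects, timepoints, gene_ids=None, samples=None):
    """Assemble an EmpiricalDataset from a dense count array and labels."""
    counts = np.asarray(counts)
    n_cells = counts.shape[1]
    subjects = list(subjects)
    timepoints = [str(t) for t in timepoints]
    if samples is None:
        samples = [f"{s}_{t}" for s, t in zip(subjects, timepoints)]
    levels = sorted(set(timepoints))
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i + 1}" for i in range(n_cells)],
            "subject_id": subjects,
            "sample_id": samples,
            "timepoint": pd.Categorical(timepoints, categories=levels, ordered=True),
        }
    )
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(counts.shape[0])]
    return EmpiricalDataset(
        counts=sp.csr_matrix(counts), gene_ids=gene_ids, cells=cells
    )


@pytest.fixture
def toy_dataset():
    """3 genes x 4 cells: 2 subjects x 2 timepoints, 1 cell each."""
    counts = np.array([[5, 0, 2, 1], [0, 3, 0, 0], [1, 1, 4, 2]])
    return build_dataset(
        counts,
        subjects=["s1", "s1", "s2", "s2"],
        timepoints=["t1", "t2", "t1", "t2"],
    )
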