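# screpsim

Simulation of paired/longitudinal single-cell RNA-seq count data with a
hierarchical gamma-Poisson model, plus parameter estimation from empirical
data, simulation-fidelity metrics, and a simulate-then-down-sample power
analysis engine.

## Model

Counts for gene *g*, subject *i*, sample *j*, cell *k* are generated in
three stages:

1. **Sample means.** Each gene's global mean is multiplied by mean-one
   subject factors and sample factors drawn from scaled symmetric Dirichlet
   distributions whose per-gene variances are themselves log-normal draws
   (hyper-parameters `mu_a/sigma_a` for subjects, `mu_b/sigma_b` for
   samples). This creates nested subject → sample → cell correlation.
2. **True expression.** Per-cell values come from a gamma distribution with
   gene-specific dispersion; designated genes are scaled by a fold change
   that ramps linearly from the first to the last timepoint.
3. **Observed counts.** Each cell's true expression is rescaled to a
   log-normally drawn expected library size (with Dirichlet-distributed
   sample-specific location shifts, or resampled from a user-supplied
   empirical library-size vector) and observed through a Poisson.

Every hyper-parameter can be estimated from a genes × cells count matrix
with subject/sample/timepoint annotations: pooled-deconvolution size
factors, the sample/subject/global mean hierarchy, variance decomposition
with a delta-method sampling-error correction, Cox–Reid adjusted-profile
NB dispersions on the largest sample (with empirical-Bayes trend
shrinkage), and per-sample log-library statistics. Designs lacking paired
or multi-sample structure fall back to packaged defaults derived from a
synthetic reference (`src/screpsim/data/defaults.yaml`, regenerated by
`scripts/derive_defaults.py`).

## Command line

```sh
# estimate parameters from a dataset directory (matrix.mtx + genes.tsv +
# barcodes.tsv + cell_metadata.tsv)
screpsim estimate --data data_dir/ --out est/

# simulate from a params file (seed mandatory)
screpsim simulate --params est/params.yaml --seed 7 --out sim/

# fidelity report comparing two datasets
screpsim assess --a data_dir/ --b sim/ --out report/ --silhouette

# power / FDR / T1E over a scenario grid
screpsim power --params est/params.yaml --seed 7 --out power/ --replicates 10
```

Every command writes a `provenance.json` (tool version, seed, config) next
to its outputs. Differential expression intent is given either inside the
params file or via `--de-config`, in one of three forms: a proportion of DE
genes plus a single log2FC magnitude (even up/down split), a pool of log2FC
values sampled per gene, or an explicit per-gene log2FC-by-timepoint map.

## Library API

```python
from screpsim import (
    read_counts_with_metadata, estimate_params, simulate_dataset,
    compare_datasets, run_power_grid, DESpec, Scenario,
)

dataset = read_counts_with_metadata("matrix.mtx", "genes.tsv", "meta.tsv",
                                    {"subject_id": "donor", "sample_id": "sample",
                                     "timepoint": "visit"})
params = estimate_params(dataset)
sim = simulate_dataset(params.with_updates(
    de_spec=DESpec(proportion_de=0.2, log2fc=0.35)), seed=1)
report = compare_datasets(dataset, sim.dataset, compute_icc=True)
```

The power engine simulates one master dataset per replicate at the grid's
envelope design, down-samples subjects / timepoints / cells per scenario
(sharing truth labels across scenarios), filters genes with more than 90%
zeros, and tests first-vs-last-timepoint DE. The builtin test is a
pseudobulk paired moderated-t; per-cell mixed-model backends can be plugged
in through the external adapter contract
(`screpsim.power.run_external_adapter`), which writes each dataset to disk,
invokes a user command, and reads back a `gene_id`/`p_value` table.

## Layout

| module | contents |
| --- | --- |
| `screpsim.core_io` | data model (`EmpiricalDataset`, `RescueParams`, `SimulatedDataset`), MTX/TSV readers and writers, subject filtering |
| `screpsim.estimation` | size factors, mean hierarchy, variance decomposition, dispersions, library parameters, `estimate_params` |
| `screpsim.simulator` | Dirichlet factors, DE resolution, gamma/Poisson stages, `simulate_dataset`, `downsample_dataset` |
| `screpsim.fidelity` | gene/cell metrics, 1-D and 2-D KS statistics, silhouettes, mixed-model ICCs, `compare_datasets` |
| `screpsim.power` | BH adjustment, zero-fraction filter, pseudobulk paired test, scenario grid engine |
| `screpsim.cli` | `screpsim` entry point |
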