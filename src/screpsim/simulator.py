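"""Hierarchical gamma-Poisson count simulator for paired/longitudinal designs.

Counts are generated in three stages: (1) sample-specific gene means built
from a global mean times mean-one multiplicative subject and sample factors
drawn from scaled symmetric Dirichlet distributions; (2) per-cell "true"
expression drawn from a gamma distribution with gene-specific dispersion,
optionally scaled by a fold change for differentially expressed genes;
(3) observed counts drawn from a Poisson after rescaling each cell's true
expression to a simulated expected library size.

Randomness comes from a single seeded generator with a fixed draw order
(cells per sample, DE assignment, factor variances, subject factors, sample
factors, library shifts, then per-sample library sizes and counts), so a
given build reproduces bit-identical output for a given seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import EmpiricalDataset, RescueParams, SimulatedDataset

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


def symmetric_dirichlet_concentration(k: int, v: float) -> float:
    """Concentration alpha making dimension-scaled Dirichlet components have
    variance ``v``: alpha = (k - v - 1) / (k * v)."""
    return (k - v - 1.0) / (k * v)


def scaled_dirichlet_factors(
    k: int, v: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw mean-one multiplicative factors of dimension ``k``.

    Draws w ~ Dir(alpha * 1_k) and returns k * w, so each row sums to k
    exactly and each component has variance ``v``. Returns shape (size, k).

    v below 1e-8 yields all-ones; v >= k - 1 (where alpha would be
    non-positive) is clamped to 0.999 * (k - 1) with a warning.
    """
    if k < 1:
        raise ValueError("dimension k must be >= 1")
    if v < 0:
        raise ValueError("target variance must be >= 0")
    if k == 1:
        return np.ones((size, 1))
    if v < _VAR_FLOOR:
        return np.ones((size, k))
    if v >= k - 1:
        warnings.warn(
            f"factor variance {v} >= k-1 = {k - 1}; clamping", stacklevel=2
        )
        v = 0.999 * (k - 1)
    alpha = symmetric_dirichlet_concentration(k, v)
    w = rng.dirichlet(np.full(k, alpha), size=size)
    return k * w


def _batched_scaled_dirichlet(
    k: int, variances: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Row g ~ k * Dir(alpha_g 1_k) with per-row target variance.

    Uses the gamma representation so per-gene concentrations vectorize.
    """
    variances = np.asarray(variances, dtype=float)
    n = variances.shape[0]
    if k == 1:
        return np.ones((n, 1))
    v = np.clip(variances, 0.0, 0.999 * (k - 1))
    if (variances >= k - 1).any():
        warnings.warn(
            f"{int((variances >= k - 1).sum())} factor variances clamped at k-1",
            stacklevel=2,
        )
    out = np.ones((n, k))
    live = v >= _VAR_FLOOR
    if live.any():
        alpha = symmetric_dirichlet_concentration(k, v[live])
        g = rng.gamma(shape=np.repeat(alpha, k).reshape(-1, k), scale=1.0)
        out[live] = k * g / g.sum(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# differential expression specification
# ---------------------------------------------------------------------------

@dataclass
class DESpec:
    """Fold-change intent, in one of three forms.

    * proportion + magnitude: ``proportion_de`` of genes get +/-``log2fc``
      between first and last timepoint (even up/down split, linear
      interpolation at interior timepoints);
    * pool: each DE gene's end-point log2FC is sampled from ``log2fc_pool``;
    * explicit: ``log2fc_matrix`` (genes x timepoints) passed through after
      validation, with row labels in ``gene_ids``.
    """

    proportion_de: float | None = None
    log2fc: float | None = None
    log2fc_pool: np.ndarray | None = None
    log2fc_matrix: np.ndarray | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        forms = [
            self.proportion_de is not None,
            self.log2fc_pool is not None,
            self.log2fc_matrix is not None,
        ]
        if sum(forms) != 1:
            raise ValueError(
                "DESpec must use exactly one form: proportion+magnitude, pool, "
                "or explicit matrix"
            )
        if self.proportion_de is not None:
            if not 0.0 <= self.proportion_de <= 1.0:
                raise ValueError("proportion_de must be in [0, 1]")
            if self.log2fc is None:
                raise ValueError("proportion form requires a log2fc magnitude")
        if self.log2fc_pool is not None:
            self.log2fc_pool = np.asarray(self.log2fc_pool, dtype=float)
            if self.proportion_de is None and self.log2fc_pool.size == 0:
                raise ValueError("log2fc_pool must be non-empty")
        if self.log2fc_matrix is not None:
            self.log2fc_matrix = np.asarray(self.log2fc_matrix, dtype=float)

    def to_dict(self) -> dict:
        d: dict = {}
        if self.proportion_de is not None:
            d = {"form": "proportion", "proportion_de": float(self.proportion_de),
                 "log2fc": float(self.log2fc)}
        elif self.log2fc_pool is not None:
            d = {"form": "pool", "log2fc_pool": [float(x) for x in self.log2fc_pool]}
        else:
            d = {
                "form": "explicit",
                "log2fc_matrix": self.log2fc_matrix.tolist(),
                "gene_ids": self.gene_ids,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DESpec":
        form = d.get("form")
        if form == "proportion":
            return cls(proportion_de=d["proportion_de"], log2fc=d["log2fc"])
        if form == "pool":
            return cls(log2fc_pool=np.asarray(d["log2fc_pool"], dtype=float),
                       proportion_de=d.get("proportion_de"))
        if form == "explicit":
            return cls(
                log2fc_matrix=np.asarray(d["log2fc_matrix"], dtype=float),
                gene_ids=d.get("gene_ids"),
            )
        raise ValueError(f"unknown DESpec form {form!r}")


def resolve_de_spec(
    de_spec: DESpec | None,
    n_genes: int,
    n_timepoints: int,
    rng: np.random.Generator,
    gene_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a :class:`DESpec` into (genes x timepoints log2FC matrix, de flags).

    The first timepoint column is always zero; interior timepoints
    interpolate linearly between zero and the end-point log2FC.
    """
    lam = np.zeros((n_genes, n_timepoints))
    flags = np.zeros(n_genes, dtype=bool)
    if de_spec is None:
        return lam, flags
    if n_timepoints < 2:
        raise ValueError("differential expression needs at least 2 timepoints")
    ramp = np.linspace(0.0, 1.0, n_timepoints)

    if de_spec.log2fc_matrix is not None:
        mat = de_spec.log2fc_matrix
        if de_spec.gene_ids is not None:
            if gene_ids is None:
                raise ValueError("explicit DESpec names genes but dataset has no ids")
            index = {g: i for i, g in enumerate(gene_ids)}
            missing = [g for g in de_spec.gene_ids if g not in index]
            if missing:
                raise ValueError(f"DESpec genes not in dataset: {missing[:5]}")
            rows = [index[g] for g in de_spec.gene_ids]
            if mat.ndim == 1:
                mat = np.outer(mat, ramp)
            if mat.shape != (len(rows), n_timepoints):
                raise ValueError("explicit log2FC matrix shape mismatch")
            lam[rows] = mat
        else:
            if mat.ndim == 1:
                mat = np.outer(mat, ramp)
            if mat.shape != (n_genes, n_timepoints):
                raise ValueError("explicit log2FC matrix shape mismatch")
            lam = mat.copy()
        if (lam[:, 0] != 0).any():
            raise ValueError("log2FC at the first timepoint must be zero")
        flags = np.any(lam != 0, axis=1)
        return lam, flags

    if de_spec.proportion_de is not None:
        n_de = int(np.ceil(de_spec.proportion_de * n_genes))
        if de_spec.proportion_de > 0 and n_de < 1:
            warnings.warn("proportion_de too small for any DE gene", stacklevel=2)
            return lam, flags
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        n_up = (n_de + 1) // 2  # odd count: extra gene goes up
        signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
        end_lfc = signs * de_spec.log2fc
    else:
        pool = de_spec.log2fc_pool
        n_de = pool.size
        de_idx = rng.choice(n_genes, size=min(n_de, n_genes), replace=False)
        end_lfc = rng.choice(pool, size=de_idx.size, replace=True)
    lam[de_idx] = np.outer(end_lfc, ramp)
    flags[de_idx] = True
    return lam, flags


# ---------------------------------------------------------------------------
# simulation stages
# ---------------------------------------------------------------------------

def simulate_sample_means(
    params: RescueParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw sample-specific gene means mu_gij = mu_g * a_gi * b_gij.

    Per gene, the subject-factor variance v_a and sample-factor variance v_b
    are drawn log-normally; subject factors a (genes x m) and per-subject
    sample factors b (genes x m x n) come from scaled symmetric Dirichlets.

    Returns (means genes x (m*n) with samples subject-major, a, b).
    """
    g, m, n = params.n_genes, params.n_subjects, params.n_timepoints
    v_a = rng.lognormal(params.mu_a, params.sigma_a, size=g)
    v_b = rng.lognormal(params.mu_b, params.sigma_b, size=g)
    a = _batched_scaled_dirichlet(m, v_a, rng)
    b = np.empty((g, m, n))
    for i in range(m):
        b[:, i, :] = _batched_scaled_dirichlet(n, v_b, rng)
    means = params.gene_means[:, None, None] * a[:, :, None] * b
    return means.reshape(g, m * n), a, b


def simulate_true_expression(
    mu: np.ndarray,
    dispersions: np.ndarray,
    log2fc: np.ndarray,
    cell_sample: np.ndarray,
    cell_timepoint: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-cell true expression x ~ Gamma(1/phi, phi * mu_gij * z_g(t)).

    ``mu`` is genes x samples; ``cell_sample`` / ``cell_timepoint`` give each
    cell's sample and timepoint index; ``log2fc`` is genes x timepoints.
    Genes with dispersion below 1e-8 are deterministic: x = mu * z.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(dispersions, dtype=float)
    if (mu < 0).any() or (phi < 0).any():
        raise ValueError("means and dispersions must be non-negative")
    z = np.power(2.0, log2fc)  # genes x timepoints
    scale_mean = mu[:, cell_sample] * z[:, cell_timepoint]  # genes x cells
    x = np.empty_like(scale_mean)
    noisy = phi >= _VAR_FLOOR
    if noisy.any():
        shape = 1.0 / phi[noisy]
        x[noisy] = rng.gamma(
            shape=shape[:, None], scale=phi[noisy, None] * scale_mean[noisy]
        )
    x[~noisy] = scale_mean[~noisy]
    return x


def library_shift_variance(alpha: float, k: int) -> float:
    """Invert alpha = (k - v - 1)/(k v): v = (k - 1) / (k alpha + 1)."""
    return (k - 1.0) / (k * alpha + 1.0)


def draw_library_sizes(
    params: RescueParams,
    cell_sample: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw expected library sizes per cell and sample shift factors d_ij.

    Parametric mode: log L ~ Normal(d_ij * mu_lib, sigma_lib). Custom mode:
    L resampled from the user's empirical library sizes, with log L shifted
    additively by (d_ij - 1) * mean(log custom) to retain sample-level
    location differences.
    """
    k = params.n_subjects * params.n_timepoints
    v_d = library_shift_variance(params.lib_concentration, k)
    d = scaled_dirichlet_factors(k, v_d, rng)[0]
    n_cells = cell_sample.shape[0]
    if params.custom_lib_sizes is None:
        if params.mu_lib <= 0 and v_d > _VAR_FLOOR:
            warnings.warn(
                "mu_lib <= 0: multiplicative library shifts invert direction",
                stacklevel=2,
            )
        log_l = rng.normal(d[cell_sample] * params.mu_lib, params.sigma_lib)
        lib = np.exp(log_l)
    else:
        base = rng.choice(params.custom_lib_sizes, size=n_cells, replace=True)
        mean_log = float(np.mean(np.log(params.custom_lib_sizes)))
        lib = np.exp(np.log(base) + (d[cell_sample] - 1.0) * mean_log)
    return lib, d


def poisson_observe(
    x: np.ndarray, lib_sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Scale true expression to the expected library and draw Poisson counts.

    Per cell, x* = L * x / sum_g x (so column sums of x* equal L exactly),
    then y ~ Poisson(x*). Cells whose true expression is all zero yield
    all-zero counts with a warning.
    """
    totals = x.sum(axis=0)
    zero_cells = totals <= 0
    if zero_cells.any():
        warnings.warn(
            f"{int(zero_cells.sum())} cells have zero total true expression",
            stacklevel=2,
        )
    safe_totals = np.where(zero_cells, 1.0, totals)
    x_star = x * (np.asarray(lib_sizes) / safe_totals)
    x_star[:, zero_cells] = 0.0
    return rng.poisson(x_star)


def _resolve_cells_per_sample(
    params: RescueParams, rng: np.random.Generator
) -> np.ndarray:
    spec = params.cells_per_sample
    n_samples = params.n_subjects * params.n_timepoints
    if isinstance(spec, int):
        return np.full(n_samples, spec, dtype=int)
    if isinstance(spec, tuple):
        lo, hi = spec
        return rng.integers(lo, hi + 1, size=n_samples)
    return np.asarray(spec, dtype=int)


def simulate_dataset(
    params: RescueParams,
    seed: int | np.random.Generator,
    keep_intermediates: bool = False,
) -> SimulatedDataset:
    """Run the full three-stage simulation; deterministic given a seed."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    g, m, n = params.n_genes, params.n_subjects, params.n_timepoints

    cells_per_sample = _resolve_cells_per_sample(params, rng)
    lam, flags = resolve_de_spec(params.de_spec, g, n, rng, params.gene_ids)
    mu, a, b = simulate_sample_means(params, rng)

    # cell bookkeeping: samples subject-major, j-th sample = j-th timepoint
    cell_sample = np.repeat(np.arange(m * n), cells_per_sample)
    cell_timepoint = cell_sample % n
    total_cells = int(cells_per_sample.sum())

    lib_sizes, d = draw_library_sizes(params, cell_sample, rng)

    # stage 2+3 per sample to bound memory
    blocks: list[sp.csr_matrix] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-chunk zero-cell warnings aggregated
        for s, c in enumerate(cells_per_sample):
            sel = slice(
                int(cells_per_sample[:s].sum()), int(cells_per_sample[: s + 1].sum())
            )
            x = simulate_true_expression(
                mu,
                params.dispersions,
                lam,
                cell_sample[sel],
                cell_timepoint[sel],
                rng,
            )
            y = poisson_observe(x, lib_sizes[sel], rng)
            blocks.append(sp.csr_matrix(y))
    counts = sp.hstack(blocks, format="csr")

    gene_ids = params.gene_ids or [f"gene{i + 1}" for i in range(g)]
    subj = np.array([f"subj{i + 1}" for i in range(m)])
    tps = [f"t{j + 1}" for j in range(n)]
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i + 1}" for i in range(total_cells)],
            "subject_id": subj[cell_sample // n],
            "sample_id": [f"subj{s // n + 1}_t{s % n + 1}" for s in cell_sample],
            "timepoint": pd.Categorical(
                [tps[t] for t in cell_timepoint], categories=tps, ordered=True
            ),
        }
    )
    dataset = EmpiricalDataset(counts=counts, gene_ids=gene_ids, cells=cells)
    return SimulatedDataset(
        dataset=dataset,
        truth_log2fc=lam,
        de_flags=flags,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        params=params,
        sample_means=mu if keep_intermediates else None,
        subject_factors=a if keep_intermediates else None,
        sample_factors=b if keep_intermediates else None,
        expected_lib_sizes=lib_sizes if keep_intermediates else None,
    )


# ---------------------------------------------------------------------------
# down-sampling
# ---------------------------------------------------------------------------

def downsample_dataset(
    sim: SimulatedDataset,
    rng: np.random.Generator,
    n_subjects: int | None = None,
    n_timepoints: int | None = None,
    cells_per_sample: int | tuple[int, int] | None = None,
) -> SimulatedDataset:
    """Down-sample subjects, timepoints, and/or cells per sample.

    Subjects are a uniform random subset; timepoints keep the first and last
    plus evenly spaced interior ones (preserving the full first-to-last fold
    change); cells are a uniform random subset per sample. The truth matrix
    is re-sliced to the retained timepoints.
    """
    ds = sim.dataset
    cells = ds.cells
    truth = sim.truth_log2fc
    keep_mask = np.ones(len(cells), dtype=bool)

    if n_subjects is not None:
        have = sorted(cells["subject_id"].unique())
        if n_subjects > len(have):
            raise ValueError(f"requested {n_subjects} subjects, have {len(have)}")
        chosen = set(rng.choice(have, size=n_subjects, replace=False))
        keep_mask &= cells["subject_id"].isin(chosen).to_numpy()

    tp_levels = list(cells["timepoint"].cat.categories)
    if n_timepoints is not None:
        t_all = len(tp_levels)
        if n_timepoints > t_all:
            raise ValueError(f"requested {n_timepoints} timepoints, have {t_all}")
        keep_tp_idx = np.unique(
            np.round(np.linspace(0, t_all - 1, n_timepoints)).astype(int)
        )
        keep_levels = [tp_levels[i] for i in keep_tp_idx]
        keep_mask &= cells["timepoint"].isin(keep_levels).to_numpy()
        truth = truth[:, keep_tp_idx]
        tp_levels = keep_levels

    idx = np.flatnonzero(keep_mask)
    sub_cells = cells.iloc[idx]

    if cells_per_sample is not None:
        chosen_rows: list[np.ndarray] = []
        for sample_id, grp in sub_cells.groupby("sample_id", observed=True, sort=True):
            if isinstance(cells_per_sample, tuple):
                target = int(rng.integers(cells_per_sample[0], cells_per_sample[1] + 1))
            else:
                target = int(cells_per_sample)
            if target > len(grp):
                raise ValueError(
                    f"sample {sample_id} has {len(grp)} cells; cannot keep {target}"
                )
            chosen_rows.append(rng.choice(grp.index.to_numpy(), size=target, replace=False))
        idx = np.sort(np.concatenate(chosen_rows))

    new_cells = cells.iloc[idx].copy()
    new_cells["timepoint"] = pd.Categorical(
        new_cells["timepoint"].astype(str),
        categories=[str(t) for t in tp_levels],
        ordered=True,
    )
    new_ds = EmpiricalDataset(
        counts=ds.counts[:, idx], gene_ids=ds.gene_ids, cells=new_cells
    )
    return SimulatedDataset(
        dataset=new_ds,
        truth_log2fc=truth,
        de_flags=sim.de_flags,
        seed=sim.seed,
        params=sim.params,
    )
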