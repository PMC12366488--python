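"""Estimate simulator hyper-parameters from an empirical dataset.

The estimation mirrors the generative model: normalize counts with pooled
deconvolution size factors, compute sample/subject/global gene means, derive
mean-one subject and sample factors, decompose their variances (subtracting
a delta-method estimate of the sampling-error component), and moment-match
log-normal hyper-parameters. Dispersions come from a Cox-Reid adjusted
profile likelihood on the single largest sample, shrunk toward a fitted
mean-dispersion trend. Library-size parameters are per-sample means/sds of
log library size, with sample shifts mapped to a symmetric Dirichlet
concentration.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.sparse.linalg import lsqr
from scipy.special import gammaln

from .core_io import EmpiricalDataset, RescueParams
from .simulator import symmetric_dirichlet_concentration

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8
_MEAN_FLOOR = 1e-8
_LARGE_CONCENTRATION = 1e6


def shipped_defaults() -> dict:
    """Hierarchy hyper-parameter defaults derived from a packaged synthetic
    reference (see ``provenance`` in the file)."""
    ref = importlib.resources.files("screpsim").joinpath("data/defaults.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def _library_size_factors(counts: sp.spmatrix) -> np.ndarray:
    lib = np.asarray(counts.sum(axis=0), dtype=float).ravel()
    mean_lib = lib[lib > 0].mean() if (lib > 0).any() else 1.0
    factors = lib / mean_lib
    factors[factors <= 0] = 1.0
    return factors / factors.mean()


def pooled_size_factors(
    counts: sp.spmatrix,
    pool_sizes: tuple[int, ...] = (21, 41, 61, 81, 101),
    min_cells_for_pooling: int = 100,
) -> np.ndarray:
    """Per-cell positive scale factors with mean one.

    Cells are summed into overlapping pools along a library-size-balanced
    ring; each pool's factor is the median count ratio against the average
    pseudo-cell, and per-cell factors solve the resulting sparse linear
    system by least squares. With fewer than ``min_cells_for_pooling`` cells
    plain library-size factors are returned instead (logged).
    """
    counts = sp.csc_matrix(counts)
    n_cells = counts.shape[1]
    if n_cells == 1:
        return np.ones(1)
    lib_factors = _library_size_factors(counts)
    if n_cells < min_cells_for_pooling:
        logger.info("using library-size factors (%d cells < pooling threshold)", n_cells)
        return lib_factors

    lib = np.asarray(counts.sum(axis=0), dtype=float).ravel()
    order = np.argsort(lib)
    # interleave small/large so pools have balanced composition
    ring = np.empty(n_cells, dtype=int)
    ring[0::2] = order[: (n_cells + 1) // 2]
    ring[1::2] = order[(n_cells + 1) // 2:][::-1]

    ref = np.asarray(counts.mean(axis=1), dtype=float).ravel()
    use = ref > 0
    dense = np.asarray(counts[use][:, ring].todense(), dtype=float)
    ref = ref[use]

    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for w in pool_sizes:
        if w > n_cells:
            continue
        csum = np.cumsum(dense, axis=1)
        csum = np.hstack([np.zeros((dense.shape[0], 1)), csum])
        for start in range(n_cells):
            stop = start + w
            if stop <= n_cells:
                pooled = csum[:, stop] - csum[:, start]
                members = ring[start:stop]
            else:  # wrap around the ring
                pooled = (csum[:, -1] - csum[:, start]) + csum[:, stop - n_cells]
                members = np.concatenate([ring[start:], ring[: stop - n_cells]])
            theta = float(np.median(pooled / ref))
            rows.extend([eq] * w)
            cols.extend(members.tolist())
            vals.extend([1.0] * w)
            rhs.append(theta)
            eq += 1
    # low-weight anchor equations keep the system full rank and set the scale
    anchor_w = 0.1
    for c in range(n_cells):
        rows.append(eq)
        cols.append(c)
        vals.append(anchor_w)
        rhs.append(anchor_w * lib_factors[c])
        eq += 1
    design = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n_cells))
    sol = lsqr(design, np.asarray(rhs), atol=1e-10, btol=1e-10)[0]
    bad = sol <= 0
    if bad.any():
        logger.warning("%d non-positive deconvolution factors replaced", bad.sum())
        sol[bad] = lib_factors[bad]
    return sol / sol.mean()


def normalized_expression(counts: sp.spmatrix, size_factors: np.ndarray) -> sp.csr_matrix:
    """Counts divided by per-cell size factors."""
    inv = sp.diags(1.0 / np.asarray(size_factors, dtype=float))
    return sp.csr_matrix(counts @ inv)


# ---------------------------------------------------------------------------
# mean hierarchy and variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class EstimationIntermediates:
    """Per-gene means, factors, and bookkeeping shared by the estimators."""

    sample_table: pd.DataFrame  # sample_id, subject_id, timepoint, n_cells
    size_factors: np.ndarray
    mu_sample: np.ndarray  # genes x N sample means of normalized expression
    mu_subject: np.ndarray  # genes x m
    mu_global: np.ndarray  # genes
    a: np.ndarray  # genes x m subject factors (NaN where mu_global == 0)
    b: np.ndarray  # genes x N sample factors (NaN where mu_subject == 0)
    var_within: np.ndarray  # genes x N within-sample variance of normalized expr
    zero_frac: np.ndarray  # per-gene fraction of zero raw counts
    subjects: list
    sample_subject_idx: np.ndarray  # sample -> subject position

    @property
    def n_samples(self) -> int:
        return self.mu_sample.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.mu_subject.shape[1]


def estimate_mean_hierarchy(
    dataset: EmpiricalDataset, size_factors: np.ndarray | None = None
) -> EstimationIntermediates:
    """Sample/subject/global gene means and the mean-one factors a, b.

    mu_sample is the per-sample mean of normalized expression over cells;
    mu_subject averages a subject's samples; mu_global averages all samples.
    a = mu_subject / mu_global and b = mu_sample / mu_subject, so
    mu_global * a * b reconstructs mu_sample exactly.
    """
    if size_factors is None:
        size_factors = pooled_size_factors(dataset.counts)
    norm = normalized_expression(dataset.counts, size_factors)
    tbl = dataset.sample_table()
    sample_ids = tbl["sample_id"].tolist()
    subjects = sorted(tbl["subject_id"].unique())
    subj_pos = {s: i for i, s in enumerate(subjects)}
    sample_subject_idx = tbl["subject_id"].map(subj_pos).to_numpy()

    g = dataset.n_genes
    n_samp = len(sample_ids)
    mu_sample = np.zeros((g, n_samp))
    var_within = np.zeros((g, n_samp))
    col_of = {sid: np.flatnonzero((dataset.cells["sample_id"] == sid).to_numpy())
              for sid in sample_ids}
    for j, sid in enumerate(sample_ids):
        cols = col_of[sid]
        if cols.size == 0:
            raise ValueError(f"sample {sid} has no cells")
        block = norm[:, cols]
        mean = np.asarray(block.mean(axis=1)).ravel()
        sq = np.asarray(block.multiply(block).mean(axis=1)).ravel()
        mu_sample[:, j] = mean
        if cols.size > 1:
            var_within[:, j] = (sq - mean**2) * cols.size / (cols.size - 1)
    var_within = np.clip(var_within, 0.0, None)

    mu_subject = np.zeros((g, len(subjects)))
    for i in range(len(subjects)):
        mu_subject[:, i] = mu_sample[:, sample_subject_idx == i].mean(axis=1)
    mu_global = mu_sample.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(mu_global[:, None] > 0, mu_subject / mu_global[:, None], np.nan)
        b = np.where(
            mu_subject[:, sample_subject_idx] > 0,
            mu_sample / mu_subject[:, sample_subject_idx],
            np.nan,
        )

    nonzero_per_gene = np.asarray((dataset.counts != 0).sum(axis=1)).ravel()
    zero_frac = 1.0 - nonzero_per_gene / dataset.n_cells
    return EstimationIntermediates(
        sample_table=tbl,
        size_factors=np.asarray(size_factors, dtype=float),
        mu_sample=mu_sample,
        mu_subject=mu_subject,
        mu_global=mu_global,
        a=a,
        b=b,
        var_within=var_within,
        zero_frac=zero_frac,
        subjects=list(subjects),
        sample_subject_idx=sample_subject_idx,
    )


def variance_decomposition(
    inter: EstimationIntermediates,
    zero_frac_cutoff: float = 0.60,
    subtract_error: bool = True,
) -> pd.DataFrame:
    """Per-gene subject/sample factor variances, corrected for sampling error.

    The raw variances are mean squared deviations of the factors from their
    construction mean of one (v_a over subjects, v_b pooled over all
    samples). The sampling-error component — present even with no true
    between-sample variation, because factors are built from finite-cell
    sample means — is estimated by the delta method from the within-sample
    variance of normalized expression and subtracted; negatives floor at 0.
    Only genes with zero fraction below the cutoff are returned.
    """
    tbl = inter.sample_table
    n_cells = tbl["n_cells"].to_numpy(dtype=float)
    m = inter.n_subjects
    retained = (inter.zero_frac < zero_frac_cutoff) & (inter.mu_global > 0)

    subj_n_samples = np.array(
        [(inter.sample_subject_idx == i).sum() for i in range(m)], dtype=float
    )
    if m < 2:
        v_a_star = np.full(inter.mu_global.shape, np.nan)
    else:
        v_a = np.nanmean((inter.a - 1.0) ** 2, axis=1)
        v_a_star = v_a
    v_b = np.nanmean((inter.b - 1.0) ** 2, axis=1)
    v_b_star = v_b

    if subtract_error:
        with np.errstate(divide="ignore", invalid="ignore"):
            var_mu = inter.var_within / n_cells[None, :]  # Var(mu_sample)
            err_b = var_mu / inter.mu_subject[:, inter.sample_subject_idx] ** 2
            err_b_mean = np.nanmean(np.where(np.isfinite(err_b), err_b, np.nan), axis=1)
            # Var(a_i) ~ (1/n_i^2) sum_j Var(mu_sample_j) / mu_global^2
            err_a = np.zeros_like(inter.a)
            for i in range(m):
                cols = inter.sample_subject_idx == i
                err_a[:, i] = var_mu[:, cols].sum(axis=1) / (
                    subj_n_samples[i] ** 2 * inter.mu_global**2
                )
            err_a_mean = np.nanmean(
                np.where(np.isfinite(err_a), err_a, np.nan), axis=1
            )
        v_b_star = np.clip(v_b - err_b_mean, 0.0, None)
        if m >= 2:
            v_a_star = np.clip(v_a_star - err_a_mean, 0.0, None)

    out = pd.DataFrame(
        {
            "v_a_star": v_a_star,
            "v_b_star": v_b_star,
            "zero_frac": inter.zero_frac,
        }
    )
    return out[retained]


def fit_lognormal_hyperparams(v_star: np.ndarray) -> tuple[float, float]:
    """Moment-match a log-normal to per-gene variances.

    With M and V the across-gene mean and variance of the (positive) values:
    sigma^2 = log(1 + V / M^2), mu = log M - sigma^2 / 2.
    """
    v = np.asarray(v_star, dtype=float)
    v = v[np.isfinite(v)]
    n_zero = int((v <= 0).sum())
    if n_zero:
        logger.info("dropping %d non-positive variance estimates", n_zero)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("no between-level variability detected; supply defaults")
    if v.size == 1:
        return float(np.log(v[0])), 0.0
    big_m = float(v.mean())
    big_v = float(v.var(ddof=1))
    sigma_sq = float(np.log1p(big_v / big_m**2))
    mu = float(np.log(big_m) - sigma_sq / 2.0)
    return mu, float(np.sqrt(sigma_sq))


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _nb_apl(y: np.ndarray, offsets: np.ndarray, phi: float) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi.

    One mean parameter per gene with fixed offsets; the mean is profiled out
    by Newton iterations, vectorized across genes.
    """
    exp_o = np.exp(offsets)[None, :]
    tot = y.sum(axis=1)
    beta = np.log(np.clip(tot, 0.5, None) / exp_o.sum())
    for _ in range(25):
        mu = np.exp(beta[:, None]) * exp_o
        w = mu / (1.0 + phi * mu)
        score = ((y - mu) / (1.0 + phi * mu)).sum(axis=1)
        info = np.clip(w.sum(axis=1), 1e-12, None)
        step = np.clip(score / info, -3.0, 3.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    mu = np.exp(beta[:, None]) * exp_o
    r = 1.0 / phi
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(np.where(mu > 0, mu / (r + mu), 1.0))
    ).sum(axis=1)
    cr = 0.5 * np.log(np.clip((mu / (1.0 + phi * mu)).sum(axis=1), 1e-12, None))
    return ll - cr


def _dispersion_trend(ave_log_cpm: np.ndarray, log_phi: np.ndarray, n_bins: int = 20):
    """Binned running-median trend of log dispersion against abundance."""
    order = np.argsort(ave_log_cpm)
    bins = np.array_split(order, max(1, min(n_bins, order.size // 2 or 1)))
    centers, medians = [], []
    for idx in bins:
        if idx.size == 0:
            continue
        centers.append(np.median(ave_log_cpm[idx]))
        medians.append(np.median(log_phi[idx]))
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    if centers.size == 1:
        return np.full_like(ave_log_cpm, medians[0])
    return np.interp(ave_log_cpm, centers, medians)


def estimate_dispersions(
    dataset: EmpiricalDataset,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene NB dispersion from the single sample with the most cells.

    Per-gene Cox-Reid adjusted profile likelihoods are evaluated on a
    log-spaced dispersion grid with offsets equal to log library size, the
    per-gene maximum is interpolated, and estimates are squeezed toward a
    binned mean-dispersion trend with empirical-Bayes weight ``prior_df``.
    """
    counts_per = dataset.cells_per_sample()
    chosen = counts_per.sort_index().idxmax()  # ties -> first sample id
    cols = np.flatnonzero((dataset.cells["sample_id"] == chosen).to_numpy())
    if cols.size < 2:
        raise ValueError(f"sample {chosen} has fewer than 2 cells")
    y = np.asarray(dataset.counts[:, cols].todense(), dtype=float)
    lib = y.sum(axis=0)
    keep_cells = lib > 0
    y = y[:, keep_cells]
    lib = lib[keep_cells]
    gene_tot = y.sum(axis=1)
    expressed = gene_tot > 0
    if not expressed.any():
        raise ValueError(f"all genes are zero in sample {chosen}")
    offsets = np.log(lib)

    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-6), np.log(30.0), 19))
    apl = np.empty((int(expressed.sum()), grid.size))
    ye = y[expressed]
    for j, phi in enumerate(grid):
        apl[:, j] = _nb_apl(ye, offsets, float(phi))

    best = np.argmax(apl, axis=1)
    log_grid = np.log(grid)
    phi_hat = np.empty(ye.shape[0])
    for g in range(ye.shape[0]):
        j = best[g]
        if 0 < j < grid.size - 1:
            x0, x1, x2 = log_grid[j - 1: j + 2]
            y0, y1, y2 = apl[g, j - 1: j + 2]
            denom = (y0 - 2 * y1 + y2)
            if denom < -1e-12:
                phi_hat[g] = np.exp(x1 - 0.5 * (x2 - x0) * (y2 - y0) / (2 * denom))
            else:
                phi_hat[g] = grid[j]
        else:
            phi_hat[g] = grid[j]

    ave_log_cpm = np.log2(1e6 * (ye.sum(axis=1) + 0.5) / (lib.sum() + 1.0))
    log_phi = np.log(phi_hat)
    trend = _dispersion_trend(ave_log_cpm, log_phi)
    df_gene = float(ye.shape[1] - 1)
    shrunk = (df_gene * log_phi + prior_df * trend) / (df_gene + prior_df)

    phi = np.zeros(dataset.n_genes)
    phi[expressed] = np.exp(shrunk)
    phi[phi < 1e-6] = 0.0
    return phi


# ---------------------------------------------------------------------------
# library-size parameters
# ---------------------------------------------------------------------------

def estimate_library_params(dataset: EmpiricalDataset) -> tuple[float, float, float]:
    """(mu_lib, sigma_lib, concentration) from per-sample log library sizes.

    mu_lib and sigma_lib average the per-sample mean and sd of log library
    size; the Dirichlet concentration comes from the variance of the
    per-sample mean-to-global ratios via the variance/concentration relation
    with dimension N.
    """
    lib = dataset.library_sizes().astype(float)
    cells = dataset.cells
    means, sds = [], []
    for _, grp in cells.groupby("sample_id", observed=True, sort=True):
        l_s = lib[grp.index.to_numpy()]
        l_s = l_s[l_s > 0]
        if l_s.size == 0:
            raise ValueError("sample with only zero-library cells")
        means.append(np.log(l_s).mean())
        sds.append(np.log(l_s).std(ddof=1) if l_s.size > 1 else 0.0)
    means = np.asarray(means)
    mu_lib = float(means.mean())
    sigma_lib = float(np.mean(sds))
    n = means.size
    if n < 2:
        warnings.warn("single sample: library shift concentration set large",
                      stacklevel=2)
        return mu_lib, sigma_lib, _LARGE_CONCENTRATION
    ratios = means / mu_lib
    v_d = float(np.mean((ratios - 1.0) ** 2))
    if v_d < _VAR_FLOOR:
        return mu_lib, sigma_lib, _LARGE_CONCENTRATION
    v_d = min(v_d, 0.999 * (n - 1))
    alpha = symmetric_dirichlet_concentration(n, v_d)
    return mu_lib, sigma_lib, float(alpha)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def estimate_params(
    dataset: EmpiricalDataset,
    zero_frac_cutoff: float = 0.60,
    defaults: dict | None = None,
    cells_per_sample: int | tuple[int, int] | None = None,
) -> RescueParams:
    """Estimate every simulator hyper-parameter the data supports.

    Hierarchy levels the design cannot identify fall back to shipped
    defaults (single sample: both levels; multi-sample but unpaired:
    between-sample deviations are assigned to the sample level and the
    subject level defaults). Each field's provenance is recorded.
    """
    if defaults is None:
        defaults = shipped_defaults()
    provenance: dict[str, str] = {}

    sf = pooled_size_factors(dataset.counts)
    inter = estimate_mean_hierarchy(dataset, sf)
    tbl = inter.sample_table
    n_samples = len(tbl)
    samples_per_subject = tbl.groupby("subject_id", observed=True).size()
    paired = (samples_per_subject >= 2).all() and inter.n_subjects >= 2

    mu_a = sigma_a = mu_b = sigma_b = None
    if paired:
        decomp = variance_decomposition(inter, zero_frac_cutoff)
        try:
            mu_a, sigma_a = fit_lognormal_hyperparams(decomp["v_a_star"].to_numpy())
            provenance["mu_a"] = provenance["sigma_a"] = "estimated"
        except ValueError:
            logger.warning("subject-level variance not identifiable; using defaults")
        try:
            mu_b, sigma_b = fit_lognormal_hyperparams(decomp["v_b_star"].to_numpy())
            provenance["mu_b"] = provenance["sigma_b"] = "estimated"
        except ValueError:
            logger.warning("sample-level variance not identifiable; using defaults")
    elif n_samples >= 2:
        # unpaired multi-sample: between-sample spread informs the sample level
        logger.warning(
            "no paired structure: sample-level variance estimated from "
            "between-sample deviations; subject level uses defaults"
        )
        retained = (inter.zero_frac < zero_frac_cutoff) & (inter.mu_global > 0)
        dev = np.nanmean(
            ((inter.mu_sample / np.where(inter.mu_global[:, None] > 0,
                                         inter.mu_global[:, None], np.nan)) - 1.0) ** 2,
            axis=1,
        )
        try:
            mu_b, sigma_b = fit_lognormal_hyperparams(dev[retained])
            provenance["mu_b"] = provenance["sigma_b"] = "estimated(unpaired)"
        except ValueError:
            pass
    else:
        logger.warning("single-sample data: hierarchy parameters use defaults")

    if mu_a is None:
        mu_a, sigma_a = defaults["mu_a"], defaults["sigma_a"]
        provenance["mu_a"] = provenance["sigma_a"] = "default"
    if mu_b is None:
        mu_b, sigma_b = defaults["mu_b"], defaults["sigma_b"]
        provenance["mu_b"] = provenance["sigma_b"] = "default"

    dispersions = estimate_dispersions(dataset)
    provenance["dispersions"] = "estimated"
    mu_lib, sigma_lib, alpha_d = estimate_library_params(dataset)
    provenance["library"] = "estimated"

    gene_means = np.where(inter.mu_global > 0, inter.mu_global, _MEAN_FLOOR)
    provenance["gene_means"] = "estimated"

    n_timepoints = dataset.cells["timepoint"].nunique()
    if cells_per_sample is None:
        cps = dataset.cells_per_sample().to_numpy()
        lo = max(1, int(np.percentile(cps, 10)))
        hi = max(lo, int(np.percentile(cps, 90)))
        cells_per_sample = (lo, hi)
        provenance["cells_per_sample"] = "estimated(p10,p90)"
    else:
        provenance["cells_per_sample"] = "user"

    return RescueParams(
        n_genes=dataset.n_genes,
        n_subjects=dataset.n_subjects,
        n_timepoints=max(1, n_timepoints),
        cells_per_sample=cells_per_sample,
        gene_means=gene_means,
        dispersions=dispersions,
        mu_a=float(mu_a),
        sigma_a=float(sigma_a),
        mu_b=float(mu_b),
        sigma_b=float(sigma_b),
        mu_lib=mu_lib,
        sigma_lib=sigma_lib,
        lib_concentration=alpha_d,
        gene_ids=list(dataset.gene_ids),
        provenance=provenance,
    )
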