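"""Similarity metrics between an empirical and a simulated dataset.

The battery covers per-gene and per-cell summary distributions (compared by
one- and two-dimensional Kolmogorov-Smirnov statistics), silhouette widths
of cells grouped by sample or subject in PCA space, and per-gene intraclass
correlations from nested random-intercept models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .core_io import EmpiricalDataset

logger = logging.getLogger(__name__)


def _log_cpm(counts: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """log2(CPM + 1) dense matrix and the kept-cell mask (zero-library cells
    are excluded with a warning)."""
    lib = np.asarray(counts.sum(axis=0), dtype=float).ravel()
    keep = lib > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-library cells",
                      stacklevel=2)
    dense = np.asarray(counts[:, keep].todense(), dtype=float)
    return np.log2(1e6 * dense / lib[keep] + 1.0), keep


def gene_level_metrics(dataset: EmpiricalDataset) -> pd.DataFrame:
    """Per-gene mean logCPM, variance logCPM, and fraction of zero counts."""
    logcpm, keep = _log_cpm(dataset.counts)
    n = keep.sum()
    mean = logcpm.mean(axis=1)
    var = logcpm.var(axis=1, ddof=1) if n > 1 else np.zeros(dataset.n_genes)
    zeros = 1.0 - np.asarray((dataset.counts[:, keep] != 0).sum(axis=1)).ravel() / n
    return pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "mean_logcpm": mean,
            "var_logcpm": var,
            "frac_zero": zeros,
        }
    )


def cell_level_metrics(dataset: EmpiricalDataset) -> pd.DataFrame:
    """Per-cell fraction of zero counts and natural-log library size."""
    lib = dataset.library_sizes().astype(float)
    nonzero = np.asarray((dataset.counts != 0).sum(axis=0)).ravel()
    frac_zero = 1.0 - nonzero / dataset.n_genes
    with np.errstate(divide="ignore"):
        log_lib = np.where(lib > 0, np.log(np.where(lib > 0, lib, 1.0)), -np.inf)
    return pd.DataFrame(
        {
            "cell_id": dataset.cells["cell_id"].to_numpy(),
            "frac_zero": frac_zero,
            "log_lib_size": log_lib,
        }
    )


def ks_statistic_1d(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup-norm ECDF distance)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic needs non-empty samples")
    return float(ks_2samp(a, b).statistic)


def ks_statistic_2d(points_a, points_b) -> float:
    """Two-sample bivariate KS statistic, Fasano-Franceschini construction.

    At every observed point of each sample, the fractions of each sample
    falling in the four open quadrants around that point are compared; the
    statistic averages the two samples' maximum absolute differences.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic needs non-empty samples")
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("points must be 2-D")

    def max_diff(origins: np.ndarray) -> float:
        best = 0.0
        ax, ay = a[:, 0], a[:, 1]
        bx, by = b[:, 0], b[:, 1]
        for ox, oy in origins:
            for sx in (1, -1):
                for sy in (1, -1):
                    fa = np.mean((sx * (ax - ox) > 0) & (sy * (ay - oy) > 0))
                    fb = np.mean((sx * (bx - ox) > 0) & (sy * (by - oy) > 0))
                    best = max(best, abs(fa - fb))
        return best

    return 0.5 * (max_diff(a) + max_diff(b))


def silhouette_by_label(
    dataset: EmpiricalDataset,
    label: str = "sample",
    n_pcs: int = 10,
    max_cells: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell silhouette widths for cells grouped by sample or subject.

    Widths are computed with Euclidean distances in the top ``n_pcs``
    principal components of logCPM.
    """
    if label not in ("sample", "subject"):
        raise ValueError("label must be 'sample' or 'subject'")
    col = f"{label}_id"
    logcpm, keep = _log_cpm(dataset.counts)
    labels = dataset.cells.loc[keep, col].to_numpy()
    if max_cells is not None and logcpm.shape[1] > max_cells:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(logcpm.shape[1], size=max_cells, replace=False)
        logcpm = logcpm[:, idx]
        labels = labels[idx]
    if len(np.unique(labels)) < 2:
        raise ValueError(f"silhouette undefined: fewer than 2 {label} labels")
    n_pcs = min(n_pcs, logcpm.shape[0] - 1, logcpm.shape[1] - 1)
    coords = PCA(n_components=n_pcs, random_state=0).fit_transform(logcpm.T)
    widths = silhouette_samples(coords, labels)
    return pd.DataFrame({label: labels, "silhouette_width": widths})


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def _icc_moments(y, subj_codes, samp_codes):
    """Unbalanced nested ANOVA (expected-mean-square) variance components."""
    n = y.size
    df_samp = pd.DataFrame({"y": y, "subj": subj_codes, "samp": samp_codes})
    samp_stats = df_samp.groupby("samp", observed=True).agg(
        mean=("y", "mean"), n=("y", "size"), subj=("subj", "first")
    )
    subj_stats = df_samp.groupby("subj", observed=True).agg(
        mean=("y", "mean"), n=("y", "size")
    )
    grand = y.mean()
    m = len(subj_stats)
    n_samp = len(samp_stats)

    samp_mean_per_cell = samp_stats["mean"].reindex(samp_codes).to_numpy()
    ssw = float(((y - samp_mean_per_cell) ** 2).sum())
    sse_df = n - n_samp
    sig_e = ssw / sse_df if sse_df > 0 else 0.0

    subj_mean_of_samp = subj_stats["mean"].reindex(samp_stats["subj"]).to_numpy()
    ssb = float(
        (samp_stats["n"].to_numpy() * (samp_stats["mean"].to_numpy() - subj_mean_of_samp) ** 2).sum()
    )
    ssa = float((subj_stats["n"].to_numpy() * (subj_stats["mean"].to_numpy() - grand) ** 2).sum())

    c_ij = samp_stats["n"].to_numpy(dtype=float)
    c_i = subj_stats["n"].to_numpy(dtype=float)
    sum_cij_sq_over_ci = (
        pd.Series(c_ij**2, index=samp_stats["subj"]).groupby(level=0).sum().to_numpy()
        / c_i
    )
    k1_num = c_i.sum() - sum_cij_sq_over_ci.sum()
    k1 = k1_num / max(n_samp - m, 1)
    sig_v = max((ssb / max(n_samp - m, 1) - sig_e) / k1, 0.0) if n_samp > m else 0.0

    k2 = (sum_cij_sq_over_ci.sum() - (c_ij**2).sum() / n) / max(m - 1, 1)
    k3 = (n - (c_i**2).sum() / n) / max(m - 1, 1)
    msa = ssa / max(m - 1, 1)
    sig_u = max((msa - sig_e - k2 * sig_v) / k3, 0.0) if m > 1 else 0.0
    return sig_u, sig_v, sig_e


def _icc_reml(y, subj_codes, samp_codes):
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "subj": subj_codes, "samp": samp_codes})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "y ~ 1", df, groups="subj", re_formula="1",
            vc_formula={"samp": "0 + C(samp)"},
        )
        fit = model.fit(reml=True, maxiter=200)
    if not fit.converged:
        raise RuntimeError("REML did not converge")
    sig_u = float(fit.cov_re.iloc[0, 0])
    sig_v = float(fit.vcomp[0])
    sig_e = float(fit.scale)
    return max(sig_u, 0.0), max(sig_v, 0.0), sig_e


def icc_from_matrix(
    values: np.ndarray,
    subjects: np.ndarray,
    samples: np.ndarray,
    method: str = "reml",
    row_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Subject/sample ICCs for each row of a values matrix (rows x cells)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = row_ids or [f"row{i + 1}" for i in range(values.shape[0])]
    rows = []
    for g in range(values.shape[0]):
        y = values[g]
        if np.allclose(y, y[0]):
            rows.append((ids[g], 0.0, 0.0, "degenerate"))
            continue
        used = method
        if method == "reml":
            try:
                sig_u, sig_v, sig_e = _icc_reml(y, subjects, samples)
            except Exception:
                sig_u, sig_v, sig_e = _icc_moments(y, subjects, samples)
                used = "moments_fallback"
        else:
            sig_u, sig_v, sig_e = _icc_moments(y, subjects, samples)
        total = sig_u + sig_v + sig_e
        if total <= 0:
            rows.append((ids[g], 0.0, 0.0, used))
        else:
            rows.append((ids[g], sig_u / total, (sig_u + sig_v) / total, used))
    return pd.DataFrame(rows, columns=["gene_id", "icc_subject", "icc_sample", "method"])


def variance_components_icc(
    dataset: EmpiricalDataset,
    genes_subset: np.ndarray | list[str] | None = None,
    method: str = "reml",
) -> pd.DataFrame:
    """Per-gene subject- and sample-level intraclass correlations on logCPM.

    For each gene a nested random-intercept model (subject, sample within
    subject) is fit; ICC_subject = var_u / total and ICC_sample =
    (var_u + var_v) / total, the latter being the correlation of two cells
    from the same sample (nesting makes ICC_sample >= ICC_subject).
    ``method`` is "reml" (falls back per gene to method-of-moments on
    non-convergence) or "moments".
    """
    if dataset.n_subjects < 2:
        raise ValueError("ICC needs >= 2 subjects")
    logcpm, keep = _log_cpm(dataset.counts)
    subj = dataset.cells.loc[keep, "subject_id"].to_numpy()
    samp = dataset.cells.loc[keep, "sample_id"].to_numpy()

    if genes_subset is None:
        idx = np.arange(dataset.n_genes)
    else:
        arr = np.asarray(genes_subset)
        if arr.dtype.kind in "SU<O" and not np.issubdtype(arr.dtype, np.integer):
            pos = {g: i for i, g in enumerate(dataset.gene_ids)}
            idx = np.array([pos[g] for g in arr])
        else:
            idx = arr.astype(int)

    return icc_from_matrix(
        logcpm[idx], subj, samp, method=method,
        row_ids=[dataset.gene_ids[g] for g in idx],
    )


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

_GENE_METRICS = ("mean_logcpm", "var_logcpm", "frac_zero")
_GENE_PAIRS = (
    ("frac_zero", "mean_logcpm"),
    ("frac_zero", "var_logcpm"),
    ("mean_logcpm", "var_logcpm"),
)
_CELL_METRICS = ("frac_zero", "log_lib_size")


@dataclass
class FidelityReport:
    """Metric tables and KS statistics comparing two datasets.

    ``reference`` labels which input is treated as the empirical reference.
    """

    reference: str
    gene_metrics_ref: pd.DataFrame
    gene_metrics_sim: pd.DataFrame
    cell_metrics_ref: pd.DataFrame
    cell_metrics_sim: pd.DataFrame
    ks_table: pd.DataFrame
    silhouette: dict = field(default_factory=dict)
    icc: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary: level, metric, statistic, value."""
        rows = [
            (r.level, r.metric, "ks", r.statistic) for r in self.ks_table.itertuples()
        ]
        for level, tbl in self.silhouette.items():
            for which, df in tbl.items():
                rows.append(
                    (level, "silhouette_width", f"mean_{which}",
                     float(df["silhouette_width"].mean()))
                )
        for which, df in self.icc.items():
            rows.append(("subject", "icc", f"median_{which}",
                         float(df["icc_subject"].median())))
            rows.append(("sample", "icc", f"median_{which}",
                         float(df["icc_sample"].median())))
        return pd.DataFrame(rows, columns=["level", "metric", "statistic", "value"])

    def write(self, out_dir) -> None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "report.tsv", sep="\t", index=False)
        self.gene_metrics_ref.to_csv(out_dir / "gene_metrics_ref.tsv", sep="\t", index=False)
        self.gene_metrics_sim.to_csv(out_dir / "gene_metrics_sim.tsv", sep="\t", index=False)
        self.cell_metrics_ref.to_csv(out_dir / "cell_metrics_ref.tsv", sep="\t", index=False)
        self.cell_metrics_sim.to_csv(out_dir / "cell_metrics_sim.tsv", sep="\t", index=False)


def match_genes_by_mean(
    ref_means: np.ndarray, sim_means: np.ndarray
) -> np.ndarray:
    """For each reference gene, index of the simulated gene with the closest
    mean expression (rank matching on sorted means)."""
    order_ref = np.argsort(ref_means)
    order_sim = np.argsort(sim_means)
    out = np.empty(ref_means.size, dtype=int)
    sim_sorted = order_sim[
        np.round(np.linspace(0, sim_means.size - 1, ref_means.size)).astype(int)
    ]
    out[order_ref] = sim_sorted
    return out


def compare_datasets(
    empirical: EmpiricalDataset,
    simulated: EmpiricalDataset,
    n_pcs: int = 10,
    compute_silhouette: bool = False,
    compute_icc: bool = False,
    icc_genes: np.ndarray | list[str] | None = None,
    icc_method: str = "reml",
    max_cells: int | None = 2000,
    rng: np.random.Generator | None = None,
) -> FidelityReport:
    """Full fidelity report: univariate and bivariate KS on gene- and
    cell-level metric distributions, plus optional silhouettes and ICCs."""
    gm_ref = gene_level_metrics(empirical)
    gm_sim = gene_level_metrics(simulated)
    cm_ref = cell_level_metrics(empirical)
    cm_sim = cell_level_metrics(simulated)

    ks_rows = []
    for metric in _GENE_METRICS:
        ks_rows.append(
            ("gene", metric, ks_statistic_1d(gm_ref[metric], gm_sim[metric]))
        )
    for mx, my in _GENE_PAIRS:
        ks_rows.append(
            (
                "gene",
                f"{mx}:{my}",
                ks_statistic_2d(gm_ref[[mx, my]].to_numpy(), gm_sim[[mx, my]].to_numpy()),
            )
        )
    for metric in _CELL_METRICS:
        ks_rows.append(
            ("cell", metric, ks_statistic_1d(cm_ref[metric], cm_sim[metric]))
        )
    ks_rows.append(
        (
            "cell",
            "frac_zero:log_lib_size",
            ks_statistic_2d(
                cm_ref[list(_CELL_METRICS)].to_numpy(),
                cm_sim[list(_CELL_METRICS)].to_numpy(),
            ),
        )
    )

    silhouette: dict = {}
    icc: dict = {}
    if compute_silhouette:
        for level in ("sample", "subject"):
            silhouette[level] = {}
            for which, ds in (("ref", empirical), ("sim", simulated)):
                try:
                    silhouette[level][which] = silhouette_by_label(
                        ds, level, n_pcs=n_pcs, max_cells=max_cells, rng=rng
                    )
                except ValueError as exc:
                    logger.warning("silhouette (%s, %s) skipped: %s", level, which, exc)
            if len(silhouette[level]) == 2:
                ks_rows.append(
                    (
                        level,
                        "silhouette_width",
                        ks_statistic_1d(
                            silhouette[level]["ref"]["silhouette_width"],
                            silhouette[level]["sim"]["silhouette_width"],
                        ),
                    )
                )
    if compute_icc:
        for which, ds in (("ref", empirical), ("sim", simulated)):
            icc[which] = variance_components_icc(ds, icc_genes, method=icc_method)
        shared = len(icc) == 2
        if shared:
            for col, level in (("icc_subject", "subject"), ("icc_sample", "sample")):
                ks_rows.append(
                    (level, col, ks_statistic_1d(icc["ref"][col], icc["sim"][col]))
                )

    ks_table = pd.DataFrame(ks_rows, columns=["level", "metric", "statistic"])
    return FidelityReport(
        reference="empirical",
        gene_metrics_ref=gm_ref,
        gene_metrics_sim=gm_sim,
        cell_metrics_ref=cm_ref,
        cell_metrics_sim=cm_sim,
        ks_table=ks_table,
        silhouette=silhouette,
        icc=icc,
    )
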