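"""Scenario-grid power / FDR / type-I-error engine.

One large master dataset is simulated per replicate (at the grid's maximum
subjects, timepoints, and cells), down-sampled to each scenario, filtered
for high-zero genes, and tested for first-vs-last-timepoint differential
expression. The builtin test is a pseudobulk paired moderated t — a
desk-scale substitute for per-cell mixed hurdle models; an external adapter
contract lets users plug in any per-gene p-value producer.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import polygamma, psi
from scipy.stats import t as t_dist

from .core_io import EmpiricalDataset, RescueParams, SimulatedDataset, write_simulated
from .simulator import downsample_dataset, simulate_dataset

logger = logging.getLogger(__name__)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the ranking and propagated as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def filter_high_zero_genes(
    dataset: EmpiricalDataset, cutoff: float = 0.90
) -> tuple[EmpiricalDataset, list[str]]:
    """Remove genes with a zero fraction strictly above ``cutoff``.

    Returns the filtered dataset and the removed gene ids (so power
    denominators remain well defined).
    """
    nonzero = np.asarray((dataset.counts != 0).sum(axis=1)).ravel()
    zero_frac = 1.0 - nonzero / dataset.n_cells
    keep = zero_frac <= cutoff
    if not keep.any():
        raise ValueError(f"all genes exceed the {cutoff:.0%} zero-fraction cutoff")
    removed = [g for g, k in zip(dataset.gene_ids, keep) if not k]
    return dataset.subset_genes(keep), removed


# ---------------------------------------------------------------------------
# builtin pseudobulk paired test
# ---------------------------------------------------------------------------

def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes moderation of sample variances (scaled-F fit by
    moments of log variances). Returns (posterior variances, prior df)."""
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e_bar = float(z.mean())
    var_z = float(z.var(ddof=1))
    excess = var_z - polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _inv_trigamma(excess)
        s0_sq = np.exp(
            e_bar - psi(df / 2.0) + np.log(df / 2.0) + psi(d0 / 2.0) - np.log(d0 / 2.0)
        )
        post = (d0 * s0_sq + df * np.where(ok, s2, 0.0)) / (d0 + df)
        post[~ok] = d0 * s0_sq / (d0 + df)
        return post, float(d0)
    # variances more concordant than chi-square sampling alone: infinite prior df
    s0_sq = np.exp(e_bar - psi(df / 2.0) + np.log(df / 2.0))
    return np.full_like(s2, s0_sq), np.inf


def _pseudobulk_logcpm(dataset: EmpiricalDataset) -> tuple[np.ndarray, pd.DataFrame]:
    tbl = dataset.sample_table()
    cells = dataset.cells
    mat = np.zeros((dataset.n_genes, len(tbl)))
    for j, sid in enumerate(tbl["sample_id"]):
        cols = np.flatnonzero((cells["sample_id"] == sid).to_numpy())
        mat[:, j] = np.asarray(dataset.counts[:, cols].sum(axis=1)).ravel()
    lib = mat.sum(axis=0)
    logcpm = np.log2(1e6 * mat / np.where(lib > 0, lib, 1.0) + 1.0)
    return logcpm, tbl


def pseudobulk_paired_test(
    dataset: EmpiricalDataset,
    contrast: str = "first_vs_last",
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-gene paired test of last-vs-first timepoint on pseudobulk logCPM.

    Counts are summed per sample, logCPM computed, and per-subject paired
    differences tested with a one-sample t statistic, with limma-style
    empirical-Bayes variance moderation by default. Subjects missing either
    contrast timepoint are dropped; with fewer than 2 complete pairs all
    p-values are NaN.
    """
    if contrast != "first_vs_last":
        raise ValueError("only the first_vs_last contrast is supported")
    logcpm, tbl = _pseudobulk_logcpm(dataset)
    levels = list(dataset.cells["timepoint"].cat.categories)
    first, last = levels[0], levels[-1]
    if first == last:
        raise ValueError("contrast needs at least 2 timepoints")

    diffs = []
    for subj, grp in tbl.groupby("subject_id", observed=True):
        j_first = grp.index[grp["timepoint"].astype(str) == str(first)]
        j_last = grp.index[grp["timepoint"].astype(str) == str(last)]
        if len(j_first) == 1 and len(j_last) == 1:
            diffs.append(logcpm[:, j_last[0]] - logcpm[:, j_first[0]])
    n = len(diffs)
    if n < 2:
        return pd.DataFrame(
            {"gene_id": dataset.gene_ids, "statistic": np.nan, "p_value": np.nan}
        )
    d = np.column_stack(diffs)  # genes x subjects
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = float(n - 1)
    if moderate:
        s2_post, d0 = _squeeze_var(s2, df)
        df_total = df + (d0 if np.isfinite(d0) else 1e6)
    else:
        s2_post, df_total = s2, df
    se = np.sqrt(s2_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
    # zero variance with a nonzero mean: unbounded t, capped
    stat = np.where((se == 0) & (mean != 0), np.sign(mean) * 1e6, stat)
    stat = np.clip(stat, -1e6, 1e6)
    p = 2.0 * t_dist.sf(np.abs(stat), df_total)
    return pd.DataFrame({"gene_id": dataset.gene_ids, "statistic": stat, "p_value": p})


def run_external_adapter(
    dataset: SimulatedDataset, command: str, workdir: str | Path | None = None
) -> pd.DataFrame:
    """Invoke a user-provided DE command on a written dataset.

    The dataset is written as an MTX directory plus metadata TSV; the command
    is run with the dataset directory appended as its final argument and must
    write ``pvalues.tsv`` (columns gene_id, p_value) into that directory.
    """
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    out_dir = Path(ctx.name if ctx else workdir)
    try:
        write_simulated(dataset, out_dir, format="mtx_dir")
        subprocess.run(command.split() + [str(out_dir)], check=True)
        res = pd.read_csv(out_dir / "pvalues.tsv", sep="\t")
        if not {"gene_id", "p_value"} <= set(res.columns):
            raise ValueError("adapter output must have gene_id and p_value columns")
        return res
    finally:
        if ctx:
            ctx.cleanup()


# ---------------------------------------------------------------------------
# scenario grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One power-analysis cell: a down-sampling target plus an optional
    symmetric perturbation of the hierarchy means mu_a and mu_b."""

    name: str
    n_subjects: int
    n_timepoints: int
    mean_cells: int
    variance_shift: float = 0.0  # added to both mu_a and mu_b
    cell_jitter: int = 100  # cells drawn uniform(mean - jitter, mean + jitter)


def default_scenario_grid(
    n_subjects: int = 5,
    n_timepoints: int = 2,
    mean_cells: int = 200,
    variance_shift: float = 0.0,
) -> list[Scenario]:
    """Baseline plus the three doubled designs."""
    base = dict(variance_shift=variance_shift)
    return [
        Scenario("baseline", n_subjects, n_timepoints, mean_cells, **base),
        Scenario("2x_subjects", 2 * n_subjects, n_timepoints, mean_cells, **base),
        Scenario("2x_timepoints", n_subjects, 2 * n_timepoints, mean_cells, **base),
        Scenario("2x_cells", n_subjects, n_timepoints, 2 * mean_cells, **base),
    ]


def _score_replicate(
    sim: SimulatedDataset,
    backend,
    alpha: float,
    zero_cutoff: float,
) -> dict:
    filtered, removed = filter_high_zero_genes(sim.dataset, zero_cutoff)
    keep_ids = set(filtered.gene_ids)
    keep_mask = np.array([g in keep_ids for g in sim.gene_ids])
    de_flags = sim.de_flags[keep_mask]

    if callable(backend):
        res = backend(filtered)
    else:
        res = pseudobulk_paired_test(filtered)
    res = res.set_index("gene_id").reindex(filtered.gene_ids)
    p_raw = res["p_value"].to_numpy()
    p_adj = bh_adjust(p_raw)

    tested = np.isfinite(p_raw)
    de = de_flags & tested
    null = ~de_flags & tested
    rejected = (p_adj < alpha) & tested
    n_rej = int(rejected.sum())
    power = float(rejected[de].mean()) if de.any() else np.nan
    fdr = float((rejected & null).sum() / n_rej) if n_rej else 0.0
    t1e = float((p_raw[null] < alpha).mean()) if null.any() else np.nan
    return {
        "power": power,
        "fdr": fdr,
        "t1e": t1e,
        "n_tested": int(tested.sum()),
        "n_filtered": len(removed),
        "n_de_tested": int(de.sum()),
        "n_rejections": n_rej,
    }


def _master_params(params: RescueParams, scenarios: list[Scenario]) -> dict[float, RescueParams]:
    """Per variance shift, params for the grid's envelope design."""
    max_m = max(s.n_subjects for s in scenarios)
    max_t = max(s.n_timepoints for s in scenarios)
    max_c = max(s.mean_cells for s in scenarios)
    jitter = max(s.cell_jitter for s in scenarios)
    lo = max(10, max_c - jitter)
    out = {}
    for shift in sorted({s.variance_shift for s in scenarios}):
        out[shift] = params.with_updates(
            n_subjects=max_m,
            n_timepoints=max_t,
            cells_per_sample=(lo, max_c + jitter),
            mu_a=params.mu_a + shift,
            mu_b=params.mu_b + shift,
        )
    return out


def evaluate_scenario(
    params: RescueParams,
    scenario: Scenario,
    seed: int,
    n_replicates: int = 10,
    alpha: float = 0.05,
    zero_cutoff: float = 0.90,
    de_backend=None,
) -> pd.DataFrame:
    """Power/FDR/T1E for a single scenario (its own master simulations)."""
    return run_power_grid(
        params,
        [scenario],
        seed=seed,
        n_replicates=n_replicates,
        alpha=alpha,
        zero_cutoff=zero_cutoff,
        de_backend=de_backend,
    )


def run_power_grid(
    params: RescueParams,
    scenarios: list[Scenario],
    seed: int,
    n_replicates: int = 10,
    alpha: float = 0.05,
    zero_cutoff: float = 0.90,
    de_backend=None,
) -> pd.DataFrame:
    """Simulate-then-down-sample power study over a scenario grid.

    Per replicate (and per distinct variance shift) one master dataset at the
    grid envelope is simulated and shared across scenarios, so scenarios are
    compared on matched draws with identical truth labels. Replicate
    failures are recorded as rows with NaN metrics, not dropped.
    """
    if params.de_spec is None:
        logger.warning("no DE spec in params: power will be undefined (NA)")
    masters = _master_params(params, scenarios)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    rows = []
    for r in range(n_replicates):
        child = rep_seeds[r].spawn(len(masters) + 1)
        ds_rng = np.random.default_rng(child[-1])
        for k, (shift, mparams) in enumerate(sorted(masters.items())):
            master = simulate_dataset(mparams, np.random.default_rng(child[k]))
            env_cells = max(s.mean_cells for s in scenarios)
            for scen in scenarios:
                if scen.variance_shift != shift:
                    continue
                kwargs: dict = {}
                if scen.n_subjects < mparams.n_subjects:
                    kwargs["n_subjects"] = scen.n_subjects
                if scen.n_timepoints < mparams.n_timepoints:
                    kwargs["n_timepoints"] = scen.n_timepoints
                if scen.mean_cells < env_cells:
                    master_min = max(10, env_cells - max(s.cell_jitter for s in scenarios))
                    lo = max(10, scen.mean_cells - scen.cell_jitter)
                    hi = scen.mean_cells + scen.cell_jitter
                    if hi > master_min:
                        logger.warning(
                            "scenario %s cell target %d exceeds master minimum %d; clamping",
                            scen.name, hi, master_min,
                        )
                        hi = master_min
                        lo = min(lo, hi)
                    kwargs["cells_per_sample"] = (lo, hi)
                try:
                    sim = (
                        downsample_dataset(master, ds_rng, **kwargs)
                        if kwargs
                        else master
                    )
                    metrics = _score_replicate(sim, de_backend, alpha, zero_cutoff)
                except Exception as exc:  # record, don't drop
                    logger.error("replicate %d scenario %s failed: %s", r, scen.name, exc)
                    metrics = {
                        "power": np.nan,
                        "fdr": np.nan,
                        "t1e": np.nan,
                        "n_tested": 0,
                        "n_filtered": 0,
                        "n_de_tested": 0,
                        "n_rejections": 0,
                        "error": str(exc),
                    }
                rows.append(
                    {"scenario": scen.name, "replicate": r,
                     "variance_shift": shift, **metrics}
                )
    return pd.DataFrame(rows)


def summarize_power(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of each rate per scenario."""
    return (
        results.groupby(["scenario", "variance_shift"], observed=True)[
            ["power", "fdr", "t1e"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
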