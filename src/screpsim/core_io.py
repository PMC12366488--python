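"""Data model, validation, and readers/writers.

Counts are stored gene-major (genes as rows, cells as columns), CSR sparse.
All coordinates are 0-based internally; MatrixMarket files use 1-based
indices per the standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = ("cell_id", "subject_id", "sample_id", "timepoint")


class DataValidationError(ValueError):
    """Raised when an input dataset violates the data model."""


def _as_csr_int(matrix) -> sp.csr_matrix:
    m = sp.csr_matrix(matrix)
    if m.nnz:
        data = m.data
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, rtol=0, atol=1e-8):
                bad = data[np.abs(data - np.rint(data)) > 1e-8][:5]
                raise DataValidationError(
                    f"counts must be integers; found non-integer entries {bad}"
                )
            data = rounded
        if (data < 0).any():
            raise DataValidationError("negative count entries are not allowed")
        m.data = data.astype(np.int64)
    else:
        m.data = m.data.astype(np.int64)
    return m


@dataclass
class EmpiricalDataset:
    """A genes x cells count matrix with per-cell sample annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows and cells as columns.
    gene_ids
        Unique identifier per gene (row).
    cells
        One row per cell (column of ``counts``) with columns
        ``cell_id, subject_id, sample_id, timepoint``. Each cell belongs to
        exactly one sample; each sample to one subject and one timepoint;
        no subject has two samples at the same timepoint.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _as_csr_int(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cells = self.cells.reset_index(drop=True).copy()
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise DataValidationError(
                f"gene_ids has {len(self.gene_ids)} entries but matrix has {g} rows"
            )
        dup = pd.Index(self.gene_ids).duplicated()
        if dup.any():
            offenders = list(pd.Index(self.gene_ids)[dup][:5])
            raise DataValidationError(f"duplicate gene ids: {offenders}")
        missing = [col for col in REQUIRED_CELL_COLUMNS if col not in self.cells]
        if missing:
            raise DataValidationError(f"cell table missing columns: {missing}")
        if len(self.cells) != c:
            raise DataValidationError(
                f"cell table has {len(self.cells)} rows but matrix has {c} columns"
            )
        if self.cells["cell_id"].duplicated().any():
            raise DataValidationError("duplicate cell ids in metadata")
        # sample -> subject/timepoint must be unique
        per_sample = self.cells.groupby("sample_id", observed=True)[
            ["subject_id", "timepoint"]
        ].nunique()
        bad = per_sample[(per_sample > 1).any(axis=1)]
        if len(bad):
            raise DataValidationError(
                f"samples mapped to multiple subjects/timepoints: {list(bad.index[:5])}"
            )
        # no duplicate (subject, timepoint) across samples
        sample_map = self.sample_table()
        dup_st = sample_map.duplicated(subset=["subject_id", "timepoint"])
        if dup_st.any():
            raise DataValidationError(
                "duplicate (subject, timepoint) pairs across samples: "
                f"{list(sample_map.loc[dup_st, 'sample_id'][:5])}"
            )
        if not isinstance(self.cells["timepoint"].dtype, pd.CategoricalDtype):
            levels = sorted(map(str, self.cells["timepoint"].astype(str).unique()))
            logger.warning(
                "timepoint order not declared; using lexicographic order %s", levels
            )
            self.cells["timepoint"] = pd.Categorical(
                self.cells["timepoint"].astype(str), categories=levels, ordered=True
            )

    # -- derived quantities ----------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.cells["subject_id"].nunique()

    @property
    def n_samples(self) -> int:
        """Total number of samples N."""
        return self.cells["sample_id"].nunique()

    def sample_table(self) -> pd.DataFrame:
        """One row per sample: sample_id, subject_id, timepoint, n cells."""
        tbl = (
            self.cells.groupby("sample_id", observed=True)
            .agg(
                subject_id=("subject_id", "first"),
                timepoint=("timepoint", "first"),
                n_cells=("cell_id", "size"),
            )
            .reset_index()
        )
        return tbl

    def cells_per_sample(self) -> pd.Series:
        return self.cells.groupby("sample_id", observed=True).size()

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_genes(self, mask_or_idx) -> "EmpiricalDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EmpiricalDataset(
            counts=self.counts[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            cells=self.cells,
        )

    def subset_cells(self, mask_or_idx) -> "EmpiricalDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EmpiricalDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cells=self.cells.iloc[idx],
        )


@dataclass
class RescueParams:
    """Full hyper-parameter set for the hierarchical gamma-Poisson simulator.

    ``gene_means`` and ``dispersions`` are per-gene; the four hierarchy
    hyper-parameters are log-scale mean/sd of the log-normal distributions the
    per-gene subject/sample factor variances are drawn from. ``lib_concentration``
    controls sample-specific library-size shifts through a symmetric Dirichlet.
    """

    n_genes: int
    n_subjects: int
    n_timepoints: int
    cells_per_sample: int | tuple[int, int] | Sequence[int]
    gene_means: np.ndarray
    dispersions: np.ndarray
    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    mu_lib: float
    sigma_lib: float
    lib_concentration: float
    custom_lib_sizes: np.ndarray | None = None
    de_spec: "object | None" = None  # simulator.DESpec; kept loose to avoid cycle
    gene_ids: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_subjects < 1 or self.n_timepoints < 1:
            raise ValueError("n_genes, n_subjects, n_timepoints must each be >= 1")
        if self.gene_means.shape != (self.n_genes,):
            raise ValueError("gene_means must have length n_genes")
        if self.dispersions.shape != (self.n_genes,):
            raise ValueError("dispersions must have length n_genes")
        if (self.gene_means <= 0).any():
            raise ValueError("gene_means must be positive")
        if (self.dispersions < 0).any():
            raise ValueError("dispersions must be non-negative")
        if min(self.sigma_a, self.sigma_b, self.sigma_lib) < 0:
            raise ValueError("sigma_a, sigma_b, sigma_lib must be >= 0")
        if self.lib_concentration <= 0:
            raise ValueError("lib_concentration must be positive")
        spec = self.cells_per_sample
        if isinstance(spec, int):
            if spec < 1:
                raise ValueError("cells_per_sample must be >= 1")
        elif isinstance(spec, tuple) and len(spec) == 2:
            lo, hi = spec
            if lo < 1 or hi < lo:
                raise ValueError("cells_per_sample bounds must satisfy 1 <= lo <= hi")
        else:
            arr = np.asarray(spec, dtype=int)
            if arr.size != self.n_subjects * self.n_timepoints:
                raise ValueError(
                    "explicit cells_per_sample must list one value per sample"
                )
            if (arr < 1).any():
                raise ValueError("cells_per_sample entries must be >= 1")
        if self.custom_lib_sizes is not None:
            cls = np.asarray(self.custom_lib_sizes, dtype=float)
            if cls.size == 0 or (cls <= 0).any():
                raise ValueError("custom_lib_sizes must be non-empty and positive")
            self.custom_lib_sizes = cls

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path, gene_table_path: str | Path | None = None) -> None:
        """Write params as YAML, with per-gene vectors in a sidecar TSV."""
        path = Path(path)
        if gene_table_path is None:
            gene_table_path = path.with_suffix(".genes.tsv")
        gene_table_path = Path(gene_table_path)
        gene_ids = self.gene_ids or [f"gene{i + 1}" for i in range(self.n_genes)]
        pd.DataFrame(
            {"gene_id": gene_ids, "mean": self.gene_means, "dispersion": self.dispersions}
        ).to_csv(gene_table_path, sep="\t", index=False)
        spec = self.cells_per_sample
        if isinstance(spec, tuple):
            cells = {"kind": "uniform", "low": int(spec[0]), "high": int(spec[1])}
        elif isinstance(spec, int):
            cells = {"kind": "fixed", "value": int(spec)}
        else:
            cells = {"kind": "explicit", "values": [int(v) for v in np.asarray(spec)]}
        doc = {
            "design": {
                "n_genes": int(self.n_genes),
                "n_subjects": int(self.n_subjects),
                "n_timepoints": int(self.n_timepoints),
                "cells_per_sample": cells,
            },
            "gene": {"table": gene_table_path.name},
            "hierarchy": {
                "mu_a": float(self.mu_a),
                "sigma_a": float(self.sigma_a),
                "mu_b": float(self.mu_b),
                "sigma_b": float(self.sigma_b),
            },
            "library": {
                "mu_lib": float(self.mu_lib),
                "sigma_lib": float(self.sigma_lib),
                "concentration": float(self.lib_concentration),
            },
            "provenance": {k: str(v) for k, v in self.provenance.items()},
        }
        if self.custom_lib_sizes is not None:
            lib_path = path.with_suffix(".libsizes.tsv")
            pd.Series(self.custom_lib_sizes, name="lib_size").to_csv(
                lib_path, sep="\t", index=False
            )
            doc["library"]["custom_lib_path"] = lib_path.name
        if self.de_spec is not None:
            doc["de_spec"] = self.de_spec.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RescueParams":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        gene_tbl = pd.read_csv(path.parent / doc["gene"]["table"], sep="\t")
        cells_doc = doc["design"]["cells_per_sample"]
        if cells_doc["kind"] == "fixed":
            cells: int | tuple[int, int] | list[int] = int(cells_doc["value"])
        elif cells_doc["kind"] == "uniform":
            cells = (int(cells_doc["low"]), int(cells_doc["high"]))
        else:
            cells = [int(v) for v in cells_doc["values"]]
        custom = None
        if "custom_lib_path" in doc["library"]:
            custom = pd.read_csv(
                path.parent / doc["library"]["custom_lib_path"], sep="\t"
            )["lib_size"].to_numpy()
        de_spec = None
        if doc.get("de_spec") is not None:
            from .simulator import DESpec

            de_spec = DESpec.from_dict(doc["de_spec"])
        return cls(
            n_genes=int(doc["design"]["n_genes"]),
            n_subjects=int(doc["design"]["n_subjects"]),
            n_timepoints=int(doc["design"]["n_timepoints"]),
            cells_per_sample=cells,
            gene_means=gene_tbl["mean"].to_numpy(),
            dispersions=gene_tbl["dispersion"].to_numpy(),
            mu_a=float(doc["hierarchy"]["mu_a"]),
            sigma_a=float(doc["hierarchy"]["sigma_a"]),
            mu_b=float(doc["hierarchy"]["mu_b"]),
            sigma_b=float(doc["hierarchy"]["sigma_b"]),
            mu_lib=float(doc["library"]["mu_lib"]),
            sigma_lib=float(doc["library"]["sigma_lib"]),
            lib_concentration=float(doc["library"]["concentration"]),
            custom_lib_sizes=custom,
            de_spec=de_spec,
            gene_ids=gene_tbl["gene_id"].astype(str).tolist(),
            provenance=doc.get("provenance", {}) or {},
        )

    def with_updates(self, **kwargs) -> "RescueParams":
        return replace(self, **kwargs)


@dataclass
class SimulatedDataset:
    """Simulated counts plus ground truth.

    ``truth_log2fc`` is genes x timepoints with the first column all zero;
    ``de_flags`` marks genes simulated with nonzero fold change.
    """

    dataset: EmpiricalDataset
    truth_log2fc: np.ndarray
    de_flags: np.ndarray
    seed: int | None = None
    params: RescueParams | None = None
    sample_means: np.ndarray | None = None
    subject_factors: np.ndarray | None = None
    sample_factors: np.ndarray | None = None
    expected_lib_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.truth_log2fc = np.asarray(self.truth_log2fc, dtype=float)
        self.de_flags = np.asarray(self.de_flags, dtype=bool)
        g = self.dataset.n_genes
        if self.truth_log2fc.shape[0] != g or self.de_flags.shape != (g,):
            raise DataValidationError("truth shapes do not match gene count")
        if not np.all(self.truth_log2fc[:, 0] == 0):
            raise DataValidationError("log2FC at the first timepoint must be zero")

    @property
    def counts(self) -> sp.csr_matrix:
        return self.dataset.counts

    @property
    def gene_ids(self) -> list[str]:
        return self.dataset.gene_ids

    @property
    def cells(self) -> pd.DataFrame:
        return self.dataset.cells

    def truth_table(self) -> pd.DataFrame:
        cols = {
            f"log2fc_t{t + 1}": self.truth_log2fc[:, t]
            for t in range(self.truth_log2fc.shape[1])
        }
        return pd.DataFrame(
            {"gene_id": self.dataset.gene_ids, "de_flag": self.de_flags, **cols}
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(matrix_path: Path) -> sp.csr_matrix:
    if matrix_path.suffix == ".mtx":
        return sp.csr_matrix(scipy.io.mmread(matrix_path))
    # dense delimited fallback: rows = genes, first column may be gene ids
    df = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    return sp.csr_matrix(df.to_numpy())


def read_counts_with_metadata(
    matrix_path: str | Path,
    genes_path: str | Path | None,
    metadata_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> EmpiricalDataset:
    """Read a count matrix plus a delimited cell-metadata table.

    ``column_map`` names the metadata columns holding the cell, subject,
    sample, and timepoint identifiers, e.g.
    ``{"cell_id": "barcode", "subject_id": "donor", "sample_id": "sample",
    "timepoint": "visit"}``. Optional keys: ``align`` ("cell_id" to join on
    ids, "order" for positional alignment; default "cell_id" when a barcodes
    file exists) and ``timepoint_order`` (explicit ordered list of levels).
    """
    column_map = dict(column_map or {})
    align = column_map.pop("align", None)
    timepoint_order = column_map.pop("timepoint_order", None)
    matrix_path = Path(matrix_path)

    counts = _read_matrix(matrix_path)
    barcodes = None
    if matrix_path.suffix == ".mtx":
        gdir = matrix_path.parent
        for candidate in ("barcodes.tsv",):
            if (gdir / candidate).exists():
                barcodes = pd.read_csv(gdir / candidate, sep="\t", header=None)[0]
                barcodes = barcodes.astype(str).tolist()

    if genes_path is not None:
        gene_df = pd.read_csv(genes_path, sep="\t", header=None)
        gene_ids = gene_df[0].astype(str).tolist()
    else:
        gene_ids = [f"gene{i + 1}" for i in range(counts.shape[0])]
    if len(gene_ids) != counts.shape[0]:
        raise DataValidationError(
            f"{len(gene_ids)} gene ids for a {counts.shape[0]}-row matrix"
        )

    meta = pd.read_csv(metadata_path, sep=None, engine="python")
    rename = {v: k for k, v in column_map.items() if v in meta.columns}
    meta = meta.rename(columns=rename)
    for col in ("subject_id", "sample_id", "timepoint"):
        if col not in meta.columns:
            raise DataValidationError(f"metadata lacks a '{col}' column (column_map?)")
    if "cell_id" not in meta.columns:
        meta["cell_id"] = [f"cell{i + 1}" for i in range(len(meta))]

    if align is None:
        align = "cell_id" if barcodes is not None else "order"
    if align == "cell_id" and barcodes is not None:
        meta_ids = set(meta["cell_id"].astype(str))
        missing = [b for b in barcodes if b not in meta_ids]
        extra = [m for m in meta["cell_id"].astype(str) if m not in set(barcodes)]
        if extra:
            raise DataValidationError(
                f"metadata cells absent from matrix: {extra[:5]}"
            )
        if missing:
            raise DataValidationError(
                f"matrix cells absent from metadata: {missing[:5]}"
            )
        meta = meta.set_index(meta["cell_id"].astype(str)).loc[barcodes].reset_index(
            drop=True
        )
    else:
        if align == "cell_id":
            logger.warning("no barcodes file; falling back to positional alignment")
        if len(meta) != counts.shape[1]:
            raise DataValidationError(
                f"metadata has {len(meta)} rows but matrix has {counts.shape[1]} columns"
            )

    if timepoint_order is not None:
        meta["timepoint"] = pd.Categorical(
            meta["timepoint"].astype(str),
            categories=[str(t) for t in timepoint_order],
            ordered=True,
        )
        if meta["timepoint"].isna().any():
            raise DataValidationError("timepoint values outside declared order")
    return EmpiricalDataset(counts=counts, gene_ids=gene_ids, cells=meta)


def _write_mtx(counts: sp.spmatrix, path: Path) -> None:
    coo = sp.coo_matrix(counts)
    with open(path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")


def write_simulated(
    dataset: SimulatedDataset, out_dir: str | Path, format: str = "mtx_dir"
) -> dict[str, str]:
    """Write a simulated dataset; returns a manifest of files written.

    ``format`` is "mtx_dir" (matrix.mtx + genes.tsv + barcodes.tsv) or
    "dense_tsv" (one genes x cells TSV). Metadata, truth, and params are
    written alongside in both cases.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if format == "mtx_dir":
        _write_mtx(dataset.counts, out_dir / "matrix.mtx")
        pd.Series(dataset.gene_ids).to_csv(
            out_dir / "genes.tsv", sep="\t", index=False, header=False
        )
        dataset.cells["cell_id"].to_csv(
            out_dir / "barcodes.tsv", sep="\t", index=False, header=False
        )
        manifest.update(
            counts="matrix.mtx", genes="genes.tsv", barcodes="barcodes.tsv"
        )
    elif format == "dense_tsv":
        dense = pd.DataFrame(
            dataset.counts.toarray(),
            index=pd.Index(dataset.gene_ids, name="gene_id"),
            columns=dataset.cells["cell_id"],
        )
        dense.to_csv(out_dir / "counts.tsv", sep="\t")
        manifest["counts"] = "counts.tsv"
    else:
        raise ValueError(f"unknown format {format!r}")

    dataset.cells.to_csv(out_dir / "cell_metadata.tsv", sep="\t", index=False)
    dataset.truth_table().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    manifest.update(metadata="cell_metadata.tsv", truth="truth.tsv")
    if dataset.params is not None:
        dataset.params.to_yaml(out_dir / "params.yaml")
        manifest["params"] = "params.yaml"
    if dataset.sample_means is not None:
        np.savetxt(out_dir / "sample_means.tsv", dataset.sample_means, delimiter="\t")
        manifest["sample_means"] = "sample_means.tsv"
    return manifest


def read_simulated_dir(out_dir: str | Path) -> EmpiricalDataset:
    """Read back a directory written by :func:`write_simulated` (counts view)."""
    out_dir = Path(out_dir)
    if (out_dir / "matrix.mtx").exists():
        return read_counts_with_metadata(
            out_dir / "matrix.mtx",
            out_dir / "genes.tsv",
            out_dir / "cell_metadata.tsv",
            column_map={"align": "cell_id"},
        )
    df = pd.read_csv(out_dir / "counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out_dir / "cell_metadata.tsv", sep="\t")
    return EmpiricalDataset(
        counts=sp.csr_matrix(df.to_numpy()),
        gene_ids=df.index.astype(str).tolist(),
        cells=meta,
    )


def filter_subjects_min_cells(
    dataset: EmpiricalDataset, min_cells: int = 25
) -> EmpiricalDataset:
    """Keep subjects whose every sample has at least ``min_cells`` cells.

    Genes left with zero total count after the subject drop are removed.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    per_sample = dataset.sample_table()
    ok_by_subject = per_sample.groupby("subject_id", observed=True)["n_cells"].min()
    keep_subjects = set(ok_by_subject[ok_by_subject >= min_cells].index)
    if not keep_subjects:
        raise DataValidationError(
            f"no subject has >= {min_cells} cells in every sample"
        )
    cell_mask = dataset.cells["subject_id"].isin(keep_subjects).to_numpy()
    out = dataset.subset_cells(cell_mask)
    totals = np.asarray(out.counts.sum(axis=1)).ravel()
    out = out.subset_genes(totals > 0)
    dropped = dataset.n_subjects - out.n_subjects
    if dropped:
        logger.info("dropped %d subjects below %d cells/sample", dropped, min_cells)
    return out
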