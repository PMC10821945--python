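"""Data containers and file I/O.

The on-disk convention is Matrix Market for the gene-by-cell count matrix with
sidecar gene/cell id lists (``<stem>.genes.txt`` / ``<stem>.cells.txt``), a TSV
cell-metadata table (cell_id, condition, cluster) and a TSV embedding table
(cell_id, dim_1..dim_d).  Cells are reconciled across the three files by an
explicit cell_id join — never by positional order — and any cell present in
the counts but missing from the metadata or embedding is an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = ["CellDataset", "RunConfig", "read_dataset", "write_dataset", "write_results"]

_FLOAT_FMT = "%.15g"  # lossless round-trip for doubles at 15 significant digits


@dataclass
class CellDataset:
    """Gene-by-cell counts with per-cell condition/cluster labels and a
    reduced-dimensional embedding.

    ``lib_sizes`` defaults to the column sums of the count matrix (sequencing
    depth N_i); a simulator or upstream pipeline may supply the true depths.
    """

    counts: np.ndarray  # J x n, non-negative integers (dense or sparse)
    cell_ids: List[str]
    conditions: np.ndarray
    clusters: np.ndarray
    embedding: np.ndarray  # n x d
    gene_ids: Optional[List[str]] = None
    lib_sizes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if scipy.sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.shape[1] != n:
            raise ValueError(
                f"dimension mismatch: counts has {self.counts.shape[1]} columns "
                f"but there are {n} cell ids"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative count in count matrix")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("non-integer counts: normalized matrices are not accepted")
        self.counts = self.counts.astype(np.int64)
        self.conditions = np.asarray(self.conditions).astype(str)
        self.clusters = np.asarray(self.clusters).astype(str)
        self.embedding = np.asarray(self.embedding, dtype=float)
        for name, v in (("conditions", self.conditions), ("clusters", self.clusters)):
            if v.shape[0] != n:
                raise ValueError(f"{name} has length {v.shape[0]}, expected {n}")
        if self.embedding.shape[0] != n:
            raise ValueError(
                f"embedding has {self.embedding.shape[0]} rows, expected {n}"
            )
        if np.any(self.conditions == "") or np.any(self.conditions == "nan"):
            raise ValueError("empty or missing condition labels")
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{j}" for j in range(self.counts.shape[0])]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match count-matrix rows")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if self.lib_sizes.shape[0] != n:
            raise ValueError("lib_sizes length does not match number of cells")
        if np.any(self.lib_sizes <= 0):
            raise ValueError("lib_sizes must be strictly positive")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def condition_levels(self) -> np.ndarray:
        return np.unique(self.conditions)


@dataclass
class RunConfig:
    """Workflow configuration with validated defaults."""

    seed: int = 0
    alpha: float = 0.05
    threshold_topology: float = 0.0
    threshold_progression: float = 0.0
    threshold_fate: float = 0.0
    lfc_threshold: float = 0.0
    r: int = 100  # permutation count for the topology test
    k: int = 10  # imbalance neighborhood size
    s: int = 10  # imbalance smoothing basis size
    K: int = 6  # spline basis functions per smoother
    test_fraction: float = 0.3
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sidecar_paths(counts_path: Path):
    stem = counts_path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_dataset(counts_path, metadata_path, embedding_path) -> CellDataset:
    """Read and reconcile the three on-disk inputs into a CellDataset."""
    counts_path = Path(counts_path)
    counts = scipy.io.mmread(str(counts_path))
    counts = np.asarray(counts.todense()) if scipy.sparse.issparse(counts) else np.asarray(counts)

    genes_path, cells_path = _sidecar_paths(counts_path)
    if not genes_path.exists() or not cells_path.exists():
        raise FileNotFoundError(
            f"sidecar id lists not found next to {counts_path} "
            f"(expected {genes_path.name} and {cells_path.name})"
        )
    gene_ids = genes_path.read_text().split()
    cell_ids = cells_path.read_text().split()
    if len(gene_ids) != counts.shape[0] or len(cell_ids) != counts.shape[1]:
        raise ValueError("sidecar id lists do not match count-matrix dimensions")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str})
    for col in ("cell_id", "condition", "cluster"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    emb = pd.read_csv(embedding_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in emb.columns:
        raise ValueError("embedding table is missing the cell_id column")

    meta = meta.set_index("cell_id")
    emb = emb.set_index("cell_id")
    for name, table in (("metadata", meta), ("embedding", emb)):
        missing = [c for c in cell_ids if c not in table.index]
        if missing:
            raise ValueError(
                f"cells present in counts but missing from {name}: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
    meta = meta.loc[cell_ids]
    emb = emb.loc[cell_ids]
    dim_cols = [c for c in emb.columns if c.startswith("dim_")]
    if not dim_cols:
        raise ValueError("embedding table has no dim_* columns")

    return CellDataset(
        counts=counts,
        cell_ids=list(cell_ids),
        conditions=meta["condition"].to_numpy(),
        clusters=meta["cluster"].to_numpy(),
        embedding=emb[dim_cols].to_numpy(dtype=float),
        gene_ids=list(gene_ids),
    )


def write_dataset(dataset: CellDataset, out_dir) -> dict:
    """Write a CellDataset in the package's on-disk convention; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_path = out / "counts.mtx"
    scipy.io.mmwrite(str(counts_path), scipy.sparse.coo_matrix(dataset.counts))
    genes_path, cells_path = _sidecar_paths(counts_path)
    genes_path.write_text("\n".join(dataset.gene_ids) + "\n")
    cells_path.write_text("\n".join(dataset.cell_ids) + "\n")

    meta_path = out / "metadata.tsv"
    pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "condition": dataset.conditions,
            "cluster": dataset.clusters,
        }
    ).to_csv(meta_path, sep="\t", index=False)

    emb_path = out / "embedding.tsv"
    emb = pd.DataFrame(
        dataset.embedding,
        columns=[f"dim_{i + 1}" for i in range(dataset.embedding.shape[1])],
    )
    emb.insert(0, "cell_id", dataset.cell_ids)
    emb.to_csv(emb_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return {
        "counts": counts_path,
        "metadata": meta_path,
        "embedding": emb_path,
    }


def write_results(result, path, fmt: Optional[str] = None) -> Path:
    """Write a test result (JSON) or a per-gene/per-lineage table (TSV).

    Floats are written at 15 significant digits so that a write/read
    round-trip is lossless.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = result.to_dict() if hasattr(result, "to_dict") else result
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
    elif fmt == "tsv":
        if isinstance(result, pd.DataFrame):
            result.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        elif hasattr(result, "to_frame"):
            result.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        else:
            raise TypeError("TSV output requires a table-like result")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
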