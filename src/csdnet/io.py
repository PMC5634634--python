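"""Reading, validating, filtering and aligning expression matrices.

Expression tables are gene-by-sample numeric matrices, one per condition.
The expression scale is arbitrary (counts, RPKM, log-scale): downstream
scoring uses Spearman rank correlation, which is invariant to monotone
per-dataset transforms, so no normalisation is performed here.  Missing or
non-numeric values are rejected at load rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "filter_genes",
    "align_matrices",
    "write_network_files",
    "read_edge_table",
    "read_edge_list",
    "read_gmt",
]


@dataclass
class ExpressionMatrix:
    """A gene x sample expression table for a single condition.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray, shape (n_genes, n_samples)
        Finite numeric expression values.
    condition_label : str
        Free-text label for the condition (tissue, treatment, species...).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but "
                f"{self.values.shape[1]} columns"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   condition_label: str = "") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            condition_label=condition_label,
        )


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


def read_expression_table(path: str | Path, dialect: str = "tsv",
                          condition_label: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated gene x sample table (plain TSV or GCT v1.2).

    TSV layout: header row of sample ids, first column gene ids.  The GCT
    dialect expects the standard ``#1.2`` version line and a dimensions line
    ahead of the table, plus a ``Description`` column that is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skiprows = 0
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ValueError(f"{path}: missing GCT version header, got "
                                 f"{version!r}")
        skiprows = 2
    table = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0,
                        dtype={0: str})
    if dialect == "gct":
        # first non-index column is the Description column
        table = table.drop(columns=table.columns[0])
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    index = [str(g) for g in table.index]
    dup = pd.Index(index).duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate gene id {index[int(np.argmax(dup))]!r}")
    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~table.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        g, s = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {index[g]!r}, "
            f"column {table.columns[s]!r}")
    if condition_label is None:
        condition_label = path.stem
    return ExpressionMatrix(
        gene_ids=index,
        sample_ids=[str(c) for c in table.columns],
        values=numeric.to_numpy(dtype=float),
        condition_label=condition_label,
    )


def filter_genes(m: ExpressionMatrix, keep_ids: set[str]) -> ExpressionMatrix:
    """Restrict a matrix to a keep-list (e.g. protein-coding gene ids).

    Row order is preserved.  Keep-list entries absent from the matrix are
    ignored with a warning; an empty intersection is a hard error.
    """
    keep_ids = set(keep_ids)
    if not keep_ids:
        raise ValueError("keep_ids must be non-empty")
    present = [g for g in m.gene_ids if g in keep_ids]
    if not present:
        raise ValueError("keep list shares no genes with the matrix")
    unknown = keep_ids.difference(m.gene_ids)
    if unknown:
        logger.warning("%d keep-list ids not in the matrix (e.g. %r); ignored",
                       len(unknown), sorted(unknown)[0])
    logger.info("filter_genes: kept %d of %d genes (%d dropped)",
                len(present), m.n_genes, m.n_genes - len(present))
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    rows = [pos[g] for g in present]
    return ExpressionMatrix(present, list(m.sample_ids), m.values[rows],
                            m.condition_label)


def align_matrices(m1: ExpressionMatrix,
                   m2: ExpressionMatrix) -> tuple[ExpressionMatrix,
                                                  ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in a common row order.

    The shared order is m1's row order; sample columns are untouched.  The
    scoring stage requires a one-to-one gene match between conditions, so a
    disjoint gene set is a hard error.
    """
    common = set(m1.gene_ids) & set(m2.gene_ids)
    if not common:
        raise ValueError("matrices share no genes")
    order = [g for g in m1.gene_ids if g in common]
    pos1 = {g: i for i, g in enumerate(m1.gene_ids)}
    pos2 = {g: i for i, g in enumerate(m2.gene_ids)}
    idx1 = [pos1[g] for g in order]
    idx2 = [pos2[g] for g in order]
    out1 = ExpressionMatrix(order, list(m1.sample_ids), m1.values[idx1],
                            m1.condition_label)
    out2 = ExpressionMatrix(list(order), list(m2.sample_ids), m2.values[idx2],
                            m2.condition_label)
    return out1, out2


EDGE_COLUMNS = ["gene_a", "gene_b", "type", "score", "rho1", "rho2"]
NODE_COLUMNS = ["gene", "k", "k_C", "k_S", "k_D", "H"]


def write_network_files(net, prefix: str | Path) -> tuple[Path, Path]:
    """Write a typed network as Cytoscape-importable edge and node TSVs.

    Returns ``(<prefix>_edges.tsv, <prefix>_nodes.tsv)``.  Gene pairs are
    written with gene_a < gene_b lexicographically.
    """
    from .network import node_summaries  # deferred: avoid import cycle

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edge_path = prefix.parent / (prefix.name + "_edges.tsv")
    node_path = prefix.parent / (prefix.name + "_nodes.tsv")

    rows = []
    for a, b, data in net.graph.edges(data=True):
        a, b = (a, b) if a < b else (b, a)
        rows.append((a, b, data["type"], data["score"],
                     data.get("rho1", np.nan), data.get("rho2", np.nan)))
    rows.sort()
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    edges.to_csv(edge_path, sep="\t", index=False, float_format="%.6g")

    if net.graph.number_of_nodes():
        summaries = node_summaries(net)
        nodes = pd.DataFrame(
            [(s.gene, s.k, s.k_C, s.k_S, s.k_D, s.H) for s in summaries],
            columns=NODE_COLUMNS)
    else:
        nodes = pd.DataFrame(columns=NODE_COLUMNS)
    nodes.to_csv(node_path, sep="\t", index=False, float_format="%.6g")
    return edge_path, node_path


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read back a typed edge table written by :func:`write_network_files`."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in EDGE_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing edge columns {missing}")
    return table


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV edge list (reference interaction network)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed edge line {line!r}")
            pairs.append((parts[0], parts[1]))
    return pairs


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, member genes."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            collections[parts[0]] = {g for g in parts[2:] if g}
    return collections
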