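"""Data containers and I/O for OTU count tables, phylogenetic trees and
distance matrices.

The count table is oriented samples x OTUs.  The TSV dialect puts samples on
rows (first column = sample id) and OTUs on columns (header row = OTU ids).
BIOM support is limited to the dense JSON flavour (OTUs on rows, samples on
columns, as in the BIOM 1.0 spec); HDF5 BIOM is out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicate ids, negative
    counts, missing branch lengths, ...)."""


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what} identifier(s): {sorted(set(dups))}")


@dataclass
class OtuTable:
    """Samples x OTUs table of non-negative integer read counts."""

    sample_ids: list
    otu_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array (samples x OTUs)")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size == 0:
            raise ValidationError("empty table (0 samples or 0 OTUs)")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=0, rtol=0):
                bad = np.argwhere(counts != rounded)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}: {counts[bad[0], bad[1]]}"
                )
            counts = rounded
        counts = np.ascontiguousarray(counts, dtype=np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class ProportionTable:
    """Row-normalised view of an :class:`OtuTable`.

    ``zero_rows`` lists samples whose total count was zero; their rows are
    all-zero rather than NaN.
    """

    sample_ids: list
    otu_ids: list
    values: np.ndarray
    zero_rows: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        totals = self.values.sum(axis=1)
        nonzero = [i for i in range(len(self.sample_ids)) if self.sample_ids[i] not in self.zero_rows]
        if nonzero and not np.allclose(totals[nonzero], 1.0, atol=1e-9):
            raise ValidationError("proportion rows must sum to 1 within 1e-9")


@dataclass
class PresenceTable:
    """0/1 indicator of positive counts, same axes as the source table."""

    sample_ids: list
    otu_ids: list
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence values must be 0 or 1")
        self.values = vals.astype(np.int64)


def to_proportions(table: OtuTable | PresenceTable) -> ProportionTable:
    """Divide each row by its total.  Zero-total rows stay all-zero and are
    flagged in ``zero_rows`` instead of raising."""
    vals = table.counts if isinstance(table, OtuTable) else table.values
    vals = np.asarray(vals, dtype=float)
    totals = vals.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    props = vals / safe[:, None]
    zero_ids = [table.sample_ids[i] for i in np.flatnonzero(zero)]
    return ProportionTable(list(table.sample_ids), list(table.otu_ids), props, zero_ids)


def to_presence(table: OtuTable | ProportionTable | PresenceTable) -> PresenceTable:
    """Code positive entries to 1 and zeros to 0. Idempotent."""
    if isinstance(table, OtuTable):
        vals = table.counts
    else:
        vals = table.values
    return PresenceTable(list(table.sample_ids), list(table.otu_ids), (np.asarray(vals) > 0).astype(np.int64))


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample's reads to ``depth`` without replacement
    (multivariate hypergeometric).

    Samples whose total is below ``depth`` are dropped with a warning.
    Reproducible for a fixed seed.
    """
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals
    keep = totals >= depth
    dropped = [table.sample_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) with total reads < {depth}: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise ValidationError("rarefy: no sample has enough reads for the requested depth")
    rng = np.random.default_rng(seed)
    rows = []
    for i in np.flatnonzero(keep):
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    return OtuTable(
        [table.sample_ids[i] for i in np.flatnonzero(keep)],
        list(table.otu_ids),
        np.array(rows, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# count-table I/O

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read a count table from ``tsv`` (samples x OTUs) or ``biom-json``
    (dense BIOM 1.0 JSON, OTUs x samples, transposed on read)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"malformed TSV table {path}: {exc}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError(f"empty table in {path}")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValidationError(f"non-numeric column {col!r} in {path}")
        return OtuTable(list(df.index), list(df.columns), df.to_numpy())
    if format == "biom-json":
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"malformed BIOM JSON {path}: line {exc.lineno}: {exc.msg}") from exc
        if obj.get("matrix_type") != "dense":
            raise ValidationError("only dense BIOM JSON tables are supported")
        otu_ids = [r["id"] for r in obj["rows"]]
        sample_ids = [c["id"] for c in obj["columns"]]
        data = np.asarray(obj["data"], dtype=float)
        if data.shape != (len(otu_ids), len(sample_ids)):
            raise ValidationError(
                f"BIOM data shape {data.shape} does not match rows/columns metadata"
            )
        return OtuTable(sample_ids, otu_ids, data.T)
    raise ValueError(f"unknown table format {format!r}")


def write_otu_table(table: OtuTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# trees

@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; leaf labels are OTU identifiers.

    Every non-root branch must carry a finite non-negative length (all the
    UniFrac variants need them).  The root's own incoming edge, if present in
    the source Newick, is ignored.
    """

    tree: TreeNode

    def __post_init__(self):
        leaves = [t.name for t in self.tree.tips()]
        if len(leaves) == 0:
            raise ValidationError("tree has no leaves")
        _check_unique(leaves, "leaf")
        for node in self.tree.postorder(include_self=False):
            if node.length is None:
                raise ValidationError(
                    f"branch leading to {node.name or '<internal>'} has no length; "
                    "branch lengths are required"
                )
            if not np.isfinite(node.length) or node.length < 0:
                raise ValidationError(
                    f"branch leading to {node.name or '<internal>'} has invalid length {node.length}"
                )
        self._leaf_names = leaves

    @property
    def leaf_names(self) -> list:
        return list(self._leaf_names)

    @property
    def n_branches(self) -> int:
        """Number of branches (non-root nodes), including leaf branches."""
        return sum(1 for _ in self.tree.postorder(include_self=False))

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(StringIO(newick)))

    def write(self, path) -> None:
        self.tree.write(str(path))


def read_tree(path) -> PhyloTree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return PhyloTree(TreeNode.read(str(path)))


# ---------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    """Symmetric n x n dissimilarity matrix with a zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if vals.shape != (n, n):
            raise ValidationError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        if np.isnan(vals).any():
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(vals, vals.T, atol=1e-8):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-8):
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = vals

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValidationError("distance matrix row and column ids differ")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))
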