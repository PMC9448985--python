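"""Binary association layers of the tripartite lncRNA-miRNA-disease network.

The pipeline consumes three binary adjacency matrices: lncRNA x disease
(LD), miRNA x disease (MD) and lncRNA x miRNA (LM).  Rows and columns are
identified by named entity registries; matrices are stored dense because
the networks involved are small (hundreds of entities per side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

EntityKind = Literal["lncRNA", "miRNA", "disease"]
ENTITY_KINDS: tuple[str, ...] = ("lncRNA", "miRNA", "disease")

Format = Literal["dense-labeled", "edge-list"]


class NetworkDataError(ValueError):
    """Raised for malformed or inconsistent association data."""


@dataclass(frozen=True)
class EntityRegistry:
    """An ordered, unique set of entity names of one kind.

    The registry fixes the mapping between external identifiers (names)
    and internal 0-based matrix indices.
    """

    kind: str
    names: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise NetworkDataError(
                f"unknown entity kind {self.kind!r}; expected one of {ENTITY_KINDS}"
            )
        names = tuple(str(n) for n in self.names)
        if any(n == "" for n in names):
            raise NetworkDataError("entity names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NetworkDataError(f"duplicate entity names: {dupes[:5]}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def position(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise NetworkDataError(f"unknown {self.kind} name {name!r}") from None


@dataclass(frozen=True)
class BipartiteAdjacency:
    """A labeled binary matrix for one association layer (LD, MD or LM)."""

    row_registry: EntityRegistry
    col_registry: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise NetworkDataError("adjacency values must be a 2-d matrix")
        if values.shape != (len(self.row_registry), len(self.col_registry)):
            raise NetworkDataError(
                f"shape {values.shape} does not match registries "
                f"({len(self.row_registry)} x {len(self.col_registry)})"
            )
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise NetworkDataError(
                f"non-binary value {values[i, j]!r} at row "
                f"{self.row_registry.names[i]!r}, column {self.col_registry.names[j]!r}"
            )
        object.__setattr__(self, "values", values.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.row_registry.names),
            columns=list(self.col_registry.names),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteAdjacency):
            return NotImplemented
        return (
            self.row_registry == other.row_registry
            and self.col_registry == other.col_registry
            and np.array_equal(self.values, other.values)
        )


def _detect_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head else ","


def read_adjacency(
    path: str | Path,
    format: Format = "dense-labeled",
    row_kind: str = "lncRNA",
    col_kind: str = "disease",
    row_registry: EntityRegistry | None = None,
    col_registry: EntityRegistry | None = None,
    header: bool = True,
) -> BipartiteAdjacency:
    """Read one association layer from a dense labeled matrix or edge list.

    Dense files carry a header row of column names and a first column of
    row names.  Edge lists carry (row_name, col_name[, value]) rows;
    entities are registered in first-appearance order unless explicit
    registries are given, and duplicate edges collapse to a single 1.
    """
    path = Path(path)
    if not path.exists():
        raise NetworkDataError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise NetworkDataError(f"empty file: {path}")
    sep = _detect_sep(path)
    if format == "dense-labeled":
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.empty:
            raise NetworkDataError(f"no data rows in {path}")
        rows = EntityRegistry(row_kind, tuple(str(n) for n in df.index))
        cols = EntityRegistry(col_kind, tuple(str(n) for n in df.columns))
        return BipartiteAdjacency(rows, cols, df.to_numpy())
    if format == "edge-list":
        df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str)
        if df.shape[1] not in (2, 3):
            raise NetworkDataError(
                f"edge list must have 2 or 3 columns, got {df.shape[1]}"
            )
        if df.empty and (row_registry is None or col_registry is None):
            raise NetworkDataError(f"empty edge list {path} without explicit registries")
        rnames = df.iloc[:, 0].astype(str)
        cnames = df.iloc[:, 1].astype(str)
        if df.shape[1] == 3:
            vals = pd.to_numeric(df.iloc[:, 2])
            bad = ~vals.isin((0, 1))
            if bad.any():
                k = int(np.argmax(bad.to_numpy()))
                raise NetworkDataError(
                    f"non-binary value {vals.iloc[k]!r} for edge "
                    f"({rnames.iloc[k]!r}, {cnames.iloc[k]!r})"
                )
        else:
            vals = pd.Series(np.ones(len(df), dtype=int))
        rows = row_registry or EntityRegistry(row_kind, tuple(dict.fromkeys(rnames)))
        cols = col_registry or EntityRegistry(col_kind, tuple(dict.fromkeys(cnames)))
        mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for rn, cn, v in zip(rnames, cnames, vals):
            if v:
                mat[rows.position(rn), cols.position(cn)] = 1
        return BipartiteAdjacency(rows, cols, mat)
    raise NetworkDataError(f"unknown format {format!r}")


def write_adjacency(
    adj: BipartiteAdjacency,
    path: str | Path,
    format: Format = "dense-labeled",
) -> Path:
    """Write a layer to disk; round-trips bit-exactly through read_adjacency."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if format == "dense-labeled":
        adj.to_frame().to_csv(path, sep=sep)
    elif format == "edge-list":
        r, c = np.nonzero(adj.values)
        df = pd.DataFrame(
            {
                adj.row_registry.kind: [adj.row_registry.names[i] for i in r],
                adj.col_registry.kind: [adj.col_registry.names[j] for j in c],
                "value": np.ones(len(r), dtype=int),
            }
        )
        df.to_csv(path, sep=sep, index=False)
    else:
        raise NetworkDataError(f"unknown format {format!r}")
    return path


def _merge_registries(
    a: EntityRegistry, b: EntityRegistry, mode: Literal["union", "intersection"]
) -> EntityRegistry:
    if a.kind != b.kind:
        raise NetworkDataError(f"entity kind mismatch: {a.kind} vs {b.kind}")
    if mode == "union":
        names = tuple(dict.fromkeys(a.names + b.names))
    else:
        names = tuple(n for n in a.names if n in b)
    if not names:
        raise NetworkDataError(f"empty {a.kind} registry after {mode}")
    return EntityRegistry(a.kind, names)


def _reindex(
    adj: BipartiteAdjacency, rows: EntityRegistry, cols: EntityRegistry
) -> BipartiteAdjacency:
    mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
    rsel = [adj.row_registry.index.get(n) for n in rows.names]
    csel = [adj.col_registry.index.get(n) for n in cols.names]
    for i, ri in enumerate(rsel):
        if ri is None:
            continue
        for j, cj in enumerate(csel):
            if cj is not None:
                mat[i, j] = adj.values[ri, cj]
    return BipartiteAdjacency(rows, cols, mat)


def align_layers(
    ld: BipartiteAdjacency,
    md: BipartiteAdjacency,
    lm: BipartiteAdjacency,
    mode: Literal["union", "intersection"] = "union",
) -> tuple[BipartiteAdjacency, BipartiteAdjacency, BipartiteAdjacency]:
    """Re-index the three layers onto shared entity registries.

    After alignment LM @ MD is a defined product with LD's shape.  Union
    mode (default) pads missing entities with zero rows/columns;
    intersection keeps only entities present in both layers that mention
    the kind.
    """
    for adj, rk, ck in ((ld, "lncRNA", "disease"), (md, "miRNA", "disease"), (lm, "lncRNA", "miRNA")):
        if adj.row_registry.kind != rk or adj.col_registry.kind != ck:
            raise NetworkDataError(
                f"layer orientation mismatch: expected {rk} rows x {ck} columns, "
                f"got {adj.row_registry.kind} x {adj.col_registry.kind}"
            )
    lncs = _merge_registries(ld.row_registry, lm.row_registry, mode)
    diseases = _merge_registries(ld.col_registry, md.col_registry, mode)
    mirnas = _merge_registries(lm.col_registry, md.row_registry, mode)
    return (
        _reindex(ld, lncs, diseases),
        _reindex(md, mirnas, diseases),
        _reindex(lm, lncs, mirnas),
    )
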