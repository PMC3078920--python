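"""Readers, writers and identifier handling for the tool's external artifacts.

All on-disk formats are UTF-8 tab-separated text; lines starting with ``#``
are comments.  An expression matrix is stored genes-in-rows with a header
row of sample identifiers; pair-lists carry four columns
(gene1, gene2, relation, support); regulatory-network files carry three
(regulator, target, type).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RELATIONS = ("pp", "mm", "pm")
INTERACTION_TYPES = ("ac", "re", "du")


class FormatError(ValueError):
    """A file did not satisfy the documented dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Real-valued genes × samples table.

    Values are assumed already normalised/log-scaled upstream; the methods
    here only require that per-gene means and standard deviations are
    meaningful.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(self.sample_ids) < 2 or len(self.gene_ids) < 2:
            raise ValueError("need at least 2 genes and 2 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
        )


@dataclass(frozen=True, order=True)
class Edge:
    gene1: str
    gene2: str
    relation: str
    support: int = 0

    def key(self) -> tuple[str, str, str]:
        return (self.gene1, self.gene2, self.relation)

    def undirected_key(self) -> tuple[str, str, str]:
        a, b = sorted((self.gene1, self.gene2))
        return (a, b, self.relation)


def canonical_edge(gene1: str, gene2: str, relation: str, support: int = 0) -> Edge:
    """Canonical storage: pp/mm unordered (sorted names); pm directed, gene1 up."""
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    if gene1 == gene2:
        raise ValueError(f"self-pair {gene1!r} not allowed")
    if relation in ("pp", "mm") and gene2 < gene1:
        gene1, gene2 = gene2, gene1
    return Edge(gene1, gene2, relation, int(support))


@dataclass
class PairList:
    """Canonicalised edge list: the tool's universal network representation.

    pp/mm edges are unordered (stored with gene1 < gene2); pm edges are
    directed with gene1 the up-regulated gene.  Each (gene1, gene2, relation)
    key appears at most once; duplicates are merged keeping the largest
    support.
    """

    edges: list[Edge] = field(default_factory=list)

    @classmethod
    def build(cls, records: Iterable[tuple]) -> "PairList":
        best: dict[tuple, Edge] = {}
        for rec in records:
            e = rec if isinstance(rec, Edge) else canonical_edge(*rec)
            e = canonical_edge(e.gene1, e.gene2, e.relation, e.support)
            k = e.key()
            if k not in best or e.support > best[k].support:
                best[k] = e
        return cls(sorted(best.values()))

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def keys(self) -> set[tuple[str, str, str]]:
        return {e.key() for e in self.edges}

    def undirected_keys(self) -> set[tuple[str, str, str]]:
        return {e.undirected_key() for e in self.edges}

    def pair_keys(self) -> set[tuple[str, str]]:
        """Relation-blind directed pairs (pp/mm already canonical)."""
        return {(e.gene1, e.gene2) for e in self.edges}

    def unordered_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.gene1, e.gene2))) for e in self.edges}

    def relations(self) -> set[str]:
        return {e.relation for e in self.edges}

    def only(self, relation: str) -> "PairList":
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        return PairList([e for e in self.edges if e.relation == relation])

    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.gene1)
            out.add(e.gene2)
        return out


@dataclass
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = dict.fromkeys(self.genes)
        self.genes = tuple(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True, order=True)
class Interaction:
    regulator: str
    target: str
    type: str


@dataclass
class SignedRegulatoryNetwork:
    """Directed ac/re/du interactions plus the full gene universe.

    The universe includes background genes that take part in no interaction
    (conventionally prefixed ``bgr_``).
    """

    interactions: list[Interaction]
    gene_universe: list[str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        universe = set(self.gene_universe)
        for it in self.interactions:
            if it.type not in INTERACTION_TYPES:
                raise ValueError(f"unknown interaction type {it.type!r}")
            k = (it.regulator, it.target)
            if k in seen:
                raise ValueError(f"duplicate interaction {k}")
            seen.add(k)
            if it.regulator not in universe or it.target not in universe:
                raise ValueError(f"interaction {k} outside gene universe")

    def of_type(self, type_: str) -> list[Interaction]:
        return [it for it in self.interactions if it.type == type_]

    def defined_genes(self) -> set[str]:
        out: set[str] = set()
        for it in self.interactions:
            out.add(it.regulator)
            out.add(it.target)
        return out


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def _read_table_lines(path: str | os.PathLike) -> list[list[str]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append(line.rstrip("\n").split("\t"))
    return rows


def read_expression_matrix(
    path: str | os.PathLike, transpose: bool = False
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression table.

    With ``transpose=True`` the file is interpreted samples-in-rows and
    flipped on read.  Duplicate gene identifiers are retained — collapsing
    to symbols is a separate, pair-level step.
    """
    rows = _read_table_lines(path)
    if len(rows) < 3:
        raise FormatError(f"{path}: need a header and at least 2 data rows")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: malformed header (need id column + data)")
    col_ids = header[1:]
    row_ids: list[str] = []
    ncol = len(col_ids)
    data = np.empty((len(rows) - 1, ncol), dtype=float)
    for r, row in enumerate(rows[1:]):
        if len(row) != ncol + 1:
            raise FormatError(
                f"{path}: ragged row {r + 2} has {len(row)} fields, expected {ncol + 1}"
            )
        row_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            try:
                data[r, c] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {row[0]!r}, "
                    f"column {col_ids[c]!r}"
                ) from None
    if transpose:
        return ExpressionMatrix(col_ids, row_ids, data.T)
    return ExpressionMatrix(row_ids, col_ids, data)


def write_expression_matrix(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# pair-list and regnet I/O
# ---------------------------------------------------------------------------


def read_pairlist(path: str | os.PathLike) -> PairList:
    rows = _read_table_lines(path)
    records = []
    for i, row in enumerate(rows, start=1):
        if row[0] == "gene1":  # optional header
            continue
        if len(row) != 4:
            raise FormatError(f"{path}: line {i}: expected 4 fields, got {len(row)}")
        g1, g2, rel, sup = row
        if rel not in RELATIONS:
            raise FormatError(f"{path}: line {i}: unknown relation {rel!r}")
        try:
            support = int(sup)
        except ValueError:
            raise FormatError(f"{path}: line {i}: bad support {sup!r}") from None
        records.append((g1, g2, rel, support))
    return PairList.build(records)


def write_pairlist(pl: PairList, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\trelation\tsupport\n")
        for e in pl.edges:
            fh.write(f"{e.gene1}\t{e.gene2}\t{e.relation}\t{e.support}\n")


def read_regnet(path: str | os.PathLike) -> SignedRegulatoryNetwork:
    rows = _read_table_lines(path)
    interactions = []
    universe: dict[str, None] = {}
    for i, row in enumerate(rows, start=1):
        if row[0] == "regulator":
            continue
        if len(row) == 1:
            # bare gene name: declares a universe member with no interactions
            universe.setdefault(row[0])
            continue
        if len(row) != 3:
            raise FormatError(f"{path}: line {i}: expected 3 fields, got {len(row)}")
        reg, tgt, typ = row
        if typ not in INTERACTION_TYPES:
            raise FormatError(f"{path}: line {i}: unknown interaction type {typ!r}")
        interactions.append(Interaction(reg, tgt, typ))
        universe.setdefault(reg)
        universe.setdefault(tgt)
    return SignedRegulatoryNetwork(interactions, list(universe))


def write_regnet(net: SignedRegulatoryNetwork, path: str | os.PathLike) -> None:
    lonely = set(net.gene_universe) - net.defined_genes()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\ttype\n")
        for it in net.interactions:
            fh.write(f"{it.regulator}\t{it.target}\t{it.type}\n")
        for g in net.gene_universe:
            if g in lonely:
                fh.write(f"{g}\n")


def read_gene_set(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    """One gene per line (first tab-field used)."""
    rows = _read_table_lines(path)
    genes = [r[0] for r in rows]
    return GeneSet(name or os.path.basename(os.fspath(path)), tuple(genes))


def read_mapping(path: str | os.PathLike) -> dict[str, str]:
    """Two-column probe → symbol table."""
    rows = _read_table_lines(path)
    mapping = {}
    for i, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise FormatError(f"{path}: line {i}: expected 2 fields")
        mapping[row[0]] = row[1]
    return mapping


# ---------------------------------------------------------------------------
# identifier collapsing and pair-list construction
# ---------------------------------------------------------------------------


def collapse_to_genes(obj, mapping: Mapping[str, str]):
    """Map probe-level identifiers to gene symbols.

    For a :class:`PairList`, edges are re-keyed to symbols and the resulting
    redundancy (several probes for one gene) removed, keeping the largest
    support per symbol pair; pm direction is preserved.  For an
    :class:`ExpressionMatrix`, rows are renamed but *not* merged — networks
    are built at probe level and de-duplicated only at the pair stage, so
    unmapped rows are dropped and duplicate-symbol rows retained.
    """
    if not mapping:
        raise ValueError("empty identifier mapping")
    if isinstance(obj, PairList):
        records = []
        for e in obj.edges:
            if e.gene1 not in mapping or e.gene2 not in mapping:
                continue
            s1, s2 = mapping[e.gene1], mapping[e.gene2]
            if s1 == s2:
                continue
            records.append((s1, s2, e.relation, e.support))
        return PairList.build(records)
    if isinstance(obj, ExpressionMatrix):
        keep = [i for i, g in enumerate(obj.gene_ids) if g in mapping]
        if len(keep) < 2:
            raise ValueError("mapping covers fewer than 2 rows")
        return ExpressionMatrix(
            [mapping[obj.gene_ids[i]] for i in keep],
            list(obj.sample_ids),
            obj.values[keep],
        )
    raise TypeError(f"cannot collapse object of type {type(obj).__name__}")


def build_pairlist_from_sets(up: GeneSet, down: GeneSet) -> PairList:
    """All up × down combinations as directed pm-convention pairs.

    This is the construction used to turn two signed gene lists (e.g. genes
    up in one population and down in another) into a query pair-list:
    column 1 genes are expected up when column 2 genes are down.
    """
    records = [
        (a, b, "pm", 0) for a in up.genes for b in down.genes if a != b
    ]
    return PairList.build(records)
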