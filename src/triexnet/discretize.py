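"""Ternary coding of expression values.

Each gene is compared to its own mean across samples: values more than
``z_cutoff`` sample standard deviations above the mean are coded +1 (up),
more than ``z_cutoff`` below are coded −1 (down), everything else 0
(around the mean).  The discretized table is not just an intermediate —
it is kept inspectable so that, for any detected clique, the samples
driving it can be read off directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix, FormatError, GeneSet, _read_table_lines

DEFAULT_Z = 0.4  # lowest cutoff used operationally: observable changes only


@dataclass
class DiscretizedMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray  # int8, entries in {-1, 0, +1}
    z_cutoff: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("codes shape does not match identifiers")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("codes must be -1, 0 or +1")
        if self.z_cutoff <= 0:
            raise ValueError("z_cutoff must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class IndicatorPair:
    """Binary matrices P (codes == +1) and M (codes == −1), "all positive forms"."""

    P: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.uint8)
        self.M = np.asarray(self.M, dtype=np.uint8)
        if self.P.shape != self.M.shape:
            raise ValueError("P and M must share a shape")
        if np.any(self.P * self.M):
            raise ValueError("P and M must be disjoint")


def discretize_matrix(
    m: ExpressionMatrix, z_cutoff: float = DEFAULT_Z, ddof: int = 1
) -> DiscretizedMatrix:
    """Ternary-code each gene by its per-gene z-score.

    ``ddof=1`` (sample standard deviation) is the default; genes with zero
    variance — e.g. flat background genes — code to all zeros rather than
    erroring.
    """
    if z_cutoff <= 0:
        raise ValueError(f"z_cutoff must be positive, got {z_cutoff}")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=ddof, keepdims=True)
    # a constant row can still get a tiny nonzero sd from float rounding of
    # the mean, which would blow up into spurious ±1 codes; detect exactly
    constant = m.values.max(axis=1) == m.values.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m.values - mu) / sd
    z[~np.isfinite(z)] = 0.0
    z[constant] = 0.0
    codes = np.zeros(m.values.shape, dtype=np.int8)
    codes[z > z_cutoff] = 1
    codes[z < -z_cutoff] = -1
    return DiscretizedMatrix(list(m.gene_ids), list(m.sample_ids), codes, z_cutoff)


def split_indicators(d: DiscretizedMatrix) -> IndicatorPair:
    return IndicatorPair((d.codes == 1).astype(np.uint8), (d.codes == -1).astype(np.uint8))


def shuffle_rows(d: DiscretizedMatrix, seed: int) -> DiscretizedMatrix:
    """Independently permute each gene's codes across samples.

    Preserves every row's −1/0/+1 histogram exactly, destroying all
    between-gene structure — the randomisation used to judge how large a
    network chance alone would build.
    """
    rng = np.random.default_rng(seed)
    shuffled = d.codes.copy()
    rng.permuted(shuffled, axis=1, out=shuffled)
    return DiscretizedMatrix(list(d.gene_ids), list(d.sample_ids), shuffled, d.z_cutoff)


def clique_sample_scores(d: DiscretizedMatrix, genes: GeneSet) -> np.ndarray:
    """Per-sample sum of codes over a gene clique.

    Samples where a co-regulated module is switched on score near +|genes|,
    switched off near −|genes|; this is the stratification score used to
    rank samples by module state.
    """
    index = {g: i for i, g in enumerate(d.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    rows = [index[g] for g in genes]
    return d.codes[rows].sum(axis=0, dtype=np.int64)


# --- discretized-table I/O (same layout as expression TSV, integer cells) ---


def write_discretized(d: DiscretizedMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# z_cutoff={d.z_cutoff}\n")
        fh.write("gene\t" + "\t".join(d.sample_ids) + "\n")
        for g, row in zip(d.gene_ids, d.codes):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_discretized(path: str | os.PathLike, z_cutoff: float | None = None) -> DiscretizedMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# z_cutoff="):
                z_cutoff = float(line.split("=", 1)[1])
            break
    if z_cutoff is None:
        raise FormatError(f"{path}: no z_cutoff header and none supplied")
    rows = _read_table_lines(path)
    header, body = rows[0], rows[1:]
    codes = np.array([[int(v) for v in r[1:]] for r in body], dtype=np.int8)
    return DiscretizedMatrix([r[0] for r in body], header[1:], codes, z_cutoff)
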