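"""Co-occurrence counting and density-conditional null thresholds.

The inner products P·P', M·M' and P·M' count, for every gene pair, the
samples in which both genes are up, both down, or gene1 up with gene2 down.
A pair is accepted when its count exceeds what permutation of two binary
vectors with the same 1-densities would produce at a stated quantile
(default 0.995, i.e. P ≈ 0.005).  Because permuting fixed-density vectors
makes the overlap hypergeometric, thresholds depend only on
(density1, density2, n_samples) and are cached per triple; an exact
hypergeometric mode provides the reference answer and a Monte-Carlo mode
reproduces the sampling procedure itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .core_io import PairList
from .discretize import DiscretizedMatrix, IndicatorPair, split_indicators

DEFAULT_QUANTILE = 0.995
DEFAULT_REPS = 1000


@dataclass
class CooccurrenceCounts:
    """pp/mm stored symmetric (read upper-triangular), pm full asymmetric."""

    gene_ids: list[str]
    pp: np.ndarray
    mm: np.ndarray
    pm: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("pp", "mm", "pm"):
            a = getattr(self, name)
            if a.shape != (n, n):
                raise ValueError(f"{name} matrix must be {n}x{n}")


def count_cooccurrence(
    ind: IndicatorPair, gene_ids: list[str] | None = None
) -> CooccurrenceCounts:
    """Inner-product co-occurrence counts.

    The diagonals of pp/mm are zeroed (self-pairs are meaningless); the pm
    diagonal is structurally zero because a gene cannot be up and down in
    the same sample.
    """
    P = ind.P.astype(np.int64)
    M = ind.M.astype(np.int64)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(P.shape[0])]
    pp = P @ P.T
    mm = M @ M.T
    pm = P @ M.T
    np.fill_diagonal(pp, 0)
    np.fill_diagonal(mm, 0)
    return CooccurrenceCounts(list(gene_ids), pp, mm, pm, P.shape[1])


@dataclass
class NullThresholdTable:
    """Acceptance thresholds for overlap counts, conditional on densities.

    ``threshold(d1, d2)`` is the stated quantile of the null overlap of two
    random binary vectors with d1 and d2 ones in n positions; an observed
    count must *strictly exceed* it to be accepted.  ``exact_hypergeometric``
    computes the discrete quantile from the hypergeometric CDF;
    ``monte_carlo`` draws ``reps`` permutation overlaps and takes the
    linear-interpolation quantile (an observed count is accepted when it
    exceeds that value, i.e. the integer threshold is its floor).
    """

    n_samples: int
    quantile: float = DEFAULT_QUANTILE
    reps: int = DEFAULT_REPS
    mode: str = "exact_hypergeometric"
    seed: int = 0
    thresholds: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0,1)")
        if self.mode not in ("exact_hypergeometric", "monte_carlo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)

    def threshold(self, d1: int, d2: int) -> int:
        if d1 > self.n_samples or d2 > self.n_samples or d1 < 0 or d2 < 0:
            raise ValueError(f"density outside [0, {self.n_samples}]: {(d1, d2)}")
        key = (min(d1, d2), max(d1, d2))
        if key not in self.thresholds:
            self.thresholds[key] = self._compute(*key)
        return self.thresholds[key]

    def _compute(self, d1: int, d2: int) -> int:
        if d1 == 0 or d2 == 0:
            return 0
        n = self.n_samples
        if self.mode == "exact_hypergeometric":
            ks = np.arange(0, min(d1, d2) + 1)
            cdf = hypergeom.cdf(ks, n, d1, d2)
            idx = int(np.searchsorted(cdf, self.quantile - 1e-12))
            return int(ks[min(idx, len(ks) - 1)])
        draws = self._rng.hypergeometric(d1, n - d1, d2, self.reps)
        return int(np.floor(np.quantile(draws, self.quantile)))

    def precompute(self, pairs) -> None:
        for d1, d2 in pairs:
            self.threshold(d1, d2)


def simulate_overlap_by_permutation(
    d1: int, d2: int, n: int, reps: int, seed: int
) -> np.ndarray:
    """Literal permutation null: shuffle two fixed-density binary vectors
    and count joint 1s.  Kept as the slow reference for the hypergeometric
    shortcut used by :class:`NullThresholdTable`."""
    rng = np.random.default_rng(seed)
    v1 = np.zeros(n, dtype=np.int8)
    v1[:d1] = 1
    v2 = np.zeros(n, dtype=np.int8)
    v2[:d2] = 1
    out = np.empty(reps, dtype=np.int64)
    for i in range(reps):
        out[i] = int(np.sum(rng.permutation(v1) * rng.permutation(v2)))
    return out


def _threshold_matrix(
    table: NullThresholdTable, dens_a: np.ndarray, dens_b: np.ndarray
) -> np.ndarray:
    uniq = {(int(a), int(b)) for a in np.unique(dens_a) for b in np.unique(dens_b)}
    lut = {k: table.threshold(*k) for k in uniq}
    out = np.empty((dens_a.size, dens_b.size), dtype=np.int64)
    for i, a in enumerate(dens_a):
        for j, b in enumerate(dens_b):
            out[i, j] = lut[(int(a), int(b))]
    return out


def extract_networks(
    counts: CooccurrenceCounts,
    d: DiscretizedMatrix,
    table: NullThresholdTable,
) -> dict[str, PairList]:
    """Keep gene pairs whose counts exceed their density-conditional threshold.

    Densities are sign-specific: a pp comparison conditions on each gene's
    +1 count, mm on the −1 counts, and pm on gene1's +1 count and gene2's
    −1 count.  Support is the observed co-occurrence count.
    """
    if table.n_samples != counts.n_samples:
        raise ValueError("threshold table built for a different sample count")
    genes = counts.gene_ids
    p_dens = (d.codes == 1).sum(axis=1)
    m_dens = (d.codes == -1).sum(axis=1)

    out: dict[str, PairList] = {}
    specs = (
        ("pp", counts.pp, p_dens, p_dens, False),
        ("mm", counts.mm, m_dens, m_dens, False),
        ("pm", counts.pm, p_dens, m_dens, True),
    )
    for rel, mat, da, db, directed in specs:
        thr = _threshold_matrix(table, da, db)
        keep = mat > thr
        if not directed:
            keep = np.triu(keep, k=1)
        else:
            np.fill_diagonal(keep, False)
        ii, jj = np.nonzero(keep)
        out[rel] = PairList.build(
            (genes[i], genes[j], rel, int(mat[i, j])) for i, j in zip(ii, jj)
        )
    return out


@dataclass
class NetworkSet:
    """Result of one discretize → count → threshold pass."""

    pp: PairList
    mm: PairList
    pm: PairList
    discretized: DiscretizedMatrix

    def __getitem__(self, rel: str) -> PairList:
        return {"pp": self.pp, "mm": self.mm, "pm": self.pm}[rel]

    def sizes(self) -> dict[str, int]:
        return {"pp": len(self.pp), "mm": len(self.mm), "pm": len(self.pm)}

    def total_size(self) -> int:
        return len(self.pp) + len(self.mm) + len(self.pm)


def build_networks_from_codes(
    d: DiscretizedMatrix,
    quantile: float = DEFAULT_QUANTILE,
    reps: int = DEFAULT_REPS,
    mode: str = "exact_hypergeometric",
    seed: int = 0,
    table: NullThresholdTable | None = None,
) -> NetworkSet:
    if table is None:
        table = NullThresholdTable(
            n_samples=d.n_samples, quantile=quantile, reps=reps, mode=mode, seed=seed
        )
    counts = count_cooccurrence(split_indicators(d), d.gene_ids)
    nets = extract_networks(counts, d, table)
    return NetworkSet(nets["pp"], nets["mm"], nets["pm"], d)


def build_networks(
    m,
    z_cutoff: float = 0.4,
    quantile: float = DEFAULT_QUANTILE,
    reps: int = DEFAULT_REPS,
    mode: str = "exact_hypergeometric",
    seed: int = 0,
    table: NullThresholdTable | None = None,
) -> NetworkSet:
    """Full pipeline: discretize an ExpressionMatrix, count, threshold."""
    from .discretize import discretize_matrix

    d = discretize_matrix(m, z_cutoff)
    return build_networks_from_codes(
        d, quantile=quantile, reps=reps, mode=mode, seed=seed, table=table
    )
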