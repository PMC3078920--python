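"""Network comparison, randomization significance and spectral reordering.

These are the interrogation tools applied after network construction:
edge-set intersections between runs/relations, reciprocity (pairs both
up-together and down-together, or up-down in both senses), a t-test on
network size against row-shuffled nulls, and leading-eigenvector
reordering to surface dense sub-graphs (cliques).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import GeneSet, PairList
from .cooccurrence import NullThresholdTable, build_networks_from_codes
from .discretize import DiscretizedMatrix, shuffle_rows


@dataclass
class ComparisonReport:
    size_a: int
    size_b: int
    shared: int
    jaccard: float
    # for comparisons involving pm: the direction-blind shared count
    shared_ignoring_direction: int | None = None


def _comparable_keys(pl: PairList, cross_class: bool, ignore_pm_direction: bool):
    if cross_class or ignore_pm_direction:
        return pl.unordered_pairs()
    # same-relation comparison: pp/mm already canonical; pm keeps direction
    return pl.pair_keys()


def intersect_pairlists(
    a: PairList, b: PairList, ignore_pm_direction: bool = False
) -> tuple[PairList, ComparisonReport]:
    """Shared edges between two pair-lists.

    Same-relation comparisons respect pm direction unless
    ``ignore_pm_direction``; cross-class comparisons (e.g. pp vs pm) are
    necessarily direction- and relation-blind, on unordered gene pairs.
    The returned PairList takes edges (and supports) from ``a``.
    """
    rels_a, rels_b = a.relations(), b.relations()
    cross = bool(rels_a and rels_b and rels_a != rels_b)
    keys_a = _comparable_keys(a, cross, ignore_pm_direction)
    keys_b = _comparable_keys(b, cross, ignore_pm_direction)
    shared_keys = keys_a & keys_b
    if cross or ignore_pm_direction:
        kept = [e for e in a.edges if tuple(sorted((e.gene1, e.gene2))) in shared_keys]
    else:
        kept = [e for e in a.edges if (e.gene1, e.gene2) in shared_keys]
    blind = len(a.unordered_pairs() & b.unordered_pairs())
    report = ComparisonReport(
        size_a=len(keys_a),
        size_b=len(keys_b),
        shared=len(shared_keys),
        jaccard=(len(shared_keys) / len(keys_a | keys_b)) if (keys_a or keys_b) else 0.0,
        shared_ignoring_direction=blind if ("pm" in rels_a | rels_b) else None,
    )
    return PairList(kept), report


def reciprocal_pairs(x: PairList, y: PairList) -> PairList:
    """Pairs showing symmetric behaviour.

    mm:pp — unordered pairs present in both networks (genes down-together
    that are also up-together).  pm:pm — pairs present in both up-down
    senses (A→B and B→A); returned once with gene1 < gene2.
    """
    rx, ry = x.relations(), y.relations()
    if rx <= {"mm", "pp"} and ry <= {"mm", "pp"} and rx and ry and rx != ry:
        shared = x.unordered_pairs() & y.unordered_pairs()
        return PairList([e for e in x.edges if (e.gene1, e.gene2) in shared])
    if rx <= {"pm"} and ry <= {"pm"} and rx and ry:
        fwd = x.pair_keys()
        rev = {(b, a) for a, b in y.pair_keys()}
        both = fwd & rev
        return PairList(
            [e for e in x.edges if (e.gene1, e.gene2) in both and e.gene1 < e.gene2]
        )
    raise ValueError(
        "reciprocal_pairs expects (mm, pp) in either order, or two pm lists"
    )


@dataclass
class SizeSignificance:
    observed_size: int
    null_sizes: list[int]
    t_statistic: float
    p_value: float
    n_randomizations: int
    degenerate: bool = False


def network_size_significance(
    d: DiscretizedMatrix,
    n_rand: int = 100,
    seed: int = 0,
    quantile: float = 0.995,
    reps: int = 1000,
    mode: str = "exact_hypergeometric",
) -> SizeSignificance:
    """One-sample t-test of null (row-shuffled) network sizes against the
    observed size.

    Shuffling preserves every row's code histogram, so one threshold table
    serves all randomizations.  The t statistic is oriented null-minus-
    observed: a real network far larger than chance gives a large-magnitude
    negative t and a one-sided p near zero.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    table = NullThresholdTable(
        n_samples=d.n_samples, quantile=quantile, reps=reps, mode=mode, seed=seed
    )
    observed = build_networks_from_codes(d, table=table).total_size()
    null_sizes = []
    for i in range(n_rand):
        shuffled = shuffle_rows(d, seed=seed + 1 + i)
        null_sizes.append(build_networks_from_codes(shuffled, table=table).total_size())
    null = np.asarray(null_sizes, dtype=float)
    sd = null.std(ddof=1)
    if observed == 0 and not null.any():
        return SizeSignificance(0, null_sizes, float("nan"), 1.0, n_rand, degenerate=True)
    if sd == 0:
        # all nulls identical: report exact count comparison instead of t
        p = 1.0 if null[0] >= observed else 0.0
        return SizeSignificance(
            observed, null_sizes, float("nan"), p, n_rand, degenerate=True
        )
    t = (null.mean() - observed) / (sd / np.sqrt(n_rand))
    p = float(stats.t.cdf(t, n_rand - 1))
    return SizeSignificance(observed, null_sizes, float(t), p, n_rand)


@dataclass
class SpectralOrdering:
    ordering: list[str]  # genes sorted by leading-eigenvector component
    components: dict[str, float]
    ranks: dict[str, int]  # gene -> position in ordering (0-based)


def spectral_reorder(
    pl: PairList, genes: GeneSet | None = None, weighted: bool = False
) -> SpectralOrdering:
    """Order genes by the leading eigenvector of the (symmetrized) adjacency.

    Dense sub-graphs concentrate the leading eigenvector's mass, so sorting
    nodes by component value places cliques contiguously.  The eigenvector
    sign is fixed by making its largest-magnitude component positive; ties
    break by gene name.  pm input is symmetrized with a warning.
    """
    names = list(genes.genes) if genes is not None else sorted(pl.genes())
    name_set = set(names)
    index = {g: i for i, g in enumerate(names)}
    if not names:
        raise ValueError("empty gene set")
    if "pm" in pl.relations():
        warnings.warn("pm adjacency symmetrized for spectral reordering")
    A = np.zeros((len(names), len(names)))
    n_edges = 0
    for e in pl.edges:
        if e.gene1 in name_set and e.gene2 in name_set:
            w = float(e.support) if weighted else 1.0
            i, j = index[e.gene1], index[e.gene2]
            A[i, j] = max(A[i, j], w)
            A[j, i] = max(A[j, i], w)
            n_edges += 1
    if n_edges == 0:
        raise ValueError("no edges among the requested genes")
    vals, vecs = np.linalg.eigh(A)
    v = vecs[:, -1]  # eigenvector of the largest eigenvalue
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    order = sorted(range(len(names)), key=lambda i: (-v[i], names[i]))
    ordering = [names[i] for i in order]
    return SpectralOrdering(
        ordering=ordering,
        components={names[i]: float(v[i]) for i in range(len(names))},
        ranks={g: r for r, g in enumerate(ordering)},
    )
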