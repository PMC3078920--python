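"""Validation of inferred networks against a known signed regulatory network.

A ground-truth network of ac (activation, +1), re (repression, −1) and du
(dual-action, ignored as 0) interactions predicts which gene pairs should
co-express: two targets reached from a common effector through same-sign
paths are expected positive (pp/mm), through opposite-sign paths expected
negative (pm).  Most expected pairs are transitive — induced by shared
regulators at path lengths 2 and 3 — so scoring an inferred network only
against direct definitions badly understates its specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    ExpressionMatrix,
    GeneSet,
    PairList,
    SignedRegulatoryNetwork,
)

Pair = tuple[str, str]


@dataclass
class SignedAdjacency:
    gene_ids: list[str]
    A: np.ndarray  # A[reg, target] in {-1, 0, +1}; du contributes 0

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.A.shape != (n, n):
            raise ValueError("adjacency must be square over gene_ids")
        if not np.isin(self.A, (-1, 0, 1)).all():
            raise ValueError("entries must be -1/0/+1")


def signed_adjacency(net: SignedRegulatoryNetwork) -> SignedAdjacency:
    genes = list(net.gene_universe)
    index = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for it in net.interactions:
        if it.type == "ac":
            A[index[it.regulator], index[it.target]] = 1
        elif it.type == "re":
            A[index[it.regulator], index[it.target]] = -1
        # du -> 0, deliberately ignored
    return SignedAdjacency(genes, A)


@dataclass
class PredictionSet:
    """Expected co-expression pairs per path depth.

    ``positive[k]`` / ``negative[k]`` are the unordered pairs first
    predictable using paths of length ≤ k (depth-1 entries are the direct
    ac/re definitions themselves).  Pairs receiving both positive and
    negative evidence are quarantined in ``ambiguous[k]`` rather than
    silently signed — the sign-cancellation caveat of reading A² alone.
    ``walk_positive[k]`` / ``walk_negative[k]`` expose the complementary
    matrix-power view: effector→target pairs whose length-k walk counts are
    purely positive or purely negative.
    """

    max_k: int
    positive: dict[int, set[Pair]] = field(default_factory=dict)
    negative: dict[int, set[Pair]] = field(default_factory=dict)
    ambiguous: dict[int, set[Pair]] = field(default_factory=dict)
    walk_positive: dict[int, set[Pair]] = field(default_factory=dict)
    walk_negative: dict[int, set[Pair]] = field(default_factory=dict)
    walk_cancelled: dict[int, set[Pair]] = field(default_factory=dict)

    def positive_at(self, k: int) -> set[Pair]:
        return self.positive.get(k, set())

    def negative_at(self, k: int) -> set[Pair]:
        return self.negative.get(k, set())

    def all_positive(self) -> set[Pair]:
        return set().union(*self.positive.values()) if self.positive else set()

    def all_negative(self) -> set[Pair]:
        return set().union(*self.negative.values()) if self.negative else set()

    def all_ambiguous(self) -> set[Pair]:
        return set().union(*self.ambiguous.values()) if self.ambiguous else set()


def _sorted_pair(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


def transitive_predictions(adj: SignedAdjacency, max_k: int = 2) -> PredictionSet:
    """Predict co-expressing pairs from shared-effector sign structure.

    Splitting A into its positive and negative parts, walk counts with an
    even/odd number of repressive steps are propagated separately, so sign
    cancellation inside A^k is visible instead of silent.  At depth k a
    target pair (t1, t2) is expected positive when some effector reaches
    both through paths (lengths ≤ k) whose sign products agree, negative
    when they disagree; direct ac/re edges are the depth-1 pairs.
    """
    if max_k not in (1, 2, 3):
        raise ValueError("max_k must be 1, 2 or 3")
    Ap = (adj.A == 1).astype(np.int64)
    An = (adj.A == -1).astype(np.int64)
    genes = adj.gene_ids
    n = len(genes)

    # walk counts by parity of repressive steps, per exact length
    Pk, Nk = Ap.copy(), An.copy()
    pos_walks = {1: Pk}
    neg_walks = {1: Nk}
    for k in range(2, max_k + 1):
        Pk, Nk = pos_walks[k - 1] @ Ap + neg_walks[k - 1] @ An, (
            pos_walks[k - 1] @ An + neg_walks[k - 1] @ Ap
        )
        pos_walks[k] = Pk
        neg_walks[k] = Nk

    preds = PredictionSet(max_k=max_k)

    # matrix-power (effector -> target) view
    for k in range(1, max_k + 1):
        wp, wn, wc = set(), set(), set()
        P, N = pos_walks[k], neg_walks[k]
        for i, j in zip(*np.nonzero(P + N)):
            if i == j:
                continue
            pair = (genes[i], genes[j])
            if P[i, j] and N[i, j]:
                wc.add(pair)
            elif P[i, j]:
                wp.add(pair)
            else:
                wn.add(pair)
        preds.walk_positive[k] = wp
        preds.walk_negative[k] = wn
        preds.walk_cancelled[k] = wc

    # direct definitions carry their own sign evidence at every depth
    direct_pos, direct_neg = set(), set()
    for i, j in zip(*np.nonzero(adj.A)):
        pair = _sorted_pair(genes[i], genes[j])
        (direct_pos if adj.A[i, j] > 0 else direct_neg).add(pair)

    # shared-effector (target -> target) view, cumulative over path lengths <= k
    Rp = np.zeros((n, n), dtype=bool)  # effector reaches target with + product
    Rn = np.zeros((n, n), dtype=bool)
    for k in range(1, max_k + 1):
        Rp |= pos_walks[k] > 0
        Rn |= neg_walks[k] > 0
        pos_ev = (Rp.T.astype(np.int64) @ Rp.astype(np.int64)) + (
            Rn.T.astype(np.int64) @ Rn.astype(np.int64)
        )
        neg_ev = (Rp.T.astype(np.int64) @ Rn.astype(np.int64)) + (
            Rn.T.astype(np.int64) @ Rp.astype(np.int64)
        )
        ev_pos, ev_neg = set(direct_pos), set(direct_neg)
        ii, jj = np.nonzero(np.triu(pos_ev + neg_ev, k=1))
        for i, j in zip(ii, jj):
            pair = _sorted_pair(genes[i], genes[j])
            if pos_ev[i, j]:
                ev_pos.add(pair)
            if neg_ev[i, j]:
                ev_neg.add(pair)
        preds.positive[k] = ev_pos - ev_neg
        preds.negative[k] = ev_neg - ev_pos
        preds.ambiguous[k] = ev_pos & ev_neg
    return preds


@dataclass
class ValidationReport:
    """Per-relation scoring of inferred networks against the definitions."""

    per_network: dict[str, dict]
    definition_totals: dict[str, int]

    def recovery(self, relation: str, type_: str) -> float:
        total = self.definition_totals.get(type_, 0)
        if total == 0:
            return float("nan")
        return self.per_network[relation]["direct"][type_] / total


def score_against_definitions(
    networks: dict[str, PairList],
    net: SignedRegulatoryNetwork,
    preds: PredictionSet,
) -> ValidationReport:
    """Count, per inferred network, edges explained by direct definitions,
    by transitive predictions, or by neither (candidate false positives).

    Matching is on unordered symbol pairs.  Every edge falls in exactly one
    of {direct, transitive, unexplained} (precedence in that order);
    background-gene pairs are additionally tallied.
    """
    def_pairs: dict[str, set[Pair]] = {"ac": set(), "du": set(), "re": set()}
    for it in net.interactions:
        def_pairs[it.type].add(_sorted_pair(it.regulator, it.target))
    defined = net.defined_genes()
    trans_pos = {
        p for k, s in preds.positive.items() if k >= 2 for p in s
    }
    trans_neg = {
        p for k, s in preds.negative.items() if k >= 2 for p in s
    }
    trans_amb = {
        p for k, s in preds.ambiguous.items() if k >= 2 for p in s
    }
    trans_any = trans_pos | trans_neg | trans_amb

    per_network = {}
    for rel, pl in networks.items():
        pairs = pl.unordered_pairs()
        direct = {t: 0 for t in ("ac", "du", "re")}
        n_trans = n_trans_pos = n_trans_neg = n_unexplained = n_bgr = 0
        for pair in pairs:
            if not (pair[0] in defined and pair[1] in defined):
                n_bgr += 1
            hit = None
            for t in ("ac", "du", "re"):
                if pair in def_pairs[t]:
                    hit = t
                    break
            if hit is not None:
                direct[hit] += 1
                continue
            if pair in trans_any:
                n_trans += 1
                if pair in trans_pos:
                    n_trans_pos += 1
                if pair in trans_neg:
                    n_trans_neg += 1
            else:
                n_unexplained += 1
        per_network[rel] = {
            "size": len(pairs),
            "direct": direct,
            "transitive": n_trans,
            "transitive_positive": n_trans_pos,
            "transitive_negative": n_trans_neg,
            "unexplained": n_unexplained,
            "background_pairs": n_bgr,
        }
    totals = {t: len(def_pairs[t]) for t in def_pairs}
    return ValidationReport(per_network, totals)


def low_variance_genes(
    m: ExpressionMatrix, fraction_of_modal: float = 0.5
) -> GeneSet:
    """Genes whose variance is below a fraction of the modal variance.

    In simulated data, genes varying only by noise cluster at a common
    (modal) variance while defined genes spread higher; selecting below
    half the mode isolates the noise-only stratum.  The mode is the peak
    of the log-variance histogram (zero-variance genes are always
    selected and excluded from the mode estimate).
    """
    if fraction_of_modal <= 0:
        raise ValueError("fraction_of_modal must be positive")
    if m.n_genes < 10:
        raise ValueError("need at least 10 genes for a stable mode estimate")
    var = m.values.var(axis=1, ddof=1)
    pos = var[var > 0]
    if pos.size == 0:
        raise ValueError("all genes have zero variance")
    logv = np.log(pos)
    if np.ptp(logv) == 0:
        modal = float(pos[0])
    else:
        counts, edges = np.histogram(logv, bins="auto")
        b = int(np.argmax(counts))
        modal = float(np.exp(0.5 * (edges[b] + edges[b + 1])))
    cut = fraction_of_modal * modal
    selected = tuple(g for g, v in zip(m.gene_ids, var) if v < cut)
    if not selected:
        raise ValueError("no gene below the variance cutoff")
    return GeneSet("low_variance", selected)


def low_variance_gene_list(m: ExpressionMatrix, fraction_of_modal: float = 0.5) -> tuple[str, ...]:
    """Like :func:`low_variance_genes` but returns an (possibly empty) tuple."""
    try:
        return low_variance_genes(m, fraction_of_modal).genes
    except ValueError as err:
        if "no gene below" in str(err):
            return ()
        raise


def subset_consensus(
    expr: ExpressionMatrix,
    k_subsets: int = 2,
    seed: int = 0,
    z_cutoff: float = 0.4,
    quantile: float = 0.995,
    reps: int = 1000,
    mode: str = "exact_hypergeometric",
):
    """Randomly partition samples into equal subsets, run the full pipeline
    on each, and intersect the resulting networks.

    Edges surviving in every subset are the consensus; pairs driven by
    low-variance noise genes are preferentially discarded by this
    procedure while defined relationships survive.
    Returns ``(subset_networks, consensus)`` where consensus maps relation
    to the intersected :class:`PairList` (supports from the first subset).
    """
    from .cooccurrence import build_networks

    if k_subsets < 2:
        raise ValueError("k_subsets must be >= 2")
    if expr.n_samples < 2 * k_subsets:
        raise ValueError("too few samples to partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(expr.n_samples)
    size = expr.n_samples // k_subsets
    subsets = []
    for i in range(k_subsets):
        idx = np.sort(order[i * size : (i + 1) * size])
        sub = expr.subset_samples(idx)
        subsets.append(
            build_networks(
                sub, z_cutoff=z_cutoff, quantile=quantile, reps=reps,
                mode=mode, seed=seed + i,
            )
        )
    consensus: dict[str, PairList] = {}
    for rel in ("pp", "mm", "pm"):
        keys = subsets[0][rel].keys()
        for s in subsets[1:]:
            keys &= s[rel].keys()
        consensus[rel] = PairList(
            [e for e in subsets[0][rel].edges if e.key() in keys]
        )
    return subsets, consensus
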