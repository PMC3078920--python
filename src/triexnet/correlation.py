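"""Pearson correlation networks and the t-test significance transform.

Used both as a standalone network method and as a filter on the
discretization networks: pp/mm edges should also be positively correlated,
pm edges negatively, at a nominally matched probability cut-off
(P ≈ 0.005, i.e. |r| ≈ 0.1032 at N around a thousand observations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix, PairList


def r_to_p(r: float, n_obs: int) -> float:
    """Two-tailed p-value of a Pearson r via t = r·sqrt(N−2)/sqrt(1−r²),
    Student t with N−2 degrees of freedom."""
    if n_obs < 3:
        raise ValueError("need at least 3 observations")
    if not -1 < r < 1:
        raise ValueError("|r| must be < 1")
    t = r * np.sqrt(n_obs - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n_obs - 2))


def p_to_r(p: float, n_obs: int) -> float:
    """Positive r cutoff whose two-tailed p equals ``p``.

    Closed-form inverse of :func:`r_to_p`: t* = t-quantile(1 − p/2, N−2),
    r = t*/sqrt(N−2+t*²).
    """
    if n_obs < 3:
        raise ValueError("need at least 3 observations")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0,1]")
    t = stats.t.isf(p / 2.0, n_obs - 2)
    return float(t / np.sqrt(n_obs - 2 + t * t))


@dataclass
class CorrelationNetwork:
    gene_ids: list[str]
    r_cutoff: float
    n_obs: int
    positive: set[tuple[str, str]] = field(default_factory=set)  # sorted pairs
    negative: set[tuple[str, str]] = field(default_factory=set)
    r_values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative edge sets must be disjoint")

    def sizes(self) -> dict[str, int]:
        return {"positive": len(self.positive), "negative": len(self.negative)}


def correlation_network(
    m: ExpressionMatrix,
    r_cutoff: float | None = None,
    p_cutoff: float | None = None,
) -> CorrelationNetwork:
    """All-pairs Pearson network at a cutoff given as r or as a p-value.

    Constant genes have undefined r and are skipped (background genes at
    zero noise must pass through harmlessly); edges require r strictly
    beyond ±cutoff.
    """
    if (r_cutoff is None) == (p_cutoff is None):
        raise ValueError("give exactly one of r_cutoff / p_cutoff")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    if r_cutoff is None:
        r_cutoff = p_to_r(p_cutoff, m.n_samples)

    sd = m.values.std(axis=1)
    keep = sd > 0
    if not keep.any():
        warnings.warn("all genes constant: empty correlation network")
        return CorrelationNetwork(list(m.gene_ids), r_cutoff, m.n_samples)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    R = np.corrcoef(m.values[keep])
    net = CorrelationNetwork(list(m.gene_ids), r_cutoff, m.n_samples)
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        r = float(R[i, j])
        a, b = sorted((genes[i], genes[j]))
        if r > r_cutoff:
            net.positive.add((a, b))
            net.r_values[(a, b)] = r
        elif r < -r_cutoff:
            net.negative.add((a, b))
            net.r_values[(a, b)] = r
    return net


def correlation_filter(pl: PairList, cn: CorrelationNetwork) -> PairList:
    """Keep pp/mm edges backed by positive correlation and pm edges backed
    by negative correlation; supports pass through unchanged."""
    kept = []
    for e in pl.edges:
        pair = tuple(sorted((e.gene1, e.gene2)))
        if e.relation in ("pp", "mm"):
            if pair in cn.positive:
                kept.append(e)
        elif e.relation == "pm":
            if pair in cn.negative:
                kept.append(e)
        else:  # pragma: no cover - PairList already validates
            raise ValueError(f"cannot filter relation {e.relation!r}")
    return PairList(kept)
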