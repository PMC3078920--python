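"""Simulator for expression data driven by a known signed regulatory network.

Generates (i) an acyclic ac/re/du network over "defined" genes, with hub
regulators so that shared-effector transitive relations are well
represented, and (ii) microarray-like expression: regulatory signal
propagates linearly down the network with per-gene standardisation, and a
``bio_noise`` level b mixes each defined gene's signal with independent
Gaussian noise as (1−b)·signal + b·ε.  Background genes (prefixed
``bgr_``) are pure noise and take part in no interaction; unlike some
simulators, their noise streams are freshly drawn every run, so two runs
share no spurious background structure.

The same seed yields the same network, signal and noise draws at every
``bio_noise`` level — only the mixing weight changes — so noise sweeps are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, Interaction, SignedRegulatoryNetwork

# edge-type mix modelled on an E. coli-style transcriptional network:
# roughly two thirds activation, a quarter repression, few dual-action
DEFAULT_FRAC_RE = 0.275
DEFAULT_FRAC_DU = 0.075


@dataclass
class SimulationConfig:
    n_defined_genes: int = 100
    n_background: int = 100
    n_samples: int = 200
    bio_noise: float = 0.1
    frac_re: float = DEFAULT_FRAC_RE
    frac_du: float = DEFAULT_FRAC_DU
    root_fraction: float = 0.15  # fraction of defined genes with no parent
    in_degree_two_prob: float = 0.3  # remaining genes have 1 or 2 parents
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_defined_genes, self.n_samples) <= 0 or self.n_background < 0:
            raise ValueError("counts must be positive")
        if self.bio_noise < 0:
            raise ValueError("bio_noise must be >= 0")
        for f in (self.frac_re, self.frac_du, self.root_fraction,
                  self.in_degree_two_prob):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.frac_re + self.frac_du > 1:
            raise ValueError("frac_re + frac_du must not exceed 1")


@dataclass
class SimulatedStudy:
    expr: ExpressionMatrix
    truth: SignedRegulatoryNetwork
    config: SimulationConfig = field(repr=False, default=None)

    def background_genes(self) -> list[str]:
        return [g for g in self.expr.gene_ids if g.startswith("bgr_")]


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    width = max(3, len(str(cfg.n_defined_genes)))
    defined = [f"G{i + 1:0{width}d}" for i in range(cfg.n_defined_genes)]
    bwidth = max(3, len(str(max(cfg.n_background, 1))))
    background = [f"bgr_{i + 1:0{bwidth}d}" for i in range(cfg.n_background)]
    return defined, background


def generate_regnet(cfg: SimulationConfig) -> SignedRegulatoryNetwork:
    """Random acyclic signed network with preferential attachment.

    Genes are ordered; every non-root gene receives 1–2 parents among
    earlier genes, chosen with probability proportional to current
    out-degree + 1, which concentrates targets on hub regulators and
    guarantees plentiful shared-effector motifs.  Edge types are drawn
    independently at the configured re/du fractions.
    """
    rng = np.random.default_rng([cfg.seed, 0xA1])
    defined, background = _gene_names(cfg)
    n = cfg.n_defined_genes
    n_roots = max(2, int(round(cfg.root_fraction * n)))
    n_roots = min(n_roots, n - 1) if n > 1 else n
    out_degree = np.zeros(n)
    interactions = []
    for child in range(n_roots, n):
        k = 2 if rng.random() < cfg.in_degree_two_prob else 1
        k = min(k, child)
        weights = out_degree[:child] + 1.0
        parents = rng.choice(child, size=k, replace=False, p=weights / weights.sum())
        for p in parents:
            out_degree[p] += 1
            u = rng.random()
            if u < cfg.frac_re:
                typ = "re"
            elif u < cfg.frac_re + cfg.frac_du:
                typ = "du"
            else:
                typ = "ac"
            interactions.append(Interaction(defined[int(p)], defined[child], typ))
    return SignedRegulatoryNetwork(interactions, defined + background)


def _topological_order(net: SignedRegulatoryNetwork, genes: list[str]) -> list[str]:
    index = {g: i for i, g in enumerate(genes)}
    children: dict[str, list[str]] = {g: [] for g in genes}
    in_deg = {g: 0 for g in genes}
    for it in net.interactions:
        children[it.regulator].append(it.target)
        in_deg[it.target] += 1
    ready = [g for g in genes if in_deg[g] == 0]
    order = []
    while ready:
        ready.sort(key=index.get)
        g = ready.pop(0)
        order.append(g)
        for c in children[g]:
            in_deg[c] -= 1
            if in_deg[c] == 0:
                ready.append(c)
    if len(order) != len(genes):
        raise ValueError("regulatory network contains a cycle")
    return order


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def simulate_expression(
    net: SignedRegulatoryNetwork, cfg: SimulationConfig
) -> SimulatedStudy:
    """Propagate signal through the network and mix in noise.

    Roots draw standard-normal values per sample.  Each regulated gene sums
    its parents' (standardised) values with edge signs — ac +, re −, du a
    fresh random sign per sample — scaled by ``effect_size``, and is then
    standardised.  The observed value is (1−b)·signal + b·ε with
    b = ``bio_noise``; background genes are ε alone.
    """
    rng_signal = np.random.default_rng([cfg.seed, 0xB2])
    rng_du = np.random.default_rng([cfg.seed, 0xC3])
    rng_eps = np.random.default_rng([cfg.seed, 0xD4])

    genes = list(net.gene_universe)
    defined = [g for g in genes if not g.startswith("bgr_")]
    background = [g for g in genes if g.startswith("bgr_")]
    ns = cfg.n_samples
    order = _topological_order(net, defined)

    parents: dict[str, list[Interaction]] = {g: [] for g in defined}
    for it in net.interactions:
        parents[it.target].append(it)

    signal: dict[str, np.ndarray] = {}
    for g in order:
        if not parents[g]:
            signal[g] = _standardize(rng_signal.standard_normal(ns))
            continue
        raw = np.zeros(ns)
        for it in sorted(parents[g]):
            if it.type == "ac":
                s = 1.0
            elif it.type == "re":
                s = -1.0
            else:  # du: ambiguous action, random sign per sample
                s = rng_du.choice((-1.0, 1.0), size=ns)
            raw = raw + cfg.effect_size * s * signal[it.regulator]
        signal[g] = _standardize(raw)

    b = cfg.bio_noise
    values = np.empty((len(genes), ns))
    row = {g: i for i, g in enumerate(genes)}
    for g in defined:
        eps = rng_eps.standard_normal(ns)
        values[row[g]] = (1.0 - b) * signal[g] + b * eps
    for g in background:
        values[row[g]] = rng_eps.standard_normal(ns)

    expr = ExpressionMatrix(genes, [f"s{j + 1}" for j in range(ns)], values)
    return SimulatedStudy(expr, net, cfg)


def generate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Network + expression in one call (the usual entry point)."""
    return simulate_expression(generate_regnet(cfg), cfg)


def planted_module_study(
    module_size: int = 20,
    n_background: int = 50,
    n_samples: int = 200,
    bio_noise: float = 0.1,
    seed: int = 0,
) -> SimulatedStudy:
    """Two antagonistic co-regulated modules plus background.

    One driver activates every gene of module M1 and represses every gene
    of module M2, so within-module pairs are expected up-together and
    down-together (symmetric pp/mm modules) and every M1–M2 pair is
    expected up-down (pm antagonism).  This is the clean configuration for
    probing relation exclusivity and reciprocity: unlike the general DAG
    generator it contains no dual-action edges and no sign-cancelling
    paths, so no pair is legitimately both positive and negative.
    """
    driver = "DRV"
    m1 = [f"M1_{i + 1:02d}" for i in range(module_size)]
    m2 = [f"M2_{i + 1:02d}" for i in range(module_size)]
    bgr = [f"bgr_{i + 1:03d}" for i in range(n_background)]
    interactions = [Interaction(driver, g, "ac") for g in m1] + [
        Interaction(driver, g, "re") for g in m2
    ]
    truth = SignedRegulatoryNetwork(interactions, [driver] + m1 + m2 + bgr)
    cfg = SimulationConfig(
        n_defined_genes=1 + 2 * module_size,
        n_background=n_background,
        n_samples=n_samples,
        bio_noise=bio_noise,
        seed=seed,
    )
    return simulate_expression(truth, cfg)
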