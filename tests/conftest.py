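import numpy as np
import pytest
from hypothesis import settings

import triexnet as tx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_expr() -> tx.ExpressionMatrix:
    rng = np.random.default_rng(42)
    return tx.ExpressionMatrix(
        [f"g{i}" for i in range(6)],
        [f"s{j}" for j in range(8)],
        rng.standard_normal((6, 8)),
    )


@pytest.fixture(scope="session")
def default_study() -> tx.SimulatedStudy:
    """100 defined + 100 background genes, 200 samples, bio-noise 0.1."""
    return tx.generate_study(tx.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_networks(default_study) -> tx.NetworkSet:
    return tx.build_networks(default_study.expr, z_cutoff=0.4)


@pytest.fixture(scope="session")
def planted_study() -> tx.SimulatedStudy:
    """Driver activates module M1 and represses M2; no du edges."""
    return tx.planted_module_study(seed=0)


@pytest.fixture(scope="session")
def planted_networks(planted_study) -> tx.NetworkSet:
    return tx.build_networks(planted_study.expr, z_cutoff=0.4)


def brute_force_counts(codes: np.ndarray):
    """Independent per-sample counting oracle for the inner-product scores."""
    n = codes.shape[0]
    pp = np.zeros((n, n), dtype=int)
    mm = np.zeros((n, n), dtype=int)
    pm = np.zeros((n, n), dtype=int)
    for s in range(codes.shape[1]):
        up = (codes[:, s] == 1).astype(int)
        down = (codes[:, s] == -1).astype(int)
        pp += np.outer(up, up)
        mm += np.outer(down, down)
        pm += np.outer(up, down)
    np.fill_diagonal(pp, 0)
    np.fill_diagonal(mm, 0)
    return pp, mm, pm
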