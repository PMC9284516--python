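import numpy as np
import pytest

from deeroligo import EnsembleSpec, generate_ensemble
from deeroligo.inversion import default_distance_grid


@pytest.fixture(scope="session")
def r_grid():
    return default_distance_grid()


@pytest.fixture(scope="session")
def cub_ensemble_1k():
    """Large Cub-model ensemble at the reference distance laws
    (intra 2.0 +/- 0.2 nm, inter 3.6 +/- 0.9 nm, plane spread 20 deg),
    shared across parameter-recovery tests."""
    return generate_ensemble(EnsembleSpec(n_configs=1000, seed=2025))


@pytest.fixture(scope="session")
def small_cub_ensemble():
    return generate_ensemble(EnsembleSpec(n_configs=5, seed=11))


def active_set_nnls_oracle(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exhaustive oracle for min ||Ax - b||^2 s.t. x >= 0 on small
    problems: enumerate every support set, solve the unconstrained LS on
    it, keep KKT-feasible candidates, return the objective-minimal one.
    Independent of the production NNLS path."""
    n = A.shape[1]
    best_x, best_obj = np.zeros(n), float(np.sum(b**2))
    for mask in range(1, 2**n):
        S = [j for j in range(n) if mask >> j & 1]
        x_s, *_ = np.linalg.lstsq(A[:, S], b, rcond=None)
        if np.any(x_s < -1e-12):
            continue
        x = np.zeros(n)
        x[S] = np.clip(x_s, 0.0, None)
        g = A.T @ (A @ x - b)  # KKT: gradient nonnegative off the support
        if np.any(g[[j for j in range(n) if j not in S]] < -1e-9):
            continue
        obj = float(np.sum((A @ x - b) ** 2))
        if obj < best_obj - 1e-15:
            best_obj, best_x = obj, x
    return best_x


@pytest.fixture(scope="session")
def active_set_oracle():
    return active_set_nnls_oracle
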