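"""Shared helpers for the test suite: random rigid motions and an
SVD-free brute-force superposition oracle."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    return random_rotation(rng), rng.uniform(-20, 20, size=3)


def brute_force_rmsd(P: np.ndarray, Q: np.ndarray, n_starts: int = 600, seed: int = 0) -> float:
    """Minimum RMSD of R@P+t onto Q by direct search over rotation vectors.

    Independent of the Kabsch/SVD route: coarse random sampling of SO(3)
    followed by local minimisation of the rotation-vector parametrisation;
    the optimal translation for a given rotation matches the centroids.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def objective(rotvec: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))

    rng = np.random.RandomState(seed)
    best_vec, best_val = np.zeros(3), objective(np.zeros(3))
    for _ in range(n_starts):
        vec = Rotation.random(random_state=rng).as_rotvec()
        val = objective(vec)
        if val < best_val:
            best_vec, best_val = vec, val
    res = minimize(objective, best_vec, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(min(best_val, res.fun))
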