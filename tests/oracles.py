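"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms they check: local alignment scores
come from exhaustive enumeration of monotone matchings, and rigid-fit rmsds
from generic numerical minimization over rotation vectors.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_local_score(s1, s2, score_of, gap):
    """Optimal local alignment score by enumerating all monotone matchings.

    An alignment is an order-preserving set of matched index pairs; interior
    unmatched positions between consecutive matches are gaps.  Exponential:
    only for sequences of length <= 8.
    """
    best = 0.0
    n, m = len(s1), len(s2)
    for k in range(1, min(n, m) + 1):
        for idx1 in combinations(range(n), k):
            for idx2 in combinations(range(m), k):
                total = sum(score_of(s1[i], s2[j]) for i, j in zip(idx1, idx2))
                gaps = sum(
                    (idx1[t + 1] - idx1[t] - 1) + (idx2[t + 1] - idx2[t] - 1)
                    for t in range(k - 1)
                )
                best = max(best, total + gap * gaps)
    return best


def brute_force_fit_rmsd(x_ref, x_mov, n_starts=12, seed=0):
    """Minimum rmsd over proper rigid transforms, by numerical optimization.

    Parametrizes rotations as rotation vectors and minimizes from several
    starts; the translation is optimal once centroids are matched.
    """
    x_ref = np.asarray(x_ref, float)
    x_mov = np.asarray(x_mov, float)
    a = x_ref - x_ref.mean(axis=0)
    b = x_mov - x_mov.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((a - b @ R.T) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best
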