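"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the textbook definitions, with no
imports from the code paths it checks.
"""

import numpy as np


def brute_force_lof(train: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Quadratic-time LOF of query points against a training set.

    Follows the k-distance / reachability-distance / local-reachability-
    density definitions literally.  Training-point densities are computed
    leaving the point itself out; query points are scored against the full
    training set (novelty setting).
    """
    train = np.asarray(train, dtype=float)
    query = np.asarray(query, dtype=float)
    n = len(train)

    d_tt = np.linalg.norm(train[:, None, :] - train[None, :, :], axis=2)
    np.fill_diagonal(d_tt, np.inf)
    knn_t = np.argsort(d_tt, axis=1)[:, :k]          # k nearest among others
    kdist = d_tt[np.arange(n), knn_t[:, -1]]         # distance to k-th nn

    def lrd_of_train(i: int) -> float:
        reach = [max(kdist[j], d_tt[i, j]) for j in knn_t[i]]
        return 1.0 / np.mean(reach)

    lrd_t = np.array([lrd_of_train(i) for i in range(n)])

    scores = []
    for q in query:
        d_q = np.linalg.norm(train - q, axis=1)
        nn = np.argsort(d_q)[:k]
        reach = [max(kdist[j], d_q[j]) for j in nn]
        lrd_q = 1.0 / np.mean(reach)
        scores.append(np.mean(lrd_t[nn]) / lrd_q)
    return np.array(scores)


def brute_force_fronts(objectives: np.ndarray) -> list[list[int]]:
    """Dominance fronts by exhaustive pairwise comparison and peeling."""
    objs = np.asarray(objectives, dtype=float)
    remaining = set(range(len(objs)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                np.all(objs[j] <= objs[i]) and np.any(objs[j] < objs[i])
                for j in remaining if j != i
            )
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


def dtlz1(genes: np.ndarray) -> tuple[float, float, float]:
    """Three-objective DTLZ1 benchmark (minimization, optimum plane sum=0.5)."""
    x = np.asarray(genes, dtype=float)
    tail = x[2:]
    g = 100 * (len(tail) + np.sum((tail - 0.5) ** 2
                                  - np.cos(20 * np.pi * (tail - 0.5))))
    return (0.5 * x[0] * x[1] * (1 + g),
            0.5 * x[0] * (1 - x[1]) * (1 + g),
            0.5 * (1 - x[0]) * (1 + g))
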