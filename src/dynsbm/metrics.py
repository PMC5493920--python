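"""Agreement measures between membership trajectories (recovery checks)."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .genmodel import MembershipTrajectories

__all__ = ["time_averaged_ari", "best_group_permutation", "permute_groups"]


def _as_Z(Z) -> np.ndarray:
    return Z.Z if isinstance(Z, MembershipTrajectories) else np.asarray(Z)


def time_averaged_ari(Z_true, Z_est) -> float:
    """Adjusted Rand index between the two partitions at each step, averaged
    over steps; computed on nodes present (in the true labelling) at that step."""
    A, B = _as_Z(Z_true), _as_Z(Z_est)
    scores = []
    for t in range(A.shape[1]):
        present = A[:, t] > 0
        if present.sum() > 1:
            scores.append(adjusted_rand_score(A[present, t], B[present, t]))
    return float(np.mean(scores))


def best_group_permutation(Z_true, Z_est, q: int) -> np.ndarray:
    """Permutation p (est group g -> true group p[g-1]+1, 0-based array) that
    maximizes pooled node-step agreement; Hungarian assignment on the
    confusion matrix."""
    A, B = _as_Z(Z_true), _as_Z(Z_est)
    mask = (A > 0) & (B > 0)
    conf = np.zeros((q, q))
    np.add.at(conf, (B[mask] - 1, A[mask] - 1), 1)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(q, dtype=np.int64)
    perm[rows] = cols
    return perm


def permute_groups(Z, perm: np.ndarray):
    """Relabel groups of Z by ``perm`` (group g -> perm[g-1]+1), keeping 0."""
    Zm = _as_Z(Z)
    out = np.zeros_like(Zm)
    mask = Zm > 0
    out[mask] = perm[Zm[mask] - 1] + 1
    return out
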