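"""Choosing the number of groups: ICL and the elbow heuristic.

ICL here is the completed log-likelihood at the MAP memberships penalized by
half the number of free parameters per block times the log of that block's
sample size: (Q-1) initial probabilities against N chains, Q(Q-1) transition
probabilities against the N(T-1) observed transitions, and the emission
parameters against the number of observable dyad-step observations D.  The
elbow rule formalizes "the slope of the log-likelihood flattens" as the Q of
maximum discrete curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import FitResult, complete_log_likelihood, fit
from .netdata import DynamicNetwork

__all__ = ["FitSettings", "ModelScan", "icl", "icl_penalty", "select_elbow",
           "scan_q"]


@dataclass
class FitSettings:
    n_init: int = 5
    max_iter: int = 100
    tol: float = 1e-6
    max_inner: int = 5
    inner_tol: float = 1e-4


def icl_penalty(q: int, n_nodes: int, n_steps: int, n_categories: int,
                n_observations: int, directed: bool) -> float:
    """Half log-sample-size per free parameter, block by block: the Q-1 free
    initial probabilities against the N chains, the Q(Q-1) free transition
    probabilities against the N(T-1) transitions, and the emission parameters
    against the number of observable dyad-step observations."""
    penalty = 0.5 * (q - 1) * np.log(n_nodes)
    if q > 1 and n_steps > 1:
        penalty += 0.5 * q * (q - 1) * np.log(n_nodes * (n_steps - 1))
    free_per_cell = n_categories  # 1 presence prob + (M - 1) category probs
    k_off = q * (q - 1) * n_steps * free_per_cell
    if not directed:
        k_off //= 2
    k_em = k_off + q * free_per_cell  # diagonal cells are time-pooled
    if n_observations > 0:
        penalty += 0.5 * k_em * np.log(n_observations)
    return float(penalty)


def icl(fit_result: FitResult, net: DynamicNetwork) -> float:
    """Integrated classification likelihood of a converged fit."""
    params = fit_result.params
    cll = complete_log_likelihood(net, fit_result.map_memberships, params)
    return float(cll - icl_penalty(params.q_groups, net.n_nodes, net.n_steps,
                                   net.n_categories, net.n_observable_dyads(),
                                   net.directed))


def select_elbow(q_values, loglik) -> int:
    """Q at the point of maximum discrete curvature of log-likelihood vs Q;
    ties go to the smallest Q, endpoints are excluded."""
    q_values = list(q_values)
    loglik = np.asarray(loglik, dtype=float)
    if len(q_values) < 3 or loglik.shape[0] != len(q_values):
        raise ValueError("need at least 3 (Q, log-likelihood) points")
    curv = (loglik[1:-1] - loglik[:-2]) - (loglik[2:] - loglik[1:-1])
    return int(q_values[1 + int(np.argmax(curv))])


@dataclass
class ModelScan:
    q_values: list[int]
    fits: list[FitResult]
    elbo: list[float] = field(default_factory=list)
    icl: list[float] = field(default_factory=list)

    @property
    def best_q_icl(self) -> int:
        return self.q_values[int(np.argmax(self.icl))]

    @property
    def best_q_elbow(self) -> int | None:
        if len(self.q_values) < 3:
            return None
        return select_elbow(self.q_values, self.elbo)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"q": self.q_values, "elbo": self.elbo, "icl": self.icl})
        df["selected_icl"] = df["q"] == self.best_q_icl
        best_e = self.best_q_elbow
        df["selected_elbow"] = df["q"] == best_e if best_e is not None else False
        return df


def scan_q(net: DynamicNetwork, q_min: int, q_max: int,
           settings: FitSettings | None = None, seed: int = 0) -> ModelScan:
    """Fit every Q in [q_min, q_max] with shared settings and per-Q seeds
    derived deterministically from ``seed``."""
    if not 1 <= q_min <= q_max:
        raise ValueError("need 1 <= q_min <= q_max")
    settings = settings or FitSettings()
    scan = ModelScan([], [], [], [])
    for q in range(q_min, q_max + 1):
        sub = int(np.random.SeedSequence([seed, q]).generate_state(1)[0] % (2 ** 31))
        fr = fit(net, q, n_init=settings.n_init, max_iter=settings.max_iter,
                 tol=settings.tol, seed=sub, max_inner=settings.max_inner,
                 inner_tol=settings.inner_tol)
        fr.icl = icl(fr, net)
        scan.q_values.append(q)
        scan.fits.append(fr)
        scan.elbo.append(fr.elbo)
        scan.icl.append(fr.icl)
    return scan
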