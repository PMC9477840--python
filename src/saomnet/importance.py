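"""Relative importance of effects and entropy-based predictability.

For a fitted evaluation function and the observed network, each actor ``i``
has an alter-choice distribution ``pi_i`` over the other ``n - 1`` members
(the probability of toggling the tie with each of them; the no-change
option is excluded here, following the measure's definition). An effect's
raw importance for ``i`` is the total variation displacement of ``pi_i``
when that effect's contribution to every alternative's gain is zeroed;
normalising across effects gives proportional contributions ``I_k(x, i)``
summing to one per actor, and averaging over actors the global ``I_k(x)``.

The degree of certainty ``R_H`` is ``1 - H(pi_i) / ln(n - 1)``: zero for a
uniform choice distribution, one when a single alter holds all mass.

Everything here is a deterministic function of the observed network, the
point estimates and the covariates — no simulation, no propagation of
parameter uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .effects import EvaluationFunction, NetworkState
from .network import DirectedNetwork

__all__ = [
    "ImportanceResult",
    "alter_choice_distribution",
    "effect_importance",
    "relative_importance",
    "degree_of_certainty",
]


@dataclass
class ImportanceResult:
    effect_names: list[str]
    pi: np.ndarray                # (n, n) rows pi_i; diagonal 0
    raw: np.ndarray               # (n, L) raw importances
    normalized: np.ndarray        # (n, L) I_k(x, i), rows sum to 1
    global_importance: np.ndarray  # (L,) I_k(x)
    r_h_actor: np.ndarray         # (n,)
    r_h: float


def _softmax_row(gain: np.ndarray, i: int) -> np.ndarray:
    g = gain.copy()
    g[i] = -np.inf
    g -= g.max()
    p = np.exp(g)
    return p / p.sum()


def alter_choice_distribution(
    net: DirectedNetwork | NetworkState, evalfn: EvaluationFunction, i: int
) -> np.ndarray:
    """``pi_i`` over the ``n - 1`` alters, as a length-n vector with 0 at i.

    ``pi_i(j)`` is proportional to ``exp`` of the evaluation gain of toggling
    ``x_ij``; the no-change alternative is excluded from the support.
    """
    state = net if isinstance(net, NetworkState) else NetworkState.from_network(net)
    return _softmax_row(evalfn.gain_vector(state, i), i)


def effect_importance(
    net: DirectedNetwork | NetworkState, evalfn: EvaluationFunction, i: int
) -> np.ndarray:
    """Raw importance of every effect for actor ``i``.

    Effect ``k`` is zeroed by removing its contribution ``beta_k *
    Delta_{k,ij}`` from the gain of every alternative (all other effects and
    weights untouched); the raw importance is ``sum_j |pi_i(j) -
    pi_i^(-k)(j)|``.
    """
    state = net if isinstance(net, NetworkState) else NetworkState.from_network(net)
    delta = evalfn.change_matrix(state, i)        # (L, n)
    beta = evalfn.beta
    gain = beta @ delta
    pi = _softmax_row(gain, i)
    raw = np.empty(evalfn.L)
    for k in range(evalfn.L):
        if beta[k] == 0.0:
            raw[k] = 0.0
            continue
        pi_minus = _softmax_row(gain - beta[k] * delta[k], i)
        raw[k] = np.abs(pi - pi_minus).sum()
    return raw


def relative_importance(
    net: DirectedNetwork, evalfn: EvaluationFunction
) -> ImportanceResult:
    """Per-actor and global relative importances plus R_H for a fitted model."""
    state = NetworkState.from_network(net)
    n, L = state.n, evalfn.L
    pi = np.zeros((n, n))
    raw = np.zeros((n, L))
    for i in range(n):
        pi[i] = alter_choice_distribution(state, evalfn, i)
        raw[i] = effect_importance(state, evalfn, i)
    totals = raw.sum(axis=1)
    normalized = np.empty_like(raw)
    degenerate = totals == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} actor(s) have an all-zero raw importance "
            "vector (all beta contributions null); assigning uniform 1/L",
            stacklevel=2,
        )
    normalized[degenerate] = 1.0 / L
    nz = ~degenerate
    normalized[nz] = raw[nz] / totals[nz, None]
    r_h_actor = _r_h_rows(pi, n)
    return ImportanceResult(
        effect_names=evalfn.names,
        pi=pi,
        raw=raw,
        normalized=normalized,
        global_importance=normalized.mean(axis=0),
        r_h_actor=r_h_actor,
        r_h=float(r_h_actor.mean()),
    )


def _r_h_rows(pi: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pi > 0, pi * np.log(pi), 0.0)
    entropy = -plogp.sum(axis=1)
    return 1.0 - entropy / np.log(n - 1)


def degree_of_certainty(
    net: DirectedNetwork, evalfn: EvaluationFunction
) -> tuple[np.ndarray, float]:
    """Per-actor and global ``R_H`` for a fitted evaluation function."""
    state = NetworkState.from_network(net)
    n = state.n
    pi = np.stack([alter_choice_distribution(state, evalfn, i) for i in range(n)])
    per_actor = _r_h_rows(pi, n)
    return per_actor, float(per_actor.mean())
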