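"""Continuous-time ministep simulation of the stationary actor-oriented process.

The process is a Markov chain on the space of directed graphs: at each
ministep a uniformly chosen focal actor either toggles one outgoing tie or
does nothing, with multinomial-logit probabilities driven by the evaluation
function (Gumbel-noise choice). With the rate parameter ``lambda`` fixed,
the number of change opportunities over one period is Poisson(n * lambda)
— or exactly round(n * lambda) in ``fixed`` mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .effects import EvaluationFunction, NetworkState
from .network import DirectedNetwork

__all__ = [
    "SimulationSettings",
    "choice_probabilities",
    "ministep",
    "simulate_chain",
    "simulate_ensemble",
]

DEGENERACY_GUARD = 10_000.0


@dataclass
class SimulationSettings:
    """Rate and ministep-count mode for one simulation period.

    ``rate`` is the expected number of tie-change opportunities per actor
    (the fixed rate parameter lambda; never estimated). ``mode`` selects
    Poisson-distributed ministep counts (continuous-time semantics, the
    default) or a deterministic count of ``round(n * rate)``.
    """

    rate: float = 36.0
    mode: str = "poisson"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.mode not in ("poisson", "fixed"):
            raise ValueError("mode must be 'poisson' or 'fixed'")
        if self.rate >= DEGENERACY_GUARD:
            warnings.warn(
                f"rate {self.rate} is at or above the degeneracy guard "
                f"({DEGENERACY_GUARD:g}); simulated networks may degenerate",
                stacklevel=2,
            )


def choice_probabilities(
    state: NetworkState, evalfn: EvaluationFunction, i: int
) -> np.ndarray:
    """Multinomial-logit probabilities over actor ``i``'s n alternatives.

    Entry ``j != i`` is the probability of toggling the tie ``x_ij``; the
    last entry is the no-change alternative (gain 0). Probabilities are
    strictly positive and sum to one.
    """
    gain = evalfn.gain_vector(state, i)
    g = np.append(gain, 0.0)
    g -= g[np.isfinite(g)].max()
    p = np.exp(g)
    return p / p.sum()


def ministep(
    state: NetworkState,
    evalfn: EvaluationFunction,
    i: int,
    rng: np.random.Generator,
) -> int | None:
    """Let actor ``i`` make one choice in place; returns the toggled alter or None."""
    p = choice_probabilities(state, evalfn, i)
    choice = int(rng.choice(len(p), p=p))
    if choice == state.n:  # no-change alternative
        return None
    state.toggle(i, choice)
    return choice


def _run_chain(
    state: NetworkState,
    evalfn: EvaluationFunction,
    settings: SimulationSettings,
    rng: np.random.Generator,
    collect_scores: bool,
) -> np.ndarray | None:
    n = state.n
    expected = n * settings.rate
    if settings.mode == "poisson":
        steps = int(rng.poisson(expected))
    else:
        steps = int(round(expected))
    actors = rng.integers(0, n, size=steps)
    # inverse-CDF sampling on precomputed uniforms keeps the loop lean
    unif = rng.random(size=steps)
    if not collect_scores:
        from ._kernel import compile_evaluation, run_compiled_chain

        run_compiled_chain(state, compile_evaluation(evalfn), actors, unif)
        return None
    scores = np.zeros(evalfn.L)
    beta = evalfn.beta
    g = np.empty(n + 1)
    for t in range(steps):
        i = int(actors[t])
        if collect_scores:
            delta = evalfn.change_matrix(state, i)  # (L, n)
            gain = beta @ delta
            gain[i] = -np.inf
        else:
            gain = evalfn.gain_vector(state, i)
        g[:n] = gain
        g[n] = 0.0
        g -= max(gain.max(), 0.0)
        p = np.exp(g)
        p /= p.sum()
        choice = int(np.searchsorted(np.cumsum(p), unif[t], side="right"))
        choice = min(choice, n)
        if collect_scores:
            expected_delta = delta @ p[:n]
            scores += (delta[:, choice] if choice < n else 0.0) - expected_delta
        if choice < n:
            state.toggle(i, choice)
    return scores


def simulate_chain(
    start: DirectedNetwork | NetworkState,
    evalfn: EvaluationFunction,
    settings: SimulationSettings,
    rng: np.random.Generator,
    return_scores: bool = False,
):
    """Simulate one period of ministeps from ``start``.

    Returns the final :class:`NetworkState`; with ``return_scores=True``,
    also the per-effect score vector ``sum_t (Delta(chosen) - E_pi[Delta])``
    accumulated along the chain (used for likelihood-ratio estimation of
    the Jacobian of expected statistics with respect to beta).
    """
    state = start.copy() if isinstance(start, NetworkState) else NetworkState.from_network(start)
    scores = _run_chain(state, evalfn, settings, rng, return_scores)
    if return_scores:
        return state, scores
    return state


def simulate_ensemble(
    start: DirectedNetwork | NetworkState,
    evalfn: EvaluationFunction,
    settings: SimulationSettings,
    R: int,
    seed: int | np.random.SeedSequence,
):
    """R independent chains from ``start``; returns final states and targets.

    Reproducibility contract: the master seed spawns one child stream per
    replicate (``SeedSequence.spawn``), so with sequential execution the
    ensemble is bit-identical for a given seed, independent of R ordering.

    Returns ``(states, stats)`` where ``stats`` is an ``(R, L)`` array of the
    per-replicate target statistics ``sum_i s_{k,i}``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(R)
    start_state = (
        start.copy() if isinstance(start, NetworkState) else NetworkState.from_network(start)
    )
    states, stats = [], np.empty((R, evalfn.L))
    for r in range(R):
        rng = np.random.default_rng(children[r])
        st = simulate_chain(start_state, evalfn, settings, rng)
        states.append(st)
        stats[r] = evalfn.statistics_total(st)
    return states, stats
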