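"""Method-of-moments estimation by Robbins-Monro stochastic approximation.

The stationary model is calibrated so that the observed network is both the
start and the target of each simulated period: the estimator seeks beta with
``E_beta[S] = S_obs`` where ``S`` is the vector of target statistics
``sum_i s_{k,i}`` evaluated at the end of a simulated period started at the
observed network. Estimation proceeds in the classic three phases:

1. an initial ensemble at the starting beta estimates the Jacobian
   ``D = dE[S]/dbeta`` by the score-function (likelihood-ratio) method with
   common chains;
2. Robbins-Monro iterations ``beta <- beta - a D^-1 (S_sim - S_obs)`` with
   the gain ``a`` halved across sub-phases and tail-averaging within each
   sub-phase;
3. a diagnostics ensemble at the final beta yields convergence t-ratios,
   the overall maximum convergence ratio, and the parameter covariance
   ``D^-1 Sigma D^-T``.

The rate parameter lambda is a fixed constant throughout, never estimated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .effects import EvaluationFunction, NetworkState
from .network import DirectedNetwork, density
from .simulate import SimulationSettings, simulate_chain

__all__ = [
    "EstimationSettings",
    "FitResult",
    "observed_targets",
    "robbins_monro_fit",
    "phase3_diagnostics",
    "wald_test",
]

logger = logging.getLogger(__name__)

T_RATIO_BOUND = 0.1
OVERALL_RATIO_BOUND = 0.15


@dataclass
class EstimationSettings:
    """Knobs of the three estimation phases.

    ``subphases`` Robbins-Monro sub-phases with gain halving (the reference
    analysis setting is 4); ``phase2_base`` iterations in the first
    sub-phase, growing by ``phase2_growth`` per sub-phase; ``phase1_n`` and
    ``phase3_n`` ensemble sizes for the Jacobian and diagnostics phases
    (the reference analysis used 20,000 phase-3 iterations; the default here
    is a desk-scale 1,000); ``initial_gain`` is the starting Robbins-Monro
    gain ``a0``; ``max_rounds`` full phase-2+3 rounds before giving up,
    restarting from the current estimate.
    """

    subphases: int = 4
    phase2_base: int = 40
    phase2_growth: float = 1.5
    phase1_n: int = 30
    phase3_n: int = 1000
    phase3_score_n: int = 150
    initial_gain: float = 0.2
    max_rounds: int = 4
    max_step: float = 0.3  # per-coordinate truncation of one RM update
    newton_step: float = 2.0
    beta_bound: float = 15.0
    jacobian_method: str = "fd"  # "fd" (common random numbers) | "score"
    fd_epsilon: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subphases", "phase2_base", "phase1_n", "phase3_n", "max_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.initial_gain <= 0:
            raise ValueError("initial_gain must be positive")


@dataclass
class FitResult:
    """Estimates, uncertainty, and convergence diagnostics for one model."""

    effect_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    covariance: np.ndarray
    t_ratios: np.ndarray
    overall_max_ratio: float
    converged: bool
    observed_targets: np.ndarray
    simulated_mean: np.ndarray
    rate: float
    settings: EstimationSettings | None = None
    seed: int = 0
    rounds_used: int = 1
    extras: dict = field(default_factory=dict)

    def summary_rows(self):
        """(name, estimate, se, p) rows mirroring a fit-report table."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        p = 2 * sps.norm.sf(np.abs(z))
        return list(zip(self.effect_names, self.beta, self.se, p))


def observed_targets(net: DirectedNetwork, evalfn: EvaluationFunction) -> np.ndarray:
    """Target statistic vector ``S_obs`` with entries ``sum_i s_{k,i}(x_obs)``."""
    return evalfn.statistics_total(NetworkState.from_network(net))


def _initial_beta(evalfn: EvaluationFunction, net: DirectedNetwork) -> np.ndarray:
    """Zero start except the out-degree effect, set to logit(observed density)."""
    beta = np.zeros(evalfn.L)
    d = min(max(density(net), 1e-6), 1 - 1e-6)
    for k, e in enumerate(evalfn.effects):
        if e.shortname == "outdegree":
            beta[k] = np.log(d / (1 - d))
    return beta


def _score_jacobian(stats: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Likelihood-ratio estimate of ``dE[S_k]/dbeta_l`` = Cov(S_k, score_l)."""
    s_c = stats - stats.mean(axis=0)
    g_c = scores - scores.mean(axis=0)
    return s_c.T @ g_c / (len(stats) - 1)


def _fd_jacobian(
    start: NetworkState,
    evalfn: EvaluationFunction,
    settings_sim: SimulationSettings,
    beta: np.ndarray,
    R: int,
    ss: np.random.SeedSequence,
    eps: float,
) -> np.ndarray:
    """Forward-difference Jacobian with common random numbers.

    For each replicate the base chain and every perturbed chain replay the
    same random stream, so the differences are driven by the perturbation
    alone — far lower variance than the score-function estimator at the
    same replicate count.
    """
    L = evalfn.L
    D = np.zeros((L, L))
    children = ss.spawn(R)
    for child in children:
        evalfn.beta = beta
        rng = np.random.default_rng(child)
        st0 = simulate_chain(start, evalfn, settings_sim, rng)
        s0 = evalfn.statistics_total(st0)
        for k in range(L):
            bk = beta.copy()
            bk[k] += eps
            evalfn.beta = bk
            rng = np.random.default_rng(child)  # common random numbers
            stk = simulate_chain(start, evalfn, settings_sim, rng)
            D[:, k] += (evalfn.statistics_total(stk) - s0) / eps
    evalfn.beta = beta
    return D / R


def _solve(D: np.ndarray, v: np.ndarray) -> np.ndarray:
    try:
        cond = np.linalg.cond(D)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("near-singular Jacobian; using generalized inverse", stacklevel=2)
        return np.linalg.pinv(D) @ v
    return np.linalg.solve(D, v)


def robbins_monro_fit(
    net_obs: DirectedNetwork,
    evalfn: EvaluationFunction,
    settings_sim: SimulationSettings,
    settings_est: EstimationSettings | None = None,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Fit the stationary model to one observed network.

    Each Robbins-Monro iteration simulates a single period started at the
    observed network and nudges beta against the deviation of the simulated
    from the observed targets. Returns a :class:`FitResult`; when the
    convergence criteria (|t-ratio| < 0.1 per effect, overall ratio < 0.15)
    are not met after ``max_rounds``, the result is flagged
    ``converged=False`` — never silently returned as converged.
    """
    est = settings_est or EstimationSettings()
    ss = np.random.SeedSequence(est.seed)
    s_obs = observed_targets(net_obs, evalfn)
    start = NetworkState.from_network(net_obs)
    beta = _initial_beta(evalfn, net_obs) if beta0 is None else np.asarray(beta0, float).copy()

    # ---- Phase 1: Jacobian at the starting beta ------------------------
    evalfn.beta = beta
    if est.jacobian_method == "fd":
        D = _fd_jacobian(start, evalfn, settings_sim, beta, est.phase1_n, ss,
                         est.fd_epsilon)
    else:
        stats1 = np.empty((est.phase1_n, evalfn.L))
        scores1 = np.empty((est.phase1_n, evalfn.L))
        for r, child in enumerate(ss.spawn(est.phase1_n)):
            rng = np.random.default_rng(child)
            st, sc = simulate_chain(start, evalfn, settings_sim, rng, return_scores=True)
            stats1[r] = evalfn.statistics_total(st)
            scores1[r] = sc
        D = _score_jacobian(stats1, scores1)
    logger.info("phase 1: Jacobian estimated from %d chains (%s)",
                est.phase1_n, est.jacobian_method)

    # ---- Phase 2: Robbins-Monro sub-phases -----------------------------
    # The update uses the diagonalised Jacobian: correlations between
    # statistics make the full inverse fragile under estimation noise,
    # while the diagonal gives stable, scale-aware steps. The Newton
    # refinement rounds below restore full-matrix precision at the end.
    dk = np.diag(D).copy()
    weak = dk <= 0
    if weak.any():  # noise floor: fall back to the row magnitude
        dk[weak] = np.abs(D).max(axis=1)[weak] + 1e-6
    gain = est.initial_gain
    for sp in range(est.subphases):
        n_iter = int(round(est.phase2_base * est.phase2_growth**sp))
        trail = []
        for child in ss.spawn(n_iter):
            rng = np.random.default_rng(child)
            evalfn.beta = beta
            st = simulate_chain(start, evalfn, settings_sim, rng)
            dev = evalfn.statistics_total(st) - s_obs
            step = np.clip(gain * dev / dk, -est.max_step, est.max_step)
            beta = np.clip(beta - step, -est.beta_bound, est.beta_bound)
            trail.append(beta)
        beta = np.mean(trail[len(trail) // 2:], axis=0)  # tail average
        gain /= 2.0
        logger.info("phase 2 sub-phase %d/%d done (%d iterations)",
                    sp + 1, est.subphases, n_iter)

    # ---- Phase 3 + Newton refinement rounds ----------------------------
    # Each extra round applies one Newton correction using the phase-3
    # ensemble's own Jacobian and mean deviation, then re-runs phase 3.
    # The best round (smallest overall ratio) is kept: if a correction
    # diverges — e.g. off a noisy, near-singular Jacobian — it is rolled
    # back rather than returned.
    best = None
    for rnd in range(est.max_rounds):
        evalfn.beta = beta
        result = phase3_diagnostics(net_obs, evalfn, settings_sim, est, ss, s_obs)
        result.rounds_used = rnd + 1
        if best is None or result.overall_max_ratio < best.overall_max_ratio:
            best = result
        if result.converged or rnd == est.max_rounds - 1:
            break
        if result.overall_max_ratio > 2.0 * best.overall_max_ratio:
            logger.info("round %d diverged (ratio %.3f); reverting to best",
                        rnd + 1, result.overall_max_ratio)
            beta = best.beta.copy()
            result = best
            break
        dbar = result.simulated_mean - s_obs
        # the score-function Jacobian from the phase-3 ensemble is unbiased
        # at the current beta, which matters more than variance here: a
        # biased derivative makes Newton corrections oscillate
        step = _solve(result.extras["jacobian"], dbar)
        norm = np.linalg.norm(step)
        if norm > est.newton_step:
            step *= est.newton_step / norm
        beta = beta - step
        logger.info("round %d not converged (max ratio %.3f); Newton correction",
                    rnd + 1, result.overall_max_ratio)
    best.rounds_used = result.rounds_used
    evalfn.beta = best.beta
    return best


def phase3_diagnostics(
    net_obs: DirectedNetwork,
    evalfn: EvaluationFunction,
    settings_sim: SimulationSettings,
    est: EstimationSettings,
    seed: int | np.random.SeedSequence | None = None,
    s_obs: np.ndarray | None = None,
) -> FitResult:
    """Phase-3 ensemble at fixed beta-hat: t-ratios, covariance, SEs.

    Per-effect convergence t-ratio: ``mean(S_sim_k - S_obs_k) / sd(S_sim_k)``.
    Overall maximum convergence ratio: ``sqrt(dbar' Sigma^+ dbar)`` with
    ``dbar`` the mean deviation and ``Sigma`` the simulated covariance.
    Parameter covariance: ``D^-1 Sigma D^-T`` with ``D`` the score-function
    Jacobian estimated on the same ensemble.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed or 0)
    if s_obs is None:
        s_obs = observed_targets(net_obs, evalfn)
    start = NetworkState.from_network(net_obs)
    # large plain ensemble for deviations/covariance of S; smaller scored
    # subset for the Jacobian (score accumulation is the expensive part)
    R = est.phase3_n
    Rs = min(est.phase3_score_n, R)
    stats = np.empty((R, evalfn.L))
    stats_s = np.empty((Rs, evalfn.L))
    scores = np.empty((Rs, evalfn.L))
    for r, child in enumerate(ss.spawn(R)):
        rng = np.random.default_rng(child)
        st = simulate_chain(start, evalfn, settings_sim, rng)
        stats[r] = evalfn.statistics_total(st)
    for r, child in enumerate(ss.spawn(Rs)):
        rng = np.random.default_rng(child)
        st, sc = simulate_chain(start, evalfn, settings_sim, rng, return_scores=True)
        stats_s[r] = evalfn.statistics_total(st)
        scores[r] = sc

    dev = stats - s_obs
    dbar = dev.mean(axis=0)
    sd = stats.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ratios = np.where(sd > 0, dbar / sd, 0.0)
    sigma = np.cov(stats, rowvar=False).reshape(evalfn.L, evalfn.L)
    sigma_inv = _psd_pinv(sigma)
    overall = float(np.sqrt(max(dbar @ sigma_inv @ dbar, 0.0)))

    D = _score_jacobian(stats_s, scores)
    try:
        Dinv = np.linalg.inv(D)
    except np.linalg.LinAlgError:
        warnings.warn("singular phase-3 Jacobian; using generalized inverse", stacklevel=2)
        Dinv = np.linalg.pinv(D)
    cov = Dinv @ sigma @ Dinv.T
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    converged = bool(
        np.all(np.abs(t_ratios) < T_RATIO_BOUND) and overall < OVERALL_RATIO_BOUND
    )
    return FitResult(
        effect_names=evalfn.names,
        beta=evalfn.beta.copy(),
        se=se,
        covariance=cov,
        t_ratios=t_ratios,
        overall_max_ratio=overall,
        converged=converged,
        observed_targets=s_obs,
        simulated_mean=stats.mean(axis=0),
        rate=settings_sim.rate,
        settings=est,
        seed=est.seed,
        extras={"jacobian": D, "sim_sd": sd},
    )


def _psd_pinv(m: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    keep = vals > tol * max(vals.max(), 1.0)
    if not keep.all():
        warnings.warn("rank-deficient simulated covariance; generalized inverse used",
                      stacklevel=2)
    inv = np.zeros_like(vals)
    inv[keep] = 1.0 / vals[keep]
    return (vecs * inv) @ vecs.T


def wald_test(fit: FitResult, effect_subset: list[str]) -> dict:
    """Multi-parameter Wald test that the named effects are jointly zero.

    ``chi2 = beta_A' Cov_AA^-1 beta_A`` with df the subset size; for a
    single effect this reduces to the squared t statistic.
    """
    idx = []
    for name in effect_subset:
        if name not in fit.effect_names:
            raise KeyError(f"effect {name!r} not in fit")
        idx.append(fit.effect_names.index(name))
    idx = np.asarray(idx)
    b = fit.beta[idx]
    sub = fit.covariance[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(sub, b))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular covariance submatrix in Wald test") from err
    df = len(idx)
    return {"chi2": chi2, "df": df, "p": float(sps.chi2.sf(chi2, df))}
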