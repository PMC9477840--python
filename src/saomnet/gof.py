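"""Simulation-based goodness-of-fit via the joint Mahalanobis distance.

Six auxiliary-statistic families summarise network topology: in- and
out-degree distributions, directed geodesic distances, the M-A-N triad
census, the mutual-clique census, and the distribution of ties across
consanguineal-relatedness classes. A model's fit is judged by the
Mahalanobis distance of the observed family vector from the cloud of
vectors simulated under the fitted model, with a one-tailed Monte-Carlo
p-value (observed kept in the reference distribution: leave-in).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .effects import EvaluationFunction
from .network import (
    DirectedNetwork,
    VillageData,
    clique_census,
    consanguineous_tie_distribution,
    geodesic_distribution,
    triad_census,
    TRIAD_CLASSES,
)
from .simulate import SimulationSettings, simulate_ensemble

__all__ = ["GofResult", "FAMILIES", "auxiliary_statistics", "mahalanobis_test", "run_gof"]

FAMILIES = (
    "indegree",
    "outdegree",
    "geodesic",
    "triad_census",
    "clique_census",
    "consanguineous_ties",
)


@dataclass
class GofResult:
    family: str
    observed: np.ndarray
    simulated: np.ndarray  # (R, m)
    mhd: float
    p: float
    replicates: int
    component_labels: list[str]


@dataclass
class GofConfig:
    """Fixed component layouts per family, derived from the observed network.

    Degree vectors are raw counts per degree value from 0 to the observed
    maximum (not cumulative); geodesics use buckets 1..5 plus a pooled
    "inf"; clique sizes run 1..observed maximum; consanguineous-tie bins are
    the distinct relatedness values present in the village.
    """

    max_indegree: int
    max_outdegree: int
    max_clique: int
    relatedness_values: tuple[float, ...]

    @classmethod
    def from_observed(cls, net: DirectedNetwork, village: VillageData) -> "GofConfig":
        r = village.dyad_covariates["consanguineal"].values
        off = ~np.eye(net.n, dtype=bool)
        vals = tuple(sorted(np.unique(np.round(r[off], 9)), reverse=True))
        cc = clique_census(net)
        return cls(
            max_indegree=int(net.in_degrees().max()),
            max_outdegree=int(net.out_degrees().max()),
            max_clique=max(cc) if cc else 1,
            relatedness_values=vals,
        )


def _degree_counts(deg: np.ndarray, top: int) -> np.ndarray:
    counts = np.bincount(np.minimum(deg.astype(int), top), minlength=top + 1)
    return counts.astype(float)


def auxiliary_statistics(
    net: DirectedNetwork, village: VillageData, family: str, config: GofConfig
) -> tuple[np.ndarray, list[str]]:
    """Fixed-layout auxiliary vector for one family (values, component labels)."""
    if family == "indegree":
        v = _degree_counts(net.in_degrees(), config.max_indegree)
        return v, [f"indeg={d}" for d in range(len(v))]
    if family == "outdegree":
        v = _degree_counts(net.out_degrees(), config.max_outdegree)
        return v, [f"outdeg={d}" for d in range(len(v))]
    if family == "geodesic":
        d = geodesic_distribution(net)
        return np.array([float(x) for x in d.values()]), list(d)
    if family == "triad_census":
        c = triad_census(net)
        return np.array([float(c[k]) for k in TRIAD_CLASSES]), list(TRIAD_CLASSES)
    if family == "clique_census":
        c = clique_census(net)
        sizes = range(1, config.max_clique + 1)
        v = [float(c.get(s, 0)) for s in sizes]
        v.append(float(sum(cnt for s, cnt in c.items() if s > config.max_clique)))
        return np.array(v), [f"size={s}" for s in sizes] + [f"size>{config.max_clique}"]
    if family == "consanguineous_ties":
        rel = village.dyad_covariates["consanguineal"]
        d = consanguineous_tie_distribution(net, rel)
        vals = config.relatedness_values
        out = [float(next((c for v, c in d.items() if abs(v - t) <= 1e-6), 0.0))
               for t in vals]
        return np.array(out), [f"r={t:g}" for t in vals]
    raise ValueError(f"unknown auxiliary family {family!r}; valid: {', '.join(FAMILIES)}")


def mahalanobis_test(observed: np.ndarray, simulated: np.ndarray) -> dict:
    """Joint Mahalanobis distance of the observed vector and Monte-Carlo p.

    The centre is the simulated mean and the scatter the simulated
    covariance; zero-variance components are dropped and a generalized
    (pseudo-)inverse used, since census vectors are frequently
    rank-deficient. The p-value is the leave-in proportion of replicates
    whose own distance from the centre is at least the observed one.
    """
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if simulated.ndim != 2 or len(simulated) < 2:
        raise ValueError("need at least 2 simulated replicates")
    centre = simulated.mean(axis=0)
    sd = simulated.std(axis=0)
    keep = sd > 1e-10
    if not keep.any():
        warnings.warn("all components constant across replicates; MHD = 0", stacklevel=2)
        mhd = 0.0 if np.allclose(observed, centre) else np.inf
        return {"mhd": mhd, "p": 1.0 if mhd == 0.0 else 0.0}
    obs_k = observed[keep]
    sim_k = simulated[:, keep]
    cen_k = centre[keep]
    cov = np.cov(sim_k, rowvar=False).reshape(keep.sum(), keep.sum())
    vals, vecs = np.linalg.eigh(cov)
    tol = 1e-10 * max(vals.max(), 1.0)
    pos = vals > tol
    if not pos.all():
        warnings.warn("rank-deficient simulated covariance; generalized inverse",
                      stacklevel=2)
    inv = np.zeros_like(vals)
    inv[pos] = 1.0 / vals[pos]
    pinv = (vecs * inv) @ vecs.T

    def _mhd(v):
        d = v - cen_k
        return float(d @ pinv @ d)

    mhd_obs = _mhd(obs_k)
    rep = np.einsum("ij,jk,ik->i", sim_k - cen_k, pinv, sim_k - cen_k)
    p = float((rep >= mhd_obs - 1e-12).mean())
    return {"mhd": mhd_obs, "p": p}


def run_gof(
    fit,
    net_obs: DirectedNetwork,
    village: VillageData,
    families: tuple[str, ...] = FAMILIES,
    R: int = 1000,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    evalfn: EvaluationFunction | None = None,
    allow_nonconverged: bool = False,
) -> dict[str, GofResult]:
    """One ensemble at beta-hat, reused across all requested families.

    ``fit`` is a FitResult; ``evalfn`` must be the evaluation function the
    fit was produced with (its beta is reset to the fitted values here).
    """
    if not fit.converged and not allow_nonconverged:
        raise RuntimeError(
            "refusing goodness-of-fit for a non-converged fit "
            f"(overall ratio {fit.overall_max_ratio:.3f}); pass "
            "allow_nonconverged=True to override"
        )
    if evalfn is None:
        raise ValueError("evalfn (the fitted evaluation function) is required")
    evalfn.beta = fit.beta
    settings = settings or SimulationSettings(rate=fit.rate)
    config = GofConfig.from_observed(net_obs, village)
    states, _ = simulate_ensemble(net_obs, evalfn, settings, R, seed)
    nets = [s.to_network(village.labels) for s in states]

    out: dict[str, GofResult] = {}
    for family in families:
        obs, labels = auxiliary_statistics(net_obs, village, family, config)
        sims = np.stack(
            [auxiliary_statistics(nn, village, family, config)[0] for nn in nets]
        )
        res = mahalanobis_test(obs, sims)
        out[family] = GofResult(
            family=family,
            observed=obs,
            simulated=sims,
            mhd=res["mhd"],
            p=res["p"],
            replicates=R,
            component_labels=labels,
        )
    return out
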