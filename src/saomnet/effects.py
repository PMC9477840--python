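"""Evaluation-function effects: statistics ``s_{k,i}(x)`` and change statistics.

Each effect ``k`` carries a per-actor network statistic ``s_{k,i}(x)`` and a
weight ``beta_k``; the evaluation function is the weighted sum
``f_i = sum_k beta_k * s_{k,i}(x)``. The gain of a ministep toggling the tie
``x_ij`` is ``sum_k beta_k * Delta_{k,ij}`` where the change statistic
``Delta_{k,ij} = s_{k,i}(x^{+-ij}) - s_{k,i}(x)`` is computed by local
bookkeeping, never by full recomputation.

All change statistics are returned as a whole row at once —
``change_vector(state, i)[j]`` is ``Delta_{k,ij}`` — because the ministep
simulator needs the gain of every alternative simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DirectedNetwork, VillageData

__all__ = [
    "NetworkState",
    "EffectSpec",
    "EvaluationFunction",
    "build_specification",
    "SPECIFICATION_NAMES",
]


class NetworkState:
    """Mutable simulation state: adjacency plus incrementally maintained caches.

    Holds the 0/1 adjacency ``x`` (float64 for fast matvecs), out-/in-degree
    vectors and the mutual-tie matrix ``m = x & x.T``, all updated in O(n)
    per toggle.
    """

    __slots__ = ("x", "outdeg", "indeg", "mutual", "n")

    def __init__(self, ties: np.ndarray):
        x = np.asarray(ties, dtype=np.float64).copy()
        if np.diagonal(x).any():
            raise ValueError("self-ties not allowed")
        self.x = x
        self.n = x.shape[0]
        self.outdeg = x.sum(axis=1)
        self.indeg = x.sum(axis=0)
        self.mutual = x * x.T

    @classmethod
    def from_network(cls, net: DirectedNetwork) -> "NetworkState":
        return cls(net.ties)

    def toggle(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("cannot toggle a self-tie")
        new = 1.0 - self.x[i, j]
        self.x[i, j] = new
        delta = 2.0 * new - 1.0
        self.outdeg[i] += delta
        self.indeg[j] += delta
        m = new * self.x[j, i]
        self.mutual[i, j] = m
        self.mutual[j, i] = m

    def copy(self) -> "NetworkState":
        s = NetworkState.__new__(NetworkState)
        s.x = self.x.copy()
        s.n = self.n
        s.outdeg = self.outdeg.copy()
        s.indeg = self.indeg.copy()
        s.mutual = self.mutual.copy()
        return s

    def to_network(self, labels=None) -> DirectedNetwork:
        return DirectedNetwork(self.x.astype(np.int8), list(labels) if labels else [])


# --------------------------------------------------------------------------
# effect specifications
# --------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """One evaluation-function effect.

    ``kind`` is one of ``structural``, ``actor-covariate``, ``dyad-covariate``
    or ``interaction``; structural effects reference no covariate. ``beta``
    is the effect's weight in the evaluation function. ``options`` carries
    internal switches (e.g. the non-centred flag of the dyadic "X" effect).
    """

    name: str
    shortname: str
    kind: str
    covariates: tuple[str, ...] = ()
    beta: float = 0.0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "structural" and self.covariates:
            raise ValueError(f"structural effect {self.name!r} must not reference covariates")
        if self.kind == "interaction" and len(self.covariates) < 1:
            raise ValueError(f"interaction effect {self.name!r} must reference covariates")


class _Bound:
    """An EffectSpec bound to a village's covariate arrays (internal)."""

    __slots__ = ("spec", "w", "v", "same_hh", "sim", "sim_mean", "vrange")

    def __init__(self, spec: EffectSpec, village: VillageData):
        self.spec = spec
        self.w = self.v = self.same_hh = self.sim = None
        short = spec.shortname
        if short in ("X", "XRecip"):
            name = spec.covariates[0]
            if name not in village.dyad_covariates:
                raise KeyError(f"effect {spec.name!r} references missing dyad covariate {name!r}")
            self.w = village.dyad_covariates[name].values
        elif short in ("alter", "ego", "same", "similarity"):
            name = spec.covariates[0]
            if name not in village.actor_covariates:
                raise KeyError(f"effect {spec.name!r} references missing actor covariate {name!r}")
            self.v = village.actor_covariates[name].values
            if short == "similarity":
                rng = self.v.max() - self.v.min()
                if rng == 0:
                    raise ValueError(f"similarity effect {spec.name!r}: covariate has zero range")
                self.sim = 1.0 - np.abs(self.v[:, None] - self.v[None, :]) / rng
                n = len(self.v)
                off = ~np.eye(n, dtype=bool)
                self.sim_mean = float(self.sim[off].mean())
        elif short == "transTripJump":
            self.same_hh = village.households.same_household().astype(np.float64)


# --- per-effect statistic and change-vector implementations -----------------
# Each takes (bound, state, i) and returns a scalar (statistic) or a length-n
# row over alters j (change vector for toggling x_ij; entry j == i is
# meaningless and masked by callers).


def _delta(state: NetworkState, i: int) -> np.ndarray:
    """+1 where the toggle would add the tie, -1 where it would drop it."""
    return 1.0 - 2.0 * state.x[i]


def _s_outdegree(b, s, i):
    return s.outdeg[i]


def _c_outdegree(b, s, i):
    return _delta(s, i)


def _s_recip(b, s, i):
    return float(s.x[i] @ s.x[:, i])


def _c_recip(b, s, i):
    return _delta(s, i) * s.x[:, i]


def _s_X(b, s, i):
    return float(s.x[i] @ b.w[i])


def _c_X(b, s, i):
    return _delta(s, i) * b.w[i]


def _s_XRecip(b, s, i):
    return float((s.x[i] * s.x[:, i]) @ b.w[i])


def _c_XRecip(b, s, i):
    return _delta(s, i) * s.x[:, i] * b.w[i]


def _s_alter(b, s, i):
    return float(s.x[i] @ b.v)


def _c_alter(b, s, i):
    return _delta(s, i) * b.v


def _s_ego(b, s, i):
    return b.v[i] * s.outdeg[i]


def _c_ego(b, s, i):
    return _delta(s, i) * b.v[i]


def _s_same(b, s, i):
    return float(s.x[i] @ (b.v == b.v[i]))


def _c_same(b, s, i):
    return _delta(s, i) * (b.v == b.v[i]).astype(float)


def _s_similarity(b, s, i):
    return float(s.x[i] @ (b.sim[i] - b.sim_mean))


def _c_similarity(b, s, i):
    return _delta(s, i) * (b.sim[i] - b.sim_mean)


def _s_outAct(b, s, i):
    return s.outdeg[i] ** 2


def _c_outAct(b, s, i):
    d = _delta(s, i)
    return d * (2.0 * s.outdeg[i] + d)


def _s_inPop(b, s, i):
    return float(s.x[i] @ s.indeg)


def _c_inPop(b, s, i):
    # toggling x_ij changes j's in-degree too: Delta = d * (indeg_{-i}(j) + 1)
    return _delta(s, i) * (s.indeg - s.x[i] + 1.0)


def _s_outPop(b, s, i):
    return float(s.x[i] @ s.outdeg)


def _c_outPop(b, s, i):
    return _delta(s, i) * s.outdeg


def _s_transTrip(b, s, i):
    row = s.x[i]
    return float(row @ (s.x @ row))


def _c_transTrip(b, s, i):
    row = s.x[i]
    # closing i->j over two-paths i->h->j, plus the toggled tie acting as the
    # middle tie i->h of triplets i->j', h->j' with h == j
    return _delta(s, i) * (row @ s.x + s.x @ row)


def _s_transRecTrip(b, s, i):
    row, col = s.x[i], s.x[:, i]
    return float((row * col) @ (row @ s.x))


def _c_transRecTrip(b, s, i):
    row, col = s.x[i], s.x[:, i]
    return _delta(s, i) * (col * (row @ s.x) + s.x @ (row * col))


def _s_threeCycle(b, s, i):
    return float(s.x[i] @ (s.x @ s.x[:, i]))


def _c_threeCycle(b, s, i):
    return _delta(s, i) * (s.x @ s.x[:, i])


def _s_denseTriads(b, s, i):
    mi = s.mutual[i]
    return 0.5 * float(mi @ (s.mutual @ mi))


def _c_denseTriads(b, s, i):
    mi = s.mutual[i]
    return _delta(s, i) * s.x[:, i] * (s.mutual @ mi)


def _s_transTripJump(b, s, i):
    row = s.x[i]
    same, diff = b.same_hh[i], 1.0 - b.same_hh[i]
    return float((row * same) @ (s.x @ (row * diff)))


def _c_transTripJump(b, s, i):
    row = s.x[i]
    same, diff = b.same_hh[i], 1.0 - b.same_hh[i]
    closing = diff * ((row * same) @ s.x)
    middle = same * (s.x @ (row * diff))
    return _delta(s, i) * (closing + middle)


def _s_sharedPop(b, s, i):
    c = s.x @ s.x[i]
    c[i] = 0.0
    return float((c * (c - 1.0)).sum()) / 2.0


def _c_sharedPop(b, s, i):
    row = s.x[i]
    c = s.x @ row  # shared-target counts c_{ih}; entry h == i is outdeg(i)
    base = c @ s.x - row * c[i]
    return _delta(s, i) * base + row * (s.indeg - row)


_IMPLS = {
    "outdegree": (_s_outdegree, _c_outdegree),
    "recip": (_s_recip, _c_recip),
    "X": (_s_X, _c_X),
    "XRecip": (_s_XRecip, _c_XRecip),
    "alter": (_s_alter, _c_alter),
    "ego": (_s_ego, _c_ego),
    "same": (_s_same, _c_same),
    "similarity": (_s_similarity, _c_similarity),
    "outAct": (_s_outAct, _c_outAct),
    "inPop": (_s_inPop, _c_inPop),
    "outPop": (_s_outPop, _c_outPop),
    "transTrip": (_s_transTrip, _c_transTrip),
    "transRecTrip": (_s_transRecTrip, _c_transRecTrip),
    "threeCycle": (_s_threeCycle, _c_threeCycle),
    "denseTriads": (_s_denseTriads, _c_denseTriads),
    "transTripJump": (_s_transTripJump, _c_transTripJump),
    "sharedPop": (_s_sharedPop, _c_sharedPop),
}


# --------------------------------------------------------------------------
# evaluation function
# --------------------------------------------------------------------------


class EvaluationFunction:
    """An ordered list of effects with an aligned weight vector ``beta``."""

    def __init__(self, effects: list[EffectSpec], village: VillageData):
        names = [e.name for e in effects]
        if len(set(names)) != len(names):
            raise ValueError("effect names must be unique")
        for e in effects:
            if e.shortname not in _IMPLS:
                raise ValueError(f"unknown effect implementation {e.shortname!r}")
        self.effects = list(effects)
        self.village = village
        self._bound = [_Bound(e, village) for e in effects]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.effects]

    @property
    def L(self) -> int:
        return len(self.effects)

    @property
    def beta(self) -> np.ndarray:
        return np.array([e.beta for e in self.effects])

    @beta.setter
    def beta(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.L,):
            raise ValueError("beta length must match effect count")
        for e, v in zip(self.effects, values):
            e.beta = float(v)

    # -- statistics ----------------------------------------------------

    def statistic(self, state: NetworkState, k: int, i: int) -> float:
        """``s_{k,i}(x)`` for effect index ``k`` and actor ``i``."""
        b = self._bound[k]
        return float(_IMPLS[b.spec.shortname][0](b, state, i))

    def statistics_actor(self, state: NetworkState, i: int) -> np.ndarray:
        return np.array([self.statistic(state, k, i) for k in range(self.L)])

    def statistics_total(self, state: NetworkState) -> np.ndarray:
        """Target vector ``S`` with entries ``sum_i s_{k,i}(x)``."""
        out = np.zeros(self.L)
        for i in range(state.n):
            out += self.statistics_actor(state, i)
        return out

    # -- change statistics ----------------------------------------------

    def change_statistic(self, state: NetworkState, k: int, i: int, j: int) -> float:
        """``Delta_{k,ij}``: change in ``s_{k,i}`` from toggling ``x_ij``."""
        if i == j:
            raise ValueError("change statistic undefined for i == j")
        b = self._bound[k]
        return float(_IMPLS[b.spec.shortname][1](b, state, i)[j])

    def change_matrix(self, state: NetworkState, i: int) -> np.ndarray:
        """``(L, n)`` array of ``Delta_{k,ij}`` over all alters ``j``."""
        out = np.empty((self.L, state.n))
        for k, b in enumerate(self._bound):
            out[k] = _IMPLS[b.spec.shortname][1](b, state, i)
        return out

    def gain_vector(self, state: NetworkState, i: int) -> np.ndarray:
        """Evaluation gains ``sum_k beta_k Delta_{k,ij}`` over all ``j``.

        The entry at ``j == i`` is set to ``-inf`` so the self-toggle can
        never be selected; the no-change alternative (gain 0) is appended by
        the caller.
        """
        gain = np.zeros(state.n)
        for b, beta in zip(self._bound, self.beta):
            if beta != 0.0:
                gain += beta * _IMPLS[b.spec.shortname][1](b, state, i)
        if not np.isfinite(gain).all():
            bad = self._first_nonfinite(state, i)
            raise FloatingPointError(f"non-finite evaluation gain from effect {bad!r}")
        gain[i] = -np.inf
        return gain

    def evaluation_gain(self, state: NetworkState, i: int, j: int) -> float:
        """Gain of toggling ``x_ij``; the no-change alternative has gain 0."""
        if i == j:
            raise ValueError("evaluation gain undefined for i == j")
        return float(self.beta @ self.change_matrix(state, i)[:, j])

    def _first_nonfinite(self, state, i):
        for k, b in enumerate(self._bound):
            row = _IMPLS[b.spec.shortname][1](b, state, i)
            if not np.isfinite(self.beta[k] * row[np.arange(state.n) != i]).all():
                return b.spec.name
        return "<unknown>"


# --------------------------------------------------------------------------
# archetypal specifications
# --------------------------------------------------------------------------

SPECIFICATION_NAMES = (
    "conventional",
    "extended",
    "networked_limited",
    "networked_comprehensive",
)

_ACTOR_COVS = (
    ("household_wealth", "Household Wealth"),
    ("household_size", "Household Size"),
    ("age", "Age"),
    ("gender", "Gender: Female"),
    ("ethnicity", "Ethnicity: Minority"),
    ("melanin", "Melanin Index"),
    ("bmi", "Body Mass Index"),
)

_HOMOPHILY = (
    ("age", "Age Similarity", "similarity"),
    ("gender", "Same Gender", "same"),
    ("ethnicity", "Same Ethnicity", "same"),
    ("melanin", "Melanin Index Similarity", "similarity"),
    ("bmi", "Body Mass Index Similarity", "similarity"),
)


def _conventional_effects() -> list[EffectSpec]:
    return [
        EffectSpec("Out-degree", "outdegree", "structural"),
        EffectSpec("Reciprocity", "recip", "structural"),
        EffectSpec("Geographic Distance", "X", "dyad-covariate", ("distance",),
                   options={"centered": False}),
        EffectSpec("Consanguineal Relatedness", "X", "dyad-covariate", ("consanguineal",),
                   options={"centered": False}),
        EffectSpec("Affinal Relatedness", "X", "dyad-covariate", ("affinal",),
                   options={"centered": False}),
    ]


def _extended_effects() -> list[EffectSpec]:
    eff = _conventional_effects()
    eff += [
        EffectSpec("Relative Wealth Rank", "X", "dyad-covariate",
                   ("relative_wealth_rank",), options={"centered": False}),
        EffectSpec("Cons. Rel. x Reciprocity", "XRecip", "interaction",
                   ("consanguineal",), options={"centered": False}),
        EffectSpec("Cons. Rel. x Relative Wealth Rank", "X", "interaction",
                   ("cons_x_wealth_rank",), options={"centered": False}),
        EffectSpec("Cons. Rel. x Geographic Distance", "X", "interaction",
                   ("cons_x_distance",), options={"centered": False}),
        EffectSpec("Godparental Relation", "X", "dyad-covariate", ("godparent",),
                   options={"centered": False}),
        EffectSpec("Infidelity Relation", "X", "dyad-covariate", ("infidelity",),
                   options={"centered": False}),
    ]
    for key, label in _ACTOR_COVS:
        eff.append(EffectSpec(f"{label} (Alter)", "alter", "actor-covariate", (key,)))
    for key, label in _ACTOR_COVS:
        eff.append(EffectSpec(f"{label} (Ego)", "ego", "actor-covariate", (key,)))
    for key, label, short in _HOMOPHILY:
        eff.append(EffectSpec(label, short, "actor-covariate", (key,)))
    return eff


def _limited_structural() -> list[EffectSpec]:
    return [
        EffectSpec("In-degree Popularity", "inPop", "structural"),
        EffectSpec("Out-degree Popularity", "outPop", "structural"),
        EffectSpec("Transitive Triplets", "transTrip", "structural"),
    ]


def _comprehensive_structural() -> list[EffectSpec]:
    return [
        EffectSpec("Out-degree Activity", "outAct", "structural"),
        EffectSpec("Transitive Reciprocated Triplets", "transRecTrip", "structural"),
        EffectSpec("Three Cycles", "threeCycle", "structural"),
        EffectSpec("Dense Triads", "denseTriads", "structural",
                   options={"required_ties": 6}),
        EffectSpec("Transitive Triplets Jumping HHs", "transTripJump", "structural"),
        EffectSpec("Shared Popularity", "sharedPop", "structural"),
    ]


def build_specification(name: str, village: VillageData) -> EvaluationFunction:
    """Build one of the four archetypal model specifications.

    ``conventional`` holds the out-degree base effect plus the four dyadic
    covariates (reciprocity, distance, consanguineal and affinal
    relatedness). ``extended`` adds relative wealth rank, the three
    consanguinity interactions, godparenthood, infidelity, and the full
    alter/ego/homophily battery. ``networked_limited`` adds in-degree
    popularity, out-degree popularity and transitive triplets;
    ``networked_comprehensive`` further adds out-degree activity, transitive
    reciprocated triplets, three-cycles, dense triads, household-jumping
    transitive triplets and shared popularity.
    """
    if name not in SPECIFICATION_NAMES:
        raise ValueError(
            f"unknown specification {name!r}; valid names: {', '.join(SPECIFICATION_NAMES)}"
        )
    village = _ensure_interactions(village) if name != "conventional" else village
    if name == "conventional":
        effects = _conventional_effects()
    elif name == "extended":
        effects = _extended_effects()
    elif name == "networked_limited":
        effects = _extended_effects() + _limited_structural()
    else:
        effects = _extended_effects() + _limited_structural() + _comprehensive_structural()
    return EvaluationFunction(effects, village)


def _ensure_interactions(village: VillageData) -> VillageData:
    """Derive the elementwise-product interaction matrices if missing."""
    from dataclasses import replace
    from .network import DyadCovariate

    dcov = dict(village.dyad_covariates)
    cons = dcov["consanguineal"].values
    if "cons_x_wealth_rank" not in dcov:
        dcov["cons_x_wealth_rank"] = DyadCovariate(
            "cons_x_wealth_rank", cons * dcov["relative_wealth_rank"].values
        )
    if "cons_x_distance" not in dcov:
        dcov["cons_x_distance"] = DyadCovariate(
            "cons_x_distance", cons * dcov["distance"].values, symmetric=True
        )
    return replace(village, dyad_covariates=dcov)
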