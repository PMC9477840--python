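"""Directed-network containers, covariates, and descriptive census statistics.

The central object is a binary directed graph over a complete census of
village residents ("actors"): ``x[i, j] = 1`` means actor ``i`` gives
tangible support to actor ``j``. Self-ties are structurally impossible.
Everything downstream (effects, simulation, estimation, goodness-of-fit)
consumes the containers defined here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "DirectedNetwork",
    "ActorCovariate",
    "DyadCovariate",
    "HouseholdAssignment",
    "VillageData",
    "build_verified_network",
    "preprocess_covariates",
    "density",
    "reciprocity_proportion",
    "transitivity_weak",
    "degree_summaries",
    "triad_census",
    "TRIAD_CLASSES",
    "clique_census",
    "geodesic_distribution",
    "consanguineous_tie_distribution",
    "graph_correlation",
    "kin_triad_composition",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class DirectedNetwork:
    """Binary directed graph with no self-ties.

    Parameters
    ----------
    ties
        ``(n, n)`` array of 0/1 tie indicators; the diagonal must be zero.
    labels
        Actor identifiers, one per row/column. Defaults to ``"a0".."a{n-1}"``.
    observation_label
        Free-text tag for the observation moment (e.g. ``"t2013"``).
    """

    ties: np.ndarray
    labels: list[str] = field(default_factory=list)
    observation_label: str = ""

    def __post_init__(self) -> None:
        ties = np.asarray(self.ties)
        if ties.ndim != 2 or ties.shape[0] != ties.shape[1]:
            raise ValueError("ties must be a square matrix")
        if ties.shape[0] < 2:
            raise ValueError("a directed network needs at least 2 actors")
        if not np.isin(ties, (0, 1)).all():
            raise ValueError("tie values must be 0 or 1")
        ties = ties.astype(np.int8, copy=True)
        if np.diagonal(ties).any():
            raise ValueError("self-ties are not allowed")
        self.ties = ties
        if not self.labels:
            self.labels = [f"a{i}" for i in range(ties.shape[0])]
        if len(self.labels) != ties.shape[0]:
            raise ValueError("labels length must equal actor count")

    @property
    def n(self) -> int:
        return self.ties.shape[0]

    @property
    def arc_count(self) -> int:
        return int(self.ties.sum())

    def out_degrees(self) -> np.ndarray:
        return self.ties.sum(axis=1)

    def in_degrees(self) -> np.ndarray:
        return self.ties.sum(axis=0)

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(self.ties.copy(), list(self.labels), self.observation_label)


@dataclass
class ActorCovariate:
    """One numeric attribute per actor (monadic covariate ``v_i``)."""

    name: str
    values: np.ndarray
    scaling: str = "raw"  # "raw" | "zscore"
    levels: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"covariate {self.name!r} must be one value per actor")
        if self.scaling not in ("raw", "zscore"):
            raise ValueError("scaling must be 'raw' or 'zscore'")


@dataclass
class DyadCovariate:
    """One numeric value per ordered pair of actors (``w_ij``); diagonal ignored."""

    name: str
    values: np.ndarray
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"dyad covariate {self.name!r} must be a square matrix")
        if self.symmetric:
            off = ~np.eye(self.values.shape[0], dtype=bool)
            if not np.allclose(self.values[off], self.values.T[off]):
                raise ValueError(f"dyad covariate {self.name!r} declared symmetric but is not")


@dataclass
class HouseholdAssignment:
    """Household identifier per actor."""

    ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 1:
            raise ValueError("household ids must be one per actor")

    @property
    def count(self) -> int:
        return len(np.unique(self.ids))

    def same_household(self) -> np.ndarray:
        """Boolean matrix: True where two actors share a household."""
        return self.ids[:, None] == self.ids[None, :]


@dataclass
class VillageData:
    """All data for one village: reports, verified network, covariates."""

    giver_reports: DirectedNetwork | None
    receiver_reports: DirectedNetwork | None
    verified: DirectedNetwork | None
    actor_covariates: dict[str, ActorCovariate]
    dyad_covariates: dict[str, DyadCovariate]
    households: HouseholdAssignment
    absent_actors: set[str] = field(default_factory=set)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        for net in (self.giver_reports, self.receiver_reports, self.verified):
            if net is not None and net.n != n:
                raise ValueError("all networks must share the village actor count")
        for cov in self.actor_covariates.values():
            if len(cov.values) != n:
                raise ValueError(f"actor covariate {cov.name!r} length != n")
        for cov in self.dyad_covariates.values():
            if cov.values.shape[0] != n:
                raise ValueError(f"dyad covariate {cov.name!r} shape != (n, n)")
        if len(self.households.ids) != n:
            raise ValueError("household assignment length != n")
        unknown = self.absent_actors - set(self.labels)
        if unknown:
            raise ValueError(f"absent actors not in labels: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return len(self.labels)


# --------------------------------------------------------------------------
# network construction and preprocessing
# --------------------------------------------------------------------------


def build_verified_network(
    giver: DirectedNetwork,
    receiver: DirectedNetwork,
    absent: set[str] | None = None,
) -> DirectedNetwork:
    """Construct the mutual-assent ("double confirmation") aid network.

    A tie ``i -> j`` is present only when ``i`` reports giving aid to ``j``
    *and* ``j`` reports receiving aid from ``i``. Actors who were away and
    gave no reports are handled by the unilateral rule: a dyad with exactly
    one absent member takes the present member's report; a dyad between two
    absent members is coded absent.
    """
    if giver.n != receiver.n:
        raise ValueError("giver and receiver reports must share n")
    absent = absent or set()
    unknown = absent - set(giver.labels)
    if unknown:
        raise ValueError(f"absent identifiers not in network labels: {sorted(unknown)}")
    absent_idx = np.array([lab in absent for lab in giver.labels], dtype=bool)

    g = giver.ties.astype(bool)
    r = receiver.ties.astype(bool)
    x = g & r
    # For (i, j): giver report comes from i, receiver report from j.
    i_absent = absent_idx[:, None] & ~absent_idx[None, :]
    j_absent = ~absent_idx[:, None] & absent_idx[None, :]
    x = np.where(i_absent, r, x)  # only j's (receiver's) report available
    x = np.where(j_absent, g, x)  # only i's (giver's) report available
    both = absent_idx[:, None] & absent_idx[None, :]
    x = np.where(both, False, x)
    np.fill_diagonal(x, False)
    return DirectedNetwork(x.astype(np.int8), list(giver.labels), giver.observation_label)


_ZSCORE_COVARIATES = ("household_wealth", "household_size", "age", "melanin", "bmi")


def _zscore(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise ValueError(f"covariate {name!r} has zero variance; cannot standardise")
    return (values - values.mean()) / sd


def preprocess_covariates(village: VillageData) -> VillageData:
    """Apply the standard covariate transformations.

    Household wealth is natural-log transformed then z-scored; household
    size, age, melanin index and BMI are z-scored; geographic distance is
    transformed to ``ln(d + 1)``; the directed dyadic relative wealth rank
    (intra-village household wealth rank of ``i`` minus rank of ``j``) is
    derived. Binary covariates pass through untouched.
    """
    acov = dict(village.actor_covariates)
    dcov = dict(village.dyad_covariates)

    if "household_wealth" in acov and acov["household_wealth"].scaling == "raw":
        wealth = acov["household_wealth"].values
        if (wealth <= 0).any():
            raise ValueError("household wealth must be positive for log transform")
        # derive household wealth ranks before standardisation
        hh_ids = village.households.ids
        uniq = np.unique(hh_ids)
        hh_wealth = np.array([wealth[hh_ids == h][0] for h in uniq])
        # rank 1 = poorest household (ascending), matching a directed
        # difference rank_i - rank_j in [-(H-1), H-1]
        order = np.argsort(np.argsort(hh_wealth)) + 1
        rank_by_hh = dict(zip(uniq.tolist(), order.tolist()))
        actor_rank = np.array([rank_by_hh[h] for h in hh_ids], dtype=float)
        rel_rank = actor_rank[:, None] - actor_rank[None, :]
        dcov["relative_wealth_rank"] = DyadCovariate("relative_wealth_rank", rel_rank)
        acov["household_wealth"] = ActorCovariate(
            "household_wealth", _zscore(np.log(wealth), "household_wealth"), "zscore"
        )

    for name in _ZSCORE_COVARIATES[1:]:
        if name in acov and acov[name].scaling == "raw":
            acov[name] = ActorCovariate(name, _zscore(acov[name].values, name), "zscore")

    if "distance" in dcov:
        d = dcov["distance"].values
        if (d < 0).any():
            raise ValueError("geographic distances must be non-negative")
        if d.max() > 50:  # raw metres rather than an already-logged matrix
            dcov["distance"] = DyadCovariate("distance", np.log(d + 1.0), symmetric=True)

    return replace(village, actor_covariates=acov, dyad_covariates=dcov)


# --------------------------------------------------------------------------
# descriptive statistics
# --------------------------------------------------------------------------


def density(net: DirectedNetwork) -> float:
    """Proportion of the n(n-1) ordered pairs that are tied."""
    n = net.n
    return net.arc_count / (n * (n - 1))


def reciprocity_proportion(net: DirectedNetwork) -> float:
    """Proportion of arcs ``i -> j`` for which ``j -> i`` is also present."""
    arcs = net.arc_count
    if arcs == 0:
        warnings.warn("reciprocity undefined for an empty network", stacklevel=2)
        return math.nan
    mutual = int((net.ties & net.ties.T).sum())
    return mutual / arcs


def transitivity_weak(net: DirectedNetwork) -> float:
    """Weak-rule transitivity: fraction of directed two-paths that are closed.

    A two-path is an ordered triple of distinct actors ``(i, h, j)`` with
    ``i -> h`` and ``h -> j``; it is closed when ``i -> j``. The ratio of
    closed to total two-paths is the weak-rule graph transitivity.
    """
    x = net.ties.astype(np.int64)
    x2 = x @ x
    np.fill_diagonal(x2, 0)  # exclude i == j (and i == h, h == j are impossible)
    two_paths = int(x2.sum())
    if two_paths == 0:
        warnings.warn("transitivity undefined: no two-paths", stacklevel=2)
        return math.nan
    closed = int((x2 * x).sum())
    return closed / two_paths


def degree_summaries(net: DirectedNetwork) -> dict[str, float]:
    """Mean degree and population-sd / max of out- and in-degrees.

    The standard deviations use the population formula (divide by ``n``):
    the network is a census of a complete population, not a sample.
    """
    outd = net.out_degrees().astype(float)
    ind = net.in_degrees().astype(float)
    return {
        "mean_degree": float(outd.mean()),
        "sd_out": float(outd.std()),
        "sd_in": float(ind.std()),
        "max_out": int(outd.max()),
        "max_in": int(ind.max()),
        "sd_formula": "population",
    }


# --------------------------------------------------------------------------
# triad census
# --------------------------------------------------------------------------

TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)


def _classify_triad(tab: int, tba: int, tac: int, tca: int, tbc: int, tcb: int) -> str:
    """Classify one labelled triple into its M-A-N isomorphism class.

    Dyad states: mutual (both arcs), asymmetric (one arc), null (none).
    Lettered variants follow the standard convention: for 021/120, "D"(own)
    is the out-star / arcs leaving the distinguished actor, "U"(p) the
    in-star; "C" the mixed path; 111D has the lone arc pointing into the
    mutual dyad, 111U out of it; 030T is the transitive, 030C the cyclic
    triple.
    """
    dyads = [(tab, tba), (tac, tca), (tbc, tcb)]
    m = sum(1 for a, b in dyads if a and b)
    a_ = sum(1 for a, b in dyads if a != b)
    n_ = 3 - m - a_
    code = f"{m}{a_}{n_}"
    if code in ("003", "012", "102", "201", "210", "300"):
        return code

    arcs = []
    for (u, v), (fwd, bwd) in zip(((0, 1), (0, 2), (1, 2)), dyads):
        if fwd:
            arcs.append((u, v))
        if bwd:
            arcs.append((v, u))

    if code == "021":
        (s1, t1), (s2, t2) = arcs
        if s1 == s2:
            return "021D"
        if t1 == t2:
            return "021U"
        return "021C"
    if code == "030":
        sources = {s for s, _ in arcs}
        return "030C" if len(sources) == 3 else "030T"
    if code == "111":
        mutual_pair = next({u, v} for (u, v), (f, b) in
                           zip(((0, 1), (0, 2), (1, 2)), dyads) if f and b)
        # the asymmetric arc: exactly one endpoint outside the mutual dyad
        for s, t in arcs:
            if s not in mutual_pair:
                return "111D"  # outsider sends into the dyad
            if t not in mutual_pair:
                return "111U"  # dyad sends out to the outsider
        raise AssertionError("unreachable 111 configuration")
    if code == "120":
        mutual_pair = next({u, v} for (u, v), (f, b) in
                           zip(((0, 1), (0, 2), (1, 2)), dyads) if f and b)
        outsider = ({0, 1, 2} - mutual_pair).pop()
        asym = [(s, t) for s, t in arcs if outsider in (s, t)]
        if all(s == outsider for s, t in asym):
            return "120D"
        if all(t == outsider for s, t in asym):
            return "120U"
        return "120C"
    raise AssertionError(f"unclassifiable dyad code {code}")


def _triad_lookup() -> np.ndarray:
    """64-entry table from the 6-bit tie pattern of a triple to a class index."""
    table = np.empty(64, dtype=np.int8)
    for bits in range(64):
        t = [(bits >> k) & 1 for k in range(6)]
        table[bits] = TRIAD_CLASSES.index(_classify_triad(*t))
    return table


_TRIAD_TABLE = _triad_lookup()


def triad_census(net: DirectedNetwork) -> dict[str, int]:
    """Count the 16 M-A-N triad classes over all unordered actor triples."""
    n = net.n
    if n < 3:
        raise ValueError("triad census requires n >= 3")
    x = net.ties
    triples = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    codes = (
        x[a, b].astype(np.int32)
        | (x[b, a].astype(np.int32) << 1)
        | (x[a, c].astype(np.int32) << 2)
        | (x[c, a].astype(np.int32) << 3)
        | (x[b, c].astype(np.int32) << 4)
        | (x[c, b].astype(np.int32) << 5)
    )
    counts = np.bincount(_TRIAD_TABLE[codes], minlength=16)
    return dict(zip(TRIAD_CLASSES, counts.tolist()))


# --------------------------------------------------------------------------
# clique census
# --------------------------------------------------------------------------


def clique_census(net: DirectedNetwork) -> dict[int, int]:
    """Counts of inclusion-maximal fully mutual vertex sets, by size.

    A "clique" here requires every ordered pair inside the set to be tied in
    both directions (completeness in a directed graph means mutuality).
    Actors in no mutual dyad appear as maximal size-1 cliques, so every
    actor belongs to at least one maximal clique.
    """
    mutual = net.ties & net.ties.T
    g = nx.from_numpy_array(mutual, create_using=nx.Graph)
    counts: dict[int, int] = {}
    for clq in nx.find_cliques(g):
        counts[len(clq)] = counts.get(len(clq), 0) + 1
    return dict(sorted(counts.items()))


# --------------------------------------------------------------------------
# geodesics
# --------------------------------------------------------------------------


def geodesic_distribution(
    net: DirectedNetwork, max_distance: int = 5, pool_beyond: bool = True
) -> dict[str, int]:
    """Counts of ordered pairs by directed shortest-path length.

    Distances ``1..max_distance`` are kept separately; by default anything
    longer is pooled with unreachable pairs into one ``"inf"`` bucket (set
    ``pool_beyond=False`` to keep a separate ``">max"`` bucket). Buckets sum
    to ``n(n-1)``.
    """
    d = shortest_path(net.ties.astype(float), method="D", unweighted=True)
    off = ~np.eye(net.n, dtype=bool)
    vals = d[off]
    out: dict[str, int] = {}
    for k in range(1, max_distance + 1):
        out[str(k)] = int((vals == k).sum())
    beyond = int(((vals > max_distance) & np.isfinite(vals)).sum())
    unreachable = int(np.isinf(vals).sum())
    if pool_beyond:
        out["inf"] = beyond + unreachable
    else:
        out[f">{max_distance}"] = beyond
        out["inf"] = unreachable
    return out


# --------------------------------------------------------------------------
# kin-structured summaries
# --------------------------------------------------------------------------


def consanguineous_tie_distribution(
    net: DirectedNetwork, relatedness: DyadCovariate, atol: float = 1e-9
) -> dict[float, int]:
    """Arc counts binned by the exact relatedness coefficient of the dyad.

    Pedigree-derived coefficients are dyadic rationals (0.5, 0.25, 0.125,
    ...), so bins use exact value matching with a small tolerance. Bin
    totals sum to the arc count.
    """
    r = relatedness.values
    if (r < -atol).any() or (r > 1 + atol).any():
        raise ValueError("relatedness coefficients must lie in [0, 1]")
    src, dst = np.nonzero(net.ties)
    arc_r = r[src, dst]
    values = np.unique(np.round(r[~np.eye(net.n, dtype=bool)] / atol) * atol)
    out: dict[float, int] = {}
    for v in sorted(values, reverse=True):
        mask = np.abs(arc_r - v) <= atol
        out[float(v)] = int(mask.sum())
    return out


def graph_correlation(a: DirectedNetwork, b: DirectedNetwork) -> float:
    """Pearson product-moment correlation over the off-diagonal cells."""
    if a.n != b.n:
        raise ValueError("networks must share n")
    off = ~np.eye(a.n, dtype=bool)
    va, vb = a.ties[off].astype(float), b.ties[off].astype(float)
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("graph correlation undefined: a network has zero variance",
                      stacklevel=2)
        return math.nan
    return float(np.corrcoef(va, vb)[0, 1])


def kin_triad_composition(
    net: DirectedNetwork,
    consanguineal: DyadCovariate,
    affinal: DyadCovariate,
    threshold: float = 0.125,
    classes: tuple[str, ...] = ("300", "210", "030T", "021U"),
) -> dict[str, tuple[int, int]]:
    """Per-triad-class share of triads whose members are pairwise close kin.

    For each requested M-A-N class, returns ``(entirely_close_kin, total)``
    where a triad counts as entirely close kin when all three unordered
    dyads satisfy ``max(consanguineal, affinal) >= threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    x = net.ties
    n = net.n
    kin = np.maximum(consanguineal.values, affinal.values) >= threshold
    triples = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    codes = (
        x[a, b].astype(np.int32)
        | (x[b, a].astype(np.int32) << 1)
        | (x[a, c].astype(np.int32) << 2)
        | (x[c, a].astype(np.int32) << 3)
        | (x[b, c].astype(np.int32) << 4)
        | (x[c, b].astype(np.int32) << 5)
    )
    cls = _TRIAD_TABLE[codes]
    all_kin = kin[a, b] & kin[a, c] & kin[b, c]
    out: dict[str, tuple[int, int]] = {}
    for name in classes:
        idx = TRIAD_CLASSES.index(name)
        mask = cls == idx
        out[name] = (int((mask & all_kin).sum()), int(mask.sum()))
    return out
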