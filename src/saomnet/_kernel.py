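"""Compiled ministep chain for plain (unscored) simulation runs.

Any evaluation function built from the effects library collapses to a
compact form: covariate effects (out-degree, dyadic X, alter/ego/same/
similarity) contribute a fixed dyadic gain matrix ``A``; reciprocity and
XRecip contribute a matrix ``B`` entering as ``x_ji * B_ij``; the nine
purely structural effects occupy fixed weight slots evaluated from the
live adjacency. A single numba kernel then runs whole chains at a few
microseconds per ministep. The numpy effects path remains the reference
implementation (and is used whenever per-effect change statistics must be
accumulated, e.g. for score vectors); agreement between the two paths is
covered by tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .effects import EvaluationFunction

__all__ = ["CompiledModel", "compile_evaluation", "run_compiled_chain"]

# structural slots: outAct inPop outPop transTrip transRecTrip threeCycle
#                   denseTriads transTripJump sharedPop
_SLOTS = {
    "outAct": 0, "inPop": 1, "outPop": 2, "transTrip": 3, "transRecTrip": 4,
    "threeCycle": 5, "denseTriads": 6, "transTripJump": 7, "sharedPop": 8,
}


class CompiledModel:
    __slots__ = ("A", "B", "sb", "hh")

    def __init__(self, A, B, sb, hh):
        self.A, self.B, self.sb, self.hh = A, B, sb, hh


def compile_evaluation(evalfn: EvaluationFunction) -> CompiledModel:
    """Fold an evaluation function into (A, B, structural-slot) form."""
    village = evalfn.village
    n = village.n
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    sb = np.zeros(len(_SLOTS))
    hh = np.asarray(village.households.ids, dtype=np.int64)
    for spec, bound in zip(evalfn.effects, evalfn._bound):
        beta = spec.beta
        if beta == 0.0:
            continue
        s = spec.shortname
        if s == "outdegree":
            A += beta
        elif s == "X":
            A += beta * bound.w
        elif s == "alter":
            A += beta * bound.v[None, :]
        elif s == "ego":
            A += beta * bound.v[:, None]
        elif s == "same":
            A += beta * (bound.v[:, None] == bound.v[None, :])
        elif s == "similarity":
            A += beta * (bound.sim - bound.sim_mean)
        elif s == "recip":
            B += beta
        elif s == "XRecip":
            B += beta * bound.w
        elif s in _SLOTS:
            sb[_SLOTS[s]] += beta
        else:  # pragma: no cover - defensive
            raise ValueError(f"effect {spec.name!r} cannot be compiled")
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(B, 0.0)
    return CompiledModel(A, B, sb, hh)


def run_compiled_chain(state, compiled: CompiledModel,
                       actors: np.ndarray, unif: np.ndarray) -> None:
    """Advance ``state`` in place by ``len(actors)`` ministeps."""
    _chain(state.x, state.outdeg, state.indeg, state.mutual,
           compiled.A, compiled.B, compiled.sb, compiled.hh,
           actors.astype(np.int64), unif)


@njit(cache=True)
def _chain(x, outdeg, indeg, mutual, A, B, sb, hh, actors, unif):
    n = x.shape[0]
    steps = actors.shape[0]
    g = np.empty(n + 1)
    p = np.empty(n + 1)
    rx = np.empty(n)
    xr = np.empty(n)
    xrc = np.empty(n)
    xc = np.empty(n)
    mmi = np.empty(n)
    cl = np.empty(n)
    mid = np.empty(n)
    cvec = np.empty(n)
    spb = np.empty(n)

    use_tt = sb[3] != 0.0
    use_trt = sb[4] != 0.0
    use_3c = sb[5] != 0.0
    use_dn = sb[6] != 0.0
    use_jp = sb[7] != 0.0
    use_sp = sb[8] != 0.0

    for t in range(steps):
        i = actors[t]
        di = outdeg[i]

        if use_tt or use_trt:
            for j in range(n):
                rx[j] = 0.0
                xr[j] = 0.0
                xrc[j] = 0.0
            for h in range(n):
                if x[i, h] > 0.0:
                    both = x[h, i] > 0.0
                    for j in range(n):
                        rx[j] += x[h, j]
                        xr[j] += x[j, h]
                        if both:
                            xrc[j] += x[j, h]
        if use_3c:
            for j in range(n):
                xc[j] = 0.0
            for h in range(n):
                if x[h, i] > 0.0:
                    for j in range(n):
                        xc[j] += x[j, h]
        if use_dn:
            for j in range(n):
                mmi[j] = 0.0
            for h in range(n):
                if mutual[i, h] > 0.0:
                    for j in range(n):
                        mmi[j] += mutual[j, h]
        if use_jp:
            for j in range(n):
                cl[j] = 0.0
                mid[j] = 0.0
            for h in range(n):
                if x[i, h] > 0.0:
                    if hh[h] == hh[i]:
                        for j in range(n):
                            cl[j] += x[h, j]
                    else:
                        for j in range(n):
                            mid[j] += x[j, h]
        if use_sp:
            for h in range(n):
                cvec[h] = 0.0
            for jp in range(n):
                if x[i, jp] > 0.0:
                    for h in range(n):
                        cvec[h] += x[h, jp]
            for j in range(n):
                spb[j] = 0.0
            for h in range(n):
                if h != i and cvec[h] > 0.0:
                    for j in range(n):
                        spb[j] += cvec[h] * x[h, j]

        gmax = 0.0
        for j in range(n):
            if j == i:
                g[j] = -1.0e300
                continue
            xij = x[i, j]
            xji = x[j, i]
            dlt = 1.0 - 2.0 * xij
            gj = dlt * (A[i, j] + xji * B[i, j])
            if sb[0] != 0.0:
                gj += sb[0] * (2.0 * di * dlt + 1.0)
            if sb[1] != 0.0:
                gj += sb[1] * dlt * (indeg[j] - xij + 1.0)
            if sb[2] != 0.0:
                gj += sb[2] * dlt * outdeg[j]
            if use_tt:
                gj += sb[3] * dlt * (rx[j] + xr[j])
            if use_trt:
                gj += sb[4] * dlt * (xji * rx[j] + xrc[j])
            if use_3c:
                gj += sb[5] * dlt * xc[j]
            if use_dn:
                gj += sb[6] * dlt * xji * mmi[j]
            if use_jp:
                if hh[j] == hh[i]:
                    gj += sb[7] * dlt * mid[j]
                else:
                    gj += sb[7] * dlt * cl[j]
            if use_sp:
                gj += sb[8] * (dlt * spb[j] + xij * (indeg[j] - xij))
            g[j] = gj
            if gj > gmax:
                gmax = gj
        g[n] = 0.0

        total = 0.0
        for j in range(n + 1):
            if j == i:
                p[j] = 0.0
            else:
                p[j] = np.exp(g[j] - gmax)
            total += p[j]

        r = unif[t] * total
        cum = 0.0
        choice = n
        for j in range(n + 1):
            cum += p[j]
            if r < cum:
                choice = j
                break

        if choice < n:
            new = 1.0 - x[i, choice]
            x[i, choice] = new
            dlt = 2.0 * new - 1.0
            outdeg[i] += dlt
            indeg[choice] += dlt
            m = new * x[choice, i]
            mutual[i, choice] = m
            mutual[choice, i] = m
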