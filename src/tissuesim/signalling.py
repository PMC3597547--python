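"""Delta-Notch lateral inhibition coupled through the neighbour graph.

Each cell carries the two-variable Collier-type system

    dn/dt = F(d_bar) - n,        F(x) = x^k / (a + x^k)
    dd/dt = v * (G(n) - d),      G(n) = 1 / (1 + b n^h)

where d_bar is the *mean* Delta activity of the cell's current neighbours
(isolated cells see d_bar = 0).  High neighbour Delta activates a cell's
Notch, which suppresses its own Delta — the feedback that generates the
alternating high/low (checkerboard-like) patterns of lateral inhibition.

The tissue update is synchronous: d_bar is computed for all cells from the
current states, then every cell's ODEs are advanced over dt (RK4) with its
d_bar frozen.  This makes the update order-independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import solve_ode

__all__ = ["CollierParams", "delta_notch_rhs", "DeltaNotchLayer",
           "step_signalling", "neighbour_delta_correlation",
           "homogeneous_fixed_point", "UNDEFINED_CORRELATION"]

UNDEFINED_CORRELATION = float("nan")


@dataclass
class CollierParams:
    a: float = 0.01    # Hill offset of Notch activation
    b: float = 100.0   # strength of Delta inhibition by Notch
    v: float = 1.0     # Delta kinetics relative to Notch
    k: float = 2.0     # Hill exponent, activation
    h: float = 2.0     # Hill exponent, inhibition

    def __post_init__(self):
        if min(self.a, self.b, self.v) <= 0 or self.k < 1 or self.h < 1:
            raise ValueError("Collier parameters out of range")

    def F(self, x):
        xk = np.power(x, self.k)
        return xk / (self.a + xk)

    def G(self, n):
        return 1.0 / (1.0 + self.b * np.power(n, self.h))


def delta_notch_rhs(state, d_bar: float, params: CollierParams) -> np.ndarray:
    """(dn/dt, dd/dt) for one cell given its neighbours' mean Delta."""
    n, d = float(state[0]), float(state[1])
    if n < -1e-9 or d < -1e-9 or d_bar < -1e-9:
        raise ValueError("Delta-Notch states and inputs must be non-negative")
    # tolerate infinitesimal negatives from RK stage extrapolation
    n, d, d_bar = max(n, 0.0), max(d, 0.0), max(d_bar, 0.0)
    dn = params.F(d_bar) - n
    dd = params.v * (params.G(n) - d)
    return np.array([dn, dd])


def homogeneous_fixed_point(params: CollierParams,
                            tol: float = 1e-14) -> tuple[float, float]:
    """(n*, d*) with n* = F(d*), d* = G(n*) by bisection on d - G(F(d)).

    phi(d) = d - G(F(d)) is increasing from negative at 0 to positive at 1,
    so a unique root exists in [0, 1].
    """
    def phi(d):
        return d - params.G(params.F(d))
    lo, hi = 0.0, 1.0
    if phi(lo) > 0 or phi(hi) < 0:
        raise RuntimeError("fixed point not bracketed in [0, 1]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if phi(mid) <= 0:
            lo = mid
        else:
            hi = mid
    d_star = 0.5 * (lo + hi)
    return float(params.F(d_star)), float(d_star)


# ---------------------------------------------------------------------------
# Tissue-level synchronous stepping
# ---------------------------------------------------------------------------

def _mean_neighbour_delta(ids, neighbour_pairs, delta):
    """Mean Delta over each cell's neighbours; isolated cells get 0."""
    acc = {i: 0.0 for i in ids}
    cnt = {i: 0 for i in ids}
    for a, b in neighbour_pairs:
        acc[a] += delta[b]
        acc[b] += delta[a]
        cnt[a] += 1
        cnt[b] += 1
    return {i: (acc[i] / cnt[i] if cnt[i] else 0.0) for i in ids}


def step_signalling(population, states: dict, params: CollierParams,
                    dt: float, substeps: int = 1) -> dict:
    """Advance all cells' Delta-Notch ODEs over dt (synchronous coupling).

    `states` maps cell id -> (n, d).  d_bar is computed once from the current
    states and held frozen while every cell is advanced by RK4 (vectorized
    over the population) with `substeps` internal steps.  Returns the new
    state map.
    """
    ids = sorted(states)
    index = {i: k for k, i in enumerate(ids)}
    n = np.array([states[i][0] for i in ids], dtype=float)
    d = np.array([states[i][1] for i in ids], dtype=float)
    if n.min(initial=0.0) < -1e-9 or d.min(initial=0.0) < -1e-9:
        raise ValueError("Delta-Notch states must be non-negative")
    acc = np.zeros(len(ids))
    cnt = np.zeros(len(ids))
    for a, b in population.neighbour_pairs():
        if a in index and b in index:
            ia, ib = index[a], index[b]
            acc[ia] += d[ib]
            acc[ib] += d[ia]
            cnt[ia] += 1
            cnt[ib] += 1
    d_bar = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    F_bar = params.F(d_bar)            # frozen over the step

    def rhs(y):
        dn = F_bar - y[0]
        dd = params.v * (params.G(np.maximum(y[0], 0.0)) - y[1])
        return np.array([dn, dd])

    y = np.array([n, d])
    h = dt / substeps
    for _ in range(substeps):
        k1 = rhs(y)
        k2 = rhs(y + h / 2 * k1)
        k3 = rhs(y + h / 2 * k2)
        k4 = rhs(y + h * k3)
        y = np.maximum(y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return {i: np.array([y[0, k], y[1, k]]) for k, i in enumerate(ids)}


def neighbour_delta_correlation(population, states: dict) -> float:
    """Pearson correlation of Delta across neighbour pairs (both orientations).

    Negative values indicate the alternating high/low lateral-inhibition
    pattern.  All-equal Delta has zero variance: returns NaN (undefined).
    """
    pairs = [(a, b) for a, b in population.neighbour_pairs()
             if a in states and b in states]
    if len(pairs) < 2:
        raise ValueError("need at least 2 neighbour pairs")
    x, y = [], []
    for a, b in pairs:
        x += [states[a][1], states[b][1]]
        y += [states[b][1], states[a][1]]
    x, y = np.array(x), np.array(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return UNDEFINED_CORRELATION
    return float(np.corrcoef(x, y)[0, 1])


class DeltaNotchLayer:
    """Per-cell Delta-Notch states riding on a simulator's population.

    Plugs into :class:`~tissuesim.cell_based.Simulator` as the signalling
    phase.  Daughters inherit the parent's state at division.  Delta and
    Notch are mirrored into ``cell.data`` for output writers.
    """

    def __init__(self, params: CollierParams | None = None,
                 initial_states: dict | None = None,
                 stream=None, noise: float = 0.05, substeps: int = 1):
        self.params = params or CollierParams()
        self.states = dict(initial_states or {})
        self._stream = stream
        self.noise = noise
        self.substeps = substeps

    def ensure_states(self, population):
        n_star, d_star = homogeneous_fixed_point(self.params)
        for cell in population.living_cells():
            if cell.id not in self.states:
                n0, d0 = n_star, d_star
                if self._stream is not None and self.noise > 0:
                    n0 = max(0.0, n0 + self.noise * float(self._stream.uniform(-1, 1)))
                    d0 = max(0.0, d0 + self.noise * float(self._stream.uniform(-1, 1)))
                self.states[cell.id] = np.array([n0, d0])

    def on_division(self, parent: int, daughter: int):
        if parent in self.states:
            self.states[daughter] = self.states[parent].copy()

    def step(self, population, dt: float):
        self.ensure_states(population)
        living = {c.id for c in population.living_cells()}
        self.states = {i: s for i, s in self.states.items() if i in living}
        self.states = step_signalling(population, self.states, self.params,
                                      dt, self.substeps)
        for cell in population.living_cells():
            n, d = self.states[cell.id]
            cell.data["notch"] = float(n)
            cell.data["delta"] = float(d)
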