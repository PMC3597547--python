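"""Monodomain cardiac electrophysiology with the Luo-Rudy 1991 cell model.

The guinea-pig ventricular action-potential model of Luo & Rudy (1991) has
eight states — transmembrane voltage V (mV), six Hodgkin-Huxley gates
(m, h, j for the fast sodium current; d, f for the slow inward calcium
current; X for the time-dependent potassium current) — plus intracellular
calcium Cai (mM).  Six membrane currents (fast Na+, slow inward, time-
dependent K+, time-independent K+, plateau K+, background) sum to I_ion and

    dV/dt = -(I_ion + I_stim) / C_m .

Tissue propagation uses the monodomain equation

    chi * C_m * dV/dt = div(sigma grad V) - chi * (I_ion + I_stim)

solved by Godunov operator splitting: a per-node cell-model step
(Rush-Larsen exponential updates for the gates, forward Euler for V and
Cai) followed by an implicit-Euler diffusion step with zero-flux boundaries.

Units throughout: mV, ms, cm, uA/cm^2, mS/cm^2 (conductances), mS/cm
(tissue conductivity), uF/cm^2, mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "LR91Params", "LR91State", "lr91_rhs", "lr91_rates", "lr91_currents",
    "lr91_steady_gates", "find_rest_state", "step_cell",
    "RegularGrid2D", "MonodomainProblem", "monodomain_step", "run_monodomain",
    "Stimulus", "s1s2_cross_field", "spiral_preset",
    "APTrace", "compute_apd", "activation_times", "conduction_velocity",
    "conduction_velocity_regression", "pseudo_ecg", "NO_AP", "CardiacError",
]

NO_AP = None          # sentinel returned when a trace holds no action potential


class CardiacError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Luo-Rudy 1991 membrane model
# ---------------------------------------------------------------------------

# physical constants and ionic concentrations of the model
_R = 8314.0        # mJ / (mol K)
_T = 310.0         # K
_F = 96484.6       # C / mol
_RTF = _R * _T / _F

_Ko, _Ki = 5.4, 145.0
_Nao, _Nai = 140.0, 18.0
_PR_NaK = 0.01833

E_NA = _RTF * np.log(_Nao / _Nai)
E_K = _RTF * np.log((_Ko + _PR_NaK * _Nao) / (_Ki + _PR_NaK * _Nai))
E_K1 = _RTF * np.log(_Ko / _Ki)
E_KP = E_K1

GATE_NAMES = ("m", "h", "j", "d", "f", "X")
STATE_NAMES = ("V",) + GATE_NAMES + ("Cai",)


@dataclass
class LR91Params:
    """Maximal conductances with per-current scaling and gate-rate scaling.

    `conductance_scale` multiplies the base conductances (ion-channel
    expression changes); `rate_scale` multiplies both alpha and beta of a
    gate, shortening its time constant without moving its steady state.
    """
    g_Na: float = 23.0
    g_si: float = 0.09
    g_K: float = 0.282 * np.sqrt(_Ko / 5.4)
    g_K1: float = 0.6047 * np.sqrt(_Ko / 5.4)
    g_Kp: float = 0.0183
    g_b: float = 0.03921
    C_m: float = 1.0                      # uF/cm^2
    conductance_scale: dict = field(default_factory=dict)
    rate_scale: dict = field(default_factory=dict)

    def g(self, name: str) -> float:
        base = getattr(self, f"g_{name}")
        return base * self.conductance_scale.get(name, 1.0)


@dataclass
class LR91State:
    """Single-cell state vector (also usable as arrays for tissue)."""
    V: float | np.ndarray
    m: float | np.ndarray
    h: float | np.ndarray
    j: float | np.ndarray
    d: float | np.ndarray
    f: float | np.ndarray
    X: float | np.ndarray
    Cai: float | np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.j,
                         self.d, self.f, self.X, self.Cai], dtype=float)

    @classmethod
    def from_vector(cls, y):
        return cls(*[np.asarray(v, dtype=float) if np.ndim(v) else float(v)
                     for v in y])

    def copy(self):
        return LR91State(*[np.array(getattr(self, n), dtype=float, copy=True)
                           if np.ndim(getattr(self, n)) else getattr(self, n)
                           for n in STATE_NAMES])


def _safe_ratio(num, den, limit):
    """num/den with the removable singularity at den=0 replaced by `limit`."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-9
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def lr91_rates(V, params: LR91Params | None = None) -> dict:
    """alpha/beta of the six gates at voltage V (vectorized).

    Non-finite rates raise, naming the offending gate.
    """
    params = params or LR91Params()
    V = np.asarray(V, dtype=float)
    rates = {}

    x = V + 47.13
    a_m = 0.32 * _safe_ratio(x, 1.0 - np.exp(-0.1 * x), 10.0)
    b_m = 0.08 * np.exp(-V / 11.0)
    rates["m"] = (a_m, b_m)

    lo = V < -40.0
    a_h = np.where(lo, 0.135 * np.exp((80.0 + V) / -6.8), 0.0)
    b_h = np.where(lo,
                   3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                   1.0 / (0.13 * (1.0 + np.exp((V + 10.66) / -11.1))))
    rates["h"] = (a_h, b_h)

    with np.errstate(over="ignore"):
        a_j = np.where(
            lo,
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
            0.0)
        b_j = np.where(
            lo,
            0.1212 * np.exp(-0.01052 * V)
            / (1.0 + np.exp(-0.1378 * (V + 40.14))),
            0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))))
    rates["j"] = (a_j, b_j)

    a_d = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
    b_d = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
    rates["d"] = (a_d, b_d)

    a_f = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
    b_f = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
    rates["f"] = (a_f, b_f)

    a_X = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
    b_X = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))
    rates["X"] = (a_X, b_X)

    for gate, (a, b) in rates.items():
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise CardiacError(f"non-finite rate for gate {gate!r}")
        s = params.rate_scale.get(gate, 1.0)
        if s != 1.0:
            rates[gate] = (a * s, b * s)
    return rates


def lr91_steady_gates(V, params: LR91Params | None = None) -> dict:
    """Gate steady states y_inf(V) = alpha / (alpha + beta)."""
    rates = lr91_rates(V, params)
    return {g: a / (a + b) for g, (a, b) in rates.items()}


def _xi_factor(V):
    """Inward-rectification factor Xi of the time-dependent K+ current."""
    V = np.asarray(V, dtype=float)
    x = V + 77.0
    with np.errstate(over="ignore"):
        xi_hi = 2.837 * _safe_ratio(np.exp(0.04 * x) - 1.0, x, 0.04) \
            / np.exp(0.04 * (V + 35.0))
    return np.where(V > -100.0, xi_hi, 1.0)


def lr91_currents(state: LR91State, params: LR91Params | None = None) -> dict:
    """The six membrane currents (uA/cm^2)."""
    p = params or LR91Params()
    V, Cai = state.V, state.Cai
    E_si = 7.7 - 13.0287 * np.log(Cai)
    I = {}
    I["Na"] = p.g("Na") * state.m ** 3 * state.h * state.j * (V - E_NA)
    I["si"] = p.g("si") * state.d * state.f * (V - E_si)
    I["K"] = p.g("K") * state.X * _xi_factor(V) * (V - E_K)
    # time-independent K+: gated by the instantaneous K1_inf
    a_K1 = 1.02 / (1.0 + np.exp(0.2385 * (V - E_K1 - 59.215)))
    b_K1 = ((0.49124 * np.exp(0.08032 * (V - E_K1 + 5.476))
             + np.exp(0.06175 * (V - E_K1 - 594.31)))
            / (1.0 + np.exp(-0.5143 * (V - E_K1 + 4.753))))
    I["K1"] = p.g("K1") * a_K1 / (a_K1 + b_K1) * (V - E_K1)
    Kp = 1.0 / (1.0 + np.exp((7.488 - V) / 5.98))
    I["Kp"] = p.g("Kp") * Kp * (V - E_KP)
    I["b"] = p.g("b") * (V + 59.87)
    return I


def lr91_rhs(state: LR91State, I_stim=0.0,
             params: LR91Params | None = None) -> np.ndarray:
    """Full model right-hand side, ordered as (V, m, h, j, d, f, X, Cai)."""
    p = params or LR91Params()
    I = lr91_currents(state, p)
    I_ion = sum(I.values())
    dV = -(I_ion + I_stim) / p.C_m
    rates = lr91_rates(state.V, p)
    dgates = [rates[g][0] * (1.0 - getattr(state, g))
              - rates[g][1] * getattr(state, g) for g in GATE_NAMES]
    dCai = -1e-4 * I["si"] + 0.07 * (1e-4 - state.Cai)
    return np.array([dV, *dgates, dCai])


def lr91_rhs_vector(t, y, I_stim=0.0, params: LR91Params | None = None):
    """Adapter for generic ODE drivers: y is the 8-vector (V..Cai)."""
    return lr91_rhs(LR91State.from_vector(y), I_stim, params)


def find_rest_state(params: LR91Params | None = None) -> LR91State:
    """Quiescent equilibrium by 1D bisection on total ionic current.

    All gates sit at their steady states and Cai at its own balance
    (dCai/dt = 0 given I_si), leaving a scalar root problem in V.
    """
    p = params or LR91Params()

    def total_current(V):
        gates = lr91_steady_gates(V, p)
        # Cai balance: -1e-4 I_si + 0.07 (1e-4 - Cai) = 0, I_si depends on Cai
        Cai = 2e-4
        for _ in range(200):
            E_si = 7.7 - 13.0287 * np.log(Cai)
            I_si = p.g("si") * gates["d"] * gates["f"] * (V - E_si)
            Cai_new = 1e-4 - (1e-4 / 0.07) * I_si
            if Cai_new <= 0:
                Cai_new = 1e-12
            if abs(Cai_new - Cai) < 1e-18:
                Cai = Cai_new
                break
            Cai = Cai_new
        st = LR91State(V, gates["m"], gates["h"], gates["j"],
                       gates["d"], gates["f"], gates["X"], Cai)
        return sum(lr91_currents(st, p).values()), st

    lo, hi = -95.0, -75.0
    f_lo, _ = total_current(lo)
    f_hi, _ = total_current(hi)
    if f_lo * f_hi > 0:
        raise CardiacError("rest state not bracketed in [-95, -75] mV")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid, st = total_current(mid)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 1e-13:
            break
    _, st = total_current(0.5 * (lo + hi))
    return st


def step_cell(state: LR91State, dt: float, I_stim=0.0,
              params: LR91Params | None = None) -> LR91State:
    """One Rush-Larsen / forward-Euler step (works on scalars or node arrays).

    Gates update exponentially with frozen rates (clamped to [0,1]); V and
    Cai by forward Euler.  V leaving [-120, 80] mV raises, advising a
    smaller dt.
    """
    if dt > 0.1:
        raise CardiacError("dt must be <= 0.1 ms for the split cell step")
    p = params or LR91Params()
    I = lr91_currents(state, p)
    I_ion = I["Na"] + I["si"] + I["K"] + I["K1"] + I["Kp"] + I["b"]
    V_new = state.V - dt * (I_ion + I_stim) / p.C_m
    if np.any(V_new < -120.0) or np.any(V_new > 80.0):
        raise CardiacError(
            "membrane voltage left [-120, 80] mV: reduce dt (instability)")
    rates = lr91_rates(state.V, p)
    new = {"V": V_new}
    for g in GATE_NAMES:
        a, b = rates[g]
        tau_inv = a + b
        y_inf = a / tau_inv
        y = getattr(state, g)
        y_new = y_inf + (y - y_inf) * np.exp(-dt * tau_inv)
        new[g] = np.clip(y_new, 0.0, 1.0)
    dCai = -1e-4 * I["si"] + 0.07 * (1e-4 - state.Cai)
    new["Cai"] = np.maximum(state.Cai + dt * dCai, 1e-12)
    return LR91State(**new)


# ---------------------------------------------------------------------------
# Tissue substrate and monodomain solver
# ---------------------------------------------------------------------------

class RegularGrid2D:
    """nx x ny node lattice with spacing dx (cm) and a 5-point Laplacian."""

    def __init__(self, nx: int, ny: int, dx: float):
        if nx < 2 or ny < 1 or dx <= 0:
            raise ValueError("grid needs nx >= 2, ny >= 1, dx > 0")
        self.nx, self.ny, self.dx = nx, ny, dx
        xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dx,
                             indexing="ij")
        self.points = np.column_stack([xs.ravel(), ys.ravel()])

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def index(self, i: int, j: int) -> int:
        return i * self.ny + j

    def laplacian(self) -> sp.csr_matrix:
        """Zero-flux 5-point Laplacian (symmetric, zero row/column sums)."""
        nx, ny, dx = self.nx, self.ny, self.dx
        n = nx * ny
        rows, cols, vals = [], [], []
        deg = np.zeros(n)
        for i in range(nx):
            for j in range(ny):
                a = self.index(i, j)
                for di, dj in ((1, 0), (0, 1)):
                    i2, j2 = i + di, j + dj
                    if i2 < nx and j2 < ny:
                        b = self.index(i2, j2)
                        rows += [a, b]
                        cols += [b, a]
                        vals += [1.0, 1.0]
                        deg[a] += 1
                        deg[b] += 1
        rows += list(range(n))
        cols += list(range(n))
        vals += list(-deg)
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr() / dx ** 2


@dataclass
class Stimulus:
    """Transmembrane stimulus over a node mask during [start, start+duration)."""
    mask: np.ndarray          # boolean, one per node
    start: float              # ms
    duration: float           # ms
    amplitude: float          # uA/cm^2 (negative = depolarizing)

    def current(self, t: float, n: int) -> np.ndarray:
        out = np.zeros(n)
        if self.start <= t < self.start + self.duration:
            out[self.mask] = self.amplitude
        return out


class MonodomainProblem:
    """Monodomain tissue problem on a 2D regular grid or a simplex mesh.

    chi (1/cm) and C_m (uF/cm^2) default to 1400 and 1; sigma is the
    (scalar, isotropic) tissue conductivity in mS/cm.  The regular-grid
    path uses the 5-point Laplacian; a SimplexMesh substrate reuses the
    P1 finite-element assembly (mass + stiffness, zero-flux).
    """

    def __init__(self, grid, params: LR91Params | None = None,
                 sigma: float = 1.75, chi: float = 1400.0, C_m: float = 1.0,
                 stimuli: list | None = None):
        if sigma <= 0 or chi <= 0 or C_m <= 0:
            raise ValueError("sigma, chi, C_m must be positive")
        self.grid = grid
        self.params = params or LR91Params(C_m=C_m)
        self.params.C_m = C_m
        self.sigma = sigma
        self.chi = chi
        self.C_m = C_m
        self.stimuli = list(stimuli or [])
        rest = find_rest_state(self.params)
        n = grid.n_nodes
        self.state = LR91State(**{k: np.full(n, getattr(rest, k))
                                  for k in STATE_NAMES})
        self.time = 0.0
        self._solver = None
        self._solver_dt = None

    @property
    def diffusion_coefficient(self) -> float:
        return self.sigma / (self.chi * self.C_m)    # cm^2/ms

    def _diffusion_solver(self, dt: float):
        """Callable advancing V by one implicit-Euler diffusion step."""
        if self._solver is None or self._solver_dt != dt:
            D = self.diffusion_coefficient
            if isinstance(self.grid, RegularGrid2D):
                L = self.grid.laplacian()
                n = self.grid.n_nodes
                A = sp.identity(n, format="csr") - dt * D * L
                solve = spla.factorized(A.tocsc())
                self._solver = solve
            else:
                from .pde import assemble_mass, assemble_stiffness
                M = assemble_mass(self.grid)
                K = assemble_stiffness(self.grid, D)
                solve = spla.factorized((M + dt * K).tocsc())
                self._solver = lambda V: solve(M @ V)
            self._solver_dt = dt
        return self._solver

    def stimulus_current(self, t: float) -> np.ndarray:
        n = self.grid.n_nodes
        out = np.zeros(n)
        for s in self.stimuli:
            out += s.current(t, n)
        return out


def monodomain_step(problem: MonodomainProblem, dt: float) -> None:
    """One Godunov-split step: cell-model update, then implicit diffusion."""
    I_stim = problem.stimulus_current(problem.time)
    problem.state = step_cell(problem.state, dt, I_stim, problem.params)
    solve = problem._diffusion_solver(dt)
    problem.state.V = solve(problem.state.V)
    problem.time += dt


def run_monodomain(problem: MonodomainProblem, t_end: float, dt: float,
                   record_nodes=None, record_every: int = 1,
                   snapshot_every: float | None = None,
                   stop_when=None):
    """Advance to t_end, recording per-node traces and/or V snapshots.

    Returns a dict with 'times', 'traces' (node -> APTrace), 'snapshots'
    (list of (t, V array)).  `stop_when(problem)`, checked at snapshot
    cadence, allows early exit.
    """
    record_nodes = list(record_nodes or [])
    times = []
    recs = {n: [] for n in record_nodes}
    snapshots = []
    next_snap = problem.time
    step_no = 0
    while problem.time < t_end - 1e-9:
        monodomain_step(problem, dt)
        step_no += 1
        if record_nodes and step_no % record_every == 0:
            times.append(problem.time)
            for n in record_nodes:
                recs[n].append(problem.state.V[n])
        if snapshot_every is not None and problem.time >= next_snap - 1e-9:
            snapshots.append((problem.time, problem.state.V.copy()))
            next_snap += snapshot_every
            if stop_when is not None and stop_when(problem):
                break
    traces = {n: APTrace(np.array(times), np.array(recs[n]))
              for n in record_nodes}
    return {"times": np.array(times), "traces": traces,
            "snapshots": snapshots}


# ---------------------------------------------------------------------------
# Stimulation protocols
# ---------------------------------------------------------------------------

def spiral_preset() -> LR91Params:
    """Ion-channel modifications used by the spiral-wave protocol.

    The slow inward (calcium) conductance is reduced and its gating
    accelerated, shortening the action potential so that the re-entrant
    wavelength fits a desk-scale sheet.  This is a documented reconstruction
    of the published class of protocol, not a fitted parameter set.
    """
    return LR91Params(
        conductance_scale={"si": 0.1},
        rate_scale={"d": 2.0, "f": 2.0},
    )


def s1s2_cross_field(problem: MonodomainProblem, s1_spec: dict,
                     s2_spec: dict) -> MonodomainProblem:
    """Configure the S1-S2 cross-field protocol on `problem`.

    Each spec holds 'region' (predicate on (x, y) or boolean mask), 'start',
    'duration', 'amplitude'.  S2 must geometrically cross the S1 wavefront
    (e.g. S1 along the left edge, S2 over one quadrant).  Overlapping
    simultaneous stimuli of opposite sign are a configuration error.
    """
    def as_mask(region):
        if isinstance(region, np.ndarray):
            return region.astype(bool).ravel()
        pts = problem.grid.points
        return np.array([bool(region(p[0], p[1])) for p in pts])

    s1 = Stimulus(as_mask(s1_spec["region"]), s1_spec["start"],
                  s1_spec["duration"], s1_spec["amplitude"])
    s2 = Stimulus(as_mask(s2_spec["region"]), s2_spec["start"],
                  s2_spec["duration"], s2_spec["amplitude"])
    overlap_time = (s1.start < s2.start + s2.duration
                    and s2.start < s1.start + s1.duration)
    if (overlap_time and np.any(s1.mask & s2.mask)
            and np.sign(s1.amplitude) != np.sign(s2.amplitude)):
        raise CardiacError("S1 and S2 overlap in space and time with "
                           "opposite signs")
    problem.stimuli = [s1, s2]
    return problem


# ---------------------------------------------------------------------------
# Postprocessing
# ---------------------------------------------------------------------------

@dataclass
class APTrace:
    times: np.ndarray        # ms, strictly increasing
    voltages: np.ndarray     # mV

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def compute_apd(trace: APTrace, percentage: float = 90.0,
                threshold: float = -40.0):
    """Action-potential duration at `percentage` repolarization.

    The repolarization level is V_peak - (p/100) (V_peak - V_rest) with
    V_rest taken pre-upstroke (the sample before the first crossing of
    `threshold`).  The duration runs from the upstroke crossing of that
    level to the downstroke re-crossing, both linearly interpolated.
    Returns ``NO_AP`` if the trace holds no action potential.
    """
    t, V = trace.times, trace.voltages
    above = V > threshold
    if not np.any(above) or above[0]:
        return NO_AP             # flat trace, or no pre-stimulus rest
    up_idx = int(np.argmax(above))
    V_rest = V[:up_idx].min()
    peak_idx = up_idx + int(np.argmax(V[up_idx:]))
    V_peak = V[peak_idx]
    if V_peak <= threshold:
        return NO_AP
    level = V_peak - (percentage / 100.0) * (V_peak - V_rest)
    # latest upstroke crossing of the level before the peak
    t_up = None
    for i in range(peak_idx - 1, -1, -1):
        if V[i] <= level < V[i + 1] or V[i] < level <= V[i + 1]:
            t_up = _interp_crossing(t[i], t[i + 1], V[i], V[i + 1], level)
            break
    if t_up is None:
        return NO_AP
    for i in range(peak_idx, len(V) - 1):
        if V[i] >= level > V[i + 1] or V[i] > level >= V[i + 1]:
            t_down = _interp_crossing(t[i], t[i + 1], V[i], V[i + 1], level)
            return float(t_down - t_up)
    return NO_AP


def activation_times(times, V_history, threshold: float = -40.0) -> np.ndarray:
    """First interpolated crossing of `threshold` per node; NaN if never.

    `V_history` is (n_times, n_nodes).
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V_history, dtype=float)
    n = V.shape[1]
    out = np.full(n, np.nan)
    for k in range(n):
        v = V[:, k]
        idx = np.nonzero((v[:-1] <= threshold) & (v[1:] > threshold))[0]
        if len(idx):
            i = idx[0]
            out[k] = _interp_crossing(times[i], times[i + 1],
                                      v[i], v[i + 1], threshold)
    return out


def conduction_velocity(act_times, positions, site_a: int, site_b: int) -> float:
    """distance(a, b) / (t_b - t_a) in cm/ms; NaN sentinel if t_a == t_b."""
    ta, tb = act_times[site_a], act_times[site_b]
    for site, tt in ((site_a, ta), (site_b, tb)):
        if not np.isfinite(tt):
            raise CardiacError(f"site {site} never activated")
    if tb == ta:
        return float("nan")
    d = float(np.linalg.norm(np.asarray(positions[site_b], dtype=float)
                             - np.asarray(positions[site_a], dtype=float)))
    return d / (tb - ta)


def conduction_velocity_regression(act_times, positions, sites) -> float:
    """CV from a least-squares fit of activation time vs distance (collinear
    sites); the slope of t(x) inverts to velocity."""
    pos = np.array([positions[s] for s in sites], dtype=float)
    t = np.array([act_times[s] for s in sites], dtype=float)
    if np.any(~np.isfinite(t)):
        raise CardiacError("regression sites include an unactivated site")
    d = np.linalg.norm(pos - pos[0], axis=1)
    slope = np.polyfit(d, t, 1)[0]
    return 1.0 / slope


def pseudo_ecg(grid: RegularGrid2D, V_snapshots, electrode,
               conductivity_ratio: float = 1.0) -> np.ndarray:
    """Extracellular potential proxy at a virtual electrode.

    Phi(t) = -k * sum_nodes grad(V) . grad(1/|x - x_e|) dA, evaluated by
    central differences on the grid with one-point (nodal) quadrature.
    The electrode must lie outside the tissue sheet.
    """
    ex, ey = float(electrode[0]), float(electrode[1])
    dx = grid.dx
    x_min, x_max = 0.0, (grid.nx - 1) * dx
    y_min, y_max = 0.0, (grid.ny - 1) * dx
    if x_min <= ex <= x_max and y_min <= ey <= y_max:
        raise CardiacError("electrode lies inside the tissue support")
    xs = np.arange(grid.nx) * dx
    ys = np.arange(grid.ny) * dx
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rx, ry = X - ex, Y - ey
    r3 = (rx ** 2 + ry ** 2) ** 1.5
    gx_inv, gy_inv = -rx / r3, -ry / r3      # grad of 1/r
    out = []
    for V in V_snapshots:
        Vg = V.reshape(grid.nx, grid.ny)
        if grid.ny == 1:
            dVdx = np.gradient(Vg[:, 0], dx).reshape(grid.nx, 1)
            dVdy = np.zeros_like(dVdx)
        else:
            dVdx, dVdy = np.gradient(Vg, dx, dx)
        integrand = dVdx * gx_inv + dVdy * gy_inv
        out.append(-conductivity_ratio * integrand.sum() * dx * dx)
    return np.array(out)
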