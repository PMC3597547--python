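"""Deterministic randomness, ODE systems and fixed-step solvers, time stepping.

Everything stochastic in the package draws through :class:`RandomStream`, a
thin wrapper around numpy's PCG64 bit generator.  The seed -> sequence map is
frozen: a given seed always yields the same draw sequence, and the generator
state can be exported/restored exactly, which is what makes checkpointed runs
bit-identical to uninterrupted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "RandomStream",
    "OdeSystem",
    "OdeSolution",
    "TimeStepper",
    "solve_ode",
    "solve_ode_until_event",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when an ODE integration produces non-finite state."""


# ---------------------------------------------------------------------------
# Random stream
# ---------------------------------------------------------------------------

class RandomStream:
    """Reproducible random source backed by numpy's PCG64.

    The bit generator is pinned to PCG64 so that the mapping from seed to
    draw sequence is stable; checkpoint replay relies on this.

    Parameters
    ----------
    seed : int
        Non-negative seed. Same seed, same sequence.
    """

    def __init__(self, seed: int):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        self._bitgen = np.random.PCG64(self.seed)
        self._rng = np.random.Generator(self._bitgen)

    def reseed(self, seed: int) -> None:
        """Reset to a fresh sequence for `seed` (exactly as a new stream)."""
        self.__init__(seed)

    # -- draws -------------------------------------------------------------

    def uniform(self, low: float = 0.0, high: float = 1.0, size=None):
        return self._rng.uniform(low, high, size=size)

    def normal(self, loc: float = 0.0, scale: float = 1.0, size=None):
        return self._rng.normal(loc, scale, size=size)

    def integer(self, low: int, high: int, size=None):
        """Uniform integer in [low, high) — empty range is an error."""
        if high <= low:
            raise ValueError(f"empty integer range [{low}, {high})")
        return self._rng.integers(low, high, size=size)

    def shuffle(self, seq) -> None:
        """In-place Fisher-Yates shuffle (lists or arrays)."""
        if isinstance(seq, list):
            for i in range(len(seq) - 1, 0, -1):
                j = int(self._rng.integers(0, i + 1))
                seq[i], seq[j] = seq[j], seq[i]
        else:
            self._rng.shuffle(seq)

    def unit_vector(self, dim: int) -> np.ndarray:
        """Uniform random direction on the (dim-1)-sphere."""
        while True:
            v = self._rng.normal(size=dim)
            n = np.linalg.norm(v)
            if n > 1e-12:
                return v / n

    # -- state for checkpointing -------------------------------------------

    def get_state(self) -> dict:
        st = self._bitgen.state
        return {
            "seed": self.seed,
            "state": str(st["state"]["state"]),
            "inc": str(st["state"]["inc"]),
            "has_uint32": int(st["has_uint32"]),
            "uinteger": int(st["uinteger"]),
        }

    def set_state(self, state: dict) -> None:
        self.seed = int(state["seed"])
        self._bitgen = np.random.PCG64()
        self._bitgen.state = {
            "bit_generator": "PCG64",
            "state": {"state": int(state["state"]), "inc": int(state["inc"])},
            "has_uint32": int(state["has_uint32"]),
            "uinteger": int(state["uinteger"]),
        }
        self._rng = np.random.Generator(self._bitgen)

    def spawn(self, key: int) -> "RandomStream":
        """Derived stream with a seed mixed from this stream's seed and `key`."""
        mixed = (self.seed * 1000003 + key * 7919 + 1) % (2**31 - 1)
        return RandomStream(mixed)


# ---------------------------------------------------------------------------
# ODE systems
# ---------------------------------------------------------------------------

@dataclass
class OdeSystem:
    """Right-hand side f(t, y, **inputs) with named state variables.

    `rhs` must be side-effect free and return a derivative vector with the
    same length as the state vector.
    """

    state_names: Sequence[str]
    rhs: Callable[..., np.ndarray]
    parameters: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def __call__(self, t: float, y: np.ndarray, **inputs) -> np.ndarray:
        dy = np.asarray(self.rhs(t, y, **inputs), dtype=float)
        if dy.shape != np.shape(y):
            raise ValueError(
                f"rhs returned shape {dy.shape}, expected {np.shape(y)}"
            )
        return dy


@dataclass
class OdeSolution:
    times: np.ndarray
    states: np.ndarray          # one row per time
    stopped_early: bool = False
    stop_time: float | None = None

    def final_state(self) -> np.ndarray:
        return self.states[-1]


class TimeStepper:
    """Iterate from `start` to `end` in steps of `dt`.

    The final step is truncated so `end` is hit exactly, never overshot.
    Yields (t_from, t_to) pairs; emits `start` and `end` exactly once each.
    """

    def __init__(self, start: float, end: float, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if end < start:
            raise ValueError("end must be >= start")
        self.start, self.end, self.dt = float(start), float(end), float(dt)

    def __iter__(self):
        t = self.start
        # guard against float drift: step count from rounding
        while t < self.end - 1e-12 * max(1.0, abs(self.end)):
            t_next = min(t + self.dt, self.end)
            if self.end - t_next < 1e-12 * max(1.0, abs(self.end)):
                t_next = self.end
            yield t, t_next
            t = t_next

    def times(self) -> np.ndarray:
        out = [self.start]
        for _, t1 in self:
            out.append(t1)
        return np.array(out)


# ---------------------------------------------------------------------------
# Fixed-step solvers
# ---------------------------------------------------------------------------

def _euler_step(f, t, y, h, inputs):
    return y + h * f(t, y, **inputs)


def _rk4_step(f, t, y, h, inputs):
    k1 = f(t, y, **inputs)
    k2 = f(t + h / 2, y + h / 2 * k1, **inputs)
    k3 = f(t + h / 2, y + h / 2 * k2, **inputs)
    k4 = f(t + h, y + h * k3, **inputs)
    return y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)


_STEPPERS = {"euler": _euler_step, "rk4": _rk4_step}


def solve_ode(system, y0, t0: float, t1: float, dt: float,
              method: str = "rk4", inputs: Mapping | None = None) -> OdeSolution:
    """Integrate `system` from t0 to t1 with fixed steps of `dt`.

    The last step is truncated so the final reported time is exactly `t1`.
    Non-finite state aborts with :class:`IntegrationError`.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in _STEPPERS:
        raise ValueError(f"unknown method {method!r}")
    stepfn = _STEPPERS[method]
    inputs = dict(inputs or {})
    f = system if callable(system) and not isinstance(system, OdeSystem) else system

    y = np.asarray(y0, dtype=float).copy()
    times = [t0]
    states = [y.copy()]
    for ta, tb in TimeStepper(t0, t1, dt):
        y = stepfn(f, ta, y, tb - ta, inputs)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={tb:g}")
        times.append(tb)
        states.append(y.copy())
    return OdeSolution(np.array(times), np.array(states))


def solve_ode_until_event(system, y0, t0: float, t_max: float, dt: float,
                          event: Callable[[np.ndarray], float],
                          method: str = "rk4",
                          inputs: Mapping | None = None) -> OdeSolution:
    """Integrate until `event(state)` changes sign, refining the stop time.

    The crossing is located by bisection on linear interpolation between the
    bracketing accepted steps, to a tolerance of 1e-8 * dt.  If no sign
    change occurs before `t_max` the full solution is returned with
    ``stopped_early=False``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stepfn = _STEPPERS[method]
    inputs = dict(inputs or {})
    f = system

    y = np.asarray(y0, dtype=float).copy()
    times = [t0]
    states = [y.copy()]
    g_prev = event(y)
    for ta, tb in TimeStepper(t0, t_max, dt):
        y_new = stepfn(f, ta, y, tb - ta, inputs)
        if not np.all(np.isfinite(y_new)):
            raise IntegrationError(f"non-finite state at t={tb:g}")
        g_new = event(y_new)
        if g_prev == 0.0 or g_prev * g_new < 0 or g_new == 0.0:
            # bisection on the linearly interpolated trajectory
            lo, hi = 0.0, 1.0
            g_lo = g_prev
            tol = 1e-8
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                g_mid = event(y + mid * (y_new - y))
                if g_lo * g_mid <= 0:
                    hi = mid
                else:
                    lo, g_lo = mid, g_mid
            frac = 0.5 * (lo + hi)
            t_stop = ta + frac * (tb - ta)
            y_stop = y + frac * (y_new - y)
            times.append(t_stop)
            states.append(y_stop)
            return OdeSolution(np.array(times), np.array(states),
                               stopped_early=True, stop_time=t_stop)
        y = y_new
        g_prev = g_new
        times.append(tb)
        states.append(y.copy())
    return OdeSolution(np.array(times), np.array(states), stopped_early=False)
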