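"""Core map: parameters, state, stimulus and the exact one-step update.

The model is a discrete-time excitable-cell map.  The membrane potential
x(t), recovery variable y(t) and slow ionic current z(t) evolve as

    x(t+1) = f( (x(t) - K y(t) + z(t) + H + I(t)) / T )
    y(t+1) = x(t)
    z(t+1) = (1 - delta) z(t) - lambda (x(t) - x_R)

with the logistic gain f(u) = u / (1 + |u|) (a tanh gain is available for
comparison with the hyperbolic-tangent ancestor of the model).  All three
components are updated synchronously from the old state.

Two regimes of the parameter space are singled out:

* case I ("fast subsystem"): delta = lambda = 0, z frozen at 0 — a 2-D map
  in (x, y) with bias H;
* case II: H = 0 and the slow current active — the full 3-D map, where z
  plays the role of a slowly drifting bias.

Every variable and parameter is dimensionless; time is in map steps (ts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Optional, Sequence, Union

import numpy as np

from . import _kernels

__all__ = [
    "GainKind",
    "ModelParams",
    "State",
    "Stimulus",
    "Trajectory",
    "logistic_gain",
    "gain_derivative",
    "step",
    "simulate",
    "jacobian",
]

GainKind = Literal["logistic", "tanh"]

_GAIN_CODE = {"logistic": _kernels.GAIN_LOGISTIC, "tanh": _kernels.GAIN_TANH}


def logistic_gain(u):
    """Logistic gain f(u) = u / (1 + |u|), odd and strictly increasing on R.

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("logistic_gain: non-finite argument")
    out = u / (1.0 + np.abs(u))
    return float(out) if out.ndim == 0 else out


def gain_derivative(u, gain: GainKind = "logistic"):
    """Derivative of the gain: 1/(1+|u|)^2 (logistic) or 1 - tanh(u)^2."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("gain_derivative: non-finite argument")
    if gain == "logistic":
        out = 1.0 / (1.0 + np.abs(u)) ** 2
    elif gain == "tanh":
        t = np.tanh(np.clip(u, -50.0, 50.0))
        out = 1.0 - t * t
    else:
        raise ValueError(f"unknown gain {gain!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector (K, T, H, delta, lambda, x_R) plus gain choice.

    K > 0 couples the recovery variable (fast-spiking dynamics), T > 0 is
    the gain "temperature", H a bias potential, ``delta`` in [0, 1] the
    inverse recovery time of z, ``lam`` >= 0 the slow-current coupling and
    ``xR`` in [-1, 1] the reversal-like parameter controlling burst
    duration.
    """

    K: float
    T: float
    H: float = 0.0
    delta: float = 0.0
    lam: float = 0.0
    xR: float = 0.0
    gain: GainKind = "logistic"

    def __post_init__(self):
        for name in ("K", "T", "H", "delta", "lam", "xR"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"ModelParams.{name} must be finite, got {v}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.T <= 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not -1.0 <= self.xR <= 1.0:
            raise ValueError(f"xR must be in [-1, 1], got {self.xR}")
        if self.gain not in _GAIN_CODE:
            raise ValueError(f"unknown gain {self.gain!r}")

    @property
    def is_case1(self) -> bool:
        """True when the slow current is frozen (delta = lambda = 0)."""
        return self.delta == 0.0 and self.lam == 0.0

    @property
    def gain_code(self) -> int:
        return _GAIN_CODE[self.gain]

    def f(self, u):
        """Evaluate this parameter set's gain function."""
        if self.gain == "logistic":
            return logistic_gain(u)
        return np.tanh(np.clip(np.asarray(u, dtype=float), -50.0, 50.0))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def mirrored(self) -> "ModelParams":
        """Sign-flipped twin (H -> -H, x_R -> -x_R); dynamics negate exactly."""
        return self.replace(H=-self.H, xR=-self.xR)


class State(NamedTuple):
    """One map state: membrane potential x, recovery y, slow current z."""

    x: float
    y: float
    z: float = 0.0


@dataclass(frozen=True)
class Stimulus:
    """External input I(t), added inside the gain argument.

    Kinds
    -----
    none          I = 0 always.
    delta_pulse   amplitude at t = onset only (width ``width`` ts).
    dc_step       amplitude for onset <= t < offset.
    pulse_train   pulses of ``width`` ts every ``period`` ts in
                  [onset, offset).
    ramp          linear rise from 0 at onset to ``amplitude`` at offset,
                  zero outside.
    custom_series ``series`` used verbatim, tiled cyclically if shorter
                  than the simulation.

    Inhibitory input is a negative amplitude.
    """

    kind: Literal["none", "delta_pulse", "dc_step", "pulse_train", "ramp",
                  "custom_series"] = "none"
    amplitude: float = 0.0
    onset: int = 0
    offset: Optional[int] = None
    period: int = 0
    width: int = 1
    slope: Optional[float] = None
    series: Optional[Sequence[float]] = None

    def array(self, n: int) -> np.ndarray:
        """Materialize I(t) for t = 0 .. n-1."""
        I = np.zeros(n)
        off = n if self.offset is None else min(self.offset, n)
        if self.kind == "none":
            pass
        elif self.kind == "delta_pulse":
            I[self.onset:min(self.onset + self.width, n)] = self.amplitude
        elif self.kind == "dc_step":
            I[self.onset:off] = self.amplitude
        elif self.kind == "pulse_train":
            if self.period <= 0:
                raise ValueError("pulse_train needs period > 0")
            for t0 in range(self.onset, off, self.period):
                I[t0:min(t0 + self.width, n)] = self.amplitude
        elif self.kind == "ramp":
            if self.offset is None:
                raise ValueError("ramp needs an offset")
            slope = (self.slope if self.slope is not None
                     else self.amplitude / max(self.offset - self.onset, 1))
            t = np.arange(self.onset, off)
            I[self.onset:off] = slope * (t - self.onset)
        elif self.kind == "custom_series":
            s = np.asarray(self.series, dtype=float)
            if s.size == 0:
                raise ValueError("custom_series needs a non-empty series")
            reps = int(np.ceil(n / s.size))
            I[:] = np.tile(s, reps)[:n]
        else:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        return I


NO_STIMULUS = Stimulus()


@dataclass
class Trajectory:
    """A simulated orbit: state arrays plus the inputs that produced it."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    I: np.ndarray
    params: ModelParams
    t0_discarded: int = 0

    def __len__(self) -> int:
        return self.x.size

    @property
    def states(self) -> Iterable[State]:
        for i in range(self.x.size):
            yield State(self.x[i], self.y[i], self.z[i])

    def final_state(self) -> State:
        return State(self.x[-1], self.y[-1], self.z[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t": np.arange(len(self)),
            "x": self.x, "y": self.y, "z": self.z, "I": self.I,
        })

    def to_csv(self, path) -> None:
        """Write `t,x,y,z,I` at full double precision (17 significant digits)."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def step(state: State | tuple, params: ModelParams, I: float = 0.0) -> State:
    """One synchronous update; all three components read the OLD state."""
    x, y, z = state
    if not all(math.isfinite(v) for v in (x, y, z, I)):
        raise ValueError("step: non-finite state or input")
    u = (x - params.K * y + z + params.H + I) / params.T
    x_new = float(params.f(u))
    z_new = (1.0 - params.delta) * z - params.lam * (x - params.xR)
    return State(x_new, x, z_new)


def simulate(params: ModelParams,
             init: State | tuple = State(0.0, 0.0, 0.0),
             n_steps: int = 1000,
             stimulus: Stimulus = NO_STIMULUS,
             discard: int = 0) -> Trajectory:
    """Iterate the map and return the last ``n_steps`` states.

    The stimulus acts from t = 0 of the run, including the ``discard``
    transient steps that are dropped from the record.  Bit-exact
    reproducible: identical inputs give identical trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if discard < 0:
        raise ValueError("discard must be >= 0")
    x0, y0, z0 = (float(v) for v in init)
    total = discard + n_steps
    I = stimulus.array(total)
    xs, ys, zs = _kernels.iterate(
        x0, y0, z0, params.K, params.T, params.H,
        params.delta, params.lam, params.xR, I, discard, n_steps,
        params.gain_code)
    bad = np.flatnonzero(~np.isfinite(xs))
    if bad.size:
        raise FloatingPointError(
            f"non-finite state at recorded step {int(bad[0])} "
            f"(after {discard} discarded)")
    return Trajectory(xs, ys, zs, I[discard:], params, t0_discarded=discard)


def jacobian(params: ModelParams, state: State | tuple,
             I: float = 0.0) -> np.ndarray:
    """Analytic Jacobian of one update at ``state`` (2x2 case I, 3x3 else)."""
    x, y, z = state
    u = (x - params.K * y + z + params.H + I) / params.T
    fp = gain_derivative(u, params.gain) / params.T
    if params.is_case1:
        return np.array([[fp, -params.K * fp], [1.0, 0.0]])
    return np.array([
        [fp, -params.K * fp, fp],
        [1.0, 0.0, 0.0],
        [-params.lam, 0.0, 1.0 - params.delta],
    ])
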