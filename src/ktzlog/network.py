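"""Gap-junction coupled networks of map units.

Electrical coupling: the synaptic current into unit i is
I_i = sum_j G (x_j - x_i) over its presynaptic neighbours, computed from
the OLD potentials; then every unit advances synchronously through the
single-cell update with its summed input.

Two experiment topologies:

* ``chain_directed`` — N units in a line, synapses i -> i+1 only (N-1
  synapses); units sit in an excitable regime and only unit 0 is kicked,
  so activity propagates down the chain when G exceeds a threshold;
* ``complete`` — all-to-all (N(N-1) synapses); units in a bursting regime
  started from random states synchronize after a transient.

An undirected pair/chain (``chain_undirected``) is included for the exact
antisymmetry checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .model import ModelParams, State, Stimulus

__all__ = [
    "NetworkConfig",
    "synaptic_currents",
    "step_network",
    "simulate_network",
    "find_propagation_threshold",
    "synchrony_order",
]

_TOPO_CODE = {"chain_directed": 0, "complete": 1, "chain_undirected": 2}


@dataclass(frozen=True)
class NetworkConfig:
    """Homogeneous gap-junction network specification."""

    N: int
    topology: str = "chain_directed"
    G: float = 0.01
    neuron_params: ModelParams = None
    init: str = "single_kick"     # or "random"
    seed: int = 0
    kick: float = 0.5             # pulse fed to unit 0 at t=0 (single_kick)

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need N >= 2")
        if self.topology not in _TOPO_CODE:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.G < 0:
            raise ValueError("G must be >= 0 (gap junctions are excitatory)")

    @property
    def n_synapses(self) -> int:
        return (self.N - 1 if self.topology == "chain_directed"
                else self.N * (self.N - 1) if self.topology == "complete"
                else 2 * (self.N - 1))

    def initial_states(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        N = self.N
        if self.init == "single_kick":
            # all units at rest; the kick arrives as input at t = 0
            return np.zeros(N), np.zeros(N), np.zeros(N)
        if self.init == "random":
            rng = np.random.default_rng(self.seed)
            return (rng.uniform(-1, 1, N), rng.uniform(-1, 1, N),
                    np.zeros(N))
        raise ValueError(f"unknown init {self.init!r}")


def synaptic_currents(x: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Gap currents I_i = sum_j G (x_j - x_i) from old potentials."""
    x = np.asarray(x, float)
    N = x.size
    G = config.G
    if config.topology == "complete":
        return G * (x.sum() - N * x)
    I = np.zeros(N)
    I[1:] += G * (x[:-1] - x[1:])
    if config.topology == "chain_undirected":
        I[:-1] += G * (x[1:] - x[:-1])
    return I


def step_network(states: Tuple[np.ndarray, np.ndarray, np.ndarray],
                 config: NetworkConfig,
                 I_ext: Optional[np.ndarray] = None
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synchronous network step from (x, y, z) arrays."""
    x, y, z = (np.asarray(a, float) for a in states)
    p = config.neuron_params
    I = synaptic_currents(x, config)
    if I_ext is not None:
        I = I + I_ext
    u = (x - p.K * y + z + p.H + I) / p.T
    x_new = np.asarray(p.f(u), float)
    z_new = (1.0 - p.delta) * z - p.lam * (x - p.xR)
    return x_new, x.copy(), z_new


def simulate_network(config: NetworkConfig, n_steps: int,
                     init: Optional[Tuple[np.ndarray, ...]] = None
                     ) -> np.ndarray:
    """Run the network, returning the (n_steps, N) membrane record."""
    p = config.neuron_params
    x0, y0, z0 = init if init is not None else config.initial_states()
    I_ext = np.zeros((n_steps, config.N))
    if init is None and config.init == "single_kick":
        I_ext[0, 0] = config.kick
    return _kernels.network_iterate(
        np.asarray(x0, float), np.asarray(y0, float), np.asarray(z0, float),
        p.K, p.T, p.H, p.delta, p.lam, p.xR, config.G,
        _TOPO_CODE[config.topology], I_ext, n_steps, p.gain_code)


def _propagates(config: NetworkConfig, horizon: int,
                threshold: float = 0.0, hysteresis: float = 0.1) -> bool:
    X = simulate_network(config, horizon)
    last = X[:, -1]
    return _kernels.spike_times(last, threshold, hysteresis).size > 0


def find_propagation_threshold(config: NetworkConfig,
                               bracket: Tuple[float, float],
                               horizon: int = 20_000,
                               tol: float = 1e-6) -> float:
    """Bisect the conductance G for chain propagation.

    The predicate is "the last unit of the chain spikes within the
    horizon".  Raises when the bracket top fails or the bottom already
    propagates.
    """
    import dataclasses

    lo, hi = bracket
    if _propagates(dataclasses.replace(config, G=lo), horizon):
        raise ValueError(f"activity already propagates at G = {lo}")
    if not _propagates(dataclasses.replace(config, G=hi), horizon):
        raise ValueError(f"propagation fails even at bracket top G = {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _propagates(dataclasses.replace(config, G=mid), horizon):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def synchrony_order(X: np.ndarray, degenerate_tol: float = 1e-12
                    ) -> float:
    """Variance-ratio order parameter in [0, 1] of an (n, N) record.

    1 - <population variance of x(t)>_t / <single-unit temporal variance>;
    1 means identical trajectories.  For constant records the metric is 1
    when all units coincide and raises otherwise (degenerate input).
    """
    X = np.asarray(X, float)
    pop_var = X.var(axis=1).mean()
    time_var = X.var(axis=0).mean()
    if time_var < degenerate_tol:
        if pop_var < degenerate_tol:
            return 1.0
        raise ValueError("degenerate record: constant but non-identical units")
    return float(1.0 - pop_var / time_var)
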