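"""Stimulus-driven behavior gallery, f-I curves and rheobase search.

Each entry of the registry pairs a parameter set and stimulus protocol
with a machine-checkable predicate formalizing the qualitative behavior
(tonic vs phasic spiking, rebound responses, accommodation, ...).  The
parameter sets were found by guided search seeded from the phase and
bifurcation structure — excitable fixed points just outside the
subcritical Neimark-Sacker limit of the fast subsystem (K = 0.6,
T = 0.26 puts the oscillatory attractor band at |H| < ~0.017, so a cell
biased at H = -0.1 rests quietly and spikes tonically when a DC input
lifts it into the band), cardiac/bursting regimes of the slow subsystem,
and a K < 0.5 node cell for integrator/accommodation protocols.  They
are registry data validated by their predicates, not canonical
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .model import ModelParams, State, Stimulus, Trajectory, simulate
from .phases import ClassifierConfig, classify_phase, detect_spikes, summarize

__all__ = [
    "BehaviorSpec",
    "BehaviorResult",
    "REGISTRY",
    "list_behaviors",
    "run_behavior",
    "f_I_curve",
    "excitability_class",
    "find_rheobase",
]

_DETECT = dict(threshold=0.0, hysteresis=0.1)


@dataclass
class BehaviorSpec:
    name: str
    params: ModelParams
    stimulus: Stimulus
    n_steps: int
    init: State
    verdict: Callable[["BehaviorResult"], bool]
    description: str = ""
    # optional second protocol for contrastive predicates (resonator,
    # accommodation, ...): the behavior holds only if the main protocol
    # responds and the contrast protocol does not (or vice versa)
    contrast_stimulus: Optional[Stimulus] = None


@dataclass
class BehaviorResult:
    spec: BehaviorSpec
    trajectory: Trajectory
    spikes: np.ndarray
    contrast_trajectory: Optional[Trajectory] = None
    contrast_spikes: Optional[np.ndarray] = None
    verdict: Optional[bool] = None


def _spikes_in(spikes: np.ndarray, a: int, b: int) -> np.ndarray:
    return spikes[(spikes >= a) & (spikes < b)]


def run_behavior(spec: BehaviorSpec) -> BehaviorResult:
    """Simulate the protocol(s) and evaluate the predicate."""
    traj = simulate(spec.params, spec.init, spec.n_steps, spec.stimulus)
    res = BehaviorResult(spec, traj, detect_spikes(traj.x, **_DETECT))
    if spec.contrast_stimulus is not None:
        ctraj = simulate(spec.params, spec.init, spec.n_steps,
                         spec.contrast_stimulus)
        res.contrast_trajectory = ctraj
        res.contrast_spikes = detect_spikes(ctraj.x, **_DETECT)
    res.verdict = bool(spec.verdict(res))
    return res


# ------------------------------------------------------------ the cells

# Fast-subsystem cell resting far below the oscillatory band; a DC input
# of ~0.1 lifts the effective bias into the band (tonic driver).
_TONIC = ModelParams(K=0.6, T=0.26, H=-0.1)
# Same subsystem biased just outside the band: strongly excitable focus
# with pronounced subthreshold ringing (single-pulse rheobase ~0.085).
_RING = ModelParams(K=0.6, T=0.26, H=-0.02)
# ... and barely outside it: very weakly damped ringing.
_RING_SLOW = ModelParams(K=0.6, T=0.26, H=-0.012)
# Slow-subsystem cell resting at the edge of the bursting wedge.
_BURST = ModelParams(K=0.6, T=0.3, delta=0.001, lam=0.001, xR=-0.35)
# Cardiac cell (autonomous CS) and its excitable neighbour for class-1
# slow spiking through the infinite-period onset.
_CARDIAC = ModelParams(K=0.6, T=0.15, delta=0.001, lam=0.001, xR=-0.25)
_CLASS1 = ModelParams(K=0.6, T=0.2, delta=0.001, lam=0.001, xR=-0.45)
# K < 0.5 node cell (real eigenvalues, no subthreshold ringing): the slow
# current returns it after a switch, producing one long spike.
_NODE = ModelParams(K=0.3, T=0.4, delta=0.001, lam=0.001, xR=-0.4)
# Fast subsystem inside the bistable band: stable FPs coexist with the OA.
_BISTABLE = ModelParams(K=0.6, T=0.25, H=0.0)

_rest_cache: Dict[ModelParams, State] = {}


def resting_state(params: ModelParams, n: int = 400_000) -> State:
    """Settle from the origin onto the cell's rest state (or attractor)."""
    if params not in _rest_cache:
        _rest_cache[params] = simulate(params, State(0.0, 0.0, 0.0), 1,
                                       discard=n).final_state()
    return _rest_cache[params]


def _pulse_pair(t1: int, a1: float, t2: int, a2: float,
                n: int) -> np.ndarray:
    I = np.zeros(n)
    I[t1] = a1
    I[t2] += a2
    return I


REGISTRY: Dict[str, BehaviorSpec] = {}


def _register(name, params, stimulus, n_steps, verdict, description,
              contrast=None) -> None:
    REGISTRY[name] = BehaviorSpec(name, params, stimulus, n_steps,
                                  resting_state(params), verdict,
                                  description, contrast)


def list_behaviors() -> List[str]:
    return sorted(REGISTRY)


def _build_registry() -> None:
    on, off, n = 2000, 8000, 12_000

    def tonic_ok(r):
        pre = _spikes_in(r.spikes, 0, on)
        dur = _spikes_in(r.spikes, on, off)
        post = _spikes_in(r.spikes, off + 500, n)
        if pre.size or post.size or dur.size < 5:
            return False
        isis = np.diff(dur)
        return isis.std() / isis.mean() < 0.2

    _register("tonic_spiking", _TONIC,
              Stimulus("dc_step", amplitude=0.1, onset=on, offset=off),
              n, tonic_ok,
              "periodic spike train only while a DC input is applied")

    def phasic_ok(r):
        return (r.spikes.size == 1
                and on <= r.spikes[0] < on + 1000)

    _register("phasic_spiking", _TONIC,
              Stimulus("dc_step", amplitude=0.12, onset=on, offset=off),
              n, phasic_ok,
              "fires once at the beginning of sustained stimulation")

    bon, boff, bn = 20_000, 220_000, 240_000

    def tonic_burst_ok(r):
        pre = _spikes_in(r.spikes, 0, bon)
        dur = _spikes_in(r.spikes, bon, boff)
        post = _spikes_in(r.spikes, boff + 2000, bn)
        if pre.size or post.size or dur.size < 20:
            return False
        isis = np.diff(dur)
        return isis.min() < 100 < isis.max()

    _register("tonic_bursting", _BURST,
              Stimulus("dc_step", amplitude=0.1, onset=bon, offset=boff),
              bn, tonic_burst_ok,
              "repeated bursts of fast spikes while a DC input is applied")

    def phasic_burst_ok(r):
        burst = _spikes_in(r.spikes, bon, bon + 2000)
        return (burst.size >= 3 and burst.size == r.spikes.size)

    _register("phasic_bursting", _BURST,
              Stimulus("dc_step", amplitude=0.03, onset=bon, offset=boff),
              bn, phasic_burst_ok,
              "a single burst at stimulation onset, then quiescence")

    def mixed_ok(r):
        dur = _spikes_in(r.spikes, on, 100_000)
        if dur.size < 100:
            return False
        isis = np.diff(dur)
        early, late = isis[:30], isis[-1000:]
        # an interburst gap early on, pure fast spiking later
        return early.max() > 100 and late.max() < 30

    _register("mixed_mode", _BURST,
              Stimulus("dc_step", amplitude=0.3, onset=on, offset=100_000),
              100_000, mixed_ok,
              "an initial burst followed by sustained tonic spiking")

    def so_ok(r):
        if r.spikes.size:
            return False
        x = r.trajectory.x[on:on + 400]
        peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1
        return peaks.size >= 3

    _register("subthreshold_oscillations", _RING,
              Stimulus("delta_pulse", amplitude=0.02, onset=on),
              n, so_ok,
              "decaying voltage ringing after a small pulse, no spike")

    def to_ok(r):
        if r.spikes.size:
            return False
        x = r.trajectory.x
        seg = x[on + 100:on + 150]
        tail = x[-1000:]
        xs = x[on:on + 400]
        peaks = np.flatnonzero((xs[1:-1] > xs[:-2]) & (xs[1:-1] >= xs[2:])) + 1
        return (peaks.size >= 20
                and seg.max() - seg.min() > 1e-6
                and tail.max() - tail.min() < 1e-10)

    _register("transient_oscillations", _RING_SLOW,
              Stimulus("delta_pulse", amplitude=0.02, onset=on),
              n, to_ok,
              "many ringing cycles after a pulse before settling back")

    def exc_ok(r):
        return (r.spikes.size == 1 and on <= r.spikes[0] < on + 100)

    _register("excitable_spiking", _RING,
              Stimulus("delta_pulse", amplitude=0.12, onset=on),
              n, exc_ok,
              "an isolated spike in response to a brief pulse")

    def rebound_ok(r):
        pre = _spikes_in(r.spikes, 0, off)
        post = _spikes_in(r.spikes, off, off + 500)
        return pre.size == 0 and post.size >= 1

    _register("rebound_spike", _RING,
              Stimulus("dc_step", amplitude=-0.2, onset=on, offset=off),
              n, rebound_ok,
              "post-inhibitory spike when a hyperpolarizing step ends")

    def rebound_burst_ok(r):
        pre = _spikes_in(r.spikes, 0, off)
        post = _spikes_in(r.spikes, off, off + 3000)
        return pre.size == 0 and post.size >= 3

    _register("rebound_burst", _BURST.replace(xR=-0.3),
              Stimulus("dc_step", amplitude=-0.05, onset=on, offset=off),
              30_000, rebound_burst_ok,
              "post-inhibitory burst of spikes")

    def primed_vs_alone_ok(r):
        return r.spikes.size >= 1 and r.contrast_spikes.size == 0

    _register("threshold_variability", _RING,
              Stimulus("custom_series",
                       series=_pulse_pair(on - 4, -0.02, on, 0.08, n)),
              n, primed_vs_alone_ok,
              "an otherwise subthreshold pulse spikes after a brief "
              "priming perturbation",
              contrast=Stimulus("delta_pulse", amplitude=0.08, onset=on))

    # focus rotation period at _RING is ~8.4 ts: a pulse pair one period
    # apart sums constructively, a half-period pair destructively
    _register("resonator", _RING,
              Stimulus("custom_series",
                       series=_pulse_pair(on, 0.06, on + 9, 0.06, n)),
              n, primed_vs_alone_ok,
              "spikes for pulse pairs at the subthreshold-ringing period, "
              "not at double the frequency",
              contrast=Stimulus("custom_series",
                                series=_pulse_pair(on, 0.06, on + 4, 0.06,
                                                   n)))

    _register("integrator", _NODE,
              Stimulus("custom_series",
                       series=_pulse_pair(on, 0.12, on + 1, 0.12, 20_000)),
              20_000, primed_vs_alone_ok,
              "immediately successive pulses sum to a spike; separated "
              "ones do not (no subthreshold ringing to resonate with)",
              contrast=Stimulus("custom_series",
                                series=_pulse_pair(on, 0.12, on + 60, 0.12,
                                                   20_000)))

    def bi_ok(r):
        settled = _spikes_in(r.spikes, on + 2000, n)
        return _spikes_in(r.spikes, 0, on).size == 0 and settled.size > 50

    _register("bistability", _BISTABLE,
              Stimulus("delta_pulse", amplitude=0.4, onset=on),
              n, bi_ok,
              "rest and sustained oscillation coexist; a pulse switches "
              "the cell onto the oscillatory attractor")

    def accom_ok(r):
        return r.spikes.size == 0 and r.contrast_spikes.size >= 1

    _register("accommodation", _NODE,
              Stimulus("ramp", amplitude=0.18, onset=on, offset=52_000),
              80_000, accom_ok,
              "no spike for a slowly ramped input; a brief pulse of the "
              "same amplitude spikes",
              contrast=Stimulus("delta_pulse", amplitude=0.18, onset=on,
                                width=200))

    def block_ok(r):
        moderate = _spikes_in(r.spikes, on + 1000, off)
        strong = _spikes_in(r.contrast_spikes, on + 1000, off)
        return moderate.size >= 5 and strong.size <= 1

    _register("nerve_blocking", _TONIC,
              Stimulus("dc_step", amplitude=0.1, onset=on, offset=off),
              n, block_ok,
              "spiking under moderate DC drive is blocked by a much "
              "stronger one",
              contrast=Stimulus("dc_step", amplitude=0.5, onset=on,
                                offset=off))

    def cardiac_ok(r):
        cfg = ClassifierConfig(min_isi_count=5)
        s = summarize(r.trajectory.x, cfg)
        return classify_phase(s, cfg) == "CS"

    _register("cardiac_spiking", _CARDIAC, Stimulus("none"),
              400_000, cardiac_ok,
              "autonomous action potentials with a long plateau and slow "
              "repolarization")

    def class1_ok(r):
        kind, _ = excitability_class(r.spec.params, (0.0, 0.3),
                                     window=100_000)
        return kind == 1

    _register("class_1", _CLASS1,
              Stimulus("dc_step", amplitude=0.1, onset=0, offset=100_000),
              100_000, class1_ok,
              "firing rate rises continuously from ~0 with input strength "
              "(infinite-period onset of slow spiking)")

    def class2_ok(r):
        kind, _ = excitability_class(r.spec.params, (0.0, 0.12),
                                     window=10_000)
        return kind == 2

    _register("class_2", _TONIC,
              Stimulus("dc_step", amplitude=0.1, onset=0, offset=10_000),
              10_000, class2_ok,
              "firing starts at a finite rate when the input crosses the "
              "oscillation threshold")


# ---------------------------------------------------------- f-I analysis


def f_I_curve(params: ModelParams, I_range: Tuple[float, float],
              n_levels: int = 40, window: int = 10_000,
              init: Optional[State] = None) -> List[Tuple[float, float]]:
    """Firing rate (spikes per 1e4 ts) versus DC amplitude."""
    if init is None:
        init = resting_state(params)
    out = []
    for I in np.linspace(I_range[0], I_range[1], n_levels):
        traj = simulate(params, init, window,
                        Stimulus("dc_step", amplitude=float(I), onset=0,
                                 offset=window))
        nspk = detect_spikes(traj.x, **_DETECT).size
        out.append((float(I), nspk * 10_000.0 / window))
    return out


def excitability_class(params: ModelParams,
                       I_range: Tuple[float, float],
                       n_levels: int = 40,
                       window: int = 10_000
                       ) -> Tuple[int, List[Tuple[float, float]]]:
    """1 if near-threshold rates fall below 10% of the plateau, else 2.

    Levels with fewer than 3 spikes in the window are treated as silent
    (isolated onset transients, not sustained firing).  Returns 0 when no
    level fires.
    """
    curve = f_I_curve(params, I_range, n_levels, window)
    rates = np.array([r for _, r in curve])
    floor = 3 * 10_000.0 / window
    firing = rates[rates >= floor]
    if firing.size == 0:
        return 0, curve
    plateau = float(np.percentile(firing, 90))
    onset_rate = float(firing[0])
    return (1 if onset_rate < 0.1 * plateau else 2), curve


def find_rheobase(params: ModelParams, bracket: Tuple[float, float],
                  pulse: Stimulus, n_steps: int = 10_000,
                  init: Optional[State] = None,
                  tol: float = 1e-6) -> float:
    """Minimal pulse amplitude eliciting a spike, by bisection to ``tol``."""
    import dataclasses

    if init is None:
        init = resting_state(params)

    def spikes_at(amp: float) -> bool:
        stim = dataclasses.replace(pulse, amplitude=amp)
        traj = simulate(params, init, n_steps, stim)
        return detect_spikes(traj.x, **_DETECT).size > 0

    lo, hi = bracket
    if spikes_at(lo):
        raise ValueError(f"lower bound {lo} already elicits a spike")
    if not spikes_at(hi):
        raise ValueError(f"upper bound {hi} does not elicit a spike")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


_build_registry()
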