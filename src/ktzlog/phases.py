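"""Spike detection, ISI statistics, regime classification and phase sweeps.

Oscillatory attractors of the map are told apart by their interspike
interval (ISI) distribution P(ISI) and oscillation amplitude:

* FP  — no spikes, amplitude ~ 0 (fixed point);
* SO  — subthreshold oscillations: cycles too small to count as spikes;
* FS  — fast spiking: unimodal P(ISI) with mean below ``isi_th``;
* CS  — cardiac spiking: long-period action potentials with a narrow
        period distribution (CV below ``cv_th``);
* ACS — aperiodic cardiac spiking: cardiac events (often carrying failed
        spike attempts on the plateau) whose period spreads broadly;
* BS  — bursting: bimodal P(ISI) (intra-burst ISIs plus interburst gaps);
* SB  — slow bursting: bursting whose interburst interval exceeds ``ibi_th``
        (an intentionally arbitrary split);
* MIXED_DUST — incessant switching between cardiac spikes and bursts
        (the chaotic "dust" band), detected as a mixture of single-spike
        and multi-spike events;
* BI  — bistable cell, only emitted by the multi-initial-condition prober.

All thresholds are configuration, not constants; every sweep output
carries the configuration that produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernels
from .model import ModelParams, State, Stimulus, Trajectory, simulate

__all__ = [
    "ClassifierConfig",
    "OscillationSummary",
    "PHASE_LABELS",
    "detect_spikes",
    "amplitude",
    "summarize",
    "classify_phase",
    "classify_params",
    "burst_segments",
    "mean_burst_duration",
    "phase_diagram",
    "winding_number_analytic",
    "winding_number_measured",
]

PHASE_LABELS = ("FP", "FS", "BS", "SB", "CS", "ACS", "SO", "MIXED_DUST", "BI")


@dataclass(frozen=True)
class ClassifierConfig:
    """All thresholds of the ISI-distribution classifier (time in ts)."""

    threshold: float = 0.0        # spike detection level on x
    hysteresis: float = 0.1       # re-arm depth below threshold
    isi_th: float = 100.0         # FS/CS split on mean ISI
    cv_th: float = 0.01           # CS/ACS split on the event-period CV
    ibi_th: float = 500.0         # BS/SB split on the interburst interval
    A_so: float = 0.05            # FP/SO amplitude cut
    A_spike: float = 1.0          # SO/spiking amplitude cut
    discard: int = 100_000        # transient length
    window: int = 1_000_000       # measurement window
    mode_gap_ratio: float = 2.0   # ISI ratio that separates P(ISI) modes
    burst_ratio: float = 10.0     # max/min ISI spread that signals two time scales
    duty_th: float = 0.15         # active fraction below which events are
                                  # cardiac spikes (with failed attempts)
                                  # rather than bursts
    peak_mass: float = 0.05       # minimum fraction of mass for a P(ISI) mode
    min_isi_count: int = 10       # fewer ISIs => low-count flag
    mixed_fraction: float = 0.2   # event share that makes a burster "dust"

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class OscillationSummary:
    """Spike times, ISI statistics and amplitude of one measured orbit."""

    spike_times: np.ndarray
    isis: np.ndarray
    amplitude_A: float
    mean_isi: float = math.nan
    var_isi: float = math.nan
    cv_isi: float = math.nan
    n_isi_peaks: int = 0
    winding: Optional[Union[Fraction, float]] = None
    label: Optional[str] = None
    low_count: bool = False

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def detect_spikes(traj: Union[Trajectory, np.ndarray],
                  threshold: float = 0.0,
                  hysteresis: float = 0.1) -> np.ndarray:
    """Spike times: upward crossings of ``threshold`` after x has been
    below ``threshold - hysteresis`` (deterministic; empty is valid)."""
    x = traj.x if isinstance(traj, Trajectory) else np.asarray(traj, float)
    return _kernels.spike_times(x, threshold, hysteresis)


def amplitude(traj: Union[Trajectory, np.ndarray]) -> float:
    """Peak-to-peak amplitude A = max x - min x over the (transient-free)
    record; 0 for a constant orbit, < 2 for any bounded one."""
    x = traj.x if isinstance(traj, Trajectory) else np.asarray(traj, float)
    return float(x.max() - x.min())


def _isi_peak_count(isis: np.ndarray, config: ClassifierConfig) -> int:
    """Modes of P(ISI), counted on a logarithmic interval axis.

    ISIs are clustered by splitting the sorted values wherever consecutive
    intervals differ by more than ``mode_gap_ratio`` (the two time scales
    of a burster — intra-burst ISIs and interburst gaps — are separated by
    an order of magnitude, while a unimodal distribution, however broad,
    has no such gap).  Clusters holding at least ``peak_mass`` of the ISIs
    count as modes.
    """
    vals = np.sort(isis)
    ratios = vals[1:] / vals[:-1]
    cuts = np.flatnonzero(ratios > config.mode_gap_ratio)
    bounds = np.concatenate([[0], cuts + 1, [vals.size]])
    sizes = np.diff(bounds)
    peaks = int(np.sum(sizes >= config.peak_mass * vals.size))
    return max(peaks, 1)


def summarize(traj: Union[Trajectory, np.ndarray],
              config: ClassifierConfig = ClassifierConfig()) -> OscillationSummary:
    """ISI statistics and amplitude of a transient-free trajectory."""
    x = traj.x if isinstance(traj, Trajectory) else np.asarray(traj, float)
    spikes = detect_spikes(x, config.threshold, config.hysteresis)
    isis = np.diff(spikes).astype(float)
    s = OscillationSummary(spikes, isis, float(x.max() - x.min()))
    if isis.size:
        s.mean_isi = float(isis.mean())
        s.var_isi = float(isis.var())
        s.cv_isi = float(math.sqrt(s.var_isi) / s.mean_isi) if s.mean_isi else 0.0
        s.n_isi_peaks = _isi_peak_count(isis, config)
    s.low_count = isis.size < config.min_isi_count
    return s


def _base_label(s: OscillationSummary, config: ClassifierConfig) -> str:
    if s.isis.size < 2:
        return "FP" if s.amplitude_A < config.A_so else "SO"
    lo, hi = float(s.isis.min()), float(s.isis.max())
    # two ISI time scales = fast within-event oscillations plus long gaps
    # (a chaotic burster broadens both modes, so this spread test is more
    # robust than counting clean histogram peaks)
    if lo < config.isi_th and hi / lo > config.burst_ratio:
        segs = burst_segments(s.spike_times)
        if len(segs) >= 5:
            st = s.spike_times
            counts = np.array([np.sum((st >= a) & (st <= b))
                               for a, b in segs])
            f_single = float(np.mean(counts == 1))
            f_burst = float(np.mean(counts >= 3))
            # the dust: isolated cardiac spikes incessantly mixed with bursts
            if (f_single >= config.mixed_fraction
                    and f_burst >= config.mixed_fraction):
                return "MIXED_DUST"
            periods = np.diff([a for a, _ in segs]).astype(float)
            durations = np.array([b - a for a, b in segs[:-1]], float)
            duty = float(durations.mean() / periods.mean())
            if duty < config.duty_th:
                # brief depolarized events on a long cycle: cardiac spikes
                # whose plateau carries failed spike attempts, periodic or
                # aperiodic depending on the spread of the event period
                cv = float(periods.std() / periods.mean())
                return "CS" if cv < config.cv_th else "ACS"
        return "SB" if hi > config.ibi_th else "BS"
    if s.mean_isi < config.isi_th:
        return "FS"
    return "CS" if s.cv_isi < config.cv_th else "ACS"


def classify_phase(summary_or_traj,
                   config: ClassifierConfig = ClassifierConfig(),
                   x: Optional[np.ndarray] = None) -> str:
    """Assign one phase label.

    Accepts an :class:`OscillationSummary` or a trajectory / x record.
    The MIXED_DUST verdict refines the burst label: the chaotic band
    between the cardiac and bursting regions incessantly switches between
    isolated cardiac spikes and multi-spike bursts, so a burster whose
    long-gap-separated events are a substantial mixture of single-spike
    and multi-spike events (each above ``mixed_fraction``) is dust.
    """
    if isinstance(summary_or_traj, OscillationSummary):
        s = summary_or_traj
    else:
        x = (summary_or_traj.x if isinstance(summary_or_traj, Trajectory)
             else np.asarray(summary_or_traj, float))
        s = summarize(x, config)
    label = _base_label(s, config)
    s.label = label
    return label


def classify_params(params: ModelParams,
                    config: ClassifierConfig = ClassifierConfig(),
                    init: State = State(0.5, 0.3, 0.0)
                    ) -> Tuple[str, OscillationSummary]:
    """Simulate at ``params`` and classify the resulting attractor."""
    traj = simulate(params, init, n_steps=config.window,
                    discard=config.discard)
    s = summarize(traj.x, config)
    label = classify_phase(s, config, x=traj.x)
    s.label = label
    return label, s


# ------------------------------------------------------------- bursts


def burst_segments(spike_times: np.ndarray,
                   gap: Optional[float] = None) -> List[Tuple[int, int]]:
    """Split a spike train into bursts at ISIs longer than ``gap``.

    With ``gap=None`` the split point is the geometric midpoint between
    the shortest and longest ISI, used only when the ISI spread exceeds a
    decade (otherwise the train is one burst).  Returns (first, last)
    spike times per burst.
    """
    st = np.asarray(spike_times)
    if st.size == 0:
        return []
    isis = np.diff(st)
    if isis.size == 0:
        return [(int(st[0]), int(st[0]))]
    if gap is None:
        if isis.max() / max(isis.min(), 1) < 10.0:
            return [(int(st[0]), int(st[-1]))]
        gap = math.sqrt(isis.min() * isis.max())
    cuts = np.flatnonzero(isis > gap)
    starts = np.concatenate([[0], cuts + 1])
    ends = np.concatenate([cuts, [st.size - 1]])
    return [(int(st[a]), int(st[b])) for a, b in zip(starts, ends)]


def mean_burst_duration(spike_times: np.ndarray,
                        gap: Optional[float] = None,
                        interior_only: bool = True) -> float:
    """Mean duration (first-to-last spike) of the detected bursts.

    ``interior_only`` drops the first and last burst, which the recording
    window may truncate.
    """
    segs = burst_segments(spike_times, gap)
    if interior_only and len(segs) > 2:
        segs = segs[1:-1]
    if not segs:
        return math.nan
    return float(np.mean([b - a for a, b in segs]))


# -------------------------------------------------------------- sweeps

_CORNERS = [State(sx, sy, sz)
            for sx in (-0.9, 0.9) for sy in (-0.9, 0.9) for sz in (-0.5, 0.5)]


def phase_diagram(p1_name: str, p1_values: Sequence[float],
                  p2_name: str, p2_values: Sequence[float],
                  base: ModelParams,
                  config: ClassifierConfig = ClassifierConfig(),
                  init: State = State(0.5, 0.3, 0.0),
                  probe_bistability: bool = False):
    """Label every cell of a 2-parameter grid.

    Returns a pandas DataFrame with columns
    ``p1, p2, label, mean_isi, var_isi, amplitude`` (and the config as
    ``DataFrame.attrs['config']``).  With ``probe_bistability`` each cell
    is re-run from 8 corner states of the cube and marked BI when
    distinct labels coexist.
    """
    import pandas as pd

    rows = []
    for v1 in p1_values:
        for v2 in p2_values:
            params = base.replace(**{p1_name: v1, p2_name: v2})
            label, s = classify_params(params, config, init)
            if probe_bistability:
                seen = {label}
                for c in _CORNERS:
                    l2, _ = classify_params(params, config, c)
                    seen.add(l2)
                    if len(seen) > 1:
                        label = "BI"
                        break
            rows.append((v1, v2, label, s.mean_isi, s.var_isi, s.amplitude_A))
    df = pd.DataFrame(rows, columns=[p1_name, p2_name, "label",
                                     "mean_isi", "var_isi", "amplitude"])
    df.attrs["config"] = config.asdict()
    return df


# ------------------------------------------------------ winding numbers


def winding_number_analytic(Kc: float) -> float:
    """Rotation number on the supercritical Neimark-Sacker line T = Kc:
    w = arccos(1/(2 Kc)) / (2 pi), defined for Kc >= 0.5."""
    if Kc < 0.5:
        raise ValueError("winding number defined only for Kc >= 0.5")
    return math.acos(1.0 / (2.0 * Kc)) / (2.0 * math.pi)


def winding_number_measured(traj: Trajectory, maxQ: int = 64,
                            center: Optional[Tuple[float, float]] = None,
                            period_tol: float = 1e-9
                            ) -> Union[Fraction, float]:
    """Measured rotation number of an oscillatory orbit.

    The phase angle around the orbit's center in the (x, y) plane is
    unwrapped and averaged per step.  If the orbit is exactly Q-periodic
    with Q <= maxQ the result is returned as the rational P/Q.
    """
    x, y = traj.x, traj.y
    if amplitude(traj) < 1e-12:
        raise ValueError("non-oscillatory trajectory")
    cx, cy = center if center is not None else (x.mean(), y.mean())
    theta = np.unwrap(np.arctan2(y - cy, x - cx))
    w = abs(theta[-1] - theta[0]) / (2.0 * math.pi * (x.size - 1))
    # exact periodicity detection
    for Q in range(1, maxQ + 1):
        if x.size > 2 * Q and np.max(np.abs(x[Q:] - x[:-Q])) < period_tol:
            P = round(w * Q)
            if P > 0:
                return Fraction(P, Q)
            break
    return float(w)
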