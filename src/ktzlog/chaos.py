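"""Lyapunov exponents, attractor dimensions and bifurcation scaling laws.

Two independent exponent estimators are provided:

* ``lyapunov_divergence`` — iterate twin orbits separated by ~1e-8 and fit
  log |x2 - x1| against t by least squares over the initial divergence
  (before the separation saturates near the gain range);
* ``lyapunov_eckmann_ruelle`` — accumulate analytic Jacobian products
  along the orbit with periodic re-orthonormalization, yielding the full
  exponent spectrum.

Dimensions: box-counting (capacity) dimension from an attractor sample,
and the Kaplan-Yorke interpolation of the sorted exponent spectrum.

Scaling: near the infinite-period and blue-sky transitions of the slow
subsystem, observables such as the mean ISI or the single-burst duration
diverge as power laws of the distance to the critical parameter; the
bifurcation point is located by bisection on a regime predicate and the
exponent by a log-log least-squares fit close to the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernels
from .model import ModelParams, State, Trajectory, simulate
from .phases import (ClassifierConfig, classify_params, detect_spikes,
                     mean_burst_duration, summarize)

__all__ = [
    "LyapunovResult",
    "ScalingFit",
    "lyapunov_divergence",
    "lyapunov_eckmann_ruelle",
    "capacity_dimension",
    "lyapunov_dimension",
    "locate_bifurcation",
    "sweep_observable",
    "fit_power_law",
    "fit_scaling",
]


@dataclass
class LyapunovResult:
    method: str                       # divergence_fit | eckmann_ruelle
    lambda_max: float                 # per time step
    spectrum: Optional[np.ndarray] = None
    fit_window: Optional[Tuple[int, int]] = None
    r_squared: Optional[float] = None
    shrinking: bool = False           # divergence never grew (stable regime)


@dataclass
class ScalingFit:
    control: str
    critical_value: float
    exponent: float
    stderr: float
    fit_range: Tuple[float, float]
    n_points: int
    decades: float
    distances: np.ndarray = field(repr=False, default=None)
    values: np.ndarray = field(repr=False, default=None)


def lyapunov_divergence(params: ModelParams,
                        init: State = State(1.0, 1.0, 0.0),
                        perturbation: float = 1e-8,
                        horizon: int = 5000,
                        saturation: float = 1e-2) -> LyapunovResult:
    """Largest exponent from the divergence of twin orbits.

    The copy starts with ``perturbation`` added to x(0); the log
    separation is fitted from t = 0 up to (not including) the first step
    where it exceeds ``saturation`` (well below the ~2 bound set by the
    gain range).  In a stable regime the separation shrinks instead and
    the (negative) contraction rate is fitted, with ``shrinking=True``.
    """
    if not 1e-12 <= perturbation <= 1e-4:
        raise ValueError("perturbation must be within [1e-12, 1e-4]")
    t1 = simulate(params, init, n_steps=horizon)
    x0, y0, z0 = init
    t2 = simulate(params, State(x0 + perturbation, y0, z0), n_steps=horizon)
    dx = np.abs(t2.x - t1.x)
    over = np.flatnonzero(dx >= saturation)
    end = int(over[0]) if over.size else horizon
    shrinking = not over.size
    if shrinking:
        # fit only above the double-precision noise floor
        ok = np.flatnonzero(dx < 1e-13)
        end = int(ok[0]) if ok.size else horizon
    t = np.arange(end)
    good = dx[:end] > 0
    logd = np.log(dx[:end][good])
    tt = t[good].astype(float)
    if tt.size < 3:
        raise RuntimeError("divergence fit window too short")
    slope, intercept = np.polyfit(tt, logd, 1)
    pred = slope * tt + intercept
    ss_res = float(np.sum((logd - pred) ** 2))
    ss_tot = float(np.sum((logd - logd.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LyapunovResult("divergence_fit", float(slope),
                          fit_window=(0, end), r_squared=r2,
                          shrinking=shrinking)


def lyapunov_eckmann_ruelle(params: ModelParams,
                            init: State = State(1.0, 1.0, 0.0),
                            n_steps: int = 1_000_000,
                            discard: int = 100_000,
                            renorm: int = 10) -> LyapunovResult:
    """Exponent spectrum from tangent-space Jacobian products.

    Uses the analytic Jacobian of the map (the logistic gain is C^1, so
    tangent propagation is well defined everywhere) with Gram-Schmidt/QR
    re-orthonormalization every ``renorm`` steps.  Returns 2 exponents in
    the fast-subsystem regime, 3 otherwise, sorted descending.
    """
    x0, y0, z0 = (float(v) for v in init)
    if params.is_case1:
        l1, l2 = _kernels.lyapunov_spectrum_caseI(
            x0, y0, params.K, params.T, params.H, discard, n_steps, renorm,
            params.gain_code)
        spec = np.array([l1, l2])
    else:
        spec = _kernels.lyapunov_spectrum_caseII(
            x0, y0, z0, params.K, params.T, params.H, params.delta,
            params.lam, params.xR, discard, n_steps, renorm,
            params.gain_code)
    spec = np.sort(spec)[::-1]
    return LyapunovResult("eckmann_ruelle", float(spec[0]), spectrum=spec)


def capacity_dimension(points: np.ndarray,
                       eps_range: Tuple[float, float] = (2.0 ** -12, 2.0 ** -4),
                       n_scales: int = 9
                       ) -> Tuple[float, float, np.ndarray]:
    """Box-counting dimension of a planar attractor sample.

    ``points``: (n, 2) array.  Box sizes are geometric steps between the
    bounds of ``eps_range`` expressed as fractions of the attractor's
    bounding box.  Returns (slope, stderr_of_slope, (eps, N) table).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    unit = (pts - lo) / span          # normalized to the unit box
    eps = np.geomspace(max(eps_range), min(eps_range), n_scales)
    counts = np.empty(n_scales)
    for i, e in enumerate(eps):
        m = int(math.ceil(1.0 / e))
        ix = np.minimum((unit[:, 0] / e).astype(np.int64), m - 1)
        iy = np.minimum((unit[:, 1] / e).astype(np.int64), m - 1)
        counts[i] = np.unique(ix * m + iy).size
    X = np.log(1.0 / eps)
    Y = np.log(counts)
    slope, stderr = _linfit_stderr(X, Y)
    return slope, stderr, np.column_stack([eps, counts])


def attractor_box_counts(params: ModelParams,
                         init: State = State(1.0, 1.0, 0.0),
                         n_steps: int = 1_000_000_000,
                         discard: int = 100_000,
                         finest: int = 14) -> np.ndarray:
    """Converged box counts of the fast-subsystem attractor in (x, y).

    Iterates the map marking an occupancy grid at resolution 2^-``finest``
    of [-1, 1]^2, then derives N(eps) for every coarser dyadic scale by
    OR-reduction.  Unlike counting a fixed sample of points, the counts
    converge in the orbit length (rare boxes carry very little natural
    measure, so short orbits systematically undercount).  Returns an
    array of (eps, N) rows, eps in fractions of the attractor box.
    """
    if not params.is_case1:
        raise ValueError("attractor_box_counts targets the 2-D fast map")
    m = 2 ** finest
    grid = _kernels.occupy_grid(float(init[0]), float(init[1]),
                                params.K, params.T, params.H,
                                discard, n_steps, m, params.gain_code)
    cur = grid.astype(bool)
    rows = []
    for k in range(finest, 1, -1):
        rows.append((2.0 ** -k, int(cur.sum())))
        cur = cur.reshape(cur.shape[0] // 2, 2,
                          cur.shape[1] // 2, 2).any(axis=(1, 3))
    return np.array(rows[::-1])


def capacity_dimension_from_counts(counts: np.ndarray,
                                   eps_range: Tuple[float, float]
                                   ) -> Tuple[float, float]:
    """Fit the box-count slope over the scales inside ``eps_range``."""
    eps, N = counts[:, 0], counts[:, 1]
    lo, hi = min(eps_range), max(eps_range)
    sel = (eps >= lo * 0.999) & (eps <= hi * 1.001)
    return _linfit_stderr(np.log(1.0 / eps[sel]), np.log(N[sel]))


def _linfit_stderr(X: np.ndarray, Y: np.ndarray) -> Tuple[float, float]:
    n = X.size
    A = np.vstack([X, np.ones(n)]).T
    coef, res, *_ = np.linalg.lstsq(A, Y, rcond=None)
    slope = float(coef[0])
    if n > 2:
        resid = Y - A @ coef
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((X - X.mean()) ** 2))
        stderr = math.sqrt(s2 / sxx)
    else:
        stderr = math.nan
    return slope, stderr


def lyapunov_dimension(spectrum: Sequence[float]) -> float:
    """Kaplan-Yorke dimension from a sorted-descending exponent spectrum:
    D = j + sum_{i<=j} l_i / |l_{j+1}| with j the largest index keeping
    the partial sum non-negative; 0 when every exponent is negative."""
    lam = np.sort(np.asarray(spectrum, float))[::-1]
    if lam[0] < 0:
        return 0.0
    csum = np.cumsum(lam)
    j = int(np.max(np.flatnonzero(csum >= 0))) + 1   # count of exponents kept
    if j >= lam.size:
        return float(lam.size)
    return float(j + csum[j - 1] / abs(lam[j]))


# ------------------------------------------------- bifurcation location


def _predicate(criterion, config: ClassifierConfig,
               init: State) -> Callable[[ModelParams], bool]:
    if callable(criterion):
        return criterion

    def has_spikes(params: ModelParams) -> bool:
        traj = simulate(params, init, n_steps=config.window,
                        discard=config.discard)
        return detect_spikes(traj.x, config.threshold,
                             config.hysteresis).size >= 2

    def is_bursting(params: ModelParams) -> bool:
        # interburst gaps well beyond the typical (median) spiking interval;
        # the median is used because the extremes flicker near a transition
        traj = simulate(params, init, n_steps=config.window,
                        discard=config.discard)
        st = detect_spikes(traj.x, config.threshold, config.hysteresis)
        if st.size < 3:
            return False
        isis = np.diff(st)
        return float(isis.max()) > 5.0 * float(np.median(isis))

    if criterion == "spike_onset":
        return has_spikes
    if criterion == "burst_duration_divergence":
        return is_bursting
    if isinstance(criterion, str) and criterion.startswith("regime_change"):
        inner = criterion[criterion.index("(") + 1:criterion.rindex(")")]
        a, b = (s.strip() for s in inner.split("->"))

        def labels(params: ModelParams) -> bool:
            label, _ = classify_params(params, config, init)
            if label not in (a, b):
                raise RuntimeError(f"probe at {params} gave {label}, "
                                   f"not {a} or {b}")
            return label == a
        return labels
    raise ValueError(f"unknown criterion {criterion!r}")


def locate_bifurcation(params: ModelParams, control: str,
                       bracket: Tuple[float, float],
                       criterion="spike_onset",
                       config: ClassifierConfig = ClassifierConfig(),
                       init: State = State(0.5, 0.3, 0.0),
                       tol: float = 1e-6) -> float:
    """Bisect ``control`` to ``tol`` on a regime predicate.

    ``criterion`` may be 'spike_onset', 'burst_duration_divergence',
    'regime_change(A->B)' or any boolean callable of ModelParams.  Raises
    if the bracket does not straddle the transition.
    """
    pred = _predicate(criterion, config, init)
    a, b = bracket
    fa = pred(params.replace(**{control: a}))
    fb = pred(params.replace(**{control: b}))
    if fa == fb:
        raise ValueError(
            f"bracket {bracket} does not straddle the transition "
            f"(predicate is {fa} at both ends)")
    while abs(b - a) > tol:
        m = 0.5 * (a + b)
        if pred(params.replace(**{control: m})) == fa:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


# --------------------------------------------------------- scaling fits

_OBSERVABLES = ("mean_ISI", "var_ISI", "burst_duration", "IBI")


def _measure(params: ModelParams, observable: str,
             config: ClassifierConfig, init: State) -> float:
    traj = simulate(params, init, n_steps=config.window,
                    discard=config.discard)
    s = summarize(traj.x, config)
    if s.isis.size < 2:
        return math.nan
    if observable == "mean_ISI":
        return s.mean_isi
    if observable == "var_ISI":
        return s.var_isi
    if observable == "IBI":
        return float(s.isis.max())
    if observable == "burst_duration":
        return mean_burst_duration(s.spike_times)
    raise ValueError(f"observable must be one of {_OBSERVABLES}")


def sweep_observable(params: ModelParams, control: str,
                     critical_value: float,
                     distances: Sequence[float],
                     observable: str = "mean_ISI",
                     side: int = +1,
                     config: ClassifierConfig = ClassifierConfig(),
                     init: State = State(0.5, 0.3, 0.0)
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Measure ``observable`` at control = critical + side*d for each d."""
    d = np.asarray(distances, float)
    vals = np.array([
        _measure(params.replace(**{control: critical_value + side * di}),
                 observable, config, init)
        for di in d])
    return d, vals


def fit_power_law(distances: np.ndarray, values: np.ndarray,
                  control: str = "", critical_value: float = math.nan,
                  max_distance: float = 0.1) -> ScalingFit:
    """Log-log least-squares slope of values vs distances.

    Points beyond ``max_distance`` (where the asymptotic law no longer
    holds) and non-finite measurements are dropped; at least 8 valid
    points spanning at least 1.5 decades are required.
    """
    d = np.asarray(distances, float)
    v = np.asarray(values, float)
    good = np.isfinite(v) & (v > 0) & (d > 0) & (d <= max_distance)
    d, v = d[good], v[good]
    if d.size < 8:
        raise ValueError(f"only {d.size} valid points (need >= 8)")
    decades = math.log10(d.max() / d.min())
    if decades < 1.5:
        raise ValueError(f"fit spans {decades:.2f} decades (need >= 1.5)")
    slope, stderr = _linfit_stderr(np.log10(d), np.log10(v))
    return ScalingFit(control, critical_value, slope, stderr,
                      (float(d.min()), float(d.max())), int(d.size),
                      decades, distances=d, values=v)


def fit_scaling(params: ModelParams, control: str, critical_value: float,
                observable: str = "mean_ISI",
                distances: Optional[Sequence[float]] = None,
                side: int = +1,
                config: ClassifierConfig = ClassifierConfig(),
                init: State = State(0.5, 0.3, 0.0)) -> ScalingFit:
    """Measure and fit a power law near a located bifurcation point."""
    if distances is None:
        distances = np.geomspace(1e-3, 1e-1, 13)
    d, v = sweep_observable(params, control, critical_value, distances,
                            observable, side, config, init)
    return fit_power_law(d, v, control, critical_value)
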