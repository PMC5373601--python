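"""Closed-form equilibria, eigenvalues and analytic stability-limit curves.

With the logistic gain the fixed-point condition x* = f(u*) collapses to
the algebraic identity x* = p0 / p with

    p0 = (1 - K) x* + H          (case I;  H -> z* in case II)
    p  = T + |p0|

so equilibria are roots of a quadratic per sign branch s = sign(p0), and
the Jacobian eigenvalues come from low-order polynomials with coefficients
in T, K, delta, lambda and p.  A root is admissible when it is real, lies
in [-1, 1], and its p0 sign agrees with the branch that produced it.

Stability-limit curves in the (K, T) plane at H = 0:

    T = 1 - K        (K <= 0.5)   supercritical pitchfork, 1FP <-> 2FP
    T = K            (K >  0.5)   supercritical Neimark-Sacker, 1FP <-> OA
    T = 1/K + K - 2  (0.5<=K<=1)  subcritical Neimark-Sacker,  2FP <-> OA

All three meet at (K, T) = (0.5, 0.5).  The H(T) limits at fixed K follow
from the same eigenvalue conditions: for K < 0.5 the critical equilibrium
satisfies an eigenvalue-at-+1 (saddle-node/pitchfork) condition giving
x* = +-(1 - sqrt(T/(1-K))), and for K >= 0.5 the unit-modulus
(Neimark-Sacker) condition KT/p^2 = 1 gives x* = +-(1 - sqrt(T/K)); the
bias then reads H = (sqrt((1-K)T) + K - 1) x* resp. (sqrt(KT) + K - 1) x*.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import ModelParams, State, simulate

__all__ = [
    "FixedPointRecord",
    "EigenSolveDetail",
    "BoundaryCurve",
    "fixed_points_case1",
    "fixed_points_case2",
    "eigenvalues_case1",
    "eigenvalues_case2",
    "fixed_points",
    "boundary_curves_case1",
    "boundary_curves_TH",
    "quasistatic_boundary",
    "classify_stability",
]

RESIDUAL_TOL = 1e-12
DEDUP_TOL = 1e-12
MARGINAL_TOL = 1e-3


@dataclass
class EigenSolveDetail:
    """Cubic-solution bookkeeping for the 3-D Jacobian spectrum.

    B is the root centroid -b/(3a) of the monic cubic; U and R are the
    depressed-cubic discriminant combinations (U = 3ac - b^2,
    R = 2b^3 - 9abc + 27a^2 d in monic coefficients) and C, D the complex
    cube-root pair entering the closed-form roots.
    """

    coefficients: np.ndarray
    method: str = "numeric_roots"
    B: complex = 0.0
    C: complex = 0.0
    D: complex = 0.0
    U: complex = 0.0
    R: complex = 0.0
    closed_form_roots: Optional[np.ndarray] = None
    numeric_roots: Optional[np.ndarray] = None
    agreement: Optional[float] = None


@dataclass
class FixedPointRecord:
    """An equilibrium with branch bookkeeping and (optionally) spectrum."""

    x_star: float
    y_star: float
    z_star: float
    s: int                      # sign branch; 0 for the degenerate p0 = 0 root
    p0: float
    p: float
    alpha: Optional[float] = None
    eigenvalues: Optional[np.ndarray] = None
    stability: Optional[str] = None
    marginal: bool = False
    detail: Optional[EigenSolveDetail] = None

    @property
    def state(self) -> State:
        return State(self.x_star, self.y_star, self.z_star)

    def residual(self, params: ModelParams) -> float:
        """|x* - f(u*)| under one exact map step (should be <= 1e-12)."""
        u = (self.x_star - params.K * self.y_star + self.z_star
             + params.H) / params.T
        return abs(self.x_star - u / (1.0 + abs(u)))


@dataclass
class BoundaryCurve:
    """A sampled analytic stability-limit curve."""

    kind: str                      # pitchfork | NS_super | NS_sub | saddle_node | quasi_static
    axes: Tuple[str, str]          # e.g. ("K", "T") or ("T", "H")
    points: np.ndarray             # shape (n, 2)
    K: Optional[float] = None      # fixed K for (T, H) slices


# ----------------------------------------------------------------- case I


def _make_record(x: float, z: float, params: ModelParams, s: int,
                 alpha: Optional[float] = None) -> Optional[FixedPointRecord]:
    p0 = (1.0 - params.K) * x + z + params.H
    p = params.T + abs(p0)
    rec = FixedPointRecord(x, x, z, s, p0, p, alpha=alpha)
    if rec.residual(params) > 1e-9:  # guards against spurious algebra roots
        return None
    return rec


def fixed_points_case1(params: ModelParams) -> List[FixedPointRecord]:
    """All admissible equilibria of the 2-D fast map.

    Solves the per-branch quadratic s(1-K)x^2 + (T + sH + K - 1)x - H = 0
    for s = +-1, keeps roots that are real, within [-1, 1] and whose
    p0 = (1-K)x + H sign matches s, and adds the degenerate p0 = 0 origin
    root when H = 0.
    """
    if not params.is_case1:
        raise ValueError("fixed_points_case1 requires delta = lam = 0")
    K, T, H = params.K, params.T, params.H
    found: List[FixedPointRecord] = []

    def admit(x: float, s: int) -> None:
        if not (math.isfinite(x) and abs(x) <= 1.0 + 1e-12):
            return
        p0 = (1.0 - K) * x + H
        if s * p0 <= 0.0:  # branch sign condition (p0 = 0 handled separately)
            return
        rec = _make_record(x, 0.0, params, s)
        if rec is not None:
            found.append(rec)

    for s in (+1, -1):
        a = s * (1.0 - K)
        b = T + s * H + K - 1.0
        c = -H
        if abs(a) < 1e-300:          # K = 1: the branch equation is linear
            if b != 0.0:
                admit(-c / b, s)
            continue
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            continue
        sq = math.sqrt(disc)
        for root in ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)):
            admit(root, s)

    if H == 0.0:
        # p0 = 0 branch: x* = 0 exactly, kept as its own record (s = 0)
        found.append(FixedPointRecord(0.0, 0.0, 0.0, 0, 0.0, T))

    return _dedupe(found)


def _dedupe(recs: List[FixedPointRecord]) -> List[FixedPointRecord]:
    out: List[FixedPointRecord] = []
    for r in sorted(recs, key=lambda r: r.x_star):
        if out and abs(r.x_star - out[-1].x_star) <= DEDUP_TOL:
            continue
        out.append(r)
    return out


def eigenvalues_case1(fp: FixedPointRecord,
                      params: ModelParams) -> np.ndarray:
    """Roots of L^2 - (T/p^2) L + K T / p^2 = 0 at the equilibrium."""
    T, K, p = params.T, params.K, fp.p
    b = -T / p ** 2
    c = K * T / p ** 2
    disc = cmath.sqrt(b * b - 4.0 * c)
    lams = np.array([(-b + disc) / 2.0, (-b - disc) / 2.0])
    fp.eigenvalues = lams
    fp.stability, fp.marginal = _classify(lams)
    return lams


# ---------------------------------------------------------------- case II


def fixed_points_case2(params: ModelParams) -> List[FixedPointRecord]:
    """Admissible equilibria of the full 3-D map (H = 0 branch analysis).

    With alpha = lambda/delta, z* = alpha (x_R - x*), and x* solves
    s(1-K-alpha)x^2 + (T + s x_R alpha + K - 1 + alpha)x - alpha x_R = 0
    per branch, with the same admissibility conditions as case I after
    substituting H -> z*.
    """
    if params.delta == 0.0:
        if params.lam == 0.0:
            raise ValueError("delta = lam = 0 is the fast subsystem; "
                             "use fixed_points_case1")
        raise ValueError("alpha = lam/delta undefined for delta = 0, lam > 0")
    K, T, xR, H = params.K, params.T, params.xR, params.H
    alpha = params.lam / params.delta
    found: List[FixedPointRecord] = []

    def admit(x: float, s: int) -> None:
        if not (math.isfinite(x) and abs(x) <= 1.0 + 1e-12):
            return
        z = alpha * (xR - x)
        p0 = (1.0 - K) * x + z + H
        if s * p0 <= 0.0:
            return
        rec = _make_record(x, z, params, s, alpha=alpha)
        if rec is not None:
            found.append(rec)

    for s in (+1, -1):
        a = s * (1.0 - K - alpha)
        b = T + s * xR * alpha + K - 1.0 + alpha + s * H
        c = -alpha * xR - H
        if abs(a) < 1e-300:
            if b != 0.0:
                admit(-c / b, s)
            continue
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            continue
        sq = math.sqrt(disc)
        for root in ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)):
            admit(root, s)

    # degenerate p0 = 0 root: x* = p0/p = 0 requires z* + H = 0
    if alpha * xR + H == 0.0:
        found.append(FixedPointRecord(0.0, 0.0, alpha * xR, 0, 0.0, T,
                                      alpha=alpha))
    return _dedupe(found)


def _cardano(coeffs: Sequence[float]) -> Tuple[np.ndarray, EigenSolveDetail]:
    """Closed-form roots of a x^3 + b x^2 + c x + d (complex Cardano)."""
    a, b, c, d = (float(v) for v in coeffs)
    bb, cc, dd = b / a, c / a, d / a
    d0 = bb * bb - 3.0 * cc
    d1 = 2.0 * bb ** 3 - 9.0 * bb * cc + 27.0 * dd
    inner = cmath.sqrt(d1 * d1 - 4.0 * d0 ** 3)
    # pick the cube-root argument of larger modulus to avoid C = 0
    cand1 = (d1 + inner) / 2.0
    cand2 = (d1 - inner) / 2.0
    base = cand1 if abs(cand1) >= abs(cand2) else cand2
    C = base ** (1.0 / 3.0)
    detail = EigenSolveDetail(
        coefficients=np.array([a, b, c, d]), method="closed_form",
        B=-bb / 3.0, U=-d0, R=d1, C=C,
        D=(d0 / C if C != 0 else 0.0))
    zeta = complex(-0.5, math.sqrt(3.0) / 2.0)
    roots = []
    for k in range(3):
        Ck = C * zeta ** k
        if Ck == 0:          # triple root
            roots.append(-bb / 3.0 + 0j)
        else:
            roots.append(-(bb + Ck + d0 / Ck) / 3.0)
    arr = np.array(roots)
    detail.closed_form_roots = arr
    return arr, detail


def eigenvalues_case2(fp: FixedPointRecord, params: ModelParams,
                      require_agreement: bool = True) -> np.ndarray:
    """Spectrum of the 3-D Jacobian at the equilibrium.

    Roots of  p^2 L^3 - [T + (1-delta) p^2] L^2
              + T (K + lambda + 1 - delta) L - K T (1-delta) = 0,
    computed both by numpy's polynomial solver (authoritative) and by the
    Cardano closed form (cross-check, must agree to 1e-8 relative away
    from branch-cut degeneracies).
    """
    K, T, dl, lm = params.K, params.T, params.delta, params.lam
    p = fp.p
    coeffs = np.array([
        p * p,
        -(T + (1.0 - dl) * p * p),
        T * (K + lm + 1.0 - dl),
        -K * T * (1.0 - dl),
    ])
    numeric = np.roots(coeffs)
    closed, detail = _cardano(coeffs)
    detail.numeric_roots = numeric
    # pair closed-form roots to numeric ones greedily
    remaining = list(closed)
    worst = 0.0
    for lam_n in numeric:
        j = int(np.argmin([abs(lam_n - lc) for lc in remaining]))
        err = abs(lam_n - remaining.pop(j)) / max(1.0, abs(lam_n))
        worst = max(worst, err)
    detail.agreement = worst
    detail.method = "numeric_roots"
    if require_agreement and worst > 1e-8:
        detail.method = "numeric_roots (closed form degenerate)"
    lams = numeric[np.argsort(-np.abs(numeric))]
    fp.eigenvalues = lams
    fp.detail = detail
    fp.stability, fp.marginal = _classify(lams)
    return lams


def fixed_points(params: ModelParams,
                 with_eigenvalues: bool = True) -> List[FixedPointRecord]:
    """Dispatch on the parameter regime and optionally attach spectra."""
    if params.is_case1:
        recs = fixed_points_case1(params)
        if with_eigenvalues:
            for r in recs:
                eigenvalues_case1(r, params)
    else:
        recs = fixed_points_case2(params)
        if with_eigenvalues:
            for r in recs:
                eigenvalues_case2(r, params)
    return recs


# ------------------------------------------------------ stability classes


def _classify(lams: np.ndarray) -> Tuple[str, bool]:
    mags = np.abs(lams)
    marginal = bool(abs(mags.max() - 1.0) <= MARGINAL_TOL)
    real = np.all(np.abs(lams.imag) < 1e-12)
    if real:
        signs = np.sign(lams.real[np.abs(lams.real) > 1e-300])
        if signs.size >= 2 and signs.min() != signs.max():
            return "saddle", marginal
    return ("stable" if mags.max() < 1.0 else "unstable"), marginal


def classify_stability(fp: FixedPointRecord, params: ModelParams,
                       verify: bool = True,
                       perturbation: float = 1e-6,
                       n_steps: int = 10_000) -> str:
    """Stability label, optionally verified by perturb-and-iterate.

    When the spectrum is away from the unit circle (|max|L|-1| > 1e-3) the
    simulation verdict (re-convergence vs departure of a 1e-6 perturbation
    after 1e4 steps) must match the eigenvalue classification; marginal
    equilibria are flagged and not simulation-checked.
    """
    if fp.eigenvalues is None:
        if params.is_case1:
            eigenvalues_case1(fp, params)
        else:
            eigenvalues_case2(fp, params)
    label = fp.stability
    if fp.marginal or not verify:
        return label
    init = State(fp.x_star + perturbation, fp.y_star, fp.z_star)
    traj = simulate(params, init, n_steps=1, discard=n_steps - 1)
    dist = abs(traj.x[-1] - fp.x_star)
    converged = dist < perturbation * 1e-2
    departed = dist > perturbation * 1e2
    expect_stable = label == "stable"
    if expect_stable and departed:
        raise AssertionError(
            f"eigenvalues say stable but perturbation grew to {dist:g}")
    if not expect_stable and converged and label != "saddle":
        raise AssertionError(
            f"eigenvalues say {label} but perturbation decayed to {dist:g}")
    return label


# ------------------------------------------------------- boundary curves


def boundary_curves_case1(K_range: Tuple[float, float] = (1e-3, 2.0),
                          n: int = 400) -> List[BoundaryCurve]:
    """The three H = 0 stability limits in the (K, T) plane."""
    lo, hi = K_range
    curves = []
    K = np.linspace(lo, min(hi, 0.5), n)
    curves.append(BoundaryCurve("pitchfork", ("K", "T"),
                                np.column_stack([K, 1.0 - K])))
    if hi > 0.5:
        K = np.linspace(0.5, hi, n)
        curves.append(BoundaryCurve("NS_super", ("K", "T"),
                                    np.column_stack([K, K])))
    if hi > 0.5:
        K = np.linspace(0.5, min(hi, 1.0), n)
        curves.append(BoundaryCurve("NS_sub", ("K", "T"),
                                    np.column_stack([K, 1.0 / K + K - 2.0])))
    return curves


def boundary_curves_TH(K: float, n: int = 400) -> List[BoundaryCurve]:
    """Fixed-point stability limits in the (T, H) plane at fixed K.

    Derived from the eigenvalue conditions on Eq-type (14)-(15) spectra:
    the critical x* = +-(1 - sqrt(T/(1-K))) (K < 0.5, real eigenvalue at
    +1) or +-(1 - sqrt(T/K)) (K >= 0.5, unit modulus), and
    H = (sqrt((1-K)T) + K - 1) x*   resp.   (sqrt(KT) + K - 1) x*.
    """
    curves: List[BoundaryCurve] = []
    if K < 0.5:
        Tmax, coef_in = 1.0 - K, 1.0 - K
        kind = "saddle_node"
    else:
        Tmax, coef_in = K, K
        kind = "NS_sub"
    T = np.linspace(1e-6, Tmax, n)
    xs = 1.0 - np.sqrt(T / coef_in)
    Hc = (np.sqrt(coef_in * T) + K - 1.0) * xs
    for sign, tag in ((+1, "+"), (-1, "-")):
        curves.append(BoundaryCurve(kind, ("T", "H"),
                                    np.column_stack([T, sign * Hc]), K=K))
    return curves


def quasistatic_boundary(K: float, T: float) -> Tuple[float, float]:
    """Adiabatic (slow-z) estimate of the FP/oscillation boundary in x_R.

    Treating z as a frozen bias, the fixed point loses stability at
    x_R = +-(K - T), valid for 0 < delta = lambda << 1.
    """
    return (K - T, -(K - T))
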