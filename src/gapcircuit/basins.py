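"""Attraction basins on the biological initial-condition segment Omega.

Biologically meaningful initial conditions form the segment
Omega = {0 <= v_Hb <= 100, v_Kr = v_Gt = v_Kni = 0} of the 4-D phase space:
a maternal Hb level with the zygotic genes off.  For a fixed spatial
position (equivalently a fixed (Bcd, Cad) pair) the basin of each point
attractor restricted to Omega is a union of intervals (c1, c2) on the Hb
axis.  Basins are estimated by integrating the shorted model from uniform
random Hb draws through the nonautonomous phase until the flow stabilizes,
assigning endpoints to attractors, and optionally sharpening the interval
boundaries by bisection.  Boundary values at successive nuclei are joined
by linear spatial interpolation into continuous boundary curves, whose
crossings with the maternal Hb gradient predict where the hb border forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core_model import CircuitParameters, MitosisSchedule
from .phase_space import Equilibrium, find_equilibria

__all__ = [
    "OMEGA_HB_RANGE",
    "BasinInterval",
    "BasinPartition",
    "BasinBoundaryCurve",
    "settle_from",
    "settle_batch",
    "integrate_omega_batch",
    "sample_basin_partition",
    "basin_boundary_profile",
    "intersect_initial_hb",
]

#: Hb range of the biological initial-condition segment Omega.
OMEGA_HB_RANGE: tuple[float, float] = (0.0, 100.0)

#: Attractor capture radius (concentration units).
DELTA_A = 1.0

#: Stabilization test: autonomous RHS sup-norm below this, or t_end reached.
STABILIZE_RHS_TOL = 1e-6
DEFAULT_T_END = 1000.0


@dataclass
class BasinInterval:
    attractor_label: str
    c1: float
    c2: float

    @property
    def length(self) -> float:
        return self.c2 - self.c1


@dataclass
class BasinPartition:
    """Per-attractor intervals of Omega's Hb axis at one spatial position."""

    position: float | tuple[float, float]  # x %EL or (v_bcd, v_cad)
    intervals: list[BasinInterval]
    gaps: list[tuple[float, float]]
    n_samples: int
    unresolved_fraction: float = 0.0
    attractors: list[Equilibrium] = field(default_factory=list)

    def total_measure(self) -> float:
        return sum(iv.length for iv in self.intervals) + sum(b - a for a, b in self.gaps)

    def owner_of(self, hb0: float) -> str:
        """Label of the attractor whose basin contains initial Hb = hb0."""
        for iv in self.intervals:
            if iv.c1 - 1e-12 <= hb0 <= iv.c2 + 1e-12:
                return iv.attractor_label
        raise ValueError(f"initial Hb {hb0} falls in an unresolved gap")

    def boundaries(self) -> list[tuple[str, str, float]]:
        """Adjacent-interval boundaries as (lower_label, upper_label, hb value)."""
        out = []
        ivs = sorted(self.intervals, key=lambda iv: iv.c1)
        for a, b in zip(ivs[:-1], ivs[1:]):
            if a.attractor_label != b.attractor_label and abs(a.c2 - b.c1) < 1e-9:
                out.append((a.attractor_label, b.attractor_label, a.c2))
        return out


@dataclass
class BasinBoundaryCurve:
    """Piecewise-linear spatial profile of one basin boundary."""

    boundary_id: tuple[str, str]
    x: np.ndarray
    hb: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.hb = np.asarray(self.hb, dtype=float)
        if len(self.x) != len(self.hb):
            raise ValueError("x and hb must have equal length")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x[0] - 1e-9) or np.any(x > self.x[-1] + 1e-9):
            raise ValueError("query outside the x-range where the boundary exists")
        out = np.interp(x, self.x, self.hb)
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Trajectory settling
# ---------------------------------------------------------------------------


def _g(u):
    return 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)


def _as_per_sample(value, t, n):
    """Broadcast a Bcd/Cad specification to one value per stacked sample."""
    if callable(value):
        value = value(t)
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError("per-sample input must be scalar or length-n")
    return arr


def _batch_rhs(params: CircuitParameters, schedule: MitosisSchedule, bcd, cad, n: int, gated: bool):
    """Stacked shorted-model RHS for n independent nuclei/initial conditions."""

    def fun(t, y):
        V = y.reshape(n, 4)
        b = _as_per_sample(bcd, t, n)
        c = _as_per_sample(cad, t, n)
        u = (
            V @ params.T.T
            + b[:, None] * params.bcd_weight[None, :]
            + c[:, None] * params.ext_weight[None, :, 0]
            + params.h[None, :]
        )
        chi = schedule.chi(t) if gated else 1.0
        dV = params.R * chi * _g(u) - params.lambda_ * V
        return dV.ravel()

    return fun


def integrate_omega_batch(
    hb0s: np.ndarray,
    bcd,
    cad,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    t_final: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> np.ndarray:
    """States at ``t_final`` for a batch of Omega initial conditions.

    ``bcd`` and ``cad`` may be scalars, per-sample arrays, or callables of
    time (returning scalar or per-sample values), so a whole row of nuclei
    can be integrated in one stacked solve.  The run follows the shorted
    model protocol: mitosis gating until T6 and the autonomous flow after.
    Defaults to ``t_final`` = tau (gastrulation).
    """
    hb0s = np.atleast_1d(np.asarray(hb0s, dtype=float))
    n = len(hb0s)
    V0 = np.zeros((n, 4))
    V0[:, 0] = hb0s
    if t_final is None:
        t_final = schedule.tau
    cuts = [schedule.t0] + [
        float(c) for c in schedule.breakpoints() if schedule.t0 < c < t_final
    ] + [float(t_final)]
    fun = _batch_rhs(params, schedule, bcd, cad, n, gated=True)
    y = V0.ravel()
    for a, b in zip(cuts[:-1], cuts[1:]):
        res = solve_ivp(fun, (a, b), y, method="LSODA", rtol=rtol, atol=atol)
        if not res.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {res.message}")
        y = res.y[:, -1]
    return y.reshape(n, 4)


def settle_batch(
    hb0s: np.ndarray,
    bcd,
    cad,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    t_end: float = DEFAULT_T_END,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    protocol: str = "full",
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of Omega initial conditions until the flow stabilizes.

    Each initial condition is (hb0, 0, 0, 0).  With ``protocol="full"`` the
    trajectories run through the nonautonomous phase (mitosis gating, Cad
    time dependence) up to the T6 freeze and then under the autonomous
    flow; with ``protocol="autonomous"`` the autonomous flow acts from the
    start, the setting in which the computed partition coincides with the
    basins of the autonomous system (used by the toy-system oracles).  The
    autonomous phase is integrated in windows until the RHS sup-norm of
    every trajectory falls below the stabilization tolerance or ``t_end``
    model minutes have elapsed.

    Returns (endpoints (n, 4), stabilized mask (n,)).
    """
    if protocol not in ("full", "autonomous"):
        raise ValueError("protocol must be 'full' or 'autonomous'")
    hb0s = np.atleast_1d(np.asarray(hb0s, dtype=float))
    n = len(hb0s)
    cad_t6 = cad(schedule.t_T6) if callable(cad) else cad

    if protocol == "full":
        V = integrate_omega_batch(
            hb0s, bcd, cad, params, schedule, schedule.t_T6, rtol, atol
        )
    else:
        V = np.zeros((n, 4))
        V[:, 0] = hb0s

    fun_auto = _batch_rhs(params, schedule, bcd, cad_t6, n, gated=False)

    def max_residual(y):
        return np.max(np.abs(fun_auto(0.0, y).reshape(n, 4)), axis=1)

    y = V.ravel()
    t_done = 0.0
    window = 100.0
    while t_done < t_end:
        if np.all(max_residual(y) < STABILIZE_RHS_TOL):
            break
        step = min(window, t_end - t_done)
        res = solve_ivp(fun_auto, (0.0, step), y, method="LSODA", rtol=rtol, atol=atol)
        if not res.success:
            raise RuntimeError(f"integration failed in autonomous phase: {res.message}")
        y = res.y[:, -1]
        t_done += step
    stabilized = max_residual(y) < STABILIZE_RHS_TOL
    return y.reshape(n, 4), stabilized


def settle_from(
    hb0: float,
    bcd: float,
    cad: Callable[[float], float] | float,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    t_end: float = DEFAULT_T_END,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    protocol: str = "full",
) -> tuple[np.ndarray, bool]:
    """Single-trajectory convenience wrapper around :func:`settle_batch`."""
    endpoints, ok = settle_batch(
        np.array([hb0]), bcd, cad, params, schedule, t_end, rtol, atol, protocol
    )
    return endpoints[0], bool(ok[0])


def _assign(endpoint: np.ndarray, attractors: list[Equilibrium], delta: float) -> str | None:
    for eq in attractors:
        if np.linalg.norm(endpoint - eq.state) < delta:
            return eq.label or eq.code
    return None


# ---------------------------------------------------------------------------
# Partition sampling
# ---------------------------------------------------------------------------


def sample_basin_partition(
    bcd: float,
    cad: Callable[[float], float] | float,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    n_samples: int = 10_000,
    seed: int = 0,
    t_end: float = DEFAULT_T_END,
    delta_a: float = DELTA_A,
    refine_bisection: bool = True,
    bisect_tol: float = 1e-3,
    position: float | tuple[float, float] | None = None,
    attractors: list[Equilibrium] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    protocol: str = "full",
    batch_size: int = 250,
) -> BasinPartition:
    """Monte-Carlo basin partition of Omega at one (Bcd, Cad input) position.

    Uniform Hb draws on [0, 100] (seeded, reproducible), each integrated
    through the nonautonomous phase and on until stabilization, then
    assigned to the attractor within ``delta_a`` of its endpoint.  Interval
    boundaries between opposing neighbouring samples are optionally
    sharpened by bisection to ``bisect_tol``.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    cad_t6 = cad(schedule.t_T6) if callable(cad) else float(cad)
    if attractors is None:
        attractors = [
            e for e in find_equilibria(bcd, cad_t6, params) if e.is_attractor
        ]
        for k, e in enumerate(attractors):
            if not e.label:
                e.label = f"A{k + 1}"

    rng = np.random.default_rng(seed)
    draws = np.sort(rng.uniform(*OMEGA_HB_RANGE, size=n_samples))
    # include the segment ends so intervals span exactly [0, 100]
    draws = np.concatenate([[OMEGA_HB_RANGE[0]], draws, [OMEGA_HB_RANGE[1]]])

    labels: list[str | None] = []
    n_unresolved = 0
    for start in range(0, len(draws), batch_size):
        chunk = draws[start : start + batch_size]
        endpoints, ok = settle_batch(
            chunk, bcd, cad, params, schedule, t_end, rtol, atol, protocol
        )
        for endpoint, good in zip(endpoints, ok):
            lab = _assign(endpoint, attractors, delta_a) if good else None
            if lab is None:
                n_unresolved += 1
            labels.append(lab)
    frac = n_unresolved / len(draws)
    if frac > 0.01:
        warnings.warn(f"{frac:.1%} of samples unresolved at position {position}", stacklevel=2)

    def classify_point(hb0: float) -> str | None:
        endpoint, good = settle_from(
            hb0, bcd, cad, params, schedule, t_end, rtol, atol, protocol
        )
        return _assign(endpoint, attractors, delta_a) if good else None

    # split points between runs of distinct labels
    splits = [OMEGA_HB_RANGE[0]]
    run_labels = [labels[0]]
    for k in range(1, len(draws)):
        if labels[k] != labels[k - 1]:
            lo, hi = draws[k - 1], draws[k]
            if refine_bisection and labels[k - 1] is not None and labels[k] is not None:
                lo_lab = labels[k - 1]
                while hi - lo > bisect_tol:
                    mid = 0.5 * (lo + hi)
                    if classify_point(mid) == lo_lab:
                        lo = mid
                    else:
                        hi = mid
            splits.append(0.5 * (lo + hi))
            run_labels.append(labels[k])
    splits.append(OMEGA_HB_RANGE[1])

    intervals = []
    gaps = []
    for lab, a, b in zip(run_labels, splits[:-1], splits[1:]):
        if b <= a:
            continue
        if lab is None:
            gaps.append((a, b))
        else:
            intervals.append(BasinInterval(lab, a, b))
    # merge touching intervals with the same label
    merged: list[BasinInterval] = []
    for iv in intervals:
        if merged and merged[-1].attractor_label == iv.attractor_label and abs(merged[-1].c2 - iv.c1) < 1e-12:
            merged[-1] = BasinInterval(iv.attractor_label, merged[-1].c1, iv.c2)
        else:
            merged.append(iv)
    if sum(1 for iv in merged) > 0:
        by_label: dict[str, int] = {}
        for iv in merged:
            by_label[iv.attractor_label] = by_label.get(iv.attractor_label, 0) + 1
        if any(v > 5 for v in by_label.values()):
            warnings.warn(f"basin with >5 disjoint components at {position}", stacklevel=2)
    return BasinPartition(
        position if position is not None else (bcd, cad_t6),
        merged, gaps, n_samples, frac, attractors,
    )


# ---------------------------------------------------------------------------
# Boundary curves and intersections
# ---------------------------------------------------------------------------


def basin_boundary_profile(
    partitions: list[BasinPartition], boundary_id: tuple[str, str]
) -> BasinBoundaryCurve:
    """Piecewise-linear spatial profile of one basin boundary.

    ``partitions`` must be ordered by (scalar) position.  A position
    contributes every adjacent-interval boundary matching ``boundary_id``
    in either orientation; with disjoint basins each component boundary is
    a separate sample (they are concatenated in Hb order at that position).
    """
    xs: list[float] = []
    hbs: list[float] = []
    want = {boundary_id, boundary_id[::-1]}
    for p in partitions:
        if not isinstance(p.position, (int, float)):
            raise ValueError("boundary profiles need scalar x positions")
        for lo, hi, val in p.boundaries():
            if (lo, hi) in want:
                xs.append(float(p.position))
                hbs.append(val)
    if not xs:
        raise ValueError(f"boundary {boundary_id} absent at every position")
    if len(xs) == 1:
        warnings.warn(f"boundary {boundary_id} present at a single position", stacklevel=2)
    order = np.argsort(xs)
    return BasinBoundaryCurve(boundary_id, np.asarray(xs)[order], np.asarray(hbs)[order])


def intersect_initial_hb(
    hb0: Callable[[float], float], curve: BasinBoundaryCurve, xtol: float = 0.01
) -> list[float]:
    """All crossings of the maternal Hb gradient with a basin boundary curve.

    Sign changes of hb0(x) - curve(x) over the curve's x-range are located
    by bisection to ``xtol`` %EL, ordered anterior to posterior.
    """
    if len(curve.x) < 2:
        return []
    a, b = float(curve.x[0]), float(curve.x[-1])
    grid = np.linspace(a, b, max(200, int((b - a) / xtol) + 1))

    def f(x):
        return float(hb0(x)) - float(curve(x))

    vals = np.array([f(x) for x in grid])
    roots = []
    for k in range(len(grid) - 1):
        v1, v2 = vals[k], vals[k + 1]
        if v1 == 0.0:
            roots.append(float(grid[k]))
        elif v1 * v2 < 0:
            roots.append(float(brentq(f, grid[k], grid[k + 1], xtol=xtol * 1e-2)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return sorted(roots)
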