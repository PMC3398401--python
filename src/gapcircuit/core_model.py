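"""Gap gene circuit equations and their integration.

The model describes the concentrations of the four gap proteins Hb, Kr, Gt
and Kni in nuclei along the anterior-posterior (A-P) axis of the early
*Drosophila* blastoderm, from the start of cleavage cycle 13 to the onset of
gastrulation at the end of cycle 14A.  Each nucleus obeys

    dv_i^a/dt = R^a * chi(t) * g(u_i^a) - lambda^a * v_i^a
                + D^a(n) * [(v_{i-1}^a - v_i^a) + (v_{i+1}^a - v_i^a)]

where ``u_i^a`` collects the regulatory input to gene ``a`` in nucleus ``i``:
the gap cross-regulation ``sum_b T[a][b] v_i^b``, the maternal Bicoid input,
external inputs from Caudal and Tailless, and a threshold offset ``h^a``.
``g`` is a sigmoid synthesis-regulation function, ``chi(t)`` gates synthesis
off during mitosis, and the diffusion term is dropped at the domain ends.

The "shorted" model is the diffusionless (and Tll-less) per-nucleus
reduction, which decouples nuclei into independent four-dimensional
dynamical systems parameterised by the local Bcd and Cad concentrations.
After the end of time class T6 of cycle 14A the Cad input and chi are
frozen, making the shorted system autonomous; that autonomous system is the
object of the phase-space analysis in :mod:`gapcircuit.phase_space`.

Concentrations are in relative units on a 0-255 scale, positions in percent
egg length (%EL), time in minutes, rates in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GENES",
    "N_GENES",
    "GeneSet",
    "CircuitParameters",
    "MitosisSchedule",
    "NuclearLattice",
    "StateMatrix",
    "ExternalInputTable",
    "Trajectory",
    "FullCircuitSolution",
    "regulation_g",
    "regulation_g_prime",
    "total_input",
    "rhs_shorted",
    "rhs_autonomous",
    "rhs_full",
    "build_lattice",
    "apply_nuclear_division",
    "integrate_shorted_nucleus",
    "integrate_full_circuit",
    "FULL_DOMAIN",
    "ANALYSIS_WINDOW",
]

#: Gene order used everywhere: state vectors, parameter rows, attractor codes.
GENES: tuple[str, ...] = ("hb", "Kr", "gt", "kni")
N_GENES: int = 4

#: Full modelled spatial domain and the restricted hb-border analysis window, %EL.
FULL_DOMAIN: tuple[float, float] = (35.0, 92.0)
ANALYSIS_WINDOW: tuple[float, float] = (37.0, 57.0)

#: Columns of the external-input weight matrix.
EXTERNAL_FACTORS: tuple[str, ...] = ("Cad", "Tll")


class GeneSet:
    """Fixed ordered set of the four modelled gap genes."""

    names = GENES

    @classmethod
    def index(cls, name: str) -> int:
        try:
            return cls.names.index(name)
        except ValueError:
            raise KeyError(f"unknown gap gene {name!r}; expected one of {cls.names}")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return N_GENES


# ---------------------------------------------------------------------------
# Parameters, schedule, lattice, state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircuitParameters:
    """All regulatory constants of the circuit.

    Attributes
    ----------
    R : (4,) maximal synthesis rates, concentration/min.
    T : (4, 4) interaction matrix; ``T[a, b]`` is the action of gene ``b``
        on gene ``a`` (weight per concentration unit).
    bcd_weight : (4,) weight of the Bcd input per gene (the ``m^a`` of the
        gene-circuit literature).
    ext_weight : (4, 2) weights of the external inputs, columns (Cad, Tll).
    h : (4,) threshold offsets (dimensionless).
    lambda_ : (4,) protein decay rates, 1/min; strictly positive.
    D : (2, 4) diffusion rates, 1/min; rows are cleavage cycles (13, 14A).
    """

    R: np.ndarray
    T: np.ndarray
    bcd_weight: np.ndarray
    ext_weight: np.ndarray
    h: np.ndarray
    lambda_: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        for name in ("R", "T", "bcd_weight", "ext_weight", "h", "lambda_", "D"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.R.shape != (N_GENES,) or self.h.shape != (N_GENES,):
            raise ValueError("R and h must have shape (4,)")
        if self.T.shape != (N_GENES, N_GENES):
            raise ValueError("T must have shape (4, 4)")
        if self.bcd_weight.shape != (N_GENES,):
            raise ValueError("bcd_weight must have shape (4,)")
        if self.ext_weight.shape != (N_GENES, len(EXTERNAL_FACTORS)):
            raise ValueError("ext_weight must have shape (4, 2): columns (Cad, Tll)")
        if self.lambda_.shape != (N_GENES,) or np.any(self.lambda_ <= 0):
            raise ValueError("lambda_ must be shape (4,) and strictly positive")
        if self.D.shape == (N_GENES,):  # convenience: same D in both cycles
            object.__setattr__(self, "D", np.vstack([self.D, self.D]))
        if self.D.shape != (2, N_GENES) or np.any(self.D < 0):
            raise ValueError("D must be shape (2, 4) (cycles 13, 14A) and >= 0")

    def d_for_cycle(self, cycle: int) -> np.ndarray:
        if cycle == 13:
            return self.D[0]
        if cycle == 14:
            return self.D[1]
        raise ValueError(f"cycle must be 13 or 14 (14A), got {cycle}")

    def with_knocked_out_row(self, gene: str) -> "CircuitParameters":
        """Copy with the gap-gene cross-regulation row of ``gene`` zeroed."""
        a = GeneSet.index(gene)
        T = self.T.copy()
        T[a, :] = 0.0
        return replace(self, T=T)


@dataclass(frozen=True)
class MitosisSchedule:
    """Timing of cleavage cycles 13 and 14A.

    Defaults follow the gene-circuit convention: cycle 13 starts at t0 = 0,
    interphase 13 lasts 16.0 min, mitosis 13 lasts 5.1 min, and cycle 14A
    spans 50 min subdivided into eight equal time classes T1-T8 of 6.25 min,
    ending at gastrulation time tau = 71.1 min.  chi(t) = 0 during mitosis
    and 1 otherwise; chi is held at 1 (and external inputs frozen) after the
    end of time class T6.
    """

    t0: float = 0.0
    interphase13_end: float = 16.0
    mitosis13_end: float = 21.1
    cycle14A_end: float = 71.1

    def __post_init__(self) -> None:
        if not (self.t0 < self.interphase13_end < self.mitosis13_end < self.cycle14A_end):
            raise ValueError("schedule times must be strictly increasing")
        if not self.mitosis13_end < self.t_T6 < self.cycle14A_end:
            raise ValueError("T6 must fall strictly inside cycle 14A")

    @property
    def tau(self) -> float:
        """Gastrulation time: end of cleavage cycle 14A (min)."""
        return self.cycle14A_end

    @property
    def time_class_edges(self) -> np.ndarray:
        """Nine edges of the eight equal time classes T1..T8 of cycle 14A."""
        return np.linspace(self.mitosis13_end, self.cycle14A_end, 9)

    @property
    def t_T6(self) -> float:
        """End of time class T6, after which the equations are autonomous."""
        return float(self.time_class_edges[6])

    def chi(self, t: float) -> float:
        """Synthesis gate: 0 during mitosis 13, 1 otherwise."""
        if self.interphase13_end <= t < self.mitosis13_end:
            return 0.0
        return 1.0

    def breakpoints(self) -> np.ndarray:
        """Times at which the right-hand side is non-smooth (for restarts)."""
        return np.array([self.interphase13_end, self.mitosis13_end, self.t_T6])


@dataclass(frozen=True)
class NuclearLattice:
    """Nuclei positions along the A-P axis for one cleavage cycle."""

    cycle: int  # 13 or 14 (== 14A)
    positions: np.ndarray
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("lattice positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class StateMatrix:
    """Concentrations v[a][i] (gene x nucleus) at one time point."""

    time: float
    values: np.ndarray  # shape (4, M)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_GENES:
            raise ValueError("values must have shape (4, M)")


class ExternalInputTable:
    """Spatio-temporal concentration table for one external factor (Cad or Tll).

    Linear interpolation in time between sample times and linear in space
    between sample positions; constant extrapolation outside the sampled
    range; evaluation for t > freeze_time (end of T6) returns the value at
    freeze_time.
    """

    def __init__(
        self,
        factor: str,
        x: Sequence[float],
        times: Sequence[float],
        values: np.ndarray,
        freeze_time: float,
    ) -> None:
        self.factor = factor
        self.x = np.asarray(x, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)  # shape (n_times, n_x)
        self.freeze_time = float(freeze_time)
        if self.values.shape != (len(self.times), len(self.x)):
            raise ValueError("values must have shape (n_times, n_x)")
        if np.any(self.values < 0):
            raise ValueError(f"{factor} concentrations must be non-negative")
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("x and times must be strictly increasing")

    def at(self, x: np.ndarray | float, t: float) -> np.ndarray:
        """Concentration at position(s) ``x`` and time ``t``."""
        t = min(float(t), self.freeze_time)
        row = np.empty(len(self.x))
        for j in range(len(self.x)):
            row[j] = np.interp(t, self.times, self.values[:, j])
        return np.interp(x, self.x, row)

    def series_at(self, x: float) -> Callable[[float], float]:
        """Time series of this factor at a fixed position, as a callable."""
        col = np.array([np.interp(x, self.x, self.values[k]) for k in range(len(self.times))])
        times = self.times
        freeze = self.freeze_time

        def series(t: float) -> float:
            return float(np.interp(min(float(t), freeze), times, col))

        return series


# ---------------------------------------------------------------------------
# Regulation function and right-hand sides
# ---------------------------------------------------------------------------


def regulation_g(u):
    """Sigmoid synthesis-regulation function g(u) = (u / sqrt(u^2 + 1) + 1) / 2.

    Strictly increasing, g(0) = 1/2, g(u) + g(-u) = 1, range (0, 1).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("regulation input u must be finite")
    out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    return float(out) if out.ndim == 0 else out


def regulation_g_prime(u):
    """Derivative g'(u) = (1 + u^2)^(-3/2) / 2 of the regulation sigmoid."""
    u = np.asarray(u, dtype=float)
    out = 0.5 * (1.0 + u * u) ** -1.5
    return float(out) if out.ndim == 0 else out


def total_input(
    gene: int,
    state: np.ndarray,
    bcd: float,
    ext: Sequence[float],
    params: CircuitParameters,
) -> float:
    """Total regulatory input u^a for one gene in one nucleus.

    ``ext`` holds the external-factor concentrations in the (Cad, Tll)
    column order of ``params.ext_weight``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_GENES,):
        raise ValueError("state must be a 4-vector")
    ext = np.asarray(ext, dtype=float)
    if ext.shape != (len(EXTERNAL_FACTORS),):
        raise ValueError("ext must have one concentration per external factor")
    return float(
        params.T[gene] @ state
        + params.bcd_weight[gene] * bcd
        + params.ext_weight[gene] @ ext
        + params.h[gene]
    )


def _inputs_shorted(state: np.ndarray, bcd: float, cad: float, params: CircuitParameters) -> np.ndarray:
    return params.T @ state + params.bcd_weight * bcd + params.ext_weight[:, 0] * cad + params.h


_NEG_TOL = 1e-6


def rhs_shorted(
    state: np.ndarray,
    t: float,
    bcd: float,
    cad: Callable[[float], float] | float,
    params: CircuitParameters,
    schedule: MitosisSchedule,
) -> np.ndarray:
    """Right-hand side of the shorted (per-nucleus, diffusionless) model.

    dv^a/dt = R^a chi(t) g(u^a) - lambda^a v^a, with u^a carrying the gap
    cross-regulation, the Bcd input and the Cad input (no Tll, no diffusion).
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < -_NEG_TOL * 255):
        raise ValueError(f"negative concentration beyond tolerance at t={t}: {state}")
    cad_val = cad(t) if callable(cad) else float(cad)
    u = _inputs_shorted(state, bcd, cad_val, params)
    return params.R * schedule.chi(t) * regulation_g(u) - params.lambda_ * state


def rhs_autonomous(
    state: np.ndarray, bcd: float, cad_t6: float, params: CircuitParameters
) -> np.ndarray:
    """Autonomous shorted right-hand side (chi = 1, Cad frozen at its T6 value)."""
    state = np.asarray(state, dtype=float)
    u = _inputs_shorted(state, bcd, cad_t6, params)
    return params.R * regulation_g(u) - params.lambda_ * state


def jacobian_autonomous(
    state: np.ndarray, bcd: float, cad_t6: float, params: CircuitParameters
) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_autonomous` at ``state``."""
    state = np.asarray(state, dtype=float)
    u = _inputs_shorted(state, bcd, cad_t6, params)
    return (params.R * regulation_g_prime(u))[:, None] * params.T - np.diag(params.lambda_)


def rhs_full(
    state: np.ndarray,
    t: float,
    bcd_at_x: np.ndarray,
    cad_table: ExternalInputTable,
    tll_table: ExternalInputTable,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    lattice: NuclearLattice,
) -> np.ndarray:
    """Right-hand side of the full circuit on a nuclear lattice.

    ``state`` has shape (4, M).  Adds the Tll input and the discrete
    diffusion term D^a(n) [(v_{i-1} - v_i) + (v_{i+1} - v_i)], with the
    missing-neighbour terms dropped at the domain ends.
    """
    state = np.asarray(state, dtype=float)
    M = len(lattice)
    if state.shape != (N_GENES, M):
        raise ValueError("state width must match the lattice")
    if np.any(state < -_NEG_TOL * 255):
        raise ValueError(f"negative concentration beyond tolerance at t={t}")
    cad = np.asarray(cad_table.at(lattice.positions, t), dtype=float)
    tll = np.asarray(tll_table.at(lattice.positions, t), dtype=float)
    u = (
        params.T @ state
        + params.bcd_weight[:, None] * bcd_at_x[None, :]
        + params.ext_weight[:, 0:1] * cad[None, :]
        + params.ext_weight[:, 1:2] * tll[None, :]
        + params.h[:, None]
    )
    dv = params.R[:, None] * schedule.chi(t) * regulation_g(u) - params.lambda_[:, None] * state
    D = params.d_for_cycle(13 if lattice.cycle == 13 else 14)
    lap = np.zeros_like(state)
    lap[:, :-1] += state[:, 1:] - state[:, :-1]  # right neighbour
    lap[:, 1:] += state[:, :-1] - state[:, 1:]  # left neighbour
    return dv + D[:, None] * lap


# ---------------------------------------------------------------------------
# Lattice construction and nuclear division
# ---------------------------------------------------------------------------


def build_lattice(domain: tuple[float, float], cycle: int) -> NuclearLattice:
    """Nuclear lattice over ``domain`` = [a, b] %EL for cycle 13 or 14A.

    Cycle-13 nuclei sit at odd-integer %EL from a to b+1 inclusive; cycle-14A
    nuclei are their daughters at p and p+1, dropped above min(b+1, 92) so
    that no nucleus leaves the full modelled domain.  This convention puts
    30 (58) nuclei on 35-92% EL and 11 (22) on 37-57% EL in cycle 13 (14A).
    """
    a, b = float(domain[0]), float(domain[1])
    if a >= b:
        raise ValueError(f"inverted domain [{a}, {b}]")
    first_odd = int(np.ceil(a))
    if first_odd % 2 == 0:
        first_odd += 1
    parents = np.arange(first_odd, np.floor(b + 1) + 0.5, 2.0)
    if cycle == 13:
        return NuclearLattice(13, parents, (a, b))
    if cycle in (14, 140):  # 14A
        clip = min(b + 1.0, FULL_DOMAIN[1])
        daughters = np.sort(np.concatenate([parents, parents + 1.0]))
        return NuclearLattice(14, daughters[daughters <= clip + 1e-9], (a, b))
    raise ValueError(f"cycle must be 13 or 14 (14A), got {cycle}")


def apply_nuclear_division(
    state13: StateMatrix, lattice13: NuclearLattice
) -> tuple[StateMatrix, NuclearLattice]:
    """Divide cycle-13 nuclei into cycle-14A daughters, copying states.

    Each parent at odd position p yields daughters at p and p+1 with the
    parent's concentration vector; daughters beyond the full-domain
    posterior bound are dropped.
    """
    if lattice13.cycle != 13:
        raise ValueError("apply_nuclear_division requires a cycle-13 lattice")
    if state13.values.shape[1] != len(lattice13):
        raise ValueError("state width must match the lattice")
    lattice14 = build_lattice(lattice13.domain, 14)
    pos14 = lattice14.positions
    # Daughter at p (odd) or p+1 (even) copies the parent at odd position p.
    parent_pos = np.where(pos14 % 2 == 1, pos14, pos14 - 1)
    parent_index = np.searchsorted(lattice13.positions, parent_pos)
    values14 = state13.values[:, parent_index]
    return StateMatrix(state13.time, values14), lattice14


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


class Trajectory:
    """Piecewise dense ODE solution, callable at any time in its span."""

    def __init__(self, segments: list, t_span: tuple[float, float]):
        self._segments = segments  # list of OdeSolution-bearing results
        self.t_span = t_span

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((self._segments[0].sol(self.t_span[0]).shape[0], len(t_arr)))
        for k, tk in enumerate(t_arr):
            seg = None
            for s in self._segments:
                if s.t[0] - 1e-12 <= tk <= s.t[-1] + 1e-12:
                    seg = s
                    break
            if seg is None:
                raise ValueError(f"time {tk} outside trajectory span {self.t_span}")
            out[:, k] = seg.sol(np.clip(tk, seg.t[0], seg.t[-1]))
        if np.ndim(t) == 0:
            return out[:, 0]
        return out

    @property
    def endpoint(self) -> np.ndarray:
        return self._segments[-1].sol(self._segments[-1].t[-1])


def _integrate_piecewise(
    fun: Callable,
    y0: np.ndarray,
    t_span: tuple[float, float],
    breakpoints: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
) -> Trajectory:
    t_start, t_end = t_span
    cuts = [t_start] + [float(b) for b in breakpoints if t_start < b < t_end] + [t_end]
    segments = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(cuts[:-1], cuts[1:]):
        res = solve_ivp(fun, (a, b), y, method=method, rtol=rtol, atol=atol, dense_output=True)
        if not res.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {res.message}")
        segments.append(res)
        y = res.y[:, -1]
    return Trajectory(segments, t_span)


def integrate_shorted_nucleus(
    bcd: float,
    cad: Callable[[float], float] | float,
    ic: np.ndarray,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    t_span: tuple[float, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the shorted model for one nucleus.

    The integrator is restarted at the chi discontinuities (mitosis edges)
    and at the T6 freeze so each segment has a smooth right-hand side.
    """
    ic = np.asarray(ic, dtype=float)
    if ic.shape != (N_GENES,):
        raise ValueError("initial condition must be a 4-vector")
    if np.any(ic < 0) or np.any(ic > 255 + 1e-9):
        raise ValueError("initial condition must lie in [0, 255]^4")
    if t_span is None:
        t_span = (schedule.t0, schedule.tau)

    def fun(t, y):
        return rhs_shorted(y, t, bcd, cad, params, schedule)

    return _integrate_piecewise(fun, ic, t_span, schedule.breakpoints(), rtol, atol, method)


class FullCircuitSolution:
    """Solution of the full circuit across the division at cycle 13 -> 14A."""

    def __init__(
        self,
        traj13: Trajectory,
        traj14: Trajectory,
        lattice13: NuclearLattice,
        lattice14: NuclearLattice,
        schedule: MitosisSchedule,
    ):
        self._traj13 = traj13
        self._traj14 = traj14
        self.lattice13 = lattice13
        self.lattice14 = lattice14
        self.schedule = schedule

    def at_time(self, t: float) -> StateMatrix:
        """State at time ``t``; on the cycle-14A lattice for t >= division."""
        if t < self.schedule.mitosis13_end:
            vals = self._traj13(t).reshape(N_GENES, len(self.lattice13))
        else:
            vals = self._traj14(t).reshape(N_GENES, len(self.lattice14))
        return StateMatrix(t, vals)

    def at_time_class(self, k: int) -> StateMatrix:
        """State at the end of time class Tk (k = 1..8) of cycle 14A."""
        if not 1 <= k <= 8:
            raise ValueError("time class must be in 1..8")
        return self.at_time(float(self.schedule.time_class_edges[k]))

    def lattice_at(self, t: float) -> NuclearLattice:
        return self.lattice13 if t < self.schedule.mitosis13_end else self.lattice14


def integrate_full_circuit(
    hb0: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    bcd: Callable[[np.ndarray], np.ndarray],
    cad_table: ExternalInputTable,
    tll_table: ExternalInputTable,
    params: CircuitParameters,
    schedule: MitosisSchedule,
    lattice13: NuclearLattice,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> FullCircuitSolution:
    """Integrate the full circuit from the start of cycle 13 to gastrulation.

    Initial conditions are the maternal Hb gradient ``hb0`` (callable of
    position or explicit per-nucleus values) with zero Kr, Gt and Kni.  The
    run covers interphase 13, mitosis 13 (chi = 0), the nuclear division,
    and cycle 14A up to tau.
    """
    if callable(hb0):
        hb_ic = np.asarray(hb0(lattice13.positions), dtype=float)
    else:
        hb_ic = np.asarray(hb0, dtype=float)
    if hb_ic.shape != (len(lattice13),):
        raise ValueError("initial Hb values must match the cycle-13 lattice")
    ic = np.zeros((N_GENES, len(lattice13)))
    ic[0] = hb_ic

    bcd13 = np.asarray(bcd(lattice13.positions), dtype=float)

    def fun13(t, y):
        state = y.reshape(N_GENES, len(lattice13))
        return rhs_full(state, t, bcd13, cad_table, tll_table, params, schedule, lattice13).ravel()

    traj13 = _integrate_piecewise(
        fun13, ic.ravel(), (schedule.t0, schedule.mitosis13_end),
        schedule.breakpoints(), rtol, atol, method,
    )

    state_at_div = StateMatrix(
        schedule.mitosis13_end, traj13.endpoint.reshape(N_GENES, len(lattice13))
    )
    state14, lattice14 = apply_nuclear_division(state_at_div, lattice13)
    bcd14 = np.asarray(bcd(lattice14.positions), dtype=float)

    def fun14(t, y):
        state = y.reshape(N_GENES, len(lattice14))
        return rhs_full(state, t, bcd14, cad_table, tll_table, params, schedule, lattice14).ravel()

    traj14 = _integrate_piecewise(
        fun14, state14.values.ravel(), (schedule.mitosis13_end, schedule.tau),
        schedule.breakpoints(), rtol, atol, method,
    )
    return FullCircuitSolution(traj13, traj14, lattice13, lattice14, schedule)
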