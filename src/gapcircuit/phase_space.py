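"""Phase-space analysis of the autonomous shorted gap gene system.

After the T6 freeze the shorted per-nucleus model is an autonomous 4-D flow
parameterised by the local Bicoid and Caudal concentrations.  This module
enumerates its equilibria by deterministic multistart root finding,
classifies their stability from the analytic Jacobian, assigns qualitative
0/X/1 expression codes, maps attractor existence domains over the Bcd-Cad
plane (with saddle-node / Hopf boundary typing), and traces the 1-D
unstable manifolds of single-unstable-eigenvalue saddles by forward
integration from S +/- eps*w along the unstable eigenvector w.

Numerical continuation is deliberately replaced by dense multistart root
finding with nearest-state label matching between neighbouring grid nodes;
boundaries are then localised to grid resolution (optionally refined by
bisection between adjacent nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

from .core_model import (
    N_GENES,
    CircuitParameters,
    jacobian_autonomous,
    rhs_autonomous,
)

__all__ = [
    "Equilibrium",
    "ExistenceDomainMap",
    "ManifoldTrace",
    "find_equilibria",
    "classify_stability",
    "code_state",
    "assign_conventional_labels",
    "scan_bcd_cad_plane",
    "trace_unstable_manifold",
]

#: Hyperbolicity tolerance on Re(lambda).
HYPERBOLICITY_TOL = 1e-6

#: Concentration thresholds for the 0/X/1 qualitative codes.
CODE_LOW, CODE_HIGH = 50.0, 150.0

#: Distance below which two equilibrium candidates are merged.
DEDUP_RADIUS = 0.5

#: Conventional attractor names for the recurring 0/X/1 codes: A1 is the
#: hb-ON attractor whose gt component varies continuously (codes 1000/10X0/
#: 1010), A2 the hb+Kr state, A3 the Kr-only state, A4 the all-off state,
#: A5/A6 the rarer states seen under alternative normalizations.
CODE_TO_LABEL = {
    "1000": "A1",
    "10X0": "A1",
    "1010": "A1",
    "1100": "A2",
    "0100": "A3",
    "0000": "A4",
    "0101": "A5",
}


def assign_conventional_labels(equilibria: list["Equilibrium"]) -> None:
    """Label attractors by their code's conventional name (A1..A5).

    Unmapped or duplicated codes fall back to the code string itself, so
    labels at one parameter point are always unique.
    """
    seen: set[str] = set()
    for eq in equilibria:
        if not eq.is_attractor:
            continue
        label = CODE_TO_LABEL.get(eq.code, eq.code)
        if label in seen:
            label = eq.code if eq.code not in seen else f"{eq.code}~{len(seen)}"
        eq.label = label
        seen.add(label)


@dataclass
class Equilibrium:
    """A fixed point of the autonomous shorted system."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # "attractor" | "saddle_k" | "nonhyperbolic"
    code: str  # quadruple over {0, X, 1}, e.g. "1000"
    label: str = ""  # matched identity (A1.., S..) where assigned

    @property
    def is_attractor(self) -> bool:
        return self.stability == "attractor"

    @property
    def n_unstable(self) -> int:
        return int(np.sum(self.eigenvalues.real > HYPERBOLICITY_TOL))


@dataclass
class ExistenceDomainMap:
    """Equilibrium sets and attractor-domain boundaries on the Bcd-Cad plane."""

    bcd_grid: np.ndarray
    cad_grid: np.ndarray
    equilibria: dict  # (i, j) -> list[Equilibrium], labels matched across nodes
    attractor_sets: dict  # (i, j) -> frozenset of attractor labels
    boundaries: list  # (node_a, node_b, lost_or_gained_label, type_tag)
    flagged_nodes: list = field(default_factory=list)

    def attractor_count(self, i: int, j: int) -> int:
        return len(self.attractor_sets[(i, j)])


@dataclass
class ManifoldTrace:
    """Two branches of a saddle's 1-D unstable manifold."""

    saddle: Equilibrium
    branches: tuple[np.ndarray, np.ndarray]  # each (n_pts, 4), arclength order

    def min_distance(self, point: np.ndarray) -> float:
        """Distance from ``point`` to the nearest stored manifold point."""
        point = np.asarray(point, dtype=float)
        return min(
            float(np.min(np.linalg.norm(br - point[None, :], axis=1)))
            for br in self.branches
            if len(br)
        )


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------


def code_state(state: np.ndarray) -> str:
    """Qualitative 0/X/1 code of a state: <50 -> 0, 50-150 -> X, >150 -> 1."""
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("state components must be non-negative")
    chars = []
    for v in state:
        if v < CODE_LOW:
            chars.append("0")
        elif v <= CODE_HIGH:
            chars.append("X")
        else:
            chars.append("1")
    return "".join(chars)


def classify_stability(
    eq_state: np.ndarray, params: CircuitParameters, v_bcd: float, v_cad: float
) -> tuple[str, np.ndarray]:
    """Stability type and Jacobian eigenvalues at an equilibrium state."""
    J = jacobian_autonomous(eq_state, v_bcd, v_cad, params)
    eig = np.linalg.eigvals(J)
    re = eig.real
    if np.any(np.abs(re) <= HYPERBOLICITY_TOL):
        return "nonhyperbolic", eig
    k = int(np.sum(re > 0))
    return ("attractor" if k == 0 else f"saddle_{k}"), eig


def _multistart_points(params: CircuitParameters, n_axis: int, n_sobol: int) -> np.ndarray:
    vmax = 1.2 * float(np.max(params.R / params.lambda_))
    vmax = max(vmax, 1.0)
    axis = np.linspace(0.0, vmax, n_axis)
    grid = np.stack(np.meshgrid(*([axis] * N_GENES), indexing="ij"), axis=-1).reshape(-1, N_GENES)
    if n_sobol > 0:
        lds = qmc.Halton(N_GENES, scramble=False).random(n_sobol) * vmax
        grid = np.vstack([grid, lds])
    return grid


def find_equilibria(
    v_bcd: float,
    v_cad: float,
    params: CircuitParameters,
    n_axis: int = 5,
    n_sobol: int = 200,
    tol: float = 1e-9,
    extra_starts: np.ndarray | None = None,
) -> list[Equilibrium]:
    """All equilibria of the autonomous shorted system at (v_bcd, v_cad).

    Newton-type root finding (hybr) from a deterministic multistart set:
    ``n_axis`` points per gene axis over [0, 1.2 max(R/lambda)] plus
    ``n_sobol`` low-discrepancy starts.  Solutions closer than 0.5
    concentration units are merged; each returned state has residual < tol.
    Warm starts may be supplied via ``extra_starts``.
    """

    def fun(v):
        return rhs_autonomous(v, v_bcd, v_cad, params)

    def jac(v):
        return jacobian_autonomous(v, v_bcd, v_cad, params)

    starts = _multistart_points(params, n_axis, n_sobol)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([np.atleast_2d(extra_starts), starts])

    found: list[np.ndarray] = []
    for x0 in starts:
        res = root(fun, x0, jac=jac, method="hybr", tol=1e-12)
        if not res.success:
            continue
        v = res.x
        if np.linalg.norm(fun(v)) >= tol:
            continue
        if np.any(v < -1e-6):
            continue
        v = np.maximum(v, 0.0)
        if any(np.linalg.norm(v - w) < DEDUP_RADIUS for w in found):
            continue
        found.append(v)
    if not found:
        import warnings

        warnings.warn(f"no equilibria found at (Bcd={v_bcd}, Cad={v_cad})", stacklevel=2)

    eqs = []
    for v in found:
        stab, eig = classify_stability(v, params, v_bcd, v_cad)
        eqs.append(Equilibrium(v, eig, stab, code_state(v)))
    # deterministic order: by hb, then Kr, gt, kni
    eqs.sort(key=lambda e: tuple(e.state))
    return eqs


# ---------------------------------------------------------------------------
# Bcd-Cad plane scan
# ---------------------------------------------------------------------------


def _match_labels(
    prev: list[Equilibrium], cur: list[Equilibrium], counter: list[int]
) -> list[str | None]:
    """Assign labels to ``cur`` attractors by nearest-state continuity.

    Returns a per-equilibrium flag list (label or None if ambiguous).
    """
    flags: list[str | None] = []
    prev_attr = [e for e in prev if e.is_attractor] if prev else []
    for e in cur:
        if not e.is_attractor:
            e.label = ""
            flags.append(e.label)
            continue
        if not prev_attr:
            counter[0] += 1
            e.label = f"A{counter[0]}"
            flags.append(e.label)
            continue
        d = np.array([np.linalg.norm(e.state - p.state) for p in prev_attr])
        order = np.argsort(d)
        if len(d) > 1 and abs(d[order[0]] - d[order[1]]) < 1e-9:
            e.label = ""
            flags.append(None)  # ambiguous match
            continue
        e.label = prev_attr[int(order[0])].label
        flags.append(e.label)
    # attractors with no inherited label (new appearance) get fresh names
    seen: set[str] = set()
    for e in cur:
        if e.is_attractor and e.label and e.label in seen:
            counter[0] += 1
            e.label = f"A{counter[0]}"
        if e.label:
            seen.add(e.label)
    return flags


def _boundary_type(lost: Equilibrium) -> str:
    """Bifurcation type from the critical eigenvalue of a disappearing attractor."""
    eig = lost.eigenvalues
    crit = eig[np.argmax(eig.real)]
    if abs(crit.imag) > 1e-8:
        return "Hopf"
    return "saddle-node"


def scan_bcd_cad_plane(
    params: CircuitParameters,
    bcd_range: tuple[float, float],
    cad_range: tuple[float, float],
    resolution: tuple[int, int] = (20, 20),
    n_axis: int = 4,
    n_sobol: int = 64,
) -> ExistenceDomainMap:
    """Attractor existence domains and bifurcation boundaries on the plane.

    Equilibria are found at every grid node (warm-started from the previous
    node's solutions), attractor labels are matched between neighbouring
    nodes by nearest-state continuity, and a boundary segment is emitted
    between nodes whose labelled attractor sets differ.  The segment is
    typed saddle-node when the disappearing attractor's critical eigenvalue
    is real, Hopf when it is a complex pair.
    """
    nb, nc = resolution
    if nb < 2 or nc < 2:
        raise ValueError("resolution must be at least 2x2")
    bcd_grid = np.linspace(bcd_range[0], bcd_range[1], nb)
    cad_grid = np.linspace(cad_range[0], cad_range[1], nc)

    equilibria: dict = {}
    attractor_sets: dict = {}
    flagged = []
    counter = [0]
    prev_row_eqs: list[list[Equilibrium]] = [[] for _ in range(nb)]

    for j, cad in enumerate(cad_grid):
        prev_eqs: list[Equilibrium] = []
        for i, bcd in enumerate(bcd_grid):
            warm = None
            neighbours = prev_eqs or prev_row_eqs[i]
            if neighbours:
                warm = np.array([e.state for e in neighbours])
            eqs = find_equilibria(
                bcd, cad, params, n_axis=n_axis, n_sobol=n_sobol, extra_starts=warm
            )
            ref = prev_eqs if prev_eqs else prev_row_eqs[i]
            flags = _match_labels(ref, eqs, counter)
            if any(f is None for f in flags):
                flagged.append((i, j))
            equilibria[(i, j)] = eqs
            attractor_sets[(i, j)] = frozenset(e.label for e in eqs if e.is_attractor and e.label)
            prev_eqs = eqs
            prev_row_eqs[i] = eqs

    boundaries = []
    for j in range(nc):
        for i in range(nb):
            for di, dj in ((1, 0), (0, 1)):
                i2, j2 = i + di, j + dj
                if i2 >= nb or j2 >= nc:
                    continue
                s1, s2 = attractor_sets[(i, j)], attractor_sets[(i2, j2)]
                if s1 == s2:
                    continue
                for label in s1 ^ s2:
                    owner = (i, j) if label in s1 else (i2, j2)
                    lost = next(
                        e for e in equilibria[owner] if e.label == label
                    )
                    boundaries.append(((i, j), (i2, j2), label, _boundary_type(lost)))
    return ExistenceDomainMap(bcd_grid, cad_grid, equilibria, attractor_sets, boundaries, flagged)


# ---------------------------------------------------------------------------
# Unstable manifolds
# ---------------------------------------------------------------------------


def trace_unstable_manifold(
    saddle: Equilibrium,
    params: CircuitParameters,
    v_bcd: float,
    v_cad: float,
    eps: float = 0.1,
    t_max: float = 500.0,
    n_points: int = 400,
    rtol: float = 1e-9,
    atol: float = 1e-10,
) -> ManifoldTrace:
    """Approximate the 1-D unstable manifold of a saddle with one unstable eigenvalue.

    Both branches are obtained by integrating the autonomous flow forward
    from S +/- eps * w, where w is the unit eigenvector of the single
    eigenvalue with positive real part, until the flow stalls at an
    attractor or t_max is reached.
    """
    if saddle.stability != "saddle_1":
        raise ValueError(f"expected a saddle_1, got {saddle.stability}")
    J = jacobian_autonomous(saddle.state, v_bcd, v_cad, params)
    eig, vec = np.linalg.eig(J)
    k = int(np.argmax(eig.real))
    w = vec[:, k].real
    w = w / np.linalg.norm(w)

    def fun(t, y):
        return rhs_autonomous(y, v_bcd, v_cad, params)

    def stalled(t, y):
        return np.linalg.norm(fun(t, y)) - 1e-8

    stalled.terminal = True
    stalled.direction = -1

    branches = []
    for sign in (+1.0, -1.0):
        y0 = np.maximum(saddle.state + sign * eps * w, 0.0)
        t_eval = np.linspace(0.0, t_max, n_points)
        res = solve_ivp(
            fun, (0.0, t_max), y0, method="LSODA", rtol=rtol, atol=atol,
            t_eval=t_eval, events=stalled,
        )
        if not res.success:
            raise RuntimeError(f"manifold integration failed: {res.message}")
        pts = res.y.T
        if res.t_events[0].size:
            pts = np.vstack([pts, res.y_events[0]])
        branches.append(pts)
    return ManifoldTrace(saddle, (branches[0], branches[1]))
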