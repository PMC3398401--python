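"""Synthetic inputs with the statistical structure the analysis assumes.

Real analyses of this model are driven by an ensemble of ~90 per-embryo
Bicoid gradients, externally measured Cad/Tll input tables, a maternal Hb
gradient, and circuit parameters fitted to expression data.  None of those
are required here: this module generates every input programmatically —
exponential Bcd ensembles with embryo-to-embryo variation in amplitude and
decay, raw intensity profiles with a quadratic background and Gaussian
noise for normalization tests, a monotone logistic maternal Hb gradient
bounded by 100, smooth Cad/Tll spatio-temporal tables (Tll inactive in the
37-57% EL analysis window), hand-designed circuit parameter fixtures with
verified phase portraits, and analytically solvable toy systems used as
oracles by the phase-space and basin machinery.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .bcd_profiles import BcdEnsemble, BcdExponential, RawIntensityProfile
from .core_model import (
    FULL_DOMAIN,
    CircuitParameters,
    ExternalInputTable,
    MitosisSchedule,
    regulation_g,
)

__all__ = [
    "SyntheticConfig",
    "gen_bcd_ensemble",
    "gen_raw_profiles",
    "gen_maternal_hb",
    "gen_external_inputs",
    "gen_parameter_fixture",
    "gen_toy_system",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic Bcd ensemble and raw profiles.

    Amplitude A and decay constant l are drawn lognormally (positivity);
    the defaults give a median amplitude of 200 relative units and a decay
    length of 15% EL (l = 1/15 per %EL), typical of exponential Bcd
    summaries on the 0-255 scale.  Two coefficient-of-variation presets are
    exposed through :func:`gen_bcd_ensemble`: "wide" (A_cv = 0.3), emulating
    a basic-normalized ensemble whose amplitude variance is exaggerated,
    and "narrow" (A_cv = 0.08, designed threshold-position sd of about
    1.2% EL), emulating a variance-minimizing normalization.
    """

    n_embryos: int = 50
    A_mean: float = 200.0
    A_cv: float = 0.3
    l_mean: float = 1.0 / 15.0
    l_cv: float = 0.03
    background: tuple[float, float, float] = (20.0, 0.1, -0.001)
    noise_sd: float = 2.0
    hb0_midpoint: float = 47.0
    hb0_steepness: float = 4.0
    seed: int = 0


_PRESETS = {
    # cv values straddling the two normalization regimes
    "wide": dict(A_cv=0.30, l_cv=0.05),
    "narrow": dict(A_cv=0.08, l_cv=0.002),
}


def preset_config(preset: str, n_embryos: int = 50, seed: int = 0) -> SyntheticConfig:
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(_PRESETS)}")
    return SyntheticConfig(n_embryos=n_embryos, seed=seed, **_PRESETS[preset])


def gen_bcd_ensemble(config: SyntheticConfig) -> BcdEnsemble:
    """Ensemble of exponential Bcd summaries with lognormal (A, l) variation.

    With the narrow preset the designed spread of threshold positions
    x = ln(A/c)/l (at the median threshold) is approximately
    sqrt((A_cv/l_mean)^2 + (x_ref * l_cv)^2) ~ 1.2% EL.
    """
    if config.n_embryos < 2:
        raise ValueError("need at least 2 embryos")
    rng = np.random.default_rng(config.seed)
    A = config.A_mean * np.exp(rng.normal(0.0, config.A_cv, config.n_embryos))
    l = config.l_mean * np.exp(rng.normal(0.0, config.l_cv, config.n_embryos))
    members = [
        BcdExponential(float(A[j]), float(l[j]), f"emb{j + 1:03d}")
        for j in range(config.n_embryos)
    ]
    tag = "variance_minimizing" if config.A_cv <= 0.1 else "basic"
    return BcdEnsemble(members, tag)


def gen_raw_profiles(
    config: SyntheticConfig,
    x: np.ndarray | None = None,
) -> tuple[list[RawIntensityProfile], BcdEnsemble]:
    """Raw intensity profiles: scaled exponential + quadratic background + noise.

    raw_j(x) = s_j * A_j exp(-l_j x) + q(x) + N(0, noise_sd); the generating
    exponentials are returned for recovery tests.  Per-embryo scales s_j
    are lognormal with cv 0.2, emulating staining-intensity variation.
    """
    if x is None:
        x = np.arange(0.0, 90.0 + 0.5, 1.0)
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(config.seed)
    truth = gen_bcd_ensemble(config)
    c0, c1, c2 = config.background
    q = c0 + c1 * x + c2 * x**2
    scales = np.exp(rng.normal(0.0, 0.2, config.n_embryos))
    raws = []
    for j, m in enumerate(truth.members):
        noise = rng.normal(0.0, config.noise_sd, len(x)) if config.noise_sd > 0 else 0.0
        raws.append(RawIntensityProfile(m.embryo_id, x, scales[j] * m(x) + q + noise))
    return raws, truth


def gen_maternal_hb(midpoint: float = 47.0, steepness: float = 4.0):
    """Maternal Hb gradient: decreasing logistic, 100 -> 0, value 50 at midpoint."""
    if steepness <= 0:
        raise ValueError("steepness must be positive")

    from scipy.special import expit

    def hb0(x):
        x = np.asarray(x, dtype=float)
        out = 100.0 * expit(-(x - midpoint) / steepness)
        return float(out) if out.ndim == 0 else out

    return hb0


def gen_external_inputs(
    schedule: MitosisSchedule | None = None,
    cad_max: float = 120.0,
    cad_midpoint: float = 60.0,
    cad_width: float = 8.0,
    tll_max: float = 80.0,
    tll_midpoint: float = 80.0,
    tll_width: float = 3.0,
) -> tuple[ExternalInputTable, ExternalInputTable]:
    """Smooth Cad and Tll spatio-temporal input tables.

    Cad rises posteriorly (logistic in x) and ramps up over time towards its
    T6 profile; Tll is confined to the far posterior and is exactly zero
    anterior of ~70% EL — in particular throughout the 37-57% EL analysis
    window.  Both tables freeze at their T6 values.
    """
    if schedule is None:
        schedule = MitosisSchedule()
    x = np.arange(FULL_DOMAIN[0], FULL_DOMAIN[1] + 0.5, 1.0)
    edges = schedule.time_class_edges
    times = np.concatenate([[schedule.t0], edges])
    cad_x = cad_max / (1.0 + np.exp(-(x - cad_midpoint) / cad_width))
    tll_x = tll_max / (1.0 + np.exp(-(x - tll_midpoint) / tll_width))
    tll_x[x < 70.0] = 0.0
    ramp = 0.6 + 0.4 * np.clip(times / schedule.t_T6, 0.0, 1.0)
    cad_vals = ramp[:, None] * cad_x[None, :]
    tll_vals = np.tile(tll_x, (len(times), 1))
    cad = ExternalInputTable("Cad", x, times, cad_vals, schedule.t_T6)
    tll = ExternalInputTable("Tll", x, times, tll_vals, schedule.t_T6)
    return cad, tll


# ---------------------------------------------------------------------------
# Circuit parameter fixtures
# ---------------------------------------------------------------------------


def gen_parameter_fixture(preset: str) -> CircuitParameters:
    """Hand-designed circuit parameters with verified phase portraits.

    Presets
    -------
    bistable_border
        A mutually repressing hb/Kr pair with hb autoactivation and a Bcd
        input to hb.  Across the 37-57% EL window (with the default median
        Bcd gradient and Cad table) it carries exactly two point attractors,
        an hb-ON state coded 1000 and a Kr-ON state coded 0100, whose basin
        boundary on the Hb axis rises posteriorly and crosses the default
        maternal Hb gradient inside the window.  gt and kni stay off.
    monostable
        Weakly coupled circuit with a single attractor everywhere.
    decoupled
        T = 0 and no Bcd/Cad/Tll inputs; per-gene equilibria at the closed
        form R g(h) / lambda.
    """
    lam = np.full(4, 0.1)
    R = np.array([20.0, 20.0, 20.0, 20.0])
    if preset == "bistable_border":
        T = np.array(
            [
                [0.05, -0.05, 0.0, 0.0],
                [-0.05, 0.05, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        bcd_w = np.array([0.05, 0.01, 0.0, 0.0])
        ext_w = np.array(
            [
                [0.0, 0.0],  # hb: no Cad/Tll input
                [0.01, 0.0],  # Kr: weak Cad activation
                [0.005, 0.0],  # gt
                [0.01, -0.02],  # kni: Cad activation, Tll repression
            ]
        )
        h = np.array([-3.5, -2.0, -5.0, -5.0])
        D = np.array([0.2, 0.2, 0.2, 0.2])
        return CircuitParameters(R, T, bcd_w, ext_w, h, lam, D)
    if preset == "monostable":
        T = np.zeros((4, 4))
        T[0, 1] = -0.005
        T[1, 0] = -0.005
        bcd_w = np.array([0.02, 0.005, 0.0, 0.0])
        ext_w = np.zeros((4, 2))
        h = np.array([-2.0, -2.0, -3.0, -3.0])
        return CircuitParameters(R, T, bcd_w, ext_w, h, lam, np.full(4, 0.2))
    if preset == "decoupled":
        T = np.zeros((4, 4))
        bcd_w = np.zeros(4)
        ext_w = np.zeros((4, 2))
        h = np.array([-1.0, 0.0, 1.0, -2.0])
        return CircuitParameters(R, T, bcd_w, ext_w, h, lam, np.zeros(4))
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# Toy systems with closed-form facts
# ---------------------------------------------------------------------------


@dataclass
class ToySystem:
    """A reduced system in the circuit RHS family with analytic facts."""

    kind: str
    params: CircuitParameters
    v_bcd: float
    v_cad: float
    facts: dict = field(default_factory=dict)


def gen_toy_system(kind: str) -> ToySystem:
    """Analytically solvable toys inside the same RHS family.

    1d_bistable
        Only hb is synthesised (R = 0 for the others), with autoactivation
        T[hb,hb] = 0.05, h = -3.5, R = 20, lambda = 0.1.  The scalar fixed
        point equation 200 g(0.05 v - 3.5) = v has three roots; the middle
        (unstable) root is the separatrix on the Hb axis, computed here by
        bracketed root finding on the closed-form equation.
    2d_saddle
        hb and Kr mutually repress (T = -0.1 off-diagonal, h = 0); by
        symmetry a saddle sits on the diagonal v_hb = v_Kr with unstable
        eigenvector (1, -1)/sqrt(2) and eigenvalues -lambda +/- |J_od|,
        where J_od = R g'(u*) T_od at the diagonal fixed point.
    1gene_fold
        The 1d_bistable gene with a Bcd input (weight m = 0.05).  The low
        attractor and the saddle annihilate in a saddle-node (fold) as Bcd
        rises; the fold locus follows from the tangency condition
        R g'(u*) T = lambda, which gives u* = -sqrt((2 R T / (2 lambda))^
        (2/3) - 1), v* = R g(u*) / lambda and the closed-form fold position
        bcd* = (u* - T v* - h) / m.
    """
    lam = np.full(4, 0.1)
    if kind == "1d_bistable":
        R = np.array([20.0, 0.0, 0.0, 0.0])
        T = np.zeros((4, 4))
        T[0, 0] = 0.05
        h = np.array([-3.5, 0.0, 0.0, 0.0])
        params = CircuitParameters(R, T, np.zeros(4), np.zeros((4, 2)), h, lam, np.zeros(4))

        def f(v):  # scalar fixed-point residual for hb
            return 20.0 * regulation_g(0.05 * v - 3.5) - 0.1 * v

        # bracketed roots of the closed-form equation (low, separatrix, high)
        roots = [brentq(f, a, b, xtol=1e-12) for a, b in ((0.0, 30.0), (30.0, 150.0), (150.0, 250.0))]
        facts = {
            "equilibria_hb": roots,
            "separatrix": roots[1],
            "attractors_hb": [roots[0], roots[2]],
            "fixed_point_residual": f,
        }
        return ToySystem(kind, params, 0.0, 0.0, facts)
    if kind == "2d_saddle":
        R = np.array([20.0, 20.0, 0.0, 0.0])
        T = np.zeros((4, 4))
        T[0, 1] = T[1, 0] = -0.1
        h = np.zeros(4)
        params = CircuitParameters(R, T, np.zeros(4), np.zeros((4, 2)), h, lam, np.zeros(4))

        def f(v):  # diagonal fixed-point residual
            return 20.0 * regulation_g(-0.1 * v) - 0.1 * v

        v_star = brentq(f, 1.0, 100.0, xtol=1e-12)
        u = -0.1 * v_star
        g_prime = 0.5 * (1.0 + u * u) ** -1.5
        j_od = 20.0 * g_prime * (-0.1)
        facts = {
            "saddle_state": np.array([v_star, v_star, 0.0, 0.0]),
            "eigenvalues_2d": (-0.1 + abs(j_od), -0.1 - abs(j_od)),
            "unstable_eigenvector": np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2.0),
        }
        return ToySystem(kind, params, 0.0, 0.0, facts)
    if kind == "1gene_fold":
        R_hb, T_hb, lam_hb, h_hb, m_hb = 20.0, 0.05, 0.1, -3.5, 0.05
        R = np.array([R_hb, 0.0, 0.0, 0.0])
        T = np.zeros((4, 4))
        T[0, 0] = T_hb
        h = np.array([h_hb, 0.0, 0.0, 0.0])
        bcd_w = np.array([m_hb, 0.0, 0.0, 0.0])
        params = CircuitParameters(R, T, bcd_w, np.zeros((4, 2)), h, lam, np.zeros(4))
        # tangency: R g'(u) T = lambda with g'(u) = ((1+u^2)^(-3/2))/2
        c = R_hb * T_hb / (2.0 * lam_hb)  # (1+u*^2)^(3/2)
        u_star = -np.sqrt(c ** (2.0 / 3.0) - 1.0)  # lower fold branch
        v_star = R_hb * regulation_g(u_star) / lam_hb
        fold_bcd = (u_star - T_hb * v_star - h_hb) / m_hb
        facts = {
            "fold_bcd": float(fold_bcd),
            "u_star": float(u_star),
            "v_star": float(v_star),
        }
        return ToySystem(kind, params, 0.0, 0.0, facts)
    raise ValueError(f"unknown toy kind {kind!r}")
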