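"""hb border extraction and Bcd-response curves.

The posterior border of the anterior hb domain is read off the modelled Hb
pattern at gastrulation time tau.  In the shorted (diffusionless) model the
solution is rough in space, so the border is defined on the linearly
interpolated profile as the anteriormost downward crossing of half the
window maximum.  In the full model the solution is smooth and the border is
the local inflection point of a cubic interpolant, bracketed around the
half-max crossing.  Response curves relate, per embryo, the border (or the
initial-Hb/basin-boundary intersection) position to the local Bcd level;
the pattern-mass variant integrates the Bcd and Hb patterns over 35-64% EL.
Knocking out the gap cross-regulation of hb (T[hb <- a] = 0) linearises the
response, which is the control used to expose the network's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .basins import BasinBoundaryCurve, intersect_initial_hb
from .bcd_profiles import BcdExponential
from .core_model import ANALYSIS_WINDOW, CircuitParameters

__all__ = [
    "BorderRecord",
    "ResponseCurvePoint",
    "MassPoint",
    "border_position_shorted",
    "border_position_full",
    "knockout_hb_inputs",
    "response_curve",
    "pattern_mass",
]

MASS_REGION: tuple[float, float] = (35.0, 64.0)


@dataclass
class BorderRecord:
    profile_id: str
    border_x: float  # %EL
    model: str  # "shorted" | "full"
    nucleus_anterior: float | None = None  # hb-expressing border nucleus, %EL
    nucleus_posterior: float | None = None  # hb-nonexpressing border nucleus, %EL
    fallback: bool = False  # full model fell back to half-max


@dataclass
class ResponseCurvePoint:
    profile_id: str
    x_star: float
    bcd_at_x: float
    class_tag: str = ""  # I | II | III


@dataclass
class MassPoint:
    profile_id: str
    bcd_mass: float
    hb_mass: float
    knockout: bool = False


class BorderAbsentError(ValueError):
    """The Hb pattern has no half-max crossing in the analysis window."""


def _window_profile(
    positions: np.ndarray, hb: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    keep = (positions >= window[0] - 1e-9) & (positions <= window[1] + 1e-9)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 nuclei in the analysis window")
    return positions[keep], hb[keep]


def _halfmax_crossing(x: np.ndarray, y: np.ndarray, half: float) -> tuple[float, int]:
    """Anteriormost downward crossing of ``half`` on the linear interpolant."""
    for k in range(len(x) - 1):
        y1, y2 = y[k], y[k + 1]
        if y1 >= half > y2:
            frac = (y1 - half) / (y1 - y2)
            return float(x[k] + frac * (x[k + 1] - x[k])), k
    raise BorderAbsentError("no downward half-max crossing in window")


def border_position_shorted(
    positions: np.ndarray,
    hb_at_tau: np.ndarray,
    profile_id: str = "",
    window: tuple[float, float] = ANALYSIS_WINDOW,
) -> BorderRecord:
    """hb border from a shorted-model solution: linear interpolation, half-max.

    The half-max reference is half the maximum of the Hb solution inside
    the window; the border is the anteriormost downward crossing.
    """
    positions = np.asarray(positions, dtype=float)
    hb = np.asarray(hb_at_tau, dtype=float)
    xw, yw = _window_profile(positions, hb, window)
    half = 0.5 * float(np.max(yw))
    bx, k = _halfmax_crossing(xw, yw, half)
    return BorderRecord(profile_id, bx, "shorted", float(xw[k]), float(xw[k + 1]))


def border_position_full(
    positions: np.ndarray,
    hb_at_tau: np.ndarray,
    profile_id: str = "",
    window: tuple[float, float] = ANALYSIS_WINDOW,
    bracket_halfwidth: float = 3.0,
) -> BorderRecord:
    """hb border from a full-model solution: cubic interpolation, inflection point.

    The border is the zero of the second derivative of a cubic spline
    through the nuclei, searched within ``bracket_halfwidth`` %EL of the
    half-max crossing; if no inflection exists there, the half-max crossing
    is returned with a fallback flag.
    """
    positions = np.asarray(positions, dtype=float)
    hb = np.asarray(hb_at_tau, dtype=float)
    xw, yw = _window_profile(positions, hb, window)
    half = 0.5 * float(np.max(yw))
    x_half, k = _halfmax_crossing(xw, yw, half)
    lo = max(xw[0], x_half - bracket_halfwidth)
    hi = min(xw[-1], x_half + bracket_halfwidth)
    spline = CubicSpline(xw, yw)
    d2 = spline.derivative(2)
    grid = np.linspace(lo, hi, 200)
    vals = d2(grid)
    # a (near-)linear profile has no genuine curvature sign change
    negligible = np.max(np.abs(vals)) < 1e-8 * max(np.max(np.abs(yw)), 1.0)
    border_x = None
    best_dist = np.inf
    for i in range(len(grid) - 1) if not negligible else ():
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            try:
                r = brentq(d2, grid[i], grid[i + 1])
            except ValueError:
                r = grid[i]
            if abs(r - x_half) < best_dist:
                best_dist = abs(r - x_half)
                border_x = float(r)
    if border_x is None:
        import warnings

        warnings.warn(f"profile {profile_id}: no inflection; falling back to half-max", stacklevel=2)
        return BorderRecord(profile_id, x_half, "full", float(xw[k]), float(xw[k + 1]), fallback=True)
    return BorderRecord(profile_id, border_x, "full", float(xw[k]), float(xw[k + 1]))


def knockout_hb_inputs(params: CircuitParameters) -> CircuitParameters:
    """Copy of the parameters with gap cross-regulation of hb switched off.

    Zeroes the whole hb row of T (T[hb <- a] = 0 for every gap gene a,
    including hb autoregulation); Bcd, Cad and Tll inputs to hb are kept.
    """
    return params.with_knocked_out_row("hb")


def response_curve(
    entries: list[dict],
    mode: str = "intersection",
) -> list[ResponseCurvePoint]:
    """Assemble the Bcd-response curve from per-profile pipeline outputs.

    Each entry must carry ``profile`` (a BcdExponential) plus, depending on
    ``mode``: ``intersections`` (list of x*, from the basin-boundary
    crossing) or ``border`` (a BorderRecord); an optional ``class_tag``.
    Profiles with no intersection/border are excluded (and reported).
    """
    if mode not in ("intersection", "border"):
        raise ValueError("mode must be 'intersection' or 'border'")
    points = []
    excluded = []
    for entry in entries:
        profile: BcdExponential = entry["profile"]
        if mode == "intersection":
            xs = entry.get("intersections") or []
            if not xs:
                excluded.append(profile.embryo_id)
                continue
            x_star = float(xs[0])
        else:
            rec = entry.get("border")
            if rec is None:
                excluded.append(profile.embryo_id)
                continue
            x_star = float(rec.border_x)
        points.append(
            ResponseCurvePoint(
                profile.embryo_id, x_star, float(profile(x_star)), entry.get("class_tag", "")
            )
        )
    if excluded:
        import logging

        logging.getLogger(__name__).info(
            "response_curve: excluded %d profiles with no %s: %s", len(excluded), mode, excluded
        )
    return points


def pattern_mass(
    profile, region: tuple[float, float] = MASS_REGION, dx: float = 0.1
) -> float:
    """Integral of a pattern over ``region`` (trapezoid at 0.1 %EL resolution).

    ``profile`` is either a callable of x or an (x, values) pair sampled on
    nuclei, in which case linear interpolation is used.
    """
    a, b = region
    grid = np.arange(a, b + dx / 2, dx)
    if callable(profile):
        vals = np.asarray([float(profile(x)) for x in grid])
    else:
        px, pv = profile
        vals = np.interp(grid, np.asarray(px, dtype=float), np.asarray(pv, dtype=float))
    return float(np.trapezoid(vals, grid))
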