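"""Per-profile labels: border mechanism, basin transition, family, solution class.

For each Bcd profile the hb border is bracketed by two nuclei, the
hb-expressing nucleus just anterior and the hb-nonexpressing nucleus just
posterior.  The *mechanism* label records which attracting set governs the
solution in each of the two nuclei at gastrulation time tau: a point
attractor (A) or a saddle's 1-D unstable manifold (M), giving AA, AM, MA or
MM.  The *transition* label records which attractor basins the maternal Hb
level selects in the two nuclei; transitions from an hb-ON attractor to the
hb-OFF attractor A3 (A1->A3 or A2->A3) define Family I, and the hb-ON to
hb-ON transition A2->A1 (where the border instead forms along an attracting
manifold) defines Family II.  The *solution class* I/II/III summarises the
qualitative anterior Kr/gt pattern of a solution at tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basins import BasinPartition
from .phase_space import Equilibrium, ManifoldTrace

__all__ = [
    "MechanismLabel",
    "TransitionLabel",
    "FamilyLabel",
    "classify_border_mechanism",
    "classify_basin_transition",
    "classify_solution_class",
    "family_from_transition",
]

DELTA_A_DEFAULT = 5.0
DELTA_M_DEFAULT = 5.0

#: Half-max threshold (of the 0-255 scale) used by the solution-class rules.
CLASS_HALFMAX = 128.0
#: Anterior window used by the solution-class rules, %EL.
ANTERIOR_WINDOW = (35.0, 50.0)


@dataclass
class MechanismLabel:
    value: str  # AA | AM | MA | MM | unclassified
    anterior_kind: str  # attractor | manifold | ambiguous
    posterior_kind: str


@dataclass
class TransitionLabel:
    from_attractor: str | None
    to_attractor: str | None

    @property
    def value(self) -> str:
        if self.from_attractor is None:
            return "none"
        return f"{self.from_attractor}->{self.to_attractor}"


def family_from_transition(transition: TransitionLabel) -> str:
    """Family label: I for A1->A3 or A2->A3, II for A2->A1, else unclassified."""
    v = transition.value
    if v in ("A1->A3", "A2->A3"):
        return "I"
    if v == "A2->A1":
        return "II"
    return "unclassified"


def _endpoint_kind(
    endpoint: np.ndarray,
    attractors: list[Equilibrium],
    manifolds: list[ManifoldTrace],
    delta_a: float,
    delta_m: float,
) -> str:
    for eq in attractors:
        if np.linalg.norm(endpoint - eq.state) < delta_a:
            return "attractor"
    for tr in manifolds:
        if tr.min_distance(endpoint) < delta_m:
            return "manifold"
    return "ambiguous"


def classify_border_mechanism(
    endpoint_anterior: np.ndarray,
    endpoint_posterior: np.ndarray,
    attractors_anterior: list[Equilibrium],
    attractors_posterior: list[Equilibrium],
    manifolds_anterior: list[ManifoldTrace] | None = None,
    manifolds_posterior: list[ManifoldTrace] | None = None,
    delta_a: float = DELTA_A_DEFAULT,
    delta_m: float = DELTA_M_DEFAULT,
) -> MechanismLabel:
    """Mechanism label from the two border nuclei's states at tau.

    Each nucleus is classified "attractor" if its solution endpoint lies
    within ``delta_a`` of a point attractor, else "manifold" if within
    ``delta_m`` of a traced unstable-manifold branch, else ambiguous.  The
    (anterior, posterior) pair maps to AA/AM/MA/MM.
    """
    ka = _endpoint_kind(
        np.asarray(endpoint_anterior, float), attractors_anterior,
        manifolds_anterior or [], delta_a, delta_m,
    )
    kp = _endpoint_kind(
        np.asarray(endpoint_posterior, float), attractors_posterior,
        manifolds_posterior or [], delta_a, delta_m,
    )
    if "ambiguous" in (ka, kp):
        return MechanismLabel("unclassified", ka, kp)
    return MechanismLabel(("A" if ka == "attractor" else "M") + ("A" if kp == "attractor" else "M"), ka, kp)


def classify_basin_transition(
    partition_anterior: BasinPartition,
    partition_posterior: BasinPartition,
    hb0_anterior: float,
    hb0_posterior: float,
) -> tuple[TransitionLabel, str]:
    """Basin transition of the initial Hb level across the border nuclei.

    Returns the (from, to) attractor pair and the derived family label;
    identical from/to attractors give (none, unclassified) — the situation
    where the border forms without a basin-to-basin transition.
    """
    from_label = partition_anterior.owner_of(hb0_anterior)
    to_label = partition_posterior.owner_of(hb0_posterior)
    if from_label == to_label:
        tr = TransitionLabel(None, None)
        return tr, "unclassified"
    tr = TransitionLabel(from_label, to_label)
    return tr, family_from_transition(tr)


def classify_solution_class(
    positions: np.ndarray,
    kr: np.ndarray,
    gt: np.ndarray,
    halfmax: float = CLASS_HALFMAX,
    anterior_window: tuple[float, float] = ANTERIOR_WINDOW,
) -> str:
    """Solution class I/II/III from the anterior Kr and gt pattern at tau.

    Class I: the anterior gt domain and the anterior Kr border (an upward
    Kr crossing posterior to a sub-half-max region) are both present;
    class III: neither is and Kr stays low anteriorly (both anterior
    patterns absent); class II: otherwise — typically ectopic anterior Kr
    in place of gt, with the anterior Kr border missing.
    """
    positions = np.asarray(positions, dtype=float)
    kr = np.asarray(kr, dtype=float)
    gt = np.asarray(gt, dtype=float)
    keep = (positions >= anterior_window[0]) & (positions <= anterior_window[1])
    xw, krw, gtw = positions[keep], kr[keep], gt[keep]

    gt_domain = bool(np.any(gtw >= halfmax))

    kr_border = False
    seen_low = False
    for v in krw:
        if v < halfmax:
            seen_low = True
        elif seen_low:  # upward crossing after a sub-half-max stretch
            kr_border = True
            break

    kr_ectopic = bool(np.any(krw >= halfmax))
    if gt_domain and kr_border:
        return "I"
    if not gt_domain and not kr_border and not kr_ectopic:
        return "III"
    return "II"
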