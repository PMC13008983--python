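"""Cost-utility analysis: QALYs, ICER and the cost-effectiveness plane.

Health states are valued with utility weights (transplant recipients 0.82,
dialysis patients 0.56, from time trade-off elicitation), so freedom from
dialysis is worth 0.26 QALY per life-year.  Cumulative incremental QALYs over
a horizon T adjust each year's utility gap by modality-specific survival:

    dQALY = sum_{t=1}^{T} [ S_Tx(t) * u_Tx - S_dial(t) * u_dial ]

QALYs are undiscounted by default.  The incremental cost-effectiveness ratio
ICER = dCost / dQALY places each country-year on the cost-effectiveness
plane: Quadrant I (dCost < 0, dQALY > 0) is dominant — cheaper and better;
Quadrant II trades higher cost for health gain and is judged against a
willingness-to-pay threshold (default $50,000/QALY); Quadrant III is
dominated; Quadrant IV saves money at a health loss.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UtilityWeights",
    "SurvivalCurves",
    "CEResult",
    "PlaneSummary",
    "DEFAULT_WTP",
    "annual_utility_gain",
    "cumulative_delta_qaly",
    "icer",
    "classify_panel",
]

DEFAULT_WTP = 50_000.0  # USD per QALY


@dataclass(frozen=True)
class UtilityWeights:
    u_tx: float = 0.82
    u_dial: float = 0.56

    def __post_init__(self) -> None:
        for name, u in (("u_tx", self.u_tx), ("u_dial", self.u_dial)):
            if not 0 <= u <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {u}")


@dataclass(frozen=True)
class SurvivalCurves:
    """Survival probabilities S(t) at integer years t = 1..T per modality."""

    s_tx: np.ndarray
    s_dial: np.ndarray

    def __post_init__(self) -> None:
        for name, s in (("s_tx", self.s_tx), ("s_dial", self.s_dial)):
            arr = np.asarray(s, dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
            if np.any(np.diff(arr) > 1e-12):
                raise ValueError(f"{name} must be non-increasing in t")
            object.__setattr__(self, name, arr)

    @property
    def horizon(self) -> int:
        return min(len(self.s_tx), len(self.s_dial))


@dataclass(frozen=True)
class CEResult:
    """Position of one comparison on the cost-effectiveness plane.

    ``icer`` is the raw ratio dCost/dQALY (negative ICERs are meaningful and
    reported as such for dominant strategies); ``icer_defined`` is False only
    when dQALY = 0 with a nonzero cost difference.  ``quadrant`` follows the
    sign pattern of (dCost, dQALY).
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    icer_defined: bool
    quadrant: str
    dominant: bool
    dominated: bool
    cost_effective: bool
    wtp: float


@dataclass(frozen=True)
class PlaneSummary:
    counts: dict[str, int]
    n: int
    panel_dominant: bool


def annual_utility_gain(weights: UtilityWeights) -> float:
    """Incremental utility of transplantation per life-year: u_tx - u_dial."""
    return weights.u_tx - weights.u_dial


def cumulative_delta_qaly(
    weights: UtilityWeights, curves: SurvivalCurves, T: int
) -> float:
    """Survival-adjusted incremental QALYs accumulated over years 1..T.

    With flat unit survival the sum collapses to T * (u_tx - u_dial).  QALYs
    are not discounted.
    """
    if T < 0:
        raise ValueError("horizon T must be >= 0")
    if T == 0:
        return 0.0
    if curves.horizon < T:
        raise ValueError(
            f"survival curves cover {curves.horizon} years, horizon T={T} requested"
        )
    s_tx = curves.s_tx[:T]
    s_dial = curves.s_dial[:T]
    return float(np.sum(s_tx * weights.u_tx - s_dial * weights.u_dial))


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    # Boundary convention: zero differences fall toward the more favourable
    # quadrant label is avoided by treating 0 as non-negative effect / cost.
    if delta_cost < 0 and delta_qaly > 0:
        return "I"
    if delta_cost >= 0 and delta_qaly > 0:
        return "II"
    if delta_cost >= 0 and delta_qaly <= 0:
        return "III"
    return "IV"


def icer(delta_cost: float, delta_qaly: float, wtp: float = DEFAULT_WTP) -> CEResult:
    """Classify an (incremental cost, incremental QALY) pair.

    Dominant strategies (Quadrant I) are cost-effective regardless of the
    threshold; Quadrant II strategies are cost-effective iff ICER < wtp.
    A zero dQALY with nonzero dCost leaves the ICER undefined (flagged, not
    a number).
    """
    quadrant = _quadrant(delta_cost, delta_qaly)
    if delta_qaly == 0:
        defined = delta_cost == 0
        ratio = 0.0 if defined else None
    else:
        defined = True
        ratio = delta_cost / delta_qaly
    dominant = quadrant == "I"
    dominated = quadrant == "III" and delta_cost > 0
    if dominant:
        cost_effective = True
    elif quadrant == "II" and defined:
        cost_effective = ratio < wtp
    else:
        cost_effective = False
    return CEResult(
        delta_cost=float(delta_cost),
        delta_qaly=float(delta_qaly),
        icer=ratio,
        icer_defined=defined,
        quadrant=quadrant,
        dominant=dominant,
        dominated=dominated,
        cost_effective=cost_effective,
        wtp=wtp,
    )


def classify_panel(outcomes: Iterable[CEResult]) -> PlaneSummary:
    """Count quadrant membership across a panel of comparisons.

    The panel is flagged dominant only when every record lies in Quadrant I
    (universal dominance).
    """
    results = list(outcomes)
    if not results:
        raise ValueError("cannot classify an empty collection of outcomes")
    counts = {"I": 0, "II": 0, "III": 0, "IV": 0}
    for res in results:
        counts[res.quadrant] += 1
    return PlaneSummary(
        counts=counts,
        n=len(results),
        panel_dominant=counts["I"] == len(results),
    )
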