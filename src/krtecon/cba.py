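"""Per-patient cost–benefit analysis of kidney transplantation versus dialysis.

The economic comparison rests on three quantities computed per country-year:

* the **annual saving** per transplanted patient, the difference between the
  annual cost of maintenance dialysis and the annual cost of post-transplant
  care (immunosuppression, monitoring, follow-up);
* the **break-even time** ``BE``, the number of years of annual savings needed
  to recoup the initial transplant episode cost (surgery, hospitalization,
  organ procurement, immediate post-operative care);
* the **net present value** ``NPV(T)`` of the transplant decision over a
  T-year horizon at discount rate ``r``, with end-of-year discounting and the
  upfront cost incurred undiscounted at t = 0.

Undiscounted cumulative cash-flow trajectories expose the "valley of death":
the initial interval during which cumulative net savings are negative.
Budget-impact scenarios scale baseline transplant volume by a multiplier phi
and translate the increment into annual and discounted cumulative savings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CBAParams",
    "CashFlowTrajectory",
    "ScenarioConfig",
    "BudgetImpactResult",
    "NoPaybackError",
    "annual_saving",
    "break_even",
    "npv",
    "cash_flow_trajectory",
    "budget_impact",
]


class NoPaybackError(ValueError):
    """Raised when annual savings are non-positive and break-even is undefined."""


@dataclass(frozen=True)
class CBAParams:
    """Discounting parameters for the net-present-value horizon.

    ``discount_rate`` is a fraction per year (0.03 = 3 %); ``horizon`` is an
    integer number of years.
    """

    discount_rate: float = 0.03
    horizon: int = 10

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise ValueError(f"horizon must be an integer >= 1, got {self.horizon}")


@dataclass(frozen=True)
class CashFlowTrajectory:
    """Undiscounted cumulative net savings S(t) on the integer-year grid 0..T.

    ``valley_set`` collects the years with S(t) < 0, ``valley_depth`` is
    min S(t) (USD, non-positive when an upfront cost exists) and
    ``valley_duration`` is the number of years spent below zero.
    """

    years: np.ndarray
    cumulative: np.ndarray
    valley_set: tuple[int, ...] = field(init=False)
    valley_depth: float = field(init=False)
    valley_duration: int = field(init=False)

    def __post_init__(self) -> None:
        below = self.cumulative < 0
        object.__setattr__(self, "valley_set", tuple(int(t) for t in self.years[below]))
        object.__setattr__(self, "valley_depth", float(self.cumulative.min()))
        object.__setattr__(self, "valley_duration", int(below.sum()))


@dataclass(frozen=True)
class ScenarioConfig:
    """Inputs of a transplant-volume expansion scenario.

    ``phi`` is the expansion multiplier (phi = 1.10 means +10 % volume),
    ``vol0`` the baseline annual transplant volume, ``annual_saving`` the
    per-patient annual saving (USD/patient-year) and ``s1`` the one-year
    transplant survival probability that converts expanded procedures into
    patient-years generating savings.
    """

    phi: float
    vol0: float
    annual_saving: float
    s1: float = 0.95

    def __post_init__(self) -> None:
        if self.phi < 1:
            raise ValueError(f"expansion multiplier phi must be >= 1, got {self.phi}")
        if self.vol0 < 0:
            raise ValueError("baseline volume must be >= 0")
        if not 0 <= self.s1 <= 1:
            raise ValueError(f"one-year survival must lie in [0, 1], got {self.s1}")


@dataclass(frozen=True)
class BudgetImpactResult:
    """Annual and discounted cumulative incremental savings of a scenario."""

    phi: float
    annual_increment: float
    cumulative_discounted: float


def annual_saving(c_dialysis: float, c_post_tx: float) -> float:
    """Annual per-patient saving: dialysis cost minus post-transplant cost.

    The signed difference is returned; a negative value flags the dominated
    case (post-transplant care more expensive than dialysis) and is rejected
    downstream by :func:`break_even`.
    """
    if c_dialysis < 0 or c_post_tx < 0:
        raise ValueError("costs must be >= 0")
    return float(c_dialysis) - float(c_post_tx)


def break_even(c_tx_initial: float, saving: float) -> float:
    """Break-even time in years: initial transplant cost over annual saving.

    Raises :class:`NoPaybackError` when ``saving <= 0`` (the upfront cost is
    never recouped), rather than silently dividing.
    """
    if c_tx_initial < 0:
        raise ValueError("initial transplant cost must be >= 0")
    if saving <= 0:
        raise NoPaybackError(
            f"annual saving is {saving:.2f} <= 0: transplant costs are never recouped"
        )
    return float(c_tx_initial) / float(saving)


def npv(saving: float, params: CBAParams, c_tx_initial: float) -> float:
    """Net present value of annual savings over ``params.horizon`` years.

    End-of-year discounting: NPV = sum_{t=1}^{T} saving/(1+r)^t - c_tx_initial,
    with the upfront cost at t = 0 undiscounted.  At r = 0 this reduces to
    saving*T - c_tx_initial exactly.
    """
    r, T = params.discount_rate, params.horizon
    t = np.arange(1, T + 1)
    return float(np.sum(saving / (1.0 + r) ** t) - c_tx_initial)


def annuity_factor(r: float, T: int) -> float:
    """Present value of a unit annual payment over T years (end-of-year)."""
    if r == 0:
        return float(T)
    return (1.0 - (1.0 + r) ** (-T)) / r


def cash_flow_trajectory(c_tx_initial: float, saving: float, T: int) -> CashFlowTrajectory:
    """Undiscounted cumulative net savings S(t) = -c_tx_initial + saving*t.

    Cash-flow accumulation is deliberately undiscounted: the valley metrics
    describe the financing gap a payer must bridge, not discounted value.
    """
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    years = np.arange(0, T + 1)
    cumulative = -float(c_tx_initial) + float(saving) * years
    return CashFlowTrajectory(years=years, cumulative=cumulative)


def budget_impact(scenario: ScenarioConfig, params: CBAParams) -> BudgetImpactResult:
    """Incremental savings from scaling transplant volume by ``scenario.phi``.

    The annual increment is (phi - 1) * vol0 * annual_saving * s1 — exactly
    linear in (phi - 1) and in each factor.  The cumulative total discounts
    that constant annual increment over the horizon at ``params.discount_rate``.
    """
    annual = (scenario.phi - 1.0) * scenario.vol0 * scenario.annual_saving * scenario.s1
    cumulative = annual * annuity_factor(params.discount_rate, params.horizon)
    return BudgetImpactResult(
        phi=scenario.phi,
        annual_increment=float(annual),
        cumulative_discounted=float(cumulative),
    )


def first_nonnegative_year(traj: CashFlowTrajectory) -> int:
    """First integer year with S(t) >= 0; equals ceil(BE) for positive savings."""
    idx = np.nonzero(traj.cumulative >= 0)[0]
    if idx.size == 0:
        raise NoPaybackError("cumulative savings never reach zero on the grid")
    return int(traj.years[idx[0]])
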