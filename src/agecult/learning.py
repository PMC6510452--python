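"""Trait-frequency recursions under age-structured social learning.

A cultural trait ``T`` spreads through a stage-structured population by
three modes of transmission: *vertical* (from one's parents, with
fidelity ``p_v``), *horizontal* (from members of one's own stage) and
*oblique* (from members of older stages up to class ``omega``), the
latter two pooled with a shared fidelity ``p_h`` and size-weighted over
the source stages.

Newborns (class 1) have a single purely-vertical learning round; the
frequency of knowledgeable newborns is the fertility-weighted frequency
of ``T`` among their parents times ``p_v``.  Learners entering classes
2-4 retain the trait if they already hold it and otherwise make one
learning attempt, split between vertical contact (proportion ``V_j`` of
learning time) and horizontal/oblique contact (``1 - V_j``).  The
post-reproductive class 5 no longer learns; its frequency is the
survival-weighted mix of maturing adults and surviving elders.

The per-stage vertical proportions ``V_2..V_4`` define a *learning life
history*.  Four named schedules are bundled: two extremes (all-vertical,
all-horizontal) and two shaped like the ethnographic time-allocation
profiles of Aka hunter-gatherers and neighbouring small-scale
agriculturalists.  The ethnographic schedules are stand-ins on the
published qualitative shape (exact per-stage values are not printed
anywhere) and are fully configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .demography import N_CLASSES, DemographyParams, PopulationState

__all__ = [
    "LearningParams",
    "Scenario",
    "SCENARIOS",
    "newborn_frequency",
    "pooled_source_frequency",
    "surviving_parent_frequency",
    "update_class_frequency",
    "update_oldest_class",
]

logger = logging.getLogger(__name__)


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class LearningParams:
    """Transmission fidelities and the fixed learning schedule.

    ``V`` holds the vertical-learning proportions of classes 2, 3 and 4
    (class 1 is purely vertical, class 5 does not learn).  ``omega`` is
    the oldest stage that can serve as a horizontal/oblique source.
    """

    p_v: float = 0.6
    p_h: float = 0.6
    omega: int = 5
    V: tuple[float, float, float] = (0.8, 0.8, 0.4)

    def __post_init__(self) -> None:
        _check_unit("p_v", self.p_v)
        _check_unit("p_h", self.p_h)
        if not 1 <= int(self.omega) <= N_CLASSES:
            raise ValueError(f"omega must be in 1..{N_CLASSES}, got {self.omega!r}")
        object.__setattr__(self, "omega", int(self.omega))
        if len(self.V) != 3:
            raise ValueError("V must give vertical proportions for classes 2..4")
        object.__setattr__(self, "V", tuple(float(v) for v in self.V))
        for j, vj in zip((2, 3, 4), self.V):
            _check_unit(f"V{j}", vj)


@dataclass(frozen=True)
class Scenario:
    """A named learning life history: vertical proportions for classes 2..4."""

    name: str
    V: tuple[float, float, float]
    description: str = ""

    def __post_init__(self) -> None:
        for j, vj in zip((2, 3, 4), self.V):
            _check_unit(f"V{j}", vj)


#: Bundled learning life histories.  The two ethnographic schedules are
#: configurable stand-ins shaped like published time-allocation data.
SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario(
            "all_vertical",
            (1.0, 1.0, 1.0),
            "Late/no horizontal learning: individuals learn only from parents.",
        ),
        Scenario(
            "hunter_gatherer",
            (0.8, 0.8, 0.4),
            "Predominantly vertical learning through childhood, shifting to "
            "horizontal/oblique in adulthood (forager-like).",
        ),
        Scenario(
            "agriculturalist",
            (0.5, 0.25, 0.1),
            "Early and increasing reliance on horizontal/oblique learning "
            "(small-scale-farmer-like).",
        ),
        Scenario(
            "all_horizontal",
            (0.0, 0.0, 0.0),
            "After the newborn vertical round, individuals learn only from "
            "peers and older non-parents.",
        ),
    )
}


def newborn_frequency(b: float, w_f: float, x4_prev: float, p_v: float) -> float:
    """Trait frequency among newborns after their vertical learning round.

    Carrier parents produce ``b + w_f`` offspring versus ``b``, so the
    probability a newborn's parent carries ``T`` is the fertility-weighted
    parental frequency; the newborn then acquires ``T`` with fidelity
    ``p_v``.
    """
    x4_prev = _check_unit("x4_prev", x4_prev)
    p_v = _check_unit("p_v", p_v)
    num = (b + w_f) * x4_prev
    den = num + b * (1.0 - x4_prev)
    if den <= 0:
        raise ValueError(
            "no offspring produced: fertility-weighted parental pool is empty"
        )
    return p_v * num / den


def pooled_source_frequency(state: PopulationState, j: int, omega: int) -> float:
    """Trait frequency among horizontal/oblique role models of a class-j learner.

    The pool spans the learner's own stage ``j`` through stage ``omega``,
    each stage weighted by its current size:
    ``sum_{z=j..omega} n_z x_z / sum_{z=j..omega} n_z``.
    """
    if not 1 <= j <= omega <= N_CLASSES:
        raise ValueError(f"need 1 <= j <= omega <= {N_CLASSES}, got j={j}, omega={omega}")
    weights = state.a[j - 1 : omega]
    den = weights.sum()
    if den <= 0:
        raise ValueError(
            f"no role models available: stages {j}..{omega} are all empty"
        )
    return float(np.dot(weights, state.x[j - 1 : omega]) / den)


def surviving_parent_frequency(
    mode: str, params: DemographyParams, x4_lagged: float, j: int
) -> float:
    """Trait frequency among the (surviving) parents of class-j learners.

    ``x4_lagged`` is the adult frequency at the learners' birth time.  In
    fertility mode carrier parents are over-represented among parents in
    proportion to ``b + w_f`` versus ``b``; in survival mode carrier
    parents are over-represented among *surviving* parents in proportion
    to ``(s4 + w_s)^j`` versus ``s4^j``; for a fitness-neutral trait the
    parental frequency is ``x4_lagged`` unchanged.
    """
    x4_lagged = _check_unit("x4_lagged", x4_lagged)
    if j < 1:
        raise ValueError("j must be at least 1")
    if mode == "fertility":
        num = (params.b + params.w_f) * x4_lagged
        den = num + params.b * (1.0 - x4_lagged)
    elif mode == "survival":
        s4 = params.s[3]
        num = (s4 + params.w_s) ** j * x4_lagged
        den = num + s4**j * (1.0 - x4_lagged)
    elif mode == "neutral":
        return x4_lagged
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den <= 0:
        raise ValueError("surviving parental pool is empty")
    return num / den


def update_class_frequency(
    x_prev_class: float,
    V_j: float,
    p_v: float,
    p_h: float,
    x_parent: float,
    x_pool: float,
) -> float:
    """One learning round for a cohort moving up into class j.

    Members who already hold the trait keep it; the naive remainder
    acquire it vertically (proportion ``V_j`` of learning contact, parent
    holds the trait with probability ``x_parent``, fidelity ``p_v``) or
    horizontally/obliquely (``1 - V_j``, pool frequency ``x_pool``,
    fidelity ``p_h``)::

        x' = x + (1 - x) (V_j x_parent p_v + (1 - V_j) p_h x_pool)
    """
    args = {
        "x_prev_class": x_prev_class,
        "V_j": V_j,
        "p_v": p_v,
        "p_h": p_h,
        "x_parent": x_parent,
        "x_pool": x_pool,
    }
    for name, value in args.items():
        _check_unit(name, value)
    gain = V_j * x_parent * p_v + (1.0 - V_j) * p_h * x_pool
    return x_prev_class + (1.0 - x_prev_class) * gain


def update_oldest_class(state: PopulationState, s4: float, s5: float) -> float:
    """Trait frequency of the post-reproductive stage at the next step.

    Class 5 does not learn; its members are adults maturing from class 4
    plus surviving elders, so the next frequency is the survival-weighted
    mean of ``x4`` and ``x5``.  If both inflows are empty the frequency
    is reported as 0 by convention (the stage will be empty).
    """
    _check_unit("s4", s4)
    _check_unit("s5", s5)
    m4 = s4 * state.a[3]
    m5 = s5 * state.a[4]
    den = m4 + m5
    if den <= 0:
        logger.warning(
            "post-reproductive stage empty at tau=%d; frequency set to 0", state.tau
        )
        return 0.0
    return float((state.x[3] * m4 + state.x[4] * m5) / den)
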