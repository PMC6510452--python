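"""Cultural niche construction: the trait erodes vertical contact time.

A niche-constructing trait (farming is the motivating example) changes
the learning environment as it spreads: the more common the trait is
among the adults of a cohort's parental generation, the less time that
cohort spends in vertical contact with its parents,

    v_j = v_b (1 - epsilon * x4_lagged),

where ``v_b`` is the baseline proportion of learning time spent with
parents, ``epsilon`` scales the strength of the feedback, and
``x4_lagged`` is the adult trait frequency at the cohort's birth time.
With ``epsilon = 0`` this reduces to a fixed schedule ``V_j = v_b``;
with ``epsilon = 1`` vertical contact vanishes as the trait fixes and
learning becomes purely horizontal/oblique.  The dynamic ``v_j``
replaces the fixed vertical proportion ``V_j`` in the class-frequency
update for classes 2-4; the newborn vertical round is not modified
(the contact-time norm acts on post-infancy learning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .demography import DemographyParams, PopulationState
from .learning import (
    LearningParams,
    pooled_source_frequency,
    surviving_parent_frequency,
    update_class_frequency,
)

__all__ = ["NicheParams", "vertical_time", "niche_update_class_frequency"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NicheParams:
    """Contact-time feedback parameters.

    ``enabled`` switches the frequency-dependent schedule on; ``v_b`` is
    the baseline vertical contact proportion and ``epsilon`` the
    niche-construction strength (0 = no feedback).
    """

    enabled: bool = False
    v_b: float = 0.6
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_b <= 1.0:
            raise ValueError(f"v_b must lie in [0, 1], got {self.v_b!r}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon!r}")


def vertical_time(params: NicheParams, x4_lagged: float) -> float:
    """Vertical contact proportion ``v_b (1 - epsilon * x4_lagged)``, clamped to [0, 1].

    Clamping can only trigger for ``epsilon > 1`` (or pathological
    combinations); it is logged when it occurs.
    """
    if not 0.0 <= x4_lagged <= 1.0:
        raise ValueError(f"x4_lagged must lie in [0, 1], got {x4_lagged!r}")
    raw = params.v_b * (1.0 - params.epsilon * x4_lagged)
    if raw < 0.0 or raw > 1.0:
        logger.debug("vertical contact time %.6g clamped to [0, 1]", raw)
        return min(max(raw, 0.0), 1.0)
    return raw


def niche_update_class_frequency(
    state: PopulationState,
    j: int,
    mode: str,
    dem: DemographyParams,
    lp: LearningParams,
    np_: NicheParams,
) -> float:
    """Class-frequency update for classes 2-4 with the dynamic schedule.

    Identical to the fixed-schedule update except that the vertical
    proportion is ``vertical_time`` evaluated at the adult frequency of
    the cohort's parental generation (lag ``j - 1`` relative to the
    current state, i.e. the adults of class 4 when the cohort was born).
    """
    if j not in (2, 3, 4):
        raise ValueError(f"niche update applies to classes 2..4, got j={j}")
    x4_lagged = state.lagged_adult_frequency(j - 1)
    v_j = vertical_time(np_, x4_lagged)
    x_parent = surviving_parent_frequency(mode, dem, x4_lagged, j)
    if (1.0 - v_j) * lp.p_h > 0:
        x_pool = pooled_source_frequency(state, j, lp.omega)
    else:
        x_pool = 0.0
    return update_class_frequency(
        float(state.x[j - 2]), v_j, lp.p_v, lp.p_h, x_parent, x_pool
    )
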