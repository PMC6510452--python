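"""Stage-structured demography with trait-dependent vital rates.

The population is divided into five life stages — infancy, early
childhood, late childhood, adulthood, and post-reproductive life — and
projected forward with an adapted Leslie matrix ``L``::

        [ 0   0   0   f4  0  ]
        [ s1  0   0   0   0  ]
    L = [ 0   s2  0   0   0  ]
        [ 0   0   s3  0   0  ]
        [ 0   0   0   s4  s5 ]

Only the adult stage (class 4) reproduces; post-reproductive survivors
remain in class 5 (self-loop) rather than leaving the population.  A
cultural trait ``T`` segregating at frequency ``x_i`` in stage ``i`` can
raise fertility (``b -> b + w_f`` in carriers) or survival
(``s_i -> s_i + w_s`` in carriers); the stage-average vital rates that
enter ``L`` are the carrier-frequency-weighted means.

Stage sizes are continuous non-negative reals; the deterministic
recursion has no demographic stochasticity (an individual-based
stochastic twin lives in :mod:`agecult.oracle`).  Internally a
population state stores stage *proportions* plus the log of total size,
so super-critical growth over thousands of steps cannot overflow; every
recursion in the model depends on the ``n_i`` only through ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "N_CLASSES",
    "MODES",
    "DemographyParams",
    "PopulationState",
    "effective_fertility",
    "effective_survival",
    "build_projection_matrix",
    "advance_counts",
    "dominant_eigenvalue",
    "stable_stage_distribution",
]

N_CLASSES = 5
#: Valid fitness modes: the trait affects fertility, survival, or neither.
MODES = ("fertility", "survival", "neutral")


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class DemographyParams:
    """Vital rates and trait fitness effects.

    Parameters
    ----------
    b
        Baseline number of offspring per adult (class-4 individual) per
        time step; carriers of ``T`` produce ``b + w_f``.
    s
        Survival probabilities ``(s1, ..., s5)``; ``s5`` is the
        self-loop survival of the post-reproductive stage.
    w_f
        Additive fertility increment of the trait (may be negative, but
        ``b + w_f`` must stay non-negative).
    w_s
        Additive survival increment of the trait, applied uniformly to
        all stages when the run is in survival mode.
    """

    b: float = 5.0
    s: tuple[float, ...] = (0.5, 0.6, 0.6, 0.6, 0.2)
    w_f: float = 0.0
    w_s: float = 0.0
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"only n_classes={N_CLASSES} is supported")
        if len(self.s) != N_CLASSES:
            raise ValueError(f"s must have {N_CLASSES} entries, got {len(self.s)}")
        object.__setattr__(self, "s", tuple(float(v) for v in self.s))
        for i, si in enumerate(self.s, start=1):
            _check_unit(f"s{i}", si)
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b!r}")
        if self.b + self.w_f < 0:
            raise ValueError(
                f"effective carrier fertility b + w_f = {self.b + self.w_f!r} "
                "must be non-negative"
            )

    def validate_survival_mode(self) -> None:
        """Check that carrier survival stays a probability in every stage."""
        for i, si in enumerate(self.s, start=1):
            if not 0.0 <= si + self.w_s <= 1.0:
                raise ValueError(
                    f"s{i} + w_s = {si + self.w_s!r} outside [0, 1]; "
                    "invalid for a survival-affecting trait"
                )


@dataclass
class PopulationState:
    """Stage-structured population state at one time step.

    Attributes
    ----------
    a
        Stage proportions (length 5, non-negative, summing to 1).
    log_total
        Natural log of total population size; ``n = a * exp(log_total)``.
    x
        Trait frequency in each stage, each in [0, 1].
    tau
        Integer time index.
    adult_freq_history
        Past adult (class-4) trait frequencies, most recent last, used to
        serve the parental-cohort lags (up to ``N_CLASSES - 1`` steps).
        Padded with the initial adult frequency at initialization.
    """

    a: np.ndarray
    log_total: float
    x: np.ndarray
    tau: int = 0
    adult_freq_history: tuple[float, ...] = ()
    extinct: bool = False

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).copy()
        self.x = np.asarray(self.x, dtype=float).copy()
        if self.a.shape != (N_CLASSES,) or self.x.shape != (N_CLASSES,):
            raise ValueError("a and x must be length-5 vectors")
        if np.any(self.a < -1e-12):
            raise ValueError("stage proportions must be non-negative")
        if not self.extinct and abs(self.a.sum() - 1.0) > 1e-9:
            raise ValueError(f"stage proportions must sum to 1, got {self.a.sum()!r}")
        if np.any(self.x < -1e-12) or np.any(self.x > 1 + 1e-12):
            raise ValueError("trait frequencies must lie in [0, 1]")
        np.clip(self.x, 0.0, 1.0, out=self.x)
        hist = tuple(float(v) for v in self.adult_freq_history)
        pad = N_CLASSES - 1 - len(hist)
        if pad > 0:
            hist = (float(self.x[3]),) * pad + hist
        self.adult_freq_history = hist

    @classmethod
    def from_counts(
        cls,
        n,
        x,
        tau: int = 0,
        adult_freq_history: tuple[float, ...] = (),
    ) -> "PopulationState":
        n = np.asarray(n, dtype=float)
        total = n.sum()
        if total <= 0:
            raise ValueError("total population size must be positive")
        return cls(
            a=n / total,
            log_total=float(np.log(total)),
            x=np.asarray(x, dtype=float),
            tau=tau,
            adult_freq_history=adult_freq_history,
        )

    @property
    def n_total(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.log_total))

    @property
    def n(self) -> np.ndarray:
        return self.a * self.n_total

    def lagged_adult_frequency(self, lag: int) -> float:
        """Adult trait frequency ``lag`` steps before the current time.

        ``lag=0`` is the current adult frequency; earlier values come
        from the history buffer (padded with the initial adult frequency
        for lags reaching before the start of the run).
        """
        if lag < 0:
            raise ValueError("lag must be non-negative")
        if lag == 0:
            return float(self.x[3])
        if lag > len(self.adult_freq_history):
            raise ValueError(f"history buffer too short for lag {lag}")
        return self.adult_freq_history[-lag]

    def pushed(self, new_a, new_log_total, new_x, extinct=False) -> "PopulationState":
        """Successor state with the current adult frequency appended to the lag buffer."""
        hist = (self.adult_freq_history + (float(self.x[3]),))[-(N_CLASSES - 1):]
        return PopulationState(
            a=new_a,
            log_total=new_log_total,
            x=new_x,
            tau=self.tau + 1,
            adult_freq_history=hist,
            extinct=extinct or self.extinct,
        )


def effective_fertility(params: DemographyParams, x4: float) -> float:
    """Stage-average fertility of the adult class at carrier frequency ``x4``.

    Carriers produce ``b + w_f`` offspring and non-carriers ``b``, so the
    class-average fertility is ``(b + w_f) x4 + b (1 - x4)``.
    """
    x4 = _check_unit("x4", x4)
    return (params.b + params.w_f) * x4 + params.b * (1.0 - x4)


def effective_survival(params: DemographyParams, s_i: float, x_i: float) -> float:
    """Stage-average survival ``s_i (1 - x_i) + x_i (s_i + w_s)``."""
    s_i = _check_unit("s_i", s_i)
    x_i = _check_unit("x_i", x_i)
    result = s_i + params.w_s * x_i
    if not 0.0 <= result <= 1.0 + 1e-12:
        raise ValueError(
            f"effective survival {result!r} outside [0, 1]; check w_s"
        )
    return min(result, 1.0)


def build_projection_matrix(
    params: DemographyParams, state: PopulationState, mode: str
) -> np.ndarray:
    """Adapted Leslie matrix for the current state under the given fitness mode.

    In fertility mode the single fertility entry ``f4`` is the
    carrier-weighted class average; in survival mode each survival entry
    is carrier-weighted; in neutral mode the matrix is independent of
    the trait frequencies.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    L = np.zeros((N_CLASSES, N_CLASSES))
    if mode == "fertility":
        L[0, 3] = effective_fertility(params, float(state.x[3]))
    else:
        L[0, 3] = params.b
    if mode == "survival":
        s_eff = [
            effective_survival(params, params.s[i], float(state.x[i]))
            for i in range(N_CLASSES)
        ]
    else:
        s_eff = list(params.s)
    L[1, 0] = s_eff[0]
    L[2, 1] = s_eff[1]
    L[3, 2] = s_eff[2]
    L[4, 3] = s_eff[3]
    L[4, 4] = s_eff[4]
    return L


def advance_counts(L: np.ndarray, n: np.ndarray) -> np.ndarray:
    """One projection step ``n -> L n``."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("stage sizes must be non-negative")
    return L @ n


def dominant_eigenvalue(L: np.ndarray) -> float:
    """Spectral radius of the projection matrix (asymptotic growth factor)."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(L, dtype=float)))))


def stable_stage_distribution(L: np.ndarray) -> np.ndarray:
    """Right eigenvector of the dominant eigenvalue, normalized to sum 1.

    This is the long-run stage structure in the Perron sense.  Note that
    with a single reproductive stage the classes-1..4 block of ``L`` is
    cyclic (imprimitive with period 4), so a generic initial structure
    converges to a period-4 orbit around this eigenvector rather than to
    the eigenvector itself; the eigenvector is the unique structure that
    reproduces itself exactly each step.
    """
    values, vectors = np.linalg.eig(np.asarray(L, dtype=float))
    radius = np.max(np.abs(values))
    # the cyclic stage block makes L imprimitive: several eigenvalues share
    # the spectral radius; take the real non-negative Perron root
    candidates = [
        k
        for k in range(len(values))
        if abs(values[k].imag) < 1e-9 * max(radius, 1.0)
        and values[k].real >= -1e-12
        and abs(abs(values[k]) - radius) < 1e-9 * max(radius, 1.0)
    ]
    if not candidates:
        raise ValueError("no real non-negative dominant eigenvalue found")
    k = candidates[0]
    v = np.real(vectors[:, k])
    v = np.abs(v)
    total = v.sum()
    if total == 0:
        raise ValueError("degenerate projection matrix")
    return v / total
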