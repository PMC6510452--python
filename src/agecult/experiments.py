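"""Simulation orchestration: single runs, sweeps, contrasts, rescue.

The canonical experiment designs are:

* a single coupled trajectory of stage sizes and trait frequencies,
* a ``(p_v, p_h)`` fidelity grid reporting the end-state population-mean
  trait frequency per cell,
* a selected-versus-neutral contrast (same run twice, once with the
  fitness effect zeroed) isolating how much of the trait's spread is due
  to its demographic advantage,
* a demographic-rescue comparison of learning life histories in a small
  declining population.

With a single reproductive stage the projection matrix is cyclic over
stages 1-4 (imprimitive, period equal to the maturation time of 4
steps), so cohort waves excited by the initial age structure never damp
and every instantaneous size-weighted statistic oscillates with period
4 indefinitely.  End-state statistics are therefore reported as means
over the final maturation cycle (the last 4 steps), which are
phase-free; the instantaneous endpoint value is also available
(``statistic="final_freq"``), and per-class frequencies are recorded so
alternatives are recoverable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .demography import (
    MODES,
    N_CLASSES,
    DemographyParams,
    PopulationState,
    build_projection_matrix,
    dominant_eigenvalue,
)
from .learning import (
    SCENARIOS,
    LearningParams,
    newborn_frequency,
    pooled_source_frequency,
    surviving_parent_frequency,
    update_class_frequency,
    update_oldest_class,
)
from .niche import NicheParams, niche_update_class_frequency, vertical_time

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "initial_state",
    "step",
    "run",
    "run_final",
    "mean_population_frequency",
    "sweep_fidelity_grid",
    "compare_to_neutral",
    "neutral_difference_grid",
    "rescue_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one deterministic simulation."""

    demography: DemographyParams = field(default_factory=DemographyParams)
    learning: LearningParams = field(default_factory=LearningParams)
    niche: NicheParams = field(default_factory=NicheParams)
    mode: str = "fertility"
    n_steps: int = 5000
    initial_total: float = 100.0
    initial_age_structure: tuple[float, ...] = (0.2,) * N_CLASSES
    initial_trait_freq: float = 0.005
    scenario: str = "hunter_gatherer"
    collapse_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.initial_total <= 0:
            raise ValueError("initial_total must be positive")
        structure = tuple(float(v) for v in self.initial_age_structure)
        if len(structure) != N_CLASSES:
            raise ValueError(f"initial_age_structure needs {N_CLASSES} entries")
        if any(v < 0 for v in structure):
            raise ValueError("initial_age_structure entries must be non-negative")
        if abs(sum(structure) - 1.0) > 1e-9:
            raise ValueError(
                f"initial_age_structure must sum to 1, got {sum(structure)!r}"
            )
        object.__setattr__(self, "initial_age_structure", structure)
        if not 0.0 <= self.initial_trait_freq <= 1.0:
            raise ValueError("initial_trait_freq must lie in [0, 1]")
        if self.mode == "survival":
            self.demography.validate_survival_mode()

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class Trajectory:
    """Recorded time series of one run.

    ``frame`` has one row per step (``n_steps + 1`` rows including the
    initial state) with columns ``tau, n1..n5, x1..x5, n_total,
    mean_freq``.
    """

    frame: pd.DataFrame
    final_state: PopulationState
    collapsed: bool = False
    extinct: bool = False
    clamp_events: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def final_mean_frequency(self) -> float:
        return float(self.frame["mean_freq"].iloc[-1])

    @property
    def final_total_size(self) -> float:
        return float(self.frame["n_total"].iloc[-1])

    @property
    def cycle_mean_frequency(self) -> float:
        """Mean frequency averaged over the final maturation cycle (4 steps)."""
        return float(self.frame["mean_freq"].iloc[-4:].mean())

    @property
    def cycle_mean_total(self) -> float:
        """Total size averaged over the final maturation cycle (4 steps)."""
        return float(self.frame["n_total"].iloc[-4:].mean())


def initial_state(config: SimulationConfig) -> PopulationState:
    """Initial population state implied by a configuration."""
    a = np.array(config.initial_age_structure, dtype=float)
    x = np.full(N_CLASSES, float(config.initial_trait_freq))
    return PopulationState(
        a=a,
        log_total=float(np.log(config.initial_total)),
        x=x,
        tau=0,
        adult_freq_history=(float(config.initial_trait_freq),) * (N_CLASSES - 1),
    )


def mean_population_frequency(state: PopulationState) -> float:
    """Size-weighted mean trait frequency, ``sum n_i x_i / sum n_i``."""
    if state.extinct:
        raise ValueError("mean frequency undefined for an extinct population")
    return float(np.dot(state.a, state.x))


def step(state: PopulationState, config: SimulationConfig) -> PopulationState:
    """One synchronous step of the coupled recursion (scalar reference path).

    Composes the documented per-operation functions; :func:`run` uses the
    vectorized kernel, and the two are cross-checked in the tests.
    """
    if state.extinct:
        return state
    dem, lp, nichep = config.demography, config.learning, config.niche
    mode = config.mode
    wf_eff = dem.w_f if mode == "fertility" else 0.0

    new_x = np.empty(N_CLASSES)
    new_x[0] = newborn_frequency(dem.b, wf_eff, float(state.x[3]), lp.p_v)
    for j in (2, 3, 4):
        if nichep.enabled:
            new_x[j - 1] = niche_update_class_frequency(state, j, mode, dem, lp, nichep)
        else:
            x4_lagged = state.lagged_adult_frequency(j - 1)
            x_parent = surviving_parent_frequency(mode, dem, x4_lagged, j)
            V_j = lp.V[j - 2]
            if (1.0 - V_j) * lp.p_h > 0:
                x_pool = pooled_source_frequency(state, j, lp.omega)
            else:
                x_pool = 0.0
            new_x[j - 1] = update_class_frequency(
                float(state.x[j - 2]), V_j, lp.p_v, lp.p_h, x_parent, x_pool
            )
    new_x[4] = update_oldest_class(state, dem.s[3], dem.s[4])

    L = build_projection_matrix(dem, state, mode)
    a_raw = L @ state.a
    growth = a_raw.sum()
    if growth <= 0:
        return state.pushed(state.a, -np.inf, new_x, extinct=True)
    return state.pushed(a_raw / growth, state.log_total + np.log(growth), new_x)


def _kernel_params(config: SimulationConfig, pv, ph, V_rows, mode: str):
    """Assemble per-run kernel parameter arrays of batch size B."""
    pv = np.atleast_1d(np.asarray(pv, dtype=float))
    B = pv.shape[0]
    dem, lp, nichep = config.demography, config.learning, config.niche
    return dict(
        b=np.full(B, dem.b),
        wf=np.full(B, dem.w_f),
        ws=np.full(B, dem.w_s),
        s=np.tile(np.array(dem.s), (B, 1)),
        pv=pv,
        ph=np.atleast_1d(np.asarray(ph, dtype=float)),
        V=np.asarray(V_rows, dtype=float).reshape(B, 3),
        omega=lp.omega,
        mode=mode,
        niche=nichep.enabled,
        vb=np.full(B, nichep.v_b),
        eps=np.full(B, nichep.epsilon),
    )


def _initial_batch(config: SimulationConfig, B: int):
    state = initial_state(config)
    a0 = np.tile(state.a, (B, 1))
    x0 = np.tile(state.x, (B, 1))
    log_n0 = np.full(B, state.log_total)
    hist0 = np.tile(
        np.array(state.adult_freq_history[::-1][: _lag_depth()]), (B, 1)
    )
    return a0, x0, log_n0, hist0


def _lag_depth() -> int:
    return 3


def run(config: SimulationConfig) -> Trajectory:
    """Run one deterministic simulation, recording every step."""
    lp = config.learning
    a0, x0, log_n0, hist0 = _initial_batch(config, 1)
    out = _kernel.iterate_batch(
        a0,
        x0,
        log_n0,
        hist0,
        n_steps=config.n_steps,
        record=True,
        **_kernel_params(config, [lp.p_v], [lp.p_h], [lp.V], config.mode),
    )
    with np.errstate(over="ignore"):
        totals = np.exp(out["traj_log_n"][:, 0])
    a_t = out["traj_a"][:, 0, :]
    x_t = out["traj_x"][:, 0, :]
    frame = pd.DataFrame(
        {
            "tau": np.arange(config.n_steps + 1),
            **{f"n{i + 1}": a_t[:, i] * totals for i in range(N_CLASSES)},
            **{f"x{i + 1}": x_t[:, i] for i in range(N_CLASSES)},
            "n_total": totals,
            "mean_freq": (a_t * x_t).sum(axis=1),
        }
    )
    final = PopulationState(
        a=out["a"][0],
        log_total=float(out["log_n"][0]),
        x=out["x"][0],
        tau=config.n_steps,
        adult_freq_history=tuple(out["hist"][0][::-1]),
        extinct=bool(out["extinct"][0]),
    )
    collapsed = bool(np.nanmin(totals) < config.collapse_threshold)
    return Trajectory(
        frame=frame,
        final_state=final,
        collapsed=collapsed,
        extinct=bool(out["extinct"][0]),
        clamp_events=out["clamp_events"],
    )


def run_final(config: SimulationConfig) -> PopulationState:
    """Run without recording; returns only the final state (fast path)."""
    lp = config.learning
    a0, x0, log_n0, hist0 = _initial_batch(config, 1)
    out = _kernel.iterate_batch(
        a0,
        x0,
        log_n0,
        hist0,
        n_steps=config.n_steps,
        record=False,
        **_kernel_params(config, [lp.p_v], [lp.p_h], [lp.V], config.mode),
    )
    return PopulationState(
        a=out["a"][0],
        log_total=float(out["log_n"][0]),
        x=out["x"][0],
        tau=config.n_steps,
        adult_freq_history=tuple(out["hist"][0][::-1]),
        extinct=bool(out["extinct"][0]),
    )


def _cycle_mean_frequency(out) -> np.ndarray:
    """Population-mean frequency averaged over the final maturation cycle."""
    return (out["cycle_a"] * out["cycle_x"]).sum(axis=2).mean(axis=0)


def _cycle_mean_total(out) -> np.ndarray:
    """Total size averaged over the final maturation cycle."""
    with np.errstate(over="ignore"):
        return np.exp(out["cycle_log_n"]).mean(axis=0)


def _grid_final_frequencies(
    config: SimulationConfig, pv_values, ph_values, mode: str,
    statistic: str = "mean_freq",
) -> np.ndarray:
    """End-state mean frequency over a fidelity grid (rows p_v, cols p_h).

    ``mean_freq`` averages over the final maturation cycle (phase-free);
    ``final_freq`` is the instantaneous endpoint value.
    """
    pv_values = np.asarray(pv_values, dtype=float)
    ph_values = np.asarray(ph_values, dtype=float)
    PV, PH = np.meshgrid(pv_values, ph_values, indexing="ij")
    B = PV.size
    V_rows = np.tile(np.array(config.learning.V), (B, 1))
    a0, x0, log_n0, hist0 = _initial_batch(config, B)
    out = _kernel.iterate_batch(
        a0,
        x0,
        log_n0,
        hist0,
        n_steps=config.n_steps,
        record=False,
        **_kernel_params(config, PV.ravel(), PH.ravel(), V_rows, mode),
    )
    if statistic == "final_freq":
        values = (out["a"] * out["x"]).sum(axis=1)
    else:
        values = _cycle_mean_frequency(out)
    return values.reshape(PV.shape)


def sweep_fidelity_grid(
    config: SimulationConfig,
    pv_values,
    ph_values,
    statistic: str = "mean_freq",
) -> pd.DataFrame:
    """Independent runs over a ``(p_v, p_h)`` grid.

    Returns a DataFrame indexed by ``p_v`` with ``p_h`` columns holding
    the end-state size-weighted population frequency: ``mean_freq``
    (default) averages over the final maturation cycle, ``final_freq``
    is the instantaneous endpoint sample.
    """
    if statistic not in ("final_freq", "mean_freq"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values = _grid_final_frequencies(
        config, pv_values, ph_values, config.mode, statistic
    )
    return pd.DataFrame(
        values,
        index=pd.Index(np.asarray(pv_values, dtype=float), name="p_v"),
        columns=pd.Index(np.asarray(ph_values, dtype=float), name="p_h"),
    )


def _neutral_twin(config: SimulationConfig) -> SimulationConfig:
    dem = config.demography
    return config.replace(
        demography=dataclasses.replace(dem, w_f=0.0, w_s=0.0)
    )


def compare_to_neutral(config: SimulationConfig) -> float:
    """Selected-minus-neutral final population-mean frequency.

    Runs the configured simulation and a twin with the fitness effect
    removed (``w_f = w_s = 0``; scenario, fidelities and demography
    otherwise identical) and returns the difference of end-state mean
    frequencies (each averaged over the final maturation cycle).
    """
    lp = config.learning
    selected = float(
        _grid_final_frequencies(config, [lp.p_v], [lp.p_h], config.mode)[0, 0]
    )
    twin = _neutral_twin(config)
    neutral = float(
        _grid_final_frequencies(twin, [lp.p_v], [lp.p_h], twin.mode)[0, 0]
    )
    return selected - neutral


def neutral_difference_grid(
    config: SimulationConfig, pv_values, ph_values
) -> pd.DataFrame:
    """Selected-minus-neutral end-state frequency over a fidelity grid."""
    selected = _grid_final_frequencies(config, pv_values, ph_values, config.mode)
    neutral = _grid_final_frequencies(
        _neutral_twin(config), pv_values, ph_values, config.mode
    )
    return pd.DataFrame(
        selected - neutral,
        index=pd.Index(np.asarray(pv_values, dtype=float), name="p_v"),
        columns=pd.Index(np.asarray(ph_values, dtype=float), name="p_h"),
    )


def rescue_experiment(
    config: SimulationConfig,
    scenarios: tuple[str, str] = ("all_vertical", "all_horizontal"),
) -> dict:
    """Compare population fate under two learning life histories.

    Runs the same demography under each scenario and reports final
    population sizes and collapse flags, together with the asymptotic
    growth factors of the trait-free and trait-fixed projection matrices
    (sub- versus super-critical demography).
    """
    results: dict = {"scenarios": {}}
    for name in scenarios:
        scen = SCENARIOS[name]
        cfg = config.replace(
            scenario=name,
            learning=dataclasses.replace(config.learning, V=scen.V),
        )
        traj = run(cfg)
        results["scenarios"][name] = {
            "final_size": traj.cycle_mean_total,
            "final_mean_freq": traj.cycle_mean_frequency,
            "collapsed": traj.collapsed,
            "trajectory": traj,
        }
    dem = config.demography
    base_state = initial_state(config.replace(initial_trait_freq=0.0))
    fixed_state = initial_state(config.replace(initial_trait_freq=1.0))
    results["lambda_baseline"] = dominant_eigenvalue(
        build_projection_matrix(dem, base_state, config.mode)
    )
    results["lambda_trait_fixed"] = dominant_eigenvalue(
        build_projection_matrix(dem, fixed_state, config.mode)
    )
    return results
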