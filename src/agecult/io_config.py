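"""Configuration parsing, presets, serialization and fixture states.

Config files are YAML documents with up to four sections —
``demography``, ``learning``, ``niche``, ``simulation`` — of flat
scalar keys::

    demography:
      b: 5.0
      s1: 0.5
      s2: 0.6
      ...
      w_f: 1.0
      mode: fertility
    learning:
      p_v: 0.6
      p_h: 0.6
      scenario: hunter_gatherer

Unknown sections or keys are rejected with an error naming them; every
defaulted key is logged.  Named presets bundle the parameterizations of
the canonical experiments.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import N_CLASSES, DemographyParams, PopulationState
from .experiments import SimulationConfig, Trajectory
from .learning import SCENARIOS, LearningParams
from .niche import NicheParams

__all__ = [
    "DEFAULTS",
    "PRESETS",
    "load_config",
    "dump_config",
    "write_trajectory",
    "read_trajectory",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

#: Default configuration: the baseline trait-spread parameterization
#: (b=5, s=(0.5,0.6,0.6,0.6,0.2), w_f=1, w_s=0.05, uniform start of 100,
#: trait introduced at 0.005, 5000 steps).
DEFAULTS: dict[str, dict] = {
    "demography": {
        "b": 5.0,
        "s1": 0.5,
        "s2": 0.6,
        "s3": 0.6,
        "s4": 0.6,
        "s5": 0.2,
        "w_f": 1.0,
        "w_s": 0.05,
        "mode": "fertility",
    },
    "learning": {
        "p_v": 0.6,
        "p_h": 0.6,
        "omega": 5,
        "scenario": "hunter_gatherer",
        "V2": None,
        "V3": None,
        "V4": None,
    },
    "niche": {"enabled": False, "v_b": 0.6, "epsilon": 0.0},
    "simulation": {
        "n_steps": 5000,
        "initial_total": 100.0,
        "initial_trait_freq": 0.005,
        "a1": 0.2,
        "a2": 0.2,
        "a3": 0.2,
        "a4": 0.2,
        "a5": 0.2,
        "collapse_threshold": 1.0,
    },
}

#: Named parameterizations of the canonical experiments.
PRESETS: dict[str, dict[str, dict]] = {
    # baseline trait spread over a fidelity grid
    "trait_spread": {},
    # same but with the rarer introduction frequency variant
    "trait_spread_rare": {"simulation": {"initial_trait_freq": 0.001}},
    # selected-vs-neutral contrast demography
    "fitness_contrast": {
        "demography": {"b": 4.0, "s1": 0.6, "s2": 0.7, "s3": 0.7, "s4": 0.7, "s5": 0.4}
    },
    # fertility-enhancing niche-constructing trait
    "niche_construction": {
        "demography": {"b": 4.0, "s1": 0.6, "s2": 0.7, "s3": 0.7, "s4": 0.7, "s5": 0.4},
        "niche": {"enabled": True, "v_b": 0.6, "epsilon": 1.0},
    },
    # fertility-decreasing (small-family-norm-like) niche-constructing trait
    "counter_selection": {
        "demography": {
            "b": 4.0,
            "s1": 0.6,
            "s2": 0.7,
            "s3": 0.7,
            "s4": 0.7,
            "s5": 0.4,
            "w_f": -2.0,
        },
        "niche": {"enabled": True, "v_b": 0.6, "epsilon": 1.0},
    },
    # demographic rescue/collapse in a small declining population
    "rescue": {
        "demography": {
            "b": 3.0,
            "s1": 0.6,
            "s2": 0.6,
            "s3": 0.6,
            "s4": 0.6,
            "s5": 0.4,
            "w_f": 1.7,
            "w_s": 0.0,
        },
        "simulation": {"initial_total": 50.0, "n_steps": 2500},
    },
}


def _merge(base: dict[str, dict], extra: dict[str, dict], origin: str) -> None:
    for section, keys in extra.items():
        if section not in base:
            raise ValueError(
                f"unknown config section {section!r} (from {origin}); "
                f"expected one of {sorted(base)}"
            )
        if not isinstance(keys, dict):
            raise ValueError(f"section {section!r} (from {origin}) must be a mapping")
        for key, value in keys.items():
            if key not in base[section]:
                raise ValueError(
                    f"unknown key {key!r} in section {section!r} (from {origin}); "
                    f"expected one of {sorted(base[section])}"
                )
            base[section][key] = value


def _parse_overrides(overrides) -> dict[str, dict]:
    """Accept either a nested mapping or ``section.key=value`` strings."""
    if overrides is None:
        return {}
    if isinstance(overrides, dict):
        return {k: dict(v) for k, v in overrides.items()}
    nested: dict[str, dict] = {}
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} must look like section.key=value")
        dotted, raw = item.split("=", 1)
        if "." not in dotted:
            raise ValueError(f"override key {dotted!r} must look like section.key")
        section, key = dotted.split(".", 1)
        nested.setdefault(section, {})[key] = yaml.safe_load(raw)
    return nested


def load_config(
    path: str | Path | None = None,
    overrides=None,
    preset: str | None = None,
) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig`.

    Precedence (lowest to highest): package defaults, named ``preset``,
    the YAML file at ``path``, then ``overrides`` (a nested mapping or a
    list of ``section.key=value`` strings).
    """
    doc = {section: dict(keys) for section, keys in DEFAULTS.items()}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        _merge(doc, PRESETS[preset], f"preset {preset!r}")
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a mapping of sections")
        _merge(doc, raw, str(path))
    _merge(doc, _parse_overrides(overrides), "overrides")

    explicit: set[tuple[str, str]] = set()
    for source in (PRESETS.get(preset, {}) if preset else {}, _parse_overrides(overrides)):
        for sec, keys in source.items():
            explicit.update((sec, k) for k in keys)
    for section, keys in doc.items():
        for key, value in keys.items():
            if (section, key) not in explicit:
                logger.debug("config default applied: %s.%s = %r", section, key, value)

    dem_sec, lrn_sec = doc["demography"], doc["learning"]
    nic_sec, sim_sec = doc["niche"], doc["simulation"]

    demography = DemographyParams(
        b=float(dem_sec["b"]),
        s=tuple(float(dem_sec[f"s{i}"]) for i in range(1, N_CLASSES + 1)),
        w_f=float(dem_sec["w_f"]),
        w_s=float(dem_sec["w_s"]),
    )
    scenario = str(lrn_sec["scenario"])
    explicit_V = [lrn_sec[f"V{j}"] for j in (2, 3, 4)]
    if any(v is not None for v in explicit_V):
        if any(v is None for v in explicit_V):
            raise ValueError("either set all of V2, V3, V4 or none of them")
        V = tuple(float(v) for v in explicit_V)
        scenario = "custom"
    else:
        if scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
            )
        V = SCENARIOS[scenario].V
    learning = LearningParams(
        p_v=float(lrn_sec["p_v"]),
        p_h=float(lrn_sec["p_h"]),
        omega=int(lrn_sec["omega"]),
        V=V,
    )
    niche = NicheParams(
        enabled=bool(nic_sec["enabled"]),
        v_b=float(nic_sec["v_b"]),
        epsilon=float(nic_sec["epsilon"]),
    )
    return SimulationConfig(
        demography=demography,
        learning=learning,
        niche=niche,
        mode=str(dem_sec["mode"]),
        n_steps=int(sim_sec["n_steps"]),
        initial_total=float(sim_sec["initial_total"]),
        initial_age_structure=tuple(
            float(sim_sec[f"a{i}"]) for i in range(1, N_CLASSES + 1)
        ),
        initial_trait_freq=float(sim_sec["initial_trait_freq"]),
        scenario=scenario,
        collapse_threshold=float(sim_sec["collapse_threshold"]),
    )


def _scenario_matches(config: SimulationConfig) -> bool:
    scen = SCENARIOS.get(config.scenario)
    return scen is not None and scen.V == config.learning.V


def dump_config(config: SimulationConfig) -> dict[str, dict]:
    """Nested mapping of all effective values (round-trips through load_config)."""
    dem, lrn, nic = config.demography, config.learning, config.niche
    out = {
        "demography": {
            "b": dem.b,
            **{f"s{i + 1}": dem.s[i] for i in range(N_CLASSES)},
            "w_f": dem.w_f,
            "w_s": dem.w_s,
            "mode": config.mode,
        },
        "learning": {
            "p_v": lrn.p_v,
            "p_h": lrn.p_h,
            "omega": lrn.omega,
            "scenario": config.scenario,
            # explicit V entries only when they do not follow from the scenario
            "V2": None if _scenario_matches(config) else lrn.V[0],
            "V3": None if _scenario_matches(config) else lrn.V[1],
            "V4": None if _scenario_matches(config) else lrn.V[2],
        },
        "niche": {"enabled": nic.enabled, "v_b": nic.v_b, "epsilon": nic.epsilon},
        "simulation": {
            "n_steps": config.n_steps,
            "initial_total": config.initial_total,
            "initial_trait_freq": config.initial_trait_freq,
            **{
                f"a{i + 1}": config.initial_age_structure[i] for i in range(N_CLASSES)
            },
            "collapse_threshold": config.collapse_threshold,
        },
    }
    return out


def write_trajectory(traj: Trajectory | pd.DataFrame, path: str | Path) -> Path:
    """Write a trajectory as CSV (12 significant digits, lossless round-trip)."""
    frame = traj.frame if isinstance(traj, Trajectory) else traj
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    expected = (
        ["tau"]
        + [f"n{i}" for i in range(1, N_CLASSES + 1)]
        + [f"x{i}" for i in range(1, N_CLASSES + 1)]
        + ["n_total", "mean_freq"]
    )
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory file {path} missing columns {missing}")
    return frame


#: Stage-structure shapes for quick-start states; pyramid/skewed
#: proportions are package choices and fully configurable.
FIXTURE_STRUCTURES: dict[str, tuple[float, ...]] = {
    "uniform": (0.2, 0.2, 0.2, 0.2, 0.2),
    "pyramid": (0.35, 0.25, 0.2, 0.12, 0.08),
    "skewed": (0.8, 0.05, 0.05, 0.05, 0.05),
}


def generate_fixture(kind: str, total: float = 100.0, freq: float = 0.005) -> PopulationState:
    """A ready-made initial state: ``uniform``, ``pyramid`` or ``skewed``."""
    if kind not in FIXTURE_STRUCTURES:
        raise ValueError(
            f"unknown fixture kind {kind!r}; available: {sorted(FIXTURE_STRUCTURES)}"
        )
    if total <= 0:
        raise ValueError("total must be positive")
    a = np.array(FIXTURE_STRUCTURES[kind], dtype=float)
    return PopulationState.from_counts(a * total, np.full(N_CLASSES, float(freq)))
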