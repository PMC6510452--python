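"""Simulation orchestration: stepping, runs, sweeps, contrasts, rescue."""

import dataclasses

import numpy as np
import pytest

import agecult as ac
from agecult import experiments as ex
from conftest import make_state


def test_config_validation():
    with pytest.raises(ValueError):
        ac.SimulationConfig(mode="magic")
    with pytest.raises(ValueError):
        ac.SimulationConfig(initial_age_structure=(0.5, 0.5, 0.2, 0.0, 0.0))
    with pytest.raises(ValueError):
        ac.SimulationConfig(initial_trait_freq=1.5)
    with pytest.raises(ValueError):
        ac.SimulationConfig(
            mode="survival",
            demography=ac.DemographyParams(s=(0.5, 0.6, 0.6, 0.98, 0.2), w_s=0.05),
        )


def test_zero_step_run_is_initial_state(spread_config):
    traj = ac.run(spread_config.replace(n_steps=0))
    assert len(traj) == 1
    row = traj.frame.iloc[0]
    assert row["n_total"] == pytest.approx(100.0)
    assert row["mean_freq"] == pytest.approx(0.005)


def test_trajectory_length_includes_initial_state(spread_config):
    traj = ac.run(spread_config.replace(n_steps=200))
    assert len(traj) == 201


def test_neutral_trait_without_learning_is_inert(spread_config):
    cfg = spread_config.replace(
        mode="neutral",
        n_steps=40,
        learning=dataclasses.replace(spread_config.learning, p_v=0.0, p_h=0.0),
    )
    traj = ac.run(cfg)
    x_cols = [f"x{i}" for i in range(2, 6)]
    # newborns never learn (p_v=0) so class 1 drops to 0; cohorts carry their
    # frequencies unchanged up the age classes
    assert (traj.frame["x1"].iloc[1:] == 0.0).all()
    for t in range(1, 40):
        for j in range(2, 5):
            assert traj.frame[f"x{j}"].iloc[t] == pytest.approx(
                traj.frame[f"x{j-1}"].iloc[t - 1], abs=1e-15
            )
    # counts follow the trait-free projection: growth per 4-step cycle
    # equals the dominant eigenvalue to high precision once transients decay
    L = ac.build_projection_matrix(cfg.demography, ac.initial_state(cfg), "neutral")
    lam = ac.dominant_eigenvalue(L)
    n = traj.frame["n_total"].to_numpy()
    assert (n[40] / n[36]) ** 0.25 == pytest.approx(lam, abs=1e-9)


def test_scalar_step_matches_vectorized_run(spread_config):
    cfg = spread_config.replace(n_steps=60)
    state = ac.initial_state(cfg)
    for _ in range(60):
        state = ac.step(state, cfg)
    frame = ac.run(cfg).frame
    np.testing.assert_allclose(
        state.x, frame[[f"x{i}" for i in range(1, 6)]].iloc[-1], rtol=0, atol=1e-12
    )
    assert state.n_total == pytest.approx(frame["n_total"].iloc[-1], rel=1e-12)


def test_scalar_step_matches_vectorized_run_under_niche_and_survival(spread_config):
    for changes in (
        dict(niche=ac.NicheParams(True, 0.6, 1.0)),
        dict(mode="survival"),
    ):
        cfg = spread_config.replace(n_steps=40, **changes)
        state = ac.initial_state(cfg)
        for _ in range(40):
            state = ac.step(state, cfg)
        frame = ac.run(cfg).frame
        np.testing.assert_allclose(
            state.x, frame[[f"x{i}" for i in range(1, 6)]].iloc[-1], rtol=0, atol=1e-12
        )


def test_single_step_against_independent_scalar_recomputation(spread_config):
    """All five class updates re-derived with plain arithmetic in the test."""
    cfg = spread_config  # b=5, s=(0.5,.6,.6,.6,.2), w_f=1, V=(0.8,0.8,0.4)
    b, wf = 5.0, 1.0
    s = [0.5, 0.6, 0.6, 0.6, 0.2]
    pv = ph = 0.6
    V = [0.8, 0.8, 0.4]
    n = [20.0] * 5
    x0 = 0.005
    state = ac.step(ac.initial_state(cfg), cfg)

    fw = lambda x: (b + wf) * x / ((b + wf) * x + b * (1 - x))
    expected = [pv * fw(x0)]
    for j in (2, 3, 4):
        pool = sum(n[j - 1 :]) and sum(nz * x0 for nz in n[j - 1 :]) / sum(n[j - 1 :])
        gain = V[j - 2] * fw(x0) * pv + (1 - V[j - 2]) * ph * pool
        expected.append(x0 + (1 - x0) * gain)
    expected.append((x0 * s[3] * n[3] + x0 * s[4] * n[4]) / (s[3] * n[3] + s[4] * n[4]))
    np.testing.assert_allclose(state.x, expected, atol=1e-15)

    f4 = (b + wf) * x0 + b * (1 - x0)
    counts = [f4 * n[3], s[0] * n[0], s[1] * n[1], s[2] * n[2], s[3] * n[3] + s[4] * n[4]]
    np.testing.assert_allclose(state.n, counts, rtol=1e-12)


def test_trivial_absorbing_steps(spread_config):
    cfg = spread_config.replace(initial_trait_freq=0.0, n_steps=10)
    traj = ac.run(cfg)
    assert (traj.frame[[f"x{i}" for i in range(1, 6)]].to_numpy() == 0.0).all()
    cfg1 = spread_config.replace(
        initial_trait_freq=1.0,
        n_steps=10,
        learning=dataclasses.replace(spread_config.learning, p_v=1.0),
    )
    traj1 = ac.run(cfg1)
    assert (traj1.frame[[f"x{i}" for i in range(1, 6)]].to_numpy() == 1.0).all()
    # carrier fertility applies throughout
    n = traj1.frame["n_total"].to_numpy()
    L = ac.build_projection_matrix(
        cfg1.demography, ac.initial_state(cfg1), "fertility"
    )
    assert L[0, 3] == pytest.approx(6.0)


def test_mean_population_frequency():
    assert ac.mean_population_frequency(make_state([10] * 5, [0.3] * 5)) == pytest.approx(0.3)
    assert ac.mean_population_frequency(
        make_state([10] * 5, [0, 0, 0, 1.0, 1.0])
    ) == pytest.approx(0.4)
    state = make_state([50, 20, 15, 10, 5], [0.1, 0.2, 0.3, 0.8, 0.9])
    assert ac.mean_population_frequency(state) == pytest.approx(0.26)


def test_run_is_deterministic(spread_config):
    cfg = spread_config.replace(n_steps=300)
    f1 = ac.run(cfg).frame
    f2 = ac.run(cfg).frame
    assert (f1.values == f2.values).all()


def test_all_vertical_perfect_fidelity_saturates(spread_config):
    cfg = spread_config.replace(
        n_steps=400,
        scenario="all_vertical",
        learning=dataclasses.replace(
            spread_config.learning, V=(1.0, 1.0, 1.0), p_v=1.0
        ),
    )
    traj = ac.run(cfg)
    assert traj.cycle_mean_frequency > 0.95
    assert traj.cycle_mean_frequency > cfg.initial_trait_freq


def test_sweep_single_cell_matches_run(spread_config):
    cfg = spread_config.replace(n_steps=300)
    grid = ac.sweep_fidelity_grid(cfg, [cfg.learning.p_v], [cfg.learning.p_h])
    assert grid.values.shape == (1, 1)
    assert grid.values[0, 0] == pytest.approx(ac.run(cfg).cycle_mean_frequency, abs=1e-12)


def test_sweep_zero_vertical_fidelity_blocks_all_vertical_scenario(spread_config):
    cfg = spread_config.replace(
        n_steps=300,
        scenario="all_vertical",
        learning=dataclasses.replace(spread_config.learning, V=(1.0, 1.0, 1.0)),
    )
    grid = ac.sweep_fidelity_grid(cfg, [0.0], np.linspace(0, 1, 4))
    # no newborn learning and no effective class learning: the trait decays
    assert (grid.values <= cfg.initial_trait_freq + 1e-12).all()


def test_sweep_monotone_in_vertical_fidelity(spread_config):
    cfg = spread_config.replace(
        n_steps=600,
        scenario="all_vertical",
        learning=dataclasses.replace(spread_config.learning, V=(1.0, 1.0, 1.0)),
    )
    values = np.linspace(0, 1, 6)
    grid = ac.sweep_fidelity_grid(cfg, values, values).values
    assert (np.diff(grid, axis=0) >= -1e-9).all()


def test_compare_to_neutral_trivial_zeroes(contrast_config):
    cfg = contrast_config.replace(
        n_steps=200,
        demography=dataclasses.replace(contrast_config.demography, w_f=0.0, w_s=0.0),
    )
    assert ac.compare_to_neutral(cfg) == pytest.approx(0.0, abs=1e-14)
    cfg2 = contrast_config.replace(
        n_steps=200,
        learning=dataclasses.replace(contrast_config.learning, p_v=0.0, p_h=0.0),
    )
    # nothing spreads in either run beyond the initial cohorts
    assert ac.compare_to_neutral(cfg2) == pytest.approx(0.0, abs=1e-9)


def _class_advantage(base, mode, scenario):
    """Selected-minus-neutral unweighted class-mean frequency (final cycle)."""
    cfg = base.replace(
        mode=mode,
        scenario=scenario,
        learning=dataclasses.replace(base.learning, V=ac.SCENARIOS[scenario].V),
    )
    x_cols = [f"x{i}" for i in range(1, 6)]
    sel = ac.run(cfg).frame[x_cols].iloc[-4:].to_numpy().mean()
    neu = ac.run(ex._neutral_twin(cfg)).frame[x_cols].iloc[-4:].to_numpy().mean()
    return sel - neu


def test_fitness_mode_selects_learning_mode_at_matched_fidelities(contrast_config):
    """A fertility benefit rewards learning from parents; a survival benefit
    rewards sampling the population at large.

    Vertical learners draw role models from the fertility-weighted
    parental pool, so a fertility-enhancing trait gains more under the
    all-vertical schedule; a survival-enhancing trait accumulates in the
    (older, larger) source classes of the horizontal/oblique pool, so
    the ordering reverses.  Compared at matched fidelities
    p_v = p_h = 0.6 on per-class frequencies (free of the growth-rate
    dilution that size weighting puts on the newborn class).
    """
    fert_vert = _class_advantage(contrast_config, "fertility", "all_vertical")
    fert_horiz = _class_advantage(contrast_config, "fertility", "all_horizontal")
    surv_vert = _class_advantage(contrast_config, "survival", "all_vertical")
    surv_horiz = _class_advantage(contrast_config, "survival", "all_horizontal")
    assert fert_vert > 0 and fert_horiz > 0 and surv_vert > 0 and surv_horiz > 0
    assert fert_vert > fert_horiz
    assert surv_horiz > surv_vert


def test_rescue_decoupled_and_collapse_cases():
    # carrier-independent growth: baseline super-critical, both scenarios grow
    growing = ac.load_config(
        preset="rescue", overrides={"demography": {"b": 6.0, "w_f": 0.0}}
    )
    res = ex.rescue_experiment(growing)
    assert res["lambda_baseline"] > 1
    for summary in res["scenarios"].values():
        assert summary["final_size"] > growing.initial_total
    # no fitness effect and sub-critical demography: both collapse
    declining = ac.load_config(preset="rescue", overrides={"demography": {"w_f": 0.0}})
    res2 = ex.rescue_experiment(declining)
    assert res2["lambda_baseline"] < 1
    for summary in res2["scenarios"].values():
        assert summary["collapsed"]
        assert summary["final_size"] < 1.0
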