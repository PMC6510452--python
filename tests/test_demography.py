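"""Stage-structured projection: vital rates, Leslie matrix, growth limits."""

import numpy as np
import pytest

import agecult as ac
from conftest import make_state


@pytest.mark.parametrize(
    "b,w_f,x4,expected",
    [(5, 1, 0.0, 5.0), (5, 1, 1.0, 6.0), (5, 1, 0.5, 5.5)],
)
def test_effective_fertility_interpolates_between_variants(b, w_f, x4, expected):
    params = ac.DemographyParams(b=b, w_f=w_f)
    assert ac.effective_fertility(params, x4) == pytest.approx(expected)


@pytest.mark.parametrize(
    "s_i,w_s,x_i,expected",
    [(0.6, 0.05, 0.0, 0.6), (0.6, 0.05, 1.0, 0.65), (0.7, 0.05, 0.4, 0.72)],
)
def test_effective_survival_is_carrier_weighted_mean(s_i, w_s, x_i, expected):
    params = ac.DemographyParams(w_s=w_s)
    assert ac.effective_survival(params, s_i, x_i) == pytest.approx(expected)


def test_effective_fertility_rejects_out_of_range_frequency(demo_params):
    with pytest.raises(ValueError):
        ac.effective_fertility(demo_params, 1.5)


def test_effective_survival_rejects_invalid_result():
    params = ac.DemographyParams(w_s=0.5)
    with pytest.raises(ValueError):
        ac.effective_survival(params, 0.9, 1.0)


def test_projection_matrix_layout(demo_params):
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(demo_params, state, "fertility")
    expected = np.zeros((5, 5))
    expected[0, 3] = 5.0  # no carriers: baseline fertility
    expected[1, 0], expected[2, 1], expected[3, 2] = 0.5, 0.6, 0.6
    expected[4, 3], expected[4, 4] = 0.6, 0.2
    np.testing.assert_allclose(L, expected)


def test_projection_matrix_neutral_mode_ignores_frequencies(demo_params):
    low = make_state([20] * 5, [0.0] * 5)
    high = make_state([20] * 5, [1.0] * 5)
    np.testing.assert_array_equal(
        ac.build_projection_matrix(demo_params, low, "neutral"),
        ac.build_projection_matrix(demo_params, high, "neutral"),
    )


def test_projection_matrix_carrier_fertility():
    # small declining population parameterization: carriers reproduce at b + w_f
    params = ac.DemographyParams(b=3.0, s=(0.6, 0.6, 0.6, 0.6, 0.4), w_f=1.7)
    state = make_state([20] * 5, [1.0] * 5)
    L = ac.build_projection_matrix(params, state, "fertility")
    assert L[0, 3] == pytest.approx(4.7)


def test_advance_counts_componentwise(demo_params):
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(demo_params, state, "fertility")
    result = ac.advance_counts(L, np.full(5, 20.0))
    np.testing.assert_allclose(result, [100.0, 10.0, 12.0, 12.0, 16.0])


def test_advance_counts_zero_vector(demo_params):
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(demo_params, state, "neutral")
    np.testing.assert_array_equal(ac.advance_counts(L, np.zeros(5)), np.zeros(5))


def test_dominant_eigenvalue_identity():
    assert ac.dominant_eigenvalue(np.eye(5)) == pytest.approx(1.0)


def test_dominant_eigenvalue_without_reproduction_is_elder_survival():
    params = ac.DemographyParams(b=0.0, s=(0.5, 0.6, 0.6, 0.6, 0.2), w_f=0.0)
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(params, state, "neutral")
    # the only recurring loop is the post-reproductive self-loop
    assert ac.dominant_eigenvalue(L) == pytest.approx(0.2, abs=1e-12)


def _bisect_quartic_root(target, lo=0.0, hi=20.0, tol=1e-12):
    """Independent root of lambda^4 = target by bisection."""
    f = lambda lam: lam**4 - target
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def test_dominant_eigenvalue_matches_characteristic_root_by_bisection():
    # det(L - lam I) = (s5 - lam)(lam^4 - f4 s1 s2 s3): the dominant root is
    # max(s5, (f4 s1 s2 s3)^(1/4)); find the quartic root independently
    params = ac.DemographyParams(b=4.0, s=(0.6, 0.7, 0.7, 0.7, 0.4), w_f=0.0)
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(params, state, "neutral")
    root = _bisect_quartic_root(4.0 * 0.6 * 0.7 * 0.7)
    assert ac.dominant_eigenvalue(L) == pytest.approx(max(root, 0.4), abs=1e-9)


def test_growth_factor_converges_to_eigenvalue_power_iteration_oracle():
    """Asymptotic growth matches the spectral radius via independent power iteration.

    The stage block is cyclic (period 4: only adults reproduce), so power
    iteration and the per-cycle growth are taken over L^4.
    """
    params = ac.DemographyParams(b=5.0, s=(0.5, 0.6, 0.6, 0.6, 0.2), w_f=0.0)
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(params, state, "neutral")
    L4 = np.linalg.matrix_power(L, 4)
    v = np.full(5, 0.2)
    for _ in range(200):
        w = L4 @ v
        growth4 = w.sum() / v.sum()
        v = w / w.sum()
    assert growth4 ** 0.25 == pytest.approx(ac.dominant_eigenvalue(L), abs=1e-10)

    cfg = ac.load_config(overrides={"demography": {"w_f": 0.0, "w_s": 0.0}}).replace(
        mode="neutral", n_steps=504, initial_trait_freq=0.0
    )
    totals = ac.run(cfg).frame["n_total"].to_numpy()
    empirical = (totals[504] / totals[500]) ** 0.25
    assert empirical == pytest.approx(ac.dominant_eigenvalue(L), abs=1e-9)


def test_stable_stage_distribution_is_invariant_structure():
    params = ac.DemographyParams(b=4.0, s=(0.6, 0.7, 0.7, 0.7, 0.4), w_f=0.0)
    state = make_state([20] * 5, [0.0] * 5)
    L = ac.build_projection_matrix(params, state, "neutral")
    v = ac.stable_stage_distribution(L)
    lam = ac.dominant_eigenvalue(L)
    assert v.sum() == pytest.approx(1.0)
    assert np.all(v > 0)
    np.testing.assert_allclose(L @ v, lam * v, atol=1e-12)


def test_population_state_validation_and_history_padding():
    state = make_state([10, 10, 10, 10, 10], [0.1] * 5)
    assert len(state.adult_freq_history) == 4
    assert state.lagged_adult_frequency(3) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        make_state([10] * 5, [1.5] * 5)
    with pytest.raises(ValueError):
        ac.DemographyParams(s=(0.5, 0.6, 0.6, 0.6, 1.2))
    with pytest.raises(ValueError):
        ac.DemographyParams(b=2.0, w_f=-3.0)
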