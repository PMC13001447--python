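"""Closed-form divergence, model fitting and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epidrift as ed
from epidrift.model import NeutralAccumulationModel, NullDivergenceModel, _points_to_xy

import pandas as pd


# ---------------------------------------------------------------- closed form


@pytest.mark.parametrize("alpha,beta", [(1e-5, 8e-5), (1e-3, 2e-3), (0.1, 0.2), (0.4, 0.4)])
@pytest.mark.parametrize("t", range(7))
def test_transition_matrix_matches_bruteforce(alpha, beta, t):
    closed = ed.transition_matrix(alpha, beta, t)
    brute = ed.transition_matrix(alpha, beta, t, brute_force=True)
    assert np.abs(closed - brute).max() < 1e-12
    assert np.allclose(closed.sum(axis=1), 1.0)


def test_expected_divergence_enumeration_oracle():
    # exhaustive enumeration over ancestor state and both descendant states
    alpha, beta, p0, t = 0.1, 0.2, 0.3, 3
    P = ed.transition_matrix(alpha, beta, t, brute_force=True)
    total = 0.0
    for s, ps in ((0, 1 - p0), (1, p0)):
        for x in (0, 1):
            for y in (0, 1):
                if x != y:
                    total += ps * P[s, x] * P[s, y]
    assert abs(ed.expected_divergence(alpha, beta, p0, t, t) - total) < 1e-12


def test_expected_divergence_limits():
    assert ed.expected_divergence(0.1, 0.2, 0.5, 0, 0) == 0.0
    # equilibrium start, long times: 2 pi (1 - pi); alpha = beta -> 0.5
    d = ed.expected_divergence(0.3, 0.3, 0.5, 10_000, 10_000)
    assert abs(d - 0.5) < 1e-9
    pi = 0.2 / (0.2 + 0.3)
    d = ed.expected_divergence(0.2, 0.3, pi, 1e6, 1e6)
    assert abs(d - 2 * pi * (1 - pi)) < 1e-9


@given(
    alpha=st.floats(1e-6, 0.4),
    beta=st.floats(1e-6, 0.4),
    t1=st.integers(0, 50),
    t2=st.integers(0, 50),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_expected_divergence_monotone_and_bounded(alpha, beta, t1, t2):
    """At equilibrium start, divergence grows with total branch length and
    never exceeds the independence limit 2 pi (1 - pi)."""
    pi = alpha / (alpha + beta)
    d1 = ed.expected_divergence(alpha, beta, pi, t1, t2)
    d2 = ed.expected_divergence(alpha, beta, pi, t1 + 1, t2)
    cap = 2 * pi * (1 - pi)
    assert -1e-12 <= d1 <= cap + 1e-12
    assert d2 >= d1 - 1e-12


def test_rate_validation():
    with pytest.raises(ValueError):
        ed.expected_divergence(0.0, 0.0, 0.5, 1, 1)
    with pytest.raises(ValueError):
        ed.expected_divergence(0.6, 0.6, 0.5, 1, 1)
    with pytest.raises(ValueError):
        ed.expected_divergence(0.1, 0.1, 1.5, 1, 1)


# -------------------------------------------------- equilibrium / rate ratio


def test_equilibrium_fraction_values():
    pi, pct = ed.equilibrium_fraction(1.62e-5, 8.55e-5)
    assert pct == 16
    assert ed.equilibrium_fraction(1.54e-5, 8.19e-5)[1] == 16
    assert ed.equilibrium_fraction(2.17e-5, 7.18e-5)[1] == 23
    assert ed.equilibrium_fraction(0.3, 0.3)[0] == 0.5
    with pytest.raises(ValueError):
        ed.equilibrium_fraction(0.0, 0.0)


def test_rate_ratio_values():
    assert ed.rate_ratio(2.17e-5, 7.18e-5) == 3.31
    assert ed.rate_ratio(3.01e-5, 7.19e-5) == 2.39
    assert ed.rate_ratio(0.1, 0.1) == 1.00
    with pytest.raises(ValueError):
        ed.rate_ratio(0.0, 1e-5)


# -------------------------------------------------------------------- fitting


def _closed_form_points(alpha, beta, p0, d0=0.0):
    rows = []
    for ti, tj in [(0, 0), (125, 125), (500, 500), (1000, 1000), (125, 500), (1000, 125), (2000, 0)]:
        d = d0 + ed.expected_divergence(alpha, beta, p0, ti, tj)
        rows.append({"t_i": ti, "t_j": tj, "delta_t": ti + tj, "d": d})
    return pd.DataFrame(rows)


def test_fit_recovers_noiseless_closed_form():
    alpha, beta = 2e-5, 9e-5
    p0 = alpha / (alpha + beta)
    pts = _closed_form_points(alpha, beta, p0)
    rates = ed.fit_neutral(pts, p0=p0, random_state=0)
    assert abs(rates.alpha - alpha) / alpha < 1e-4
    assert abs(rates.beta - beta) / beta < 1e-4
    assert rates.d0 < 1e-8


def test_fit_constant_data_is_boundary_and_null_wins():
    rng = np.random.default_rng(0)
    pts = pd.DataFrame(
        {
            "t_i": np.repeat([0, 125, 500, 1000], 5),
            "t_j": np.repeat([0, 125, 500, 1000], 5),
            "d": 0.01 + rng.normal(0, 1e-4, 20),
        }
    )
    pts["delta_t"] = pts["t_i"] + pts["t_j"]
    with pytest.warns(RuntimeWarning):
        rates = ed.fit_neutral(pts, random_state=0)
    assert rates.boundary
    X, y = _points_to_xy(pts)
    null = NullDivergenceModel().fit(X, y)
    with pytest.warns(RuntimeWarning):
        neutral = NeutralAccumulationModel(random_state=0).fit(X, y)
    comp = ed.compare_models(null, neutral)
    assert comp.p_value > 0.05


def test_fit_requires_enough_points():
    pts = pd.DataFrame({"t_i": [0, 1], "t_j": [0, 1], "d": [0.0, 0.1]})
    with pytest.raises(ValueError):
        ed.fit_neutral(pts)


def test_logistic_beats_null_on_saturating_data_and_errors_small_n():
    t = np.array([0, 100, 200, 400, 800, 1600, 3200, 6400], dtype=float)
    d = 0.3 / (1 + np.exp(-0.01 * (t - 400)))
    pts = pd.DataFrame({"t_i": t / 2, "t_j": t / 2, "delta_t": t, "d": d})
    logi = ed.fit_logistic(pts, random_state=0)
    null = ed.fit_null(pts)
    assert logi.rss_ < null.rss_
    comp = ed.compare_models(null, logi)
    assert comp.p_value < 0.01
    with pytest.raises(ValueError):
        ed.fit_logistic(pts.iloc[:2])


def test_compare_models_identical_rss():
    X = np.column_stack([np.arange(10.0), np.arange(10.0)])
    y = np.full(10, 0.5)
    null = NullDivergenceModel().fit(X, y)
    alt = NullDivergenceModel().fit(X, y)
    alt.n_params_ = 3  # same RSS, more parameters
    comp = ed.compare_models(null, alt)
    assert comp.f_statistic == 0.0
    assert comp.p_value == 1.0


def test_compare_models_rejects_non_nested():
    X = np.column_stack([np.arange(10.0), np.arange(10.0)])
    y = np.linspace(0, 1, 10)
    a = NullDivergenceModel().fit(X, y)
    b = NullDivergenceModel().fit(X, y)
    with pytest.raises(ValueError):
        ed.compare_models(a, b)


# ------------------------------------------------------------------ bootstrap


def _line_points(alpha, beta, rng, noise=2e-4):
    p0 = alpha / (alpha + beta)
    rows = []
    for li in range(1, 7):
        for t in (125, 500, 1000):
            d = ed.expected_divergence(alpha, beta, p0, t, 0) + rng.normal(0, noise)
            rows.append(
                {"t_i": t, "t_j": 0, "delta_t": t, "d": d, "line_i": f"L{li}", "line_j": "ancestor"}
            )
    return pd.DataFrame(rows)


def test_bootstrap_degenerate_single_replicate():
    rng = np.random.default_rng(3)
    pts = _line_points(2e-5, 9e-5, rng, noise=0.0)
    rates = ed.bootstrap_rates(pts, n_boot=1, seed=0, n_starts=20, p0=2e-5 / 11e-5, random_state=0)
    # a single bootstrap refit gives a zero-width percentile interval
    lo, hi = rates.ci["alpha"]
    assert hi - lo < 1e-12


def test_bootstrap_interval_covers_truth_on_clean_data():
    rng = np.random.default_rng(4)
    pts = _line_points(2e-5, 9e-5, rng)
    rates = ed.bootstrap_rates(pts, n_boot=30, seed=1, n_starts=15, p0=2e-5 / 11e-5, random_state=0)
    lo, hi = rates.ci["alpha"]
    assert lo <= 2e-5 <= hi
    lo, hi = rates.ci["beta"]
    assert lo <= 9e-5 <= hi
    assert rates.ci["alpha"][0] <= rates.alpha <= rates.ci["alpha"][1]


def test_bootstrap_requires_lines():
    pts = _line_points(2e-5, 9e-5, np.random.default_rng(0)).iloc[:6]
    pts = pts[pts["line_i"].isin(["L1", "L2"])]
    with pytest.raises(ValueError):
        ed.bootstrap_rates(pts, n_boot=2, seed=0)
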