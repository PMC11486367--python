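"""Incremental analysis, tornado, parameter sampling, PSA, CEAC."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from ponv_cea import (
    ArmOutcome,
    CostComponents,
    ModelParameter,
    PSAResult,
    ceac,
    default_wtp_grid,
    incremental_analysis,
    make_model,
    net_monetary_benefit,
    one_way_sensitivity,
    psa_percentile_ci,
    run_psa,
    sample_parameter,
    tornado,
)


def _outcome(arm, societal_total, qaly):
    # a stand-in arm outcome with the whole cost in one payer component
    return ArmOutcome(arm, CostComponents(prophylaxis=societal_total), qaly)


# -- incremental analysis --------------------------------------------------

def test_incremental_reproduces_published_societal_row():
    ram = _outcome("ramosetron", 16.89, 0.0121)
    none = _outcome("no_antiemetic", 18.72, 0.0114)
    r = incremental_analysis(ram, none, "societal")
    assert r.delta_cost == pytest.approx(-1.83)
    assert r.delta_qaly == pytest.approx(0.0007)
    assert r.dominance == "intervention_dominant"
    assert r.icer == pytest.approx(-1.83 / 0.0007)


def test_incremental_edge_cases():
    a = _outcome("a", 10.0, 0.01)
    assert incremental_analysis(a, a, "payer").icer is None
    assert incremental_analysis(a, a, "payer").dominance == "none"
    r = incremental_analysis(_outcome("a", 20.0, 0.011), a, "payer")
    assert r.icer == pytest.approx(10.0 / 0.001)
    with pytest.raises(ValueError):
        incremental_analysis(a, a, "hospital")


def test_dominance_truth_table():
    base = _outcome("c", 10.0, 0.01)
    for dc, dq in itertools.product((-1.0, 0.0, 1.0), repeat=2):
        r = incremental_analysis(_outcome("i", 10.0 + dc, 0.01 + dq), base, "payer")
        if dc < 0 and dq > 0:
            assert r.dominance == "intervention_dominant"
        elif dc > 0 and dq < 0:
            assert r.dominance == "comparator_dominant"
        else:
            assert r.dominance == "none"
        assert (r.icer is None) == (dq == 0)


def test_net_monetary_benefit_arithmetic():
    assert net_monetary_benefit(0, 0, 123456.0) == 0.0
    assert net_monetary_benefit(-1.83, 0.0007, 5000.0) == pytest.approx(5.33)
    assert net_monetary_benefit(10.0, 0.001, 10000.0) == pytest.approx(0.0)


# -- one-way / tornado -----------------------------------------------------

def test_one_way_degenerate_and_error_cases(base_params, calibrated_model):
    pinned = dataclasses.replace(
        base_params,
        parameters={
            **base_params.parameters,
            "cost_ramosetron": ModelParameter(
                "cost_ramosetron", "cost", 13.94, low=13.94, high=13.94, dist_family="gamma"
            ),
        },
    )
    entry = one_way_sensitivity(pinned, "cost_ramosetron", calibrated_model, "payer")
    assert entry.bar_width == 0.0
    with pytest.raises(KeyError):
        one_way_sensitivity(base_params, "nope", calibrated_model, "payer")
    unbounded = dataclasses.replace(
        base_params,
        parameters={
            **base_params.parameters,
            "cost_ramosetron": ModelParameter("cost_ramosetron", "cost", 13.94),
        },
    )
    with pytest.raises(ValueError, match="bounds"):
        one_way_sensitivity(unbounded, "cost_ramosetron", calibrated_model, "payer")


def test_irrelevant_parameter_gives_zero_bar(base_params, calibrated_model):
    extra = dict(base_params.parameters)
    extra["cost_unused_drug"] = ModelParameter(
        "cost_unused_drug", "cost", 5.0, low=1.0, high=10.0, dist_family="gamma"
    )
    params = dataclasses.replace(base_params, parameters=extra)
    entry = one_way_sensitivity(params, "cost_unused_drug", calibrated_model, "payer")
    assert entry.bar_width == 0.0


def test_tornado_sorted_and_permutation_invariant(base_params, calibrated_model):
    names = ["cost_ramosetron", "cost_palonosetron", "horizon_days", "utility_no_ponv"]
    entries = tornado(base_params, calibrated_model, "payer", parameter_names=names)
    widths = [e.bar_width for e in entries]
    assert widths == sorted(widths, reverse=True)
    reordered = tornado(
        base_params, calibrated_model, "payer", parameter_names=names[::-1]
    )
    assert [e.parameter for e in entries] == [e.parameter for e in reordered]
    single = tornado(base_params, calibrated_model, "payer", parameter_names=names[:1])
    assert len(single) == 1


def test_tornado_rankings_against_published_ordering(base_params, calibrated_model):
    """Soft check: the ramosetron drug cost should dominate the payer tornado,
    and its one-way ICER range should span negative to positive values."""
    entries = tornado(base_params, calibrated_model, "payer")
    ranking = [e.parameter for e in entries]
    print("payer tornado ranking:", ranking[:6])
    assert ranking[0] == "cost_ramosetron"
    top = entries[0]
    assert top.icer_at_low < 0 < top.icer_at_high
    societal = [e.parameter for e in tornado(base_params, calibrated_model, "societal")]
    print("societal tornado ranking:", societal[:6])


# -- parameter sampling ----------------------------------------------------

def test_gamma_sampler_moment_match():
    p = ModelParameter("g", "cost", 4.0, se=2.0, dist_family="gamma")
    rng = np.random.default_rng(1)
    draws = np.array([sample_parameter(p, rng) for _ in range(100_000)])
    # shape 4, scale 1 by moment matching
    assert draws.mean() == pytest.approx(4.0, abs=0.05)
    assert draws.std() == pytest.approx(2.0, abs=3 * 2.0 / np.sqrt(2 * len(draws)) + 0.02)
    assert draws.min() >= 0


def test_beta_sampler_moment_match():
    p = ModelParameter("b", "probability", 0.5, se=0.1, dist_family="beta")
    rng = np.random.default_rng(2)
    draws = np.array([sample_parameter(p, rng) for _ in range(100_000)])
    assert draws.mean() == pytest.approx(0.5, abs=3 * 0.1 / np.sqrt(len(draws)) + 0.001)
    assert draws.var() == pytest.approx(0.01, abs=0.001)
    assert 0 <= draws.min() and draws.max() <= 1


def test_normal_sampler_and_support_redraw():
    p = ModelParameter("t", "time", 1.0, se=0.5, dist_family="normal")
    rng = np.random.default_rng(3)
    draws = np.array([sample_parameter(p, rng) for _ in range(50_000)])
    assert draws.min() > 0  # negative times redrawn
    assert draws.mean() == pytest.approx(1.0, abs=0.05)  # mild truncation bias only


def test_fixed_and_error_cases():
    fixed = ModelParameter("f", "cost", 7.0, dist_family="fixed")
    rng = np.random.default_rng(4)
    assert sample_parameter(fixed, rng) == 7.0
    no_se = ModelParameter("x", "cost", 7.0, dist_family="gamma")
    with pytest.raises(Exception):
        sample_parameter(no_se, rng)
    tight_beta = ModelParameter("b", "probability", 0.5, se=0.6, dist_family="beta")
    with pytest.raises(ValueError, match="too large"):
        sample_parameter(tight_beta, rng)


# -- PSA -------------------------------------------------------------------

def test_psa_reproducible_and_shaped(base_params, calibrated_model):
    a = run_psa(base_params, calibrated_model, n_iterations=50, seed=9)
    b = run_psa(base_params, calibrated_model, n_iterations=50, seed=9)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    assert a.n_iterations == 50
    assert len(a.perspective_draws("payer")) == 50
    with pytest.raises(TypeError):
        run_psa(base_params, calibrated_model, n_iterations=5, seed="abc")


def test_psa_all_fixed_equals_base_case(base_params, calibrated_model):
    frozen = dataclasses.replace(
        base_params,
        parameters={
            name: dataclasses.replace(p, dist_family="fixed")
            for name, p in base_params.parameters.items()
        },
    )
    psa = run_psa(frozen, calibrated_model, n_iterations=1, seed=0)
    outcome_i, outcome_c = calibrated_model(base_params)
    row = psa.perspective_draws("societal").iloc[0]
    assert row["delta_cost"] == pytest.approx(
        outcome_i.total_societal - outcome_c.total_societal, abs=1e-12
    )
    assert row["delta_qaly"] == pytest.approx(outcome_i.qaly - outcome_c.qaly, abs=1e-15)


def test_psa_mean_converges_to_base_case_cost(base_params, calibrated_model):
    # every cost component is multilinear in independent draws, so the PSA
    # mean of delta-cost estimates the base-case delta-cost
    psa = run_psa(base_params, calibrated_model, n_iterations=5000, seed=17)
    outcome_i, outcome_c = calibrated_model(base_params)
    for perspective in ("payer", "societal"):
        df = psa.perspective_draws(perspective)
        dc = df["delta_cost"].to_numpy()
        base = outcome_i.total(perspective) - outcome_c.total(perspective)
        mc_se = dc.std() / np.sqrt(len(dc))
        assert abs(dc.mean() - base) < 3 * mc_se


# -- CEAC and percentile intervals -----------------------------------------

def _synthetic_psa(dc, dq, perspective="payer"):
    n = len(dc)
    draws = pd.DataFrame(
        {
            "iteration": np.arange(n),
            "perspective": perspective,
            "delta_cost": dc,
            "delta_qaly": dq,
        }
    )
    return PSAResult(n_iterations=n, seed=0, draws=draws)


def test_ceac_limits_and_monotonicity():
    rng = np.random.default_rng(5)
    psa = _synthetic_psa(rng.normal(-1, 1, 500), rng.uniform(1e-4, 1e-3, 500))
    grid = default_wtp_grid()
    points = ceac(psa, grid, "payer")
    probs = [p.probability_cost_effective for p in points]
    assert all(0.0 <= p <= 1.0 for p in probs)
    assert np.all(np.diff(probs) >= 0)  # all dQ > 0 => monotone in wtp
    # all draws cheaper and more effective: certainty at wtp = 0
    sure = _synthetic_psa(np.full(100, -1.0), np.full(100, 1e-4))
    assert ceac(sure, [0.0], "payer")[0].probability_cost_effective == 1.0
    assert ceac(sure, [-1e9], "payer")[0].probability_cost_effective == 0.0
    with pytest.raises(ValueError):
        ceac(psa, [], "payer")


def test_percentile_ci_order_statistics_oracle():
    rng = np.random.default_rng(6)
    u = rng.uniform(size=100_000)
    psa = _synthetic_psa(u, np.full_like(u, 1e-4))
    ci = psa_percentile_ci(psa, perspective="payer")
    lo, hi = ci["delta_cost_ci"]
    assert lo == pytest.approx(0.025, abs=0.005)
    assert hi == pytest.approx(0.975, abs=0.005)
    # constant draws give a zero-width interval
    const = _synthetic_psa(np.full(100, 2.5), np.full(100, 1e-4))
    lo, hi = psa_percentile_ci(const, perspective="payer")["delta_cost_ci"]
    assert lo == hi == 2.5


def test_percentile_ci_refuses_small_samples():
    small = _synthetic_psa(np.ones(10), np.ones(10) * 1e-4)
    with pytest.raises(ValueError, match="too few"):
        psa_percentile_ci(small, perspective="payer")


def test_published_delta_qaly_interval_is_positive(base_params, calibrated_model):
    """Soft check: the 95% interval of the QALY gain stays positive."""
    psa = run_psa(base_params, calibrated_model, n_iterations=1000, seed=12)
    ci = psa_percentile_ci(psa, perspective="societal")
    print("delta-QALY 95% CI:", ci["delta_qaly_ci"])
    assert ci["delta_qaly_ci"][0] > 0
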