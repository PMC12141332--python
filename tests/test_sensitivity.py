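"""Distribution fitting, tornado analysis, PSA, CE plane, and CEAC."""

import math

import numpy as np
import pytest
from scipy import stats

from hearscreen.markov_econ import net_monetary_benefit
from hearscreen.pipeline import evaluate_strategies, icer_pair
from hearscreen.sensitivity import (
    PSASample,
    ce_plane_quadrants,
    ceac,
    fit_beta,
    fit_gamma,
    one_way,
    run_psa,
    tornado,
)


@pytest.fixture(scope="module")
def model(life_table):
    lt = life_table
    return lambda p: evaluate_strategies(p, lt=lt)


# --- distribution fits ------------------------------------------------------


def test_beta_symmetric_range_gives_equal_shapes():
    a, b = fit_beta(0.5, 0.3, 0.7)
    assert a == pytest.approx(b)


@pytest.mark.parametrize("mean, low, high", [(0.149, 0.1192, 0.1788), (0.8, 0.78, 0.82), (0.003, 0.0024, 0.0036)])
def test_beta_moments_recovered(mean, low, high):
    a, b = fit_beta(mean, low, high)
    assert a > 0 and b > 0
    assert a / (a + b) == pytest.approx(mean, abs=1e-9)
    sd_target = (high - low) / (2 * 1.96)
    sd_fit = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert sd_fit == pytest.approx(sd_target, rel=1e-9)


def test_beta_range_implied_sd_example():
    a, b = fit_beta(0.149, 0.1192, 0.1788)
    sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert sd == pytest.approx(0.0152, abs=2e-4)


def test_beta_variance_cap_keeps_shapes_positive():
    # implied sd far exceeds what a beta with this mean can carry
    a, b = fit_beta(0.1, 0.0, 5.0)
    assert a > 0 and b > 0
    assert a / (a + b) == pytest.approx(0.1, abs=1e-9)


def test_beta_domain_errors():
    with pytest.raises(ValueError):
        fit_beta(0.0, 0.1, 0.2)
    with pytest.raises(ValueError):
        fit_beta(1.0, 0.1, 0.2)
    with pytest.raises(ValueError):
        fit_beta(0.5, 0.7, 0.3)


def test_gamma_moments():
    shape, scale = fit_gamma(34.1, 18.9, 144)
    assert shape * scale == pytest.approx(34.1, abs=1e-9)
    assert shape == pytest.approx(1.142, abs=1e-3)
    sd = (144 - 18.9) / (2 * 1.96)
    assert math.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)
    with pytest.raises(ValueError):
        fit_gamma(-1.0, 0.0, 1.0)


# --- one-way / tornado ------------------------------------------------------


def test_degenerate_range_gives_zero_span(params, model):
    entry = one_way("u_normal", params, model, ("concurrent", "unhs_only"))
    assert entry.degenerate
    assert entry.span == 0.0
    assert entry.icer_low == entry.icer_high


def test_gene_screen_cost_monotonically_raises_concurrent_icer(params, model):
    """Cheaper gene screening makes concurrent screening more cost-effective."""
    entry = one_way("cost_genetic_screening", params, model, ("concurrent", "unhs_only"))
    base = icer_pair(model(params), "concurrent", "unhs_only")
    assert entry.icer_low < base < entry.icer_high


def test_linear_cost_parameter_midpoint_icer(params, model):
    """A cost entering totals linearly: midpoint ICER = mean of endpoint ICERs
    (the QALY increment does not depend on the cost)."""
    p = params["cost_genetic_screening"]
    mid = (p.low + p.high) / 2
    icer_at = lambda v: icer_pair(
        model(params.override("cost_genetic_screening", v)), "concurrent", "unhs_only"
    )
    assert icer_at(mid) == pytest.approx((icer_at(p.low) + icer_at(p.high)) / 2, abs=0.02)


def test_tornado_sorted_and_bracketing(params, model):
    entries = tornado(
        params,
        model,
        ("concurrent", "unhs_only"),
        top=None,
        parameter_names=[
            "cost_genetic_screening",
            "uptake_ci",
            "fail_unhs",
            "u_normal",
            "cost_ci_annual",
        ],
    )
    assert {e.parameter for e in entries} == {
        "cost_genetic_screening",
        "uptake_ci",
        "fail_unhs",
        "u_normal",
        "cost_ci_annual",
    }
    spans = [e.span for e in entries if not math.isnan(e.span)]
    assert spans == sorted(spans, reverse=True)
    # monotone cost parameters bracket the baseline ICER
    base = icer_pair(model(params), "concurrent", "unhs_only")
    for e in entries:
        if e.parameter.startswith("cost_"):
            assert min(e.icer_low, e.icer_high) <= base <= max(e.icer_low, e.icer_high)
    top2 = tornado(params, model, ("concurrent", "unhs_only"), top=2,
                   parameter_names=["cost_genetic_screening", "uptake_ci", "fail_unhs"])
    assert len(top2) == 2


def test_ci_uptake_policy_sweep(params, model):
    """CI uptake swept over its policy range returns two distinct ICERs."""
    entry = one_way("uptake_ci", params, model, ("concurrent", "unhs_only"))
    assert (entry.low, entry.high) == (0.2, 1.0)
    assert entry.icer_low != entry.icer_high


# --- PSA --------------------------------------------------------------------


def _stub_model(_p):
    return {}


def test_psa_same_seed_reproducible(params, model):
    a = run_psa(params, 6, seed=11, model=model)
    b = run_psa(params, 6, seed=11, model=model)
    assert all(x.outcomes == y.outcomes for x, y in zip(a.samples, b.samples))
    assert all(x.values == y.values for x, y in zip(a.samples, b.samples))


def test_psa_extending_draws_preserves_prefix(params):
    short = run_psa(params, 4, seed=3, model=_stub_model)
    long = run_psa(params, 8, seed=3, model=_stub_model)
    for name in short.raw_draws:
        assert np.array_equal(short.raw_draws[name], long.raw_draws[name][:4])


def test_psa_sampled_means_recover_baselines(params):
    """CLT check: each sampled parameter's mean is within 3 sd/sqrt(n)."""
    n = 2000
    res = run_psa(params, n, seed=5, model=_stub_model)
    for name, draws in res.raw_draws.items():
        p = params[name]
        if p.psa_dist == "fixed" or p.degenerate:
            assert np.all(draws == p.baseline)
            continue
        sd = draws.std(ddof=1)
        assert abs(draws.mean() - p.baseline) <= 3 * sd / math.sqrt(n), name


def test_psa_group_renormalization_and_domains(params):
    res = run_psa(params, 20, seed=9, model=_stub_model)
    for s in res.samples:
        for group in params.groups:
            assert math.isclose(sum(s.values[n] for n in group), 1.0, abs_tol=1e-9)
        for name, v in s.values.items():
            role = params[name].role
            if role in ("probability", "utility"):
                assert 0.0 <= v <= 1.0
            elif role == "cost":
                assert v >= 0.0


def test_psa_all_fixed_returns_baseline_every_draw(params, model):
    frozen = params.with_values(params.values())
    for p in list(frozen.parameters.values()):
        frozen.parameters[p.name] = type(p)(
            p.name, p.role, p.baseline, p.baseline, p.baseline, "fixed", p.units
        )
    baseline = model(params)
    res = run_psa(frozen, 3, seed=1, model=model)
    for s in res.samples:
        for name, (c, q) in s.outcomes.items():
            assert c == pytest.approx(baseline[name].cost, rel=1e-12)
            assert q == pytest.approx(baseline[name].qaly, rel=1e-12)


# --- CE plane and CEAC ------------------------------------------------------


def _sample(i, **outcomes):
    return PSASample(i, {}, outcomes)


def test_quadrants_all_first_quadrant():
    samples = [_sample(i, a=(10.0, 2.0), b=(5.0, 1.0)) for i in range(4)]
    quads = ce_plane_quadrants(samples, ("a", "b"))
    assert quads == {"q1": 1.0, "q2": 0.0, "q3": 0.0, "q4": 0.0}


def test_quadrants_hand_recount_with_boundaries():
    # (dE, dC) per draw, relative to reference (0, 0)
    deltas = [(1, 1), (1, -1), (-1, 1), (-1, -1), (0, 1), (1, 0), (0, 0), (2, 3), (-2, 3), (3, -2)]
    samples = [_sample(i, s=(dc, de), ref=(0.0, 0.0)) for i, (de, dc) in enumerate(deltas)]
    quads = ce_plane_quadrants(samples, ("s", "ref"))
    # boundary draws go to the positive side: (0,1)->q1, (1,0)->q1, (0,0)->q1
    expected = {"q1": 5 / 10, "q2": 2 / 10, "q3": 1 / 10, "q4": 2 / 10}
    assert quads == expected
    assert sum(quads.values()) == pytest.approx(1.0)


def test_ceac_single_draw_winner_takes_all():
    samples = [_sample(0, cheap=(100.0, 10.0), effective=(200.0, 11.0))]
    curve = ceac(samples, [0, 50, 99, 101, 1000])
    # ICER of effective vs cheap is 100: below -> cheap wins, above -> effective
    assert list(curve.prob("cheap")) == [1.0, 1.0, 1.0, 0.0, 0.0]
    assert list(curve.prob("effective")) == [0.0, 0.0, 0.0, 1.0, 1.0]


def test_ceac_exact_ties_split_equally():
    samples = [_sample(0, a=(100.0, 10.0), b=(100.0, 10.0))]
    curve = ceac(samples, [0, 500])
    assert np.allclose(curve.probabilities, 0.5)


def test_ceac_matches_brute_force_enumeration():
    rng = np.random.default_rng(42)
    names = ("s1", "s2", "s3")
    samples = []
    for i in range(20):
        outcomes = {n: (float(rng.uniform(50, 150)), float(rng.uniform(5, 15))) for n in names}
        samples.append(_sample(i, **outcomes))
    wtps = [0.0, 5.0, 10.0, 25.0, 100.0]
    curve = ceac(samples, wtps)
    for wi, w in enumerate(wtps):
        tally = dict.fromkeys(names, 0.0)
        for s in samples:
            nmbs = {n: net_monetary_benefit(*s.outcomes[n], w) for n in names}
            best = max(nmbs.values())
            winners = [n for n, v in nmbs.items() if v == best]
            for n in winners:
                tally[n] += 1 / len(winners)
        for ni, n in enumerate(names):
            assert curve.probabilities[wi, ni] == pytest.approx(tally[n] / 20)


def test_ceac_probabilities_sum_to_one():
    rng = np.random.default_rng(7)
    samples = [
        _sample(i, a=(float(rng.uniform(0, 10)), float(rng.uniform(0, 5))),
                b=(float(rng.uniform(0, 10)), float(rng.uniform(0, 5))))
        for i in range(15)
    ]
    curve = ceac(samples, [0, 1, 2, 3])
    assert np.allclose(curve.probabilities.sum(axis=1), 1.0)


def test_beta_gamma_sampling_distributions_match_scipy(params):
    """The PSA draws follow the fitted distributions (KS sanity check)."""
    res = run_psa(params, 400, seed=21, model=_stub_model)
    p = params["cost_genetic_screening"]
    shape, scale = fit_gamma(p.baseline, p.low, p.high)
    ks = stats.kstest(res.raw_draws[p.name], stats.gamma(shape, scale=scale).cdf)
    assert ks.pvalue > 0.001
    b = params["hl_given_fail"]
    a_, b_ = fit_beta(b.baseline, b.low, b.high)
    ks2 = stats.kstest(res.raw_draws[b.name], stats.beta(a_, b_).cdf)
    assert ks2.pvalue > 0.001
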