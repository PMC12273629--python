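"""ABC machinery tests: kernels, bookkeeping, Bayes factors, toy recovery.

Heavier parameter-recovery and model-selection checks on the full embryo
model live in test_acceptance.py; the toy models here exercise the inference
machinery itself against analytically transparent targets.
"""

import math

import numpy as np
import pandas as pd
import pytest

from blastabc import (
    ABCConfig,
    DiscreteUniform,
    Fixed,
    LogUniform,
    PosteriorSample,
    SyntheticSpec,
    Uniform,
    abc_mcmc,
    bayes_factor,
    calibrate_epsilon,
    generate_dataset,
    posterior_median_params,
    rejection_abc,
)
from blastabc.abc import (
    DEFAULT_BASE_PRIORS,
    InitialisationError,
    kass_raftery_label,
    make_base_model,
    sample_prior,
)

QUAD_PRIORS = {"x": Uniform(0.0, 1.0)}


def quad_model(theta):
    """Toy simulator: S is the squared distance of x from 0.3."""
    return (theta["x"] - 0.3) ** 2


# ---------------------------------------------------------------------------
# priors and kernels

def test_prior_samples_stay_in_support():
    rng = np.random.default_rng(0)
    priors = {
        "u": Uniform(0.2, 0.4),
        "g": LogUniform(1e-6, 1.0),
        "d": DiscreteUniform((0, 1, 2)),
        "f": Fixed(7.0),
    }
    for _ in range(200):
        theta = sample_prior(priors, rng)
        assert all(priors[k].in_support(v) for k, v in theta.items())
    assert theta["f"] == 7.0


def test_discrete_proposal_is_lazy_and_symmetric():
    rng = np.random.default_rng(1)
    prior = DiscreteUniform((0, 1, 2), move_prob=0.5)
    n = 4000
    from_0 = [prior.propose(0, 1.0, rng) for _ in range(n)]
    from_1 = [prior.propose(1, 1.0, rng) for _ in range(n)]
    assert set(from_0) == {0, 1}  # never jumps two steps
    assert set(from_1) == {0, 1, 2}
    # symmetry: q(1|0) == q(0|1) == move_prob / 2, within sampling error
    q10 = from_0.count(1) / n
    q01 = from_1.count(0) / n
    assert q10 == pytest.approx(0.25, abs=0.03)
    assert q01 == pytest.approx(0.25, abs=0.03)


def test_loguniform_spans_decades():
    rng = np.random.default_rng(2)
    draws = [LogUniform(1e-6, 1.0).sample(rng) for _ in range(2000)]
    # log-uniform: ~half the draws fall below the geometric midpoint 1e-3
    frac_below = np.mean(np.array(draws) < 1e-3)
    assert 0.4 < frac_below < 0.6


# ---------------------------------------------------------------------------
# ABC-MCMC

def test_huge_epsilon_accepts_every_in_support_proposal():
    cfg = ABCConfig(epsilon=1e12, n_iterations=400, seed=0,
                    proposal_scales={"x": 0.01})
    sample = abc_mcmc(quad_model, QUAD_PRIORS, cfg)
    # with a tiny step almost no proposal leaves [0, 1]
    assert sample.n_moves / cfg.n_iterations > 0.9
    assert len(sample.accepted) == cfg.n_iterations


def test_out_of_support_proposals_leave_chain_in_place():
    priors = {"x": Uniform(0.0, 1.0)}
    cfg = ABCConfig(epsilon=1e12, n_iterations=300, seed=3,
                    proposal_scales={"x": 50.0})  # nearly every step exits [0,1]
    sample = abc_mcmc(quad_model, priors, cfg)
    xs = sample.to_frame()["x"]
    assert xs.between(0, 1).all()
    assert sample.n_moves < cfg.n_iterations


def test_chain_concentrates_inside_epsilon_ball():
    cfg = ABCConfig(epsilon=0.0025, n_iterations=2000, seed=4, burn_in=100)
    sample = abc_mcmc(quad_model, QUAD_PRIORS, cfg)
    xs = sample.to_frame()["x"]
    assert ((xs - 0.3).abs() <= 0.05 + 1e-12).all()  # sqrt(0.0025)
    assert abs(float(xs.median()) - 0.3) < 0.02


def test_mcmc_seed_determinism():
    cfg = ABCConfig(epsilon=0.01, n_iterations=500, seed=5)
    a = abc_mcmc(quad_model, QUAD_PRIORS, cfg).to_frame()
    b = abc_mcmc(quad_model, QUAD_PRIORS, cfg).to_frame()
    pd.testing.assert_frame_equal(a, b)


def test_initialisation_failure_reports_min_s():
    cfg = ABCConfig(epsilon=1e-12, n_iterations=10, seed=6, init_budget=50)
    with pytest.raises(InitialisationError, match="minimum S seen"):
        abc_mcmc(quad_model, QUAD_PRIORS, cfg)


def test_burn_in_and_thinning_bookkeeping():
    cfg = ABCConfig(epsilon=1e12, n_iterations=100, seed=7, burn_in=20, thinning=4)
    sample = abc_mcmc(quad_model, QUAD_PRIORS, cfg)
    assert len(sample.accepted) == 20
    assert len(sample.chain_trace) == 100


def test_noiseless_recovery_of_alpha_and_rho(base_params):
    """ABC-MCMC on noiseless snapshots recovers alpha and rho within 15%."""
    data = generate_dataset(
        SyntheticSpec(base_params, n_embryos=30, noise="none", seed=11)
    )
    model = make_base_model(
        data,
        fixed=dict(
            beta=base_params.beta, zeta=base_params.zeta, l=base_params.l,
            eta=base_params.eta, m=base_params.m,
        ),
    )
    priors = {"alpha": Uniform(0.01, 0.15), "rho": Uniform(0.0, 1.0)}
    eps = calibrate_epsilon(model, priors, quantile=0.02, n_pilot=300, seed=1)
    cfg = ABCConfig(epsilon=eps, n_iterations=1500, seed=12, burn_in=150)
    med = posterior_median_params(abc_mcmc(model, priors, cfg))
    assert abs(med["alpha"] - base_params.alpha) / base_params.alpha < 0.15
    assert abs(med["rho"] - base_params.rho) / base_params.rho < 0.15


# ---------------------------------------------------------------------------
# rejection ABC

def test_infinite_epsilon_accepts_every_draw():
    sample = rejection_abc(quad_model, QUAD_PRIORS, epsilon=1e12,
                           target_acceptances=50, seed=0)
    assert sample.n_proposed == 50
    assert sample.acceptance_rate == 1.0


def test_rejection_abc_seed_reproducible():
    a = rejection_abc(quad_model, QUAD_PRIORS, 0.01, 40, seed=8)
    b = rejection_abc(quad_model, QUAD_PRIORS, 0.01, 40, seed=8)
    assert a.n_proposed == b.n_proposed
    pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


def test_acceptance_rate_monotone_in_epsilon():
    rates = []
    for eps in (0.001, 0.01, 0.1, 1.0):
        s = rejection_abc(quad_model, QUAD_PRIORS, eps, 30,
                          max_proposals=100_000, seed=9)
        rates.append(s.acceptance_rate)
    assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))


def test_better_fitting_model_accepts_more():
    """The model matching the data-generating centre wins at a common eps."""
    good = lambda th: (th["x"] - 0.3) ** 2   # data centred at 0.3
    bad = lambda th: (th["x"] - 0.3) ** 2 + 0.01  # systematic offset
    eps = 0.0125
    sa = rejection_abc(good, QUAD_PRIORS, eps, 100, max_proposals=50_000, seed=10)
    sb = rejection_abc(bad, QUAD_PRIORS, eps, 100, max_proposals=50_000, seed=10)
    assert sa.acceptance_rate > sb.acceptance_rate
    assert bayes_factor(sa, sb).bayes_factor > 1


def test_pre_feedback_model_accepted_more_often_than_null(base_params):
    """On data generated with PrE feedback, the feedback model's prior-
    predictive acceptance rate exceeds the no-feedback (l = 0) model's."""
    from blastabc import SyntheticSpec, generate_dataset
    from blastabc.abc import DiscreteUniform, Fixed

    data = generate_dataset(SyntheticSpec(base_params, n_embryos=60, seed=123))
    model = make_base_model(data)
    eps = calibrate_epsilon(model, DEFAULT_BASE_PRIORS, quantile=0.01,
                            n_pilot=600, seed=1)
    feedback = {**DEFAULT_BASE_PRIORS, "l": DiscreteUniform((1, 2))}
    null = {**DEFAULT_BASE_PRIORS, "l": Fixed(0)}
    sa = rejection_abc(model, feedback, eps, 60, max_proposals=60_000, seed=2)
    sb = rejection_abc(model, null, eps, 60, max_proposals=60_000, seed=3)
    assert sa.acceptance_rate > sb.acceptance_rate
    assert bayes_factor(sa, sb).bayes_factor > 1


def test_rejection_abc_budget_exhaustion_raises():
    with pytest.raises(InitialisationError, match="min S"):
        rejection_abc(quad_model, QUAD_PRIORS, 1e-15, 10, max_proposals=100, seed=11)


# ---------------------------------------------------------------------------
# Bayes factors

def fake_sample(n_acc, n_prop, eps=1.0):
    return PosteriorSample([{"x": 0.0}] * n_acc, n_prop, eps)


def test_printed_bookkeeping_reproduces_bf_17():
    """500/6289 vs 500/105027 at a common threshold gives BF ~ 16.7."""
    res = bayes_factor(fake_sample(500, 6289), fake_sample(500, 105_027))
    assert res.bayes_factor == pytest.approx(105_027 / 6289, rel=1e-12)
    assert round(res.bayes_factor) == 17
    assert res.label == "positive"


def test_printed_bookkeeping_reproduces_bf_45():
    """500/585 vs 500/26575 gives BF ~ 45, strong evidence."""
    res = bayes_factor(fake_sample(500, 585), fake_sample(500, 26_575))
    assert res.bayes_factor == pytest.approx(26_575 / 585, rel=1e-12)
    assert round(res.bayes_factor) == 45
    assert res.label == "strong"


def test_identical_bookkeeping_gives_bf_one():
    res = bayes_factor(fake_sample(100, 1000), fake_sample(100, 1000))
    assert res.bayes_factor == 1.0
    assert res.label == "barely worth mentioning"


def test_zero_denominator_acceptances_error():
    with pytest.raises(ZeroDivisionError):
        bayes_factor(fake_sample(10, 100), fake_sample(0, 100))


def test_mismatched_epsilon_rejected():
    with pytest.raises(ValueError, match="common epsilon"):
        bayes_factor(fake_sample(10, 100, eps=1.0), fake_sample(10, 100, eps=2.0))


@pytest.mark.parametrize(
    "bf,label",
    [
        (1.5, "barely worth mentioning"),
        (17, "positive"),
        (45, "strong"),
        (200, "very strong"),
        (1 / 45, "strong"),  # evidence grading is symmetric in direction
    ],
)
def test_kass_raftery_labels(bf, label):
    assert kass_raftery_label(bf) == label


# ---------------------------------------------------------------------------
# posterior summaries

def test_single_accepted_vector_is_its_own_median():
    s = PosteriorSample([{"alpha": 0.07, "l": 2}], 1, 1.0)
    assert posterior_median_params(s) == {"alpha": 0.07, "l": 2}


def test_median_of_three_alphas():
    s = PosteriorSample([{"alpha": a} for a in (0.05, 0.06, 0.07)], 3, 1.0)
    assert posterior_median_params(s)["alpha"] == pytest.approx(0.06)


def test_discrete_mode_tie_breaks_to_larger_exponent():
    s = PosteriorSample([{"m": 1}, {"m": 2}, {"m": 1}, {"m": 2}], 4, 1.0)
    assert posterior_median_params(s)["m"] == 2


def test_empty_posterior_errors():
    with pytest.raises(ValueError):
        posterior_median_params(PosteriorSample([], 10, 1.0))


def test_calibrated_epsilon_hits_target_acceptance():
    eps = calibrate_epsilon(quad_model, QUAD_PRIORS, quantile=0.1,
                            n_pilot=2000, seed=13)
    # S = (x-0.3)^2 <= eps iff |x-0.3| <= sqrt(eps); prior mass ~ 2 sqrt(eps)
    assert 2 * math.sqrt(eps) == pytest.approx(0.1, abs=0.02)
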