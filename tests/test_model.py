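"""Deterministic compartment-model tests: RHS algebra, solver, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastabc import (
    BaseParams,
    ChimeraParams,
    EmbryoState,
    asymptotic_te_fraction,
    base_rhs,
    chimera_rhs,
    injected_morula,
    make_variant,
    solve,
)
from blastabc.model import (
    MORULA,
    SPECIES,
    ModelDomainError,
    SolverError,
    _rhs_array,
    rho_effective,
)

# ---------------------------------------------------------------------------
# right-hand sides

param_strategy = st.builds(
    BaseParams,
    alpha=st.floats(0.0, 0.2),
    beta=st.floats(0.0, 1.0),
    rho=st.floats(0.0, 1.0),
    zeta=st.floats(0.0, 0.01),
    l=st.sampled_from([0, 1, 2]),
    eta=st.floats(0.0, 0.01),
    m=st.sampled_from([0, 1, 2]),
)

state_strategy = st.builds(
    EmbryoState,
    t=st.just(0.0),
    B=st.floats(0.0, 50.0),
    T=st.floats(0.0, 200.0),
    C=st.floats(0.0, 50.0),
    P=st.floats(0.0, 50.0),
    E=st.floats(0.0, 50.0),
)


def test_rhs_all_rates_zero_is_absorbing():
    p = BaseParams(alpha=0, beta=0, rho=0.5, zeta=0, l=0, eta=0, m=0)
    dy = base_rhs(MORULA, p)
    assert all(v == 0 for v in dy.values())


def test_rhs_pure_growth():
    p = BaseParams(alpha=0.1, beta=0, rho=0.5, zeta=0, l=0, eta=0, m=0)
    dy = base_rhs(MORULA, p)
    assert dy["B"] == pytest.approx(0.8)
    assert all(dy[k] == 0 for k in ("T", "C", "P", "E"))


@settings(max_examples=100, deadline=None)
@given(state=state_strategy, params=param_strategy)
def test_total_flux_is_alpha_times_total(state, params):
    """Transition terms cancel pairwise: d(total)/dt = alpha * total."""
    dy = base_rhs(state, params)
    assert sum(dy.values()) == pytest.approx(params.alpha * state.host_total, rel=1e-9, abs=1e-9)


def test_base_rhs_rejects_donor_cells(base_params):
    with pytest.raises(ModelDomainError):
        base_rhs(EmbryoState(B=8, D_plus=1), base_params)


def test_chimera_reduces_to_base_without_donors(base_params):
    cp = ChimeraParams(base=base_params, alpha_D=0.02, a=0.5, n=1, variant="GFC")
    state = EmbryoState(B=4, T=10, C=5, P=3, E=2)
    assert {k: v for k, v in chimera_rhs(state, cp).items() if k in SPECIES[:5]} == pytest.approx(
        base_rhs(state, base_params)
    )


def test_crowding_off_donors_invisible(base_params):
    """a=0, Fgf4-/- donors at the host growth rate leave the host RHS unchanged."""
    cp = ChimeraParams(base=base_params, alpha_D=base_params.alpha, a=0.0, variant="GF")
    state = EmbryoState(B=4, T=10, C=5, P=3, E=2, D_minus=10)
    host = EmbryoState(B=4, T=10, C=5, P=3, E=2)
    dy = chimera_rhs(state, cp)
    expected = base_rhs(host, base_params)
    for k in SPECIES[:5]:
        assert dy[k] == pytest.approx(expected[k])
    assert dy["D_minus"] == pytest.approx(10 * base_params.alpha)


def test_fgf4_plus_donors_boost_pre_induction(base_params):
    cp = ChimeraParams(base=base_params, alpha_D=0.02, a=0.0, variant="GF")
    with_dp = chimera_rhs(EmbryoState(B=0, C=5, E=2, D_plus=10), cp)
    without = chimera_rhs(EmbryoState(B=0, C=5, E=2, D_minus=10), cp)
    assert with_dp["P"] > without["P"]


def test_rho_effective_decreases_in_donor_number():
    donors = np.arange(0, 30)
    vals = [rho_effective(0.35, 0.1, 1, d) for d in donors]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    # n=0 makes crowding donor-independent
    const = {rho_effective(0.35, 0.1, 0, d) for d in donors[1:]}
    assert len(const) == 1


def test_chimera_rejects_mixed_donor_genotypes(chimera_params):
    with pytest.raises(ModelDomainError):
        chimera_rhs(EmbryoState(B=8, D_plus=5, D_minus=5), chimera_params)


@pytest.mark.parametrize(
    "variant,kwargs",
    [
        ("F", dict(alpha_D=0.02, a=0.0)),
        ("GF", dict(alpha_D=0.02, a=1.0)),
        ("FC", dict(alpha_D=0.02, a=1.0)),
    ],
)
def test_variant_constraints_enforced(base_params, variant, kwargs):
    with pytest.raises(ModelDomainError):
        ChimeraParams(base=base_params, variant=variant, **kwargs)


def test_make_variant_pins_constrained_parameters(base_params):
    f = make_variant(base_params, "F")
    assert f.alpha_D == base_params.alpha and f.a == 0.0
    fc = make_variant(base_params, "FC", a=0.3)
    assert fc.alpha_D == base_params.alpha and fc.a == 0.3


# ---------------------------------------------------------------------------
# solver

def test_four_doublings_from_morula(growth_only_params):
    traj = solve(growth_only_params, t_max=48.0)
    assert traj.final_state.total == pytest.approx(128.0, rel=1e-6)


def test_t_max_zero_returns_initial_state(base_params):
    traj = solve(base_params, t_max=0.0)
    assert traj.t.shape == (1,)
    assert traj.final_state.to_array() == pytest.approx(MORULA.to_array())


def test_total_growth_closed_form(chimera_params):
    """With alpha_D = alpha the grand total is (8 + D0) * exp(alpha t)."""
    cp = make_variant(chimera_params.base, "FC", a=0.05)
    traj = solve(cp, initial=injected_morula("minus", 10), t_max=48.0)
    expected = 18.0 * np.exp(cp.base.alpha * traj.t)
    np.testing.assert_allclose(traj.totals(), expected, rtol=1e-6)


def test_solution_stays_nonnegative(base_params):
    traj = solve(base_params, t_max=48.0)
    assert traj.y.min() >= 0.0


def test_rk4_oracle_equivalence(base_params):
    """Adaptive solver agrees with a fixed-step RK4 oracle at h = 1e-3 h."""
    h = 1e-3
    n = int(48.0 / h)
    y = MORULA.to_array()
    f = lambda yy: _rhs_array(yy, base_params)
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    final = solve(base_params, t_max=48.0).final_state.to_array()
    mask = y > 1e-12
    assert np.max(np.abs(final[mask] - y[mask]) / y[mask]) < 1e-5


def test_chimera_zero_donors_matches_base_trajectory(base_params, chimera_params):
    base_traj = solve(base_params, t_max=48.0)
    chi_traj = solve(chimera_params, initial=MORULA, t_max=48.0)
    np.testing.assert_allclose(chi_traj.y[:, :5], base_traj.y[:, :5], rtol=1e-6, atol=1e-8)


def test_crowding_monotonicity_in_donor_number(chimera_params):
    """More donors => more host TE and fewer host ICM derivatives at 48 h."""
    te, icm = [], []
    for n_donor in (0, 5, 10, 15, 20):
        f = solve(chimera_params, initial=injected_morula("minus", n_donor)).final_state
        te.append(f.T)
        icm.append(f.C + f.P + f.E)
    assert all(a <= b + 1e-9 for a, b in zip(te, te[1:]))
    assert all(a >= b - 1e-9 for a, b in zip(icm, icm[1:]))


def test_solver_rejects_mixed_donor_initial(chimera_params):
    with pytest.raises(ModelDomainError):
        solve(chimera_params, initial=EmbryoState(B=8, D_plus=5, D_minus=5))


# ---------------------------------------------------------------------------
# asymptotic TE fraction

def test_te_fraction_is_one_minus_rho():
    p = BaseParams(alpha=0.06, beta=0.25, rho=0.35, zeta=0, l=0, eta=0, m=0)
    assert asymptotic_te_fraction(p) == pytest.approx(0.65, abs=1e-4)


def test_te_fraction_rho_one_all_internalise():
    p = BaseParams(alpha=0.06, beta=0.25, rho=1.0, zeta=0, l=0, eta=0, m=0)
    assert asymptotic_te_fraction(p) == pytest.approx(0.0, abs=1e-6)


def test_te_fraction_symmetric_split():
    p = BaseParams(alpha=0.03, beta=10.0, rho=0.5, zeta=0, l=0, eta=0, m=0)
    assert asymptotic_te_fraction(p) == pytest.approx(0.5, abs=1e-4)


def test_te_fraction_errors_when_blastomeres_remain():
    p = BaseParams(alpha=0.06, beta=0.01, rho=0.35, zeta=0, l=0, eta=0, m=0)
    with pytest.raises(SolverError, match="t_max"):
        asymptotic_te_fraction(p)


# ---------------------------------------------------------------------------
# parameter validation

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(alpha=-0.1, beta=0.2, rho=0.5, zeta=0, l=0, eta=0, m=0),
        dict(alpha=0.1, beta=0.2, rho=1.5, zeta=0, l=0, eta=0, m=0),
        dict(alpha=0.1, beta=0.2, rho=0.5, zeta=0, l=3, eta=0, m=0),
    ],
)
def test_invalid_base_params_rejected(kwargs):
    with pytest.raises(ModelDomainError):
        BaseParams(**kwargs)


def test_negative_compartment_rejected():
    with pytest.raises(ModelDomainError):
        EmbryoState(B=-1.0)
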