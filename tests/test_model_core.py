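"""Local kinetics: rate shapes, threshold dynamics, reaction step."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gogrow import (ModelParameters, TissueState, hypoxic_state,
                    mitotic_coefficient, necrotic_rate, reaction_step,
                    switch_rate_IP, switch_rate_PI, total_density,
                    update_thresholds)
from gogrow.model_core import ConfigError


def _state_from(P, I, B, N, tau_h=0.7, tau_l=0.85):
    shape = np.shape(P)
    return TissueState(P=np.asarray(P, float), I=np.asarray(I, float),
                       B=np.asarray(B, float), N=np.asarray(N, float),
                       tau_h=np.full(shape, tau_h), tau_l=np.full(shape, tau_l))


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(tau_h0=0.9, tau_l0=0.85),          # hypoxic above lethal
    dict(tau_l0=0.99, tau_l_cap=0.98),      # cap below initial
    dict(C_ref=0.0),
    dict(dt=-0.1),
    dict(B0=0.8),                           # healthy tissue hypoxic at start
    dict(M_max=-1.0),
    dict(ramp_form="nope"),
    dict(mitotic_form="nope"),
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ConfigError):
        ModelParameters(**bad)


def test_threshold_invariant_holds_by_construction(params):
    assert 0 < params.tau_h0 < params.tau_l0 <= params.tau_l_cap <= 1
    assert params.tau_h_cap < params.tau_l_cap
    assert params.B0 / params.C_ref < params.tau_h0


# ---------------------------------------------------------------------------
# total density and hypoxic state
# ---------------------------------------------------------------------------

def test_total_density_is_pointwise_sum():
    st_ = _state_from([[0.1]], [[0.2]], [[0.5]], [[0.0]])
    assert total_density(st_)[0, 0] == pytest.approx(0.8)


def test_total_density_zero_state():
    z = np.zeros((4, 4))
    assert np.all(total_density(_state_from(z, z, z, z)) == 0.0)


def test_total_density_matches_naive_loop(rng):
    fields = [rng.random((6, 5)) for _ in range(4)]
    st_ = _state_from(*fields)
    C = total_density(st_)
    for i in range(6):
        for j in range(5):
            expected = sum(f[i, j] for f in fields)
            assert C[i, j] == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("C,expected", [(0.0, 0.0), (1.0, 1.0), (2.0, 1.0),
                                        (0.5, 0.5)])
def test_hypoxic_state_linear_clamp(C, expected, params):
    assert hypoxic_state(np.array(C), params) == pytest.approx(expected)


def test_hypoxic_state_monotone_in_C(params):
    C = np.linspace(0, 2, 101)
    H = hypoxic_state(C, params)
    assert np.all(np.diff(H) >= 0)
    assert np.all((H >= 0) & (H <= 1))


def test_hypoxic_state_rejects_bad_C_ref(params):
    p = object.__new__(ModelParameters)
    p.__dict__.update(params.to_dict())
    p.C_ref = 0.0
    with pytest.raises(ConfigError):
        hypoxic_state(np.array(0.5), p)


# ---------------------------------------------------------------------------
# mitotic coefficient
# ---------------------------------------------------------------------------

def test_mitosis_maximal_in_normoxia(params):
    H = np.array(0.0)
    M = mitotic_coefficient(H, np.array(0.5), np.array(0.9), params)
    assert M == pytest.approx(params.M_max)


def test_mitosis_zero_above_lethal_threshold(params):
    M = mitotic_coefficient(np.array(0.95), np.array(0.5), np.array(0.9),
                            params)
    assert M == 0.0


def test_mitosis_linear_ramp_midpoint():
    p = ModelParameters(M_max=1.0, mitotic_form="linear")
    M = mitotic_coefficient(np.array(0.7), np.array(0.5), np.array(0.9), p)
    assert M == pytest.approx(0.5)


def test_mitosis_linear_form_continuous_at_both_thresholds():
    p = ModelParameters(mitotic_form="linear")
    th, tl, eps = np.array(0.6), np.array(0.9), 1e-9
    for x in (th, tl):
        lo = mitotic_coefficient(x - eps, th, tl, p)
        hi = mitotic_coefficient(x + eps, th, tl, p)
        assert abs(lo - hi) < 1e-6 * p.M_max


def test_mitosis_inverse_form_reciprocal_decay(params):
    # M = M_max * tau_h / H between the thresholds; positive at tau_l itself
    th, tl = np.array(0.7), np.array(0.85)
    M = mitotic_coefficient(np.array(0.8), th, tl, params)
    assert M == pytest.approx(params.M_max * 0.7 / 0.8)
    assert mitotic_coefficient(tl, th, tl, params) > 0


def test_mitosis_rejects_inverted_thresholds(params):
    with pytest.raises(ValueError):
        mitotic_coefficient(np.array(0.5), np.array(0.9), np.array(0.8),
                            params)


# ---------------------------------------------------------------------------
# necrotic rate
# ---------------------------------------------------------------------------

def test_no_death_below_lethal_threshold(params):
    H = np.linspace(0, 0.849, 50)
    assert np.all(necrotic_rate(H, np.array(0.85), params) == 0.0)


def test_death_maximal_at_full_anoxia(params):
    assert necrotic_rate(np.array(1.0), np.array(0.85), params) \
        == pytest.approx(params.mu_max)


def test_necrotic_linear_ramp_midpoint():
    p = ModelParameters(mu_max=0.2, necrotic_form="linear")
    mu = necrotic_rate(np.array(0.9), np.array(0.8), p)
    assert mu == pytest.approx(0.1)


def test_necrotic_step_form_rapid_death(params):
    mu = necrotic_rate(np.array(0.851), np.array(0.85), params)
    assert mu == pytest.approx(params.mu_max)


# ---------------------------------------------------------------------------
# phenotype switch rates
# ---------------------------------------------------------------------------

def test_switch_PI_silent_in_normoxia_and_maximal_at_anoxia(params):
    th = np.array(0.7)
    assert switch_rate_PI(np.array(0.0), th, params) == 0.0
    assert switch_rate_PI(np.array(1.0), th, params) \
        == pytest.approx(params.beta_PI)


def test_switch_PI_ramp_midpoint():
    p = ModelParameters(beta_PI=0.4)
    assert switch_rate_PI(np.array(0.8), np.array(0.6), p) \
        == pytest.approx(0.2)


def test_switch_IP_full_in_normoxia_and_zero_past_lethal(params):
    th, tl = np.array(0.5), np.array(0.9)
    assert switch_rate_IP(np.array(0.0), th, tl, params) \
        == pytest.approx(params.beta_IP)
    assert switch_rate_IP(np.array(0.95), th, tl, params) == 0.0


def test_switch_IP_ramp_midpoint():
    p = ModelParameters(beta_IP=0.3)
    r = switch_rate_IP(np.array(0.7), np.array(0.5), np.array(0.9), p)
    assert r == pytest.approx(0.15)


@given(H=st.floats(0.0, 1.0))
def test_switch_rates_bounded_and_opposed(H, ):
    p = ModelParameters()
    th = np.array(p.tau_h0)
    tl = np.array(p.tau_l0)
    pi = float(switch_rate_PI(np.array(H), th, p))
    ip = float(switch_rate_IP(np.array(H), th, tl, p))
    assert 0.0 <= pi <= p.beta_PI
    assert 0.0 <= ip <= p.beta_IP
    if H <= p.tau_h0:
        assert pi == 0.0 and ip == pytest.approx(p.beta_IP)


def test_continuous_rates_have_no_jump_at_thresholds(params):
    # H(C), switch rates, and the linear forms of M and mu are continuous
    eps = 1e-9
    th, tl = np.array(0.7), np.array(0.85)
    p_lin = ModelParameters(mitotic_form="linear", necrotic_form="linear")
    for f in (lambda H: switch_rate_PI(H, th, params),
              lambda H: switch_rate_IP(H, th, tl, params),
              lambda H: mitotic_coefficient(H, th, tl, p_lin),
              lambda H: necrotic_rate(H, tl, p_lin)):
        for x0 in (0.7, 0.85):
            lo = float(f(np.array(x0 - eps)))
            hi = float(f(np.array(x0 + eps)))
            assert abs(hi - lo) < 1e-6


# ---------------------------------------------------------------------------
# threshold dynamics
# ---------------------------------------------------------------------------

def test_thresholds_unchanged_without_tumor(params):
    z = np.zeros((3, 3))
    st_ = _state_from(z, z, z + 0.5, z, params.tau_h0, params.tau_l0)
    update_thresholds(st_, params, aa_active=False, dt=0.1)
    assert np.all(st_.tau_h == params.tau_h0)
    assert np.all(st_.tau_l == params.tau_l0)


def test_instant_reset_under_aa(params):
    st_ = _state_from(np.full((2, 2), 0.3), np.zeros((2, 2)),
                      np.zeros((2, 2)), np.zeros((2, 2)), 0.88, 0.95)
    update_thresholds(st_, params, aa_active=True, dt=0.1)
    assert np.all(st_.tau_h == params.tau_h0)
    assert np.all(st_.tau_l == params.tau_l0)


def test_single_euler_step_of_threshold_rise():
    p = ModelParameters(alpha=1.0, tau_h_cap=0.9)
    st_ = _state_from(np.full((1, 1), 0.5), np.zeros((1, 1)),
                      np.zeros((1, 1)), np.zeros((1, 1)), 0.7, 0.85)
    update_thresholds(st_, p, aa_active=False, dt=0.1)
    # d(tau_h) = alpha * P * (cap - tau_h) * dt = 1 * 0.5 * 0.2 * 0.1
    assert st_.tau_h[0, 0] == pytest.approx(0.71)


def test_gradual_relaxation_under_aa():
    p = ModelParameters(relax_rate=1.0)
    st_ = _state_from(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                      np.zeros((1, 1)), 0.9, 0.96)
    update_thresholds(st_, p, aa_active=True, dt=0.1)
    assert st_.tau_h[0, 0] == pytest.approx(0.9 + 0.1 * (p.tau_h0 - 0.9))
    assert st_.tau_h[0, 0] > p.tau_h0


def test_threshold_ordering_preserved_through_updates(params, rng):
    P = rng.random((8, 8)) * 0.5
    st_ = _state_from(P, np.zeros_like(P), np.full_like(P, 0.5),
                      np.zeros_like(P), params.tau_h0, params.tau_l0)
    for k in range(200):
        update_thresholds(st_, params, aa_active=(k % 7 == 0), dt=0.1)
        assert np.all(st_.tau_h < st_.tau_l)
        assert np.all(st_.tau_h <= params.tau_h_cap + 1e-12)
        assert np.all(st_.tau_l <= params.tau_l_cap + 1e-12)


# ---------------------------------------------------------------------------
# reaction step
# ---------------------------------------------------------------------------

def test_reaction_conserves_mass_without_mitosis(rng):
    p = ModelParameters(M_max=0.0)
    P, I = rng.random((5, 5)) * 0.3, rng.random((5, 5)) * 0.3
    B, N = rng.random((5, 5)) * 0.4, rng.random((5, 5)) * 0.2
    st_ = _state_from(P, I, B, N)
    before = total_density(st_).sum()
    for _ in range(50):
        reaction_step(st_, p, dt=0.1)
    assert total_density(st_).sum() == pytest.approx(before, rel=1e-13)


def test_single_cell_pure_mitosis_euler_step():
    p = ModelParameters(M_max=1.0, beta_PI=0.0, beta_IP=0.0, mu_max=0.0)
    st_ = _state_from([[0.1]], [[0.0]], [[0.0]], [[0.0]])
    reaction_step(st_, p, dt=0.1)
    assert st_.P[0, 0] == pytest.approx(0.11)


def test_reaction_matches_scalar_euler_oracle(rng):
    """A randomized single cell follows an independently coded scalar
    explicit-Euler update to machine precision."""
    p = ModelParameters()
    P0, I0 = rng.random() * 0.3, rng.random() * 0.3
    B0, N0 = 0.5, rng.random() * 0.2
    st_ = _state_from([[P0]], [[I0]], [[B0]], [[N0]])
    dt = p.dt
    # scalar oracle, written directly from the kinetic definitions
    C = P0 + I0 + B0 + N0
    H = min(max(C / p.C_ref, 0.0), 1.0)
    if H <= p.tau_h0:
        M = p.M_max
    elif H <= p.tau_l0:
        M = p.M_max * p.tau_h0 / H
    else:
        M = 0.0
    mu = p.mu_max if H > p.tau_l0 else 0.0
    b_pi = p.beta_PI * min(max((H - p.tau_h0) / (1 - p.tau_h0), 0.0), 1.0)
    b_ip = p.beta_IP * (1 - min(max((H - p.tau_h0) / (p.tau_l0 - p.tau_h0),
                                    0.0), 1.0))
    eP = P0 + dt * (M * P0 + b_ip * I0 - b_pi * P0 - mu * P0)
    eI = I0 + dt * (b_pi * P0 - b_ip * I0 - mu * I0)
    eB = B0 - dt * mu * B0
    eN = N0 + dt * mu * (P0 + I0 + B0)
    reaction_step(st_, p, dt)
    assert st_.P[0, 0] == pytest.approx(eP, abs=1e-12)
    assert st_.I[0, 0] == pytest.approx(eI, abs=1e-12)
    assert st_.B[0, 0] == pytest.approx(eB, abs=1e-12)
    assert st_.N[0, 0] == pytest.approx(eN, abs=1e-12)


def test_outflow_capping_prevents_negative_densities():
    # dt large enough that uncapped switching would overdraw P
    p = ModelParameters(beta_PI=0.9, mu_max=2.0, dt=2.0)
    st_ = _state_from([[0.2]], [[0.1]], [[0.6]], [[0.05]])
    before = total_density(st_).sum()
    reaction_step(st_, p, dt=2.0)
    for f in (st_.P, st_.I, st_.B, st_.N):
        assert np.all(f >= 0.0)
    # capping keeps the step conservative apart from mitosis
    assert total_density(st_).sum() >= before - 1e-12


def test_necrosis_is_monotone_nondecreasing(rng):
    p = ModelParameters()
    P = rng.random((6, 6)) * 0.5
    I = rng.random((6, 6)) * 0.5
    st_ = _state_from(P, I, np.full((6, 6), 0.5), np.zeros((6, 6)))
    prev = st_.N.copy()
    for _ in range(100):
        reaction_step(st_, p, dt=0.1)
        assert np.all(st_.N >= prev - 1e-15)
        prev = st_.N.copy()


def test_normoxic_exponential_growth_closed_form():
    """Spatially uniform state far below the hypoxic threshold grows as
    P(t) = P0 * (1 + M_max*dt)^n exactly."""
    p = ModelParameters(beta_IP=0.0)
    P0 = 1e-4
    st_ = _state_from(np.full((3, 3), P0), np.zeros((3, 3)),
                      np.full((3, 3), 0.3), np.zeros((3, 3)))
    n = 200
    for _ in range(n):
        reaction_step(st_, p, dt=p.dt)
    expected = P0 * (1 + p.M_max * p.dt) ** n
    assert np.allclose(st_.P, expected, rtol=1e-12)


def test_state_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        TissueState(P=np.zeros((2, 2)), I=np.zeros((2, 3)),
                    B=np.zeros((2, 2)), N=np.zeros((2, 2)),
                    tau_h=np.zeros((2, 2)), tau_l=np.zeros((2, 2)))
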