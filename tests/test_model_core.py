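"""Rate functions, influx, parameter accounting and the V2 constraint."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thymodyn import (
    InfeasibleInfluxError,
    InfluxMode,
    ModelSpec,
    Population,
    StageParameters,
    apply_continuity_constraint,
    count_free_parameters,
    default_ground_truth,
    ensure_beta,
    free_parameter_names,
    progenitor_influx,
    proliferation_rate,
    rhs,
    solve_beta,
)
from thymodyn.dde import _compiled_rhs
from thymodyn.parameters import ONE_CELL

from conftest import make_random_admissible_spec


# -- free-parameter accounting -------------------------------------------------


@pytest.mark.parametrize(
    "model_class,variant,expected",
    [("M1", "V1", 39), ("M1", "V2", 36), ("M2", "V1", 43), ("M2", "V2", 40)],
)
def test_free_parameter_counts(model_class, variant, expected):
    assert count_free_parameters(model_class, variant) == expected
    assert len(free_parameter_names(model_class, variant)) == expected


@pytest.mark.parametrize("model_class", ["M1", "M2"])
def test_variant_and_class_count_relations(model_class):
    v1 = count_free_parameters(model_class, "V1")
    v2 = count_free_parameters(model_class, "V2")
    assert v2 == v1 - 3  # V2 derives the three postnatal amplitudes
    assert count_free_parameters("M2", "V1") == count_free_parameters("M1", "V1") + 4


def test_v2_names_exclude_postnatal_amplitudes():
    names = free_parameter_names("M1", "V2")
    for amp in ("post_c_N", "post_c_P", "post_c_48"):
        assert amp not in names
    assert "pre_c_N" in names and "beta" not in names


# -- proliferation rate --------------------------------------------------------


def test_prenatal_rate_matches_hand_evaluation():
    """Direct symbolic evaluation of the prenatal decreasing-rate formula."""
    spec = ModelSpec(t0=10.3, prenatal=StageParameters(b_N=0.1, c_N=5.0))
    r0 = proliferation_rate(spec.prenatal, spec, Population.DN, 10.3)
    r1 = proliferation_rate(spec.prenatal, spec, Population.DN, 20.3)
    assert r0 == pytest.approx(5.0 * 0.1, abs=1e-12)
    assert r1 == pytest.approx(5.0 * 0.1 * math.exp(-0.1 * 10.0), abs=1e-12)


def test_postnatal_rate_absolute_clock_hand_evaluation():
    spec = ModelSpec(postnatal=StageParameters(b_P=0.06, c_P=1.0))
    r = proliferation_rate(spec.postnatal, spec, Population.DP, 25.0)
    assert r == pytest.approx(1.0 * math.exp(-0.06 * 25.0), abs=1e-12)


def test_rate_strictly_decreasing_and_positive():
    rng = np.random.default_rng(0)
    for _ in range(10):
        spec = make_random_admissible_spec(rng)
        grid = np.linspace(spec.t0, spec.t0 + 9.0, 100)
        rates = [
            proliferation_rate(spec.prenatal, spec, pop, t)
            for pop in Population
            for t in grid
        ]
        assert all(r > 0 for r in rates)
        for pop in Population:
            r = [proliferation_rate(spec.prenatal, spec, pop, t) for t in grid]
            assert np.all(np.diff(r) < 0)


def test_rate_decays_to_zero():
    spec = ModelSpec(t0=10.3, prenatal=StageParameters(b_N=0.1, c_N=5.0))
    far = proliferation_rate(spec.prenatal, spec, Population.DN, spec.t0 + 1e4)
    near = proliferation_rate(spec.prenatal, spec, Population.DN, spec.t0)
    assert far < 1e-6 * near


def test_rate_domain_and_population_errors():
    spec = ModelSpec(t0=10.3)
    with pytest.raises(ValueError):
        proliferation_rate(spec.prenatal, spec, Population.DN, 9.0)
    with pytest.raises(ValueError):
        proliferation_rate(spec.prenatal, spec, "CD4SP", 12.0)


def test_density_factor_reduces_growth_at_capacity():
    """M2 at carrying capacity grows strictly slower than M1 with the same
    decay parameters."""
    stage = StageParameters(b_N=0.1, c_N=5.0, b_P=0.1, c_P=5.0, b_4=0.1,
                            b_8=0.1, c_48=5.0, K_N=1.0, K=2.0)
    m1 = ModelSpec(model_class="M1", t0=10.3, prenatal=stage)
    m2 = ModelSpec(model_class="M2", t0=10.3, prenatal=stage)
    state = np.array([1.0, 1.0, 0.5, 0.5, 0.0])  # N at K_N, P+S4+S8 at K
    for pop in Population:
        r1 = proliferation_rate(m1.prenatal, m1, pop, 12.0, state)
        r2 = proliferation_rate(m2.prenatal, m2, pop, 12.0, state)
        assert r2 < r1
        assert r2 == pytest.approx(0.0, abs=1e-12)  # exactly at capacity


def test_m2_requires_state():
    spec = ModelSpec(model_class="M2",
                     prenatal=StageParameters(b_N=0.1, c_N=1, K_N=1.0, K=1.0),
                     postnatal=StageParameters(K_N=1.0, K=1.0))
    with pytest.raises(ValueError):
        proliferation_rate(spec.prenatal, spec, Population.DN, 12.0)


# -- progenitor influx and beta ------------------------------------------------


def test_influx_one_cell_at_onset():
    spec = ensure_beta(ModelSpec(t0=10.3, b0=0.01, tau_b=15.0))
    assert progenitor_influx(spec, spec.t0) == pytest.approx(ONE_CELL, rel=1e-10)


def test_influx_midpoint_is_half_plateau():
    spec = ensure_beta(ModelSpec(t0=10.3, b0=0.01, tau_b=15.0))
    assert progenitor_influx(spec, 15.0) == pytest.approx(0.005, abs=1e-12)


def test_influx_modes():
    spec = ensure_beta(ModelSpec(t0=10.3, b0=0.01, tau_b=15.0))
    assert progenitor_influx(spec, 400.0, InfluxMode.ZERO) == 0.0
    assert progenitor_influx(spec, 400.0, InfluxMode.CONSTANT_B0) == 0.01
    grid = np.linspace(10.3, 19.5, 50)
    values = [progenitor_influx(spec, t) for t in grid]
    assert np.all(np.diff(values) >= 0) and max(values) <= spec.b0


def test_influx_requires_beta():
    spec = ModelSpec(t0=10.3, b0=0.01, tau_b=15.0)  # beta unset
    with pytest.raises(ValueError):
        progenitor_influx(spec, 12.0, InfluxMode.LOGISTIC)


def test_solve_beta_matches_bisection_oracle():
    b0, tau_b, t0 = 0.01, 15.0, 10.3

    def influx(beta, t):
        return b0 / (1.0 + math.exp(-beta * (t - tau_b)))

    lo, hi = 1e-6, 100.0
    for _ in range(200):  # bisection on the defining equation
        mid = 0.5 * (lo + hi)
        if influx(mid, t0) > ONE_CELL:
            lo = mid
        else:
            hi = mid
    assert solve_beta(b0, tau_b, t0) == pytest.approx(0.5 * (lo + hi), rel=1e-8)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    b0=st.floats(1e-5, 1.0),
    gap=st.floats(0.5, 10.0),
    t0=st.floats(5.0, 15.0),
)
def test_solve_beta_roundtrip(b0, gap, t0):
    """Derived steepness reproduces one cell at onset for random feasible
    (b0, tau_b, t0) triples."""
    spec = ensure_beta(ModelSpec(t0=t0, b0=b0, tau_b=t0 + gap, birth_time=16.0))
    value = progenitor_influx(spec, t0)
    assert abs(value - ONE_CELL) / ONE_CELL < 1e-8


def test_solve_beta_infeasible():
    with pytest.raises(InfeasibleInfluxError):
        solve_beta(1e-8, 15.0, 10.3)
    with pytest.raises(InfeasibleInfluxError):
        solve_beta(0.01, 10.0, 10.3)  # midpoint before onset


# -- right-hand side -----------------------------------------------------------


def test_rhs_pure_influx_source():
    spec = ensure_beta(ModelSpec(t0=10.3, b0=0.01, tau_b=15.0))
    d = rhs(12.0, np.zeros(5), 0.0, spec, spec.prenatal, InfluxMode.CONSTANT_B0)
    assert d == pytest.approx([0.01, 0, 0, 0, 0], abs=1e-15)


def test_rhs_matches_independent_transcription():
    """Component-wise check against a second, inline transcription of the
    five balance equations."""
    rng = np.random.default_rng(3)
    spec = ensure_beta(make_random_admissible_spec(rng))
    y = np.array([1.0, 2.0, 0.5, 0.4, 0.1])
    delayed = 0.7
    t = 14.2
    p = spec.prenatal
    rho = {
        "N": p.c_N * p.b_N * math.exp(-p.b_N * (t - spec.t0)),
        "P": p.c_P * p.b_P * math.exp(-p.b_P * (t - spec.t0)),
        "4": p.c_48 * p.b_4 * math.exp(-p.b_4 * (t - spec.t0)),
        "8": p.c_48 * p.b_8 * math.exp(-p.b_8 * (t - spec.t0)),
    }
    b_t = spec.b0 / (1.0 + math.exp(-spec.beta * (t - spec.tau_b)))
    expected = [
        rho["N"] * y[0] - p.d_N * y[0] - p.s_N * y[0] + b_t,
        rho["P"] * y[1] - p.d_P * y[1] - (p.s_4 + p.s_8) * y[1] + p.s_N * delayed,
        rho["4"] * y[2] - p.d_4 * y[2] - p.s_04 * y[2] + p.s_4 * y[1],
        rho["8"] * y[3] - p.d_8 * y[3] - p.s_08 * y[3] + p.s_8 * y[1],
        p.d_N * y[0] + p.d_P * y[1] + p.d_4 * y[2] + p.d_8 * y[3] - p.delta * y[4],
    ]
    got = rhs(t, y, delayed, spec, p, InfluxMode.LOGISTIC)
    assert got == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(data=st.data())
def test_rhs_mass_balance_identity(data):
    """Sum of derivatives equals proliferation + influx - degradation -
    exports + (delayed-in minus instantaneous-out) transfer mismatch."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    spec = ensure_beta(make_random_admissible_spec(rng))
    y = rng.uniform(0, 2, 5)
    delayed = rng.uniform(0, 2)
    t = rng.uniform(spec.t0, spec.t0 + 8)
    p = spec.prenatal
    d = rhs(t, y, delayed, spec, p, InfluxMode.LOGISTIC)
    prolif = sum(
        proliferation_rate(p, spec, pop, t) * y[i]
        for i, pop in enumerate(Population)
    )
    b_t = progenitor_influx(spec, t)
    expected = (
        prolif + b_t - p.delta * y[4] - p.s_04 * y[2] - p.s_08 * y[3]
        + p.s_N * delayed - p.s_N * y[0]
    )
    assert d.sum() == pytest.approx(expected, abs=1e-12)


def test_rhs_rejects_negative_state():
    spec = ensure_beta(ModelSpec(t0=10.3))
    with pytest.raises(ValueError):
        rhs(12.0, np.array([-1.0, 0, 0, 0, 0]), 0.0, spec, spec.prenatal)


@pytest.mark.parametrize("model_class,variant", [("M1", "V1"), ("M2", "V1"), ("M1", "V2")])
@pytest.mark.parametrize("postnatal", [False, True])
def test_compiled_rhs_matches_reference(model_class, variant, postnatal):
    """The solver's bound closure agrees with the public rhs exactly."""
    spec = default_ground_truth(model_class, variant)
    stage = spec.postnatal if postnatal else spec.prenatal
    mode = InfluxMode.CONSTANT_B0 if postnatal else InfluxMode.LOGISTIC
    f = _compiled_rhs(spec, stage, mode)
    rng = np.random.default_rng(8)
    for _ in range(20):
        y = rng.uniform(0, 2, 5)
        delayed = rng.uniform(0, 2)
        t = rng.uniform(20.0, 40.0) if postnatal else rng.uniform(spec.t0, 19.5)
        assert np.asarray(f(t, y, delayed)) == pytest.approx(
            rhs(t, y, delayed, spec, stage, mode), rel=1e-13, abs=1e-15
        )


# -- V2 amplitude (continuity) constraint ---------------------------------------


def test_continuity_constraint_arithmetic():
    pre = StageParameters(b_N=0.05, c_N=2.0, b_P=0.05, c_P=2.0, b_4=0.05, c_48=2.0)
    c_N, c_P, c_48 = apply_continuity_constraint(pre, 10.3)
    expected = 0.05 * 2.0 * math.exp(0.05 * 10.3)  # = 0.1 * exp(0.515)
    assert c_N == pytest.approx(expected, rel=1e-12)
    assert c_P == pytest.approx(expected, rel=1e-12)
    assert c_48 == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.1673639, abs=5e-7)


def test_continuity_constraint_zero_decay():
    pre = StageParameters()  # all b = 0
    assert apply_continuity_constraint(pre, 10.3) == (0.0, 0.0, 0.0)


def test_constraint_applied_is_idempotent():
    spec = default_ground_truth("M1", "V2")
    once = spec.with_constraint_applied()
    twice = once.with_constraint_applied()
    assert once.postnatal.c_N == twice.postnatal.c_N
    assert once.postnatal.c_P == twice.postnatal.c_P
    assert once.postnatal.c_48 == twice.postnatal.c_48


def test_constraint_gives_exact_rate_continuity_when_decay_carried_over():
    """With the postnatal decay rates equal to the prenatal ones (and the
    absolute decay clock), the derived amplitudes make the proliferation
    function continuous at birth."""
    from dataclasses import replace

    spec = default_ground_truth("M1", "V1")
    post = replace(spec.postnatal, b_N=spec.prenatal.b_N, b_P=spec.prenatal.b_P,
                   b_4=spec.prenatal.b_4, b_8=spec.prenatal.b_8)
    spec = replace(spec, variant="V2", postnatal=post).with_constraint_applied()
    T = spec.birth_time
    for pop in (Population.DN, Population.DP, Population.SP4):
        before = proliferation_rate(spec.prenatal, spec, pop, T)
        after = proliferation_rate(spec.postnatal, spec, pop, T)
        assert after == pytest.approx(before, rel=1e-12)


# -- serialization ---------------------------------------------------------------


def test_flat_dict_roundtrip():
    spec = default_ground_truth("M2", "V2")
    again = ModelSpec.from_flat_dict(spec.to_flat_dict())
    assert again.to_flat_dict() == spec.to_flat_dict()
    assert again.model_class == spec.model_class
    assert again.prenatal == spec.prenatal
    assert again.postnatal == spec.postnatal


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        ModelSpec(t0=25.0).validate()  # onset after birth
    with pytest.raises(ValueError):
        ModelSpec(prenatal=StageParameters(d_N=-0.1)).validate()
    with pytest.raises(ValueError):
        ModelSpec(model_class="M2").validate()  # missing capacities
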