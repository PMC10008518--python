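"""Forward-model unit and property tests.

The independent oracle throughout is brute-force trapezoid quadrature of
the defining convolution integrals, built only from scipy.stats gamma
CDF values and numpy — none of the package's grid/convolution machinery.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbpm import (IndividualParams, PopulationParams, basis_component,
                  basis_matrix_values, evaluate_aif, injection_profile)


def oracle_crv(t, alpha, beta, duration):
    t = np.asarray(t, dtype=float)
    return (stats.gamma.cdf(t, alpha, scale=1 / beta)
            - stats.gamma.cdf(t - duration, alpha, scale=1 / beta)) / duration


def oracle_basis(tq, alpha, beta, phi, delta, duration, h=5e-4):
    """Brute-force quadrature of A(t) = int_0^t phi e^{-phi(t-s)} CRV(s-delta) ds."""
    out = []
    for t in np.atleast_1d(tq):
        s = np.arange(0.0, max(t, 0.0) + h / 2, h)
        if s.size < 2:
            out.append(0.0)
            continue
        integrand = phi * np.exp(-phi * (t - s)) * oracle_crv(s - delta, alpha, beta, duration)
        out.append(np.trapezoid(integrand, s))
    return np.asarray(out)


class TestInjectionProfile:
    def test_zero_before_injection(self):
        assert injection_profile(np.array([0.0, -1.0]), 2.0, 3.0, 1.0) == pytest.approx([0, 0])

    def test_bolus_limit_is_gamma_density(self):
        # unit-area boxcar shrinking to zero width -> Gamma pdf
        t = np.array([0.2, 0.5, 1.0, 2.0])
        tiny = injection_profile(t, 2.0, 3.0, 1e-6)
        assert tiny == pytest.approx(stats.gamma.pdf(t, 2.0, scale=1 / 3.0), rel=1e-4)

    def test_matches_quadrature_convolution(self):
        # direct convolution of the Gamma pdf with the unit-area boxcar
        alpha, beta, dur, t = 2.0, 3.0, 1.0, 1.5
        s = np.linspace(0.0, dur, 200001)
        expected = np.trapezoid(stats.gamma.pdf(t - s, alpha, scale=1 / beta) / dur, s)
        assert injection_profile(t, alpha, beta, dur)[()] == pytest.approx(expected, rel=1e-6)

    def test_unit_mass(self):
        t = np.linspace(0, 60, 20001)
        mass = np.trapezoid(injection_profile(t, 3.0, 9.0, 2.0), t)
        assert mass == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("alpha,beta,dur", [(-1, 3, 1), (2, 0, 1), (2, 3, 0)])
    def test_invalid_parameters_raise(self, alpha, beta, dur):
        with pytest.raises(ValueError):
            injection_profile(np.array([1.0]), alpha, beta, dur)


class TestBasisComponent:
    def test_causality(self, fdg_pop):
        t = np.array([0.0, 0.05, 0.1])
        assert basis_component(t, 1, fdg_pop, delta=0.1, duration=1.0) == pytest.approx([0, 0, 0])

    def test_fast_rate_limit_approaches_injection_profile(self):
        # phi -> inf: exponential density -> Dirac, A_j -> delayed CRV
        pop = PopulationParams(alpha=2.0, beta=3.0, rates=(5000.0,))
        t = np.array([0.5, 1.0, 2.0, 4.0])
        a = basis_component(t, 1, pop, delta=0.0, duration=1.0)
        crv = oracle_crv(t, 2.0, 3.0, 1.0)
        assert a == pytest.approx(crv, rel=2e-3)

    def test_matches_nested_quadrature(self):
        pop = PopulationParams(alpha=2.0, beta=3.0, rates=(0.5,))
        t = np.array([1.0, 2.0, 5.0, 10.0])
        mine = basis_component(t, 1, pop, delta=0.0, duration=1.0)
        orc = oracle_basis(t, 2.0, 3.0, 0.5, 0.0, 1.0)
        assert mine == pytest.approx(orc, rel=1e-4)

    def test_out_of_range_component_raises(self, fdg_pop):
        with pytest.raises(IndexError):
            basis_component(np.array([1.0]), 4, fdg_pop, 0.0, 1.0)
        with pytest.raises(IndexError):
            basis_component(np.array([1.0]), 0, fdg_pop, 0.0, 1.0)

    @pytest.mark.parametrize("delta", [-0.4, -0.1, 0.0, 0.25, 0.5])
    def test_delay_handling_against_oracle(self, delta):
        """Positive and negative delays both match brute-force quadrature."""
        pop = PopulationParams(alpha=3.0, beta=9.0, rates=(1.2,))
        t = np.array([0.5, 1.0, 2.0, 5.0])
        mine = basis_component(t, 1, pop, delta, duration=1.0)
        orc = oracle_basis(t, 3.0, 9.0, 1.2, delta, 1.0)
        mask = orc > 1e-3 * orc.max()
        assert mine[mask] == pytest.approx(orc[mask], rel=1e-4)


class TestEvaluateAif:
    def test_zero_weights_zero_curve(self, fdg_pop):
        indiv = IndividualParams(pi=(0.0, 0.0, 0.0), delta=0.1)
        t = np.linspace(0, 10, 30)
        assert evaluate_aif(t, fdg_pop, indiv, 1.0) == pytest.approx(np.zeros(30))

    def test_single_component_scaling(self):
        pop = PopulationParams(alpha=2.0, beta=3.0, rates=(0.8,))
        t = np.linspace(0.2, 8, 15)
        doubled = evaluate_aif(t, pop, IndividualParams(pi=(2.0,)), 1.0)
        single = basis_component(t, 1, pop, 0.0, 1.0)
        assert doubled == pytest.approx(2.0 * single, rel=1e-12)

    def test_curve_is_component_sum_with_canonical_shape(self, fdg_pop):
        indiv = IndividualParams(pi=(5.0, 1.0, 0.2), delta=0.1)
        t = np.linspace(0.0, 60.0, 2001)
        curve = evaluate_aif(t, fdg_pop, indiv, 1.0)
        expected = sum(p * basis_component(t, j + 1, fdg_pop, 0.1, 1.0)
                       for j, p in enumerate(indiv.pi))
        assert curve == pytest.approx(expected, rel=1e-10)
        # zero plateau, single peak, decaying tail
        assert np.all(curve[t <= 0.1] == 0)
        peak = np.argmax(curve)
        assert 0 < peak < len(t) - 1
        assert np.all(np.diff(curve[t > 10.0]) <= 1e-12)
        assert np.all(curve >= 0)
        assert curve[-1] < 0.05 * curve[peak]

    def test_dimension_mismatch_raises(self, fdg_pop):
        with pytest.raises(ValueError):
            evaluate_aif(np.array([1.0]), fdg_pop, IndividualParams(pi=(1.0,)), 1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(0.1, 3.0), b=st.floats(0.1, 3.0))
    def test_linearity_in_weights(self, fdg_pop, a, b):
        t = np.linspace(0.2, 20, 40)
        p1, p2 = np.array([5.0, 1.0, 0.2]), np.array([1.0, 2.0, 0.5])
        combo = evaluate_aif(t, fdg_pop, IndividualParams(pi=tuple(a * p1 + b * p2)), 1.0)
        parts = (a * evaluate_aif(t, fdg_pop, IndividualParams(pi=tuple(p1)), 1.0)
                 + b * evaluate_aif(t, fdg_pop, IndividualParams(pi=tuple(p2)), 1.0))
        assert combo == pytest.approx(parts, rel=1e-9, abs=1e-12)


class TestDomainTypes:
    def test_rates_must_decrease_strictly(self):
        with pytest.raises(ValueError):
            PopulationParams(alpha=2.0, beta=3.0, rates=(1.0, 2.0))
        with pytest.raises(ValueError):
            PopulationParams(alpha=2.0, beta=3.0, rates=(1.0, 1.0))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            IndividualParams(pi=(1.0, -0.1))

    def test_sampling_curve_validation(self):
        from pbpm import SamplingCurve
        with pytest.raises(ValueError, match="increasing"):
            SamplingCurve("s", [0, 2, 1.0], [1, 1, 1.0], 1.0)
        with pytest.raises(ValueError, match="at least 3"):
            SamplingCurve("s", [0, 1.0], [1, 1.0], 1.0)
        with pytest.raises(ValueError, match="weights"):
            SamplingCurve("s", [0, 1, 2.0], [1, 1, 1.0], 1.0, weights=[1, 0, 1.0])


def test_oracle_equivalence_across_parameter_grid():
    """Basis components match independent quadrature over a parameter sweep."""
    rng = np.random.default_rng(5)
    tq = np.array([0.75, 1.5, 3.0, 6.0, 10.0])
    for _ in range(12):
        alpha = rng.uniform(1.5, 6.0)
        beta = rng.uniform(3.0, 15.0)
        phi = 10 ** rng.uniform(-1.5, 0.8)
        delta = rng.uniform(-0.5, 0.5)
        dur = float(rng.choice([1 / 12, 1.0, 2.0]))
        pop = PopulationParams(alpha=alpha, beta=beta, rates=(phi,))
        mine = basis_component(tq, 1, pop, delta, dur)
        orc = oracle_basis(tq, alpha, beta, phi, delta, dur)
        mask = orc >= 0.05 * orc.max()
        assert mine[mask] == pytest.approx(orc[mask], rel=1e-4), \
            f"mismatch at alpha={alpha}, beta={beta}, phi={phi}, delta={delta}, dur={dur}"


def test_basis_matrix_columns_match_components(fdg_pop):
    t = np.linspace(0.25, 20, 12)
    A = basis_matrix_values(t, fdg_pop, 0.2, 1.0)
    assert A.shape == (12, 3)
    for j in range(3):
        assert A[:, j] == pytest.approx(basis_component(t, j + 1, fdg_pop, 0.2, 1.0))
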