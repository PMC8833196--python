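"""Ideal-gas-of-organisms calculus and cumulant reconstruction."""

import math

import numpy as np
import pytest

from evotherm import (
    CumulantSpec,
    K_required,
    Ne_of,
    PhenoModel,
    U_of,
    cumulants_from_samples,
    euler_first_law_check,
    grand_potential,
    intensives,
    reconstruct_grand_potential,
)
from evotherm.phenomenology import entropy_from_intensives

MODEL = PhenoModel(a=1.0, b=1.0, n=2.0)


def random_models_points(rng, n=20):
    for _ in range(n):
        model = PhenoModel(
            a=float(rng.uniform(0.2, 3.0)),
            b=float(rng.uniform(0.2, 3.0)),
            n=float(rng.uniform(1.2, 4.0)),
        )
        S = float(rng.uniform(0.5, 5.0))
        K = float(rng.uniform(0.1, 5.0))
        yield model, S, K


class TestLoss:
    def test_reference_point(self):
        assert U_of(MODEL, 2.0, 3.0) == pytest.approx(4 * math.e**1.5, rel=1e-14)

    def test_K_zero_power_law(self):
        model = PhenoModel(a=2.0, b=1.0, n=3.0)
        assert U_of(model, 1.7, 0.0) == pytest.approx(2.0 * 1.7**3, rel=1e-14)

    def test_homogeneity_degree_n(self, rng):
        for model, S, K in random_models_points(rng, 10):
            lam = float(rng.uniform(0.5, 2.0))
            assert U_of(model, lam * S, lam * K) == pytest.approx(
                lam**model.n * U_of(model, S, K), rel=1e-12
            )

    def test_invalid_domain(self):
        with pytest.raises(ValueError, match="S"):
            U_of(MODEL, 0.0, 1.0)
        with pytest.raises(ValueError):
            PhenoModel(a=1.0, b=1.0, n=1.0)


class TestIntensives:
    def test_reference_point(self):
        st = intensives(MODEL, 2.0, 3.0)
        U = 4 * math.e**1.5
        assert st.mu == pytest.approx(U / 2, rel=1e-14)      # (b/S) U
        assert st.T_evo == pytest.approx(U / 4, rel=1e-14)   # (mu/b)(n - bK/S)
        assert st.Omega == pytest.approx(-U, rel=1e-14)      # (1-n) U

    def test_temperature_sign_change(self):
        # K = n S / b makes dU/dS vanish
        model = PhenoModel(a=1.5, b=0.7, n=2.5)
        S = 2.0
        K = model.n * S / model.b
        assert intensives(model, S, K).T_evo == pytest.approx(0.0, abs=1e-12)

    def test_finite_difference_gradients(self, rng):
        for model, S, K in random_models_points(rng, 20):
            st = intensives(model, S, K)
            hS, hK = 1e-5 * S, 1e-5 * max(K, 1.0)
            T_fd = (U_of(model, S + hS, K) - U_of(model, S - hS, K)) / (2 * hS)
            mu_fd = (U_of(model, S, K + hK) - U_of(model, S, K - hK)) / (2 * hK)
            assert T_fd == pytest.approx(st.T_evo, rel=1e-6, abs=1e-6 * st.U)
            assert mu_fd == pytest.approx(st.mu, rel=1e-6)

    def test_symbolic_differentiation_oracle(self):
        """Analytic intensives match exact symbolic partial derivatives."""
        import sympy as sp

        a, b, n, S, K = sp.symbols("a b n S K", positive=True)
        U_sym = a * S**n * sp.exp(b * K / S)
        point = {a: 1.3, b: 0.7, n: 2.2, S: 1.9, K: 2.4}
        model = PhenoModel(a=1.3, b=0.7, n=2.2)
        st = intensives(model, 1.9, 2.4)
        assert float(sp.diff(U_sym, S).subs(point)) == pytest.approx(
            st.T_evo, rel=1e-12
        )
        assert float(sp.diff(U_sym, K).subs(point)) == pytest.approx(
            st.mu, rel=1e-12
        )

    def test_intensive_temperature_closed_form(self, rng):
        """T = (mu/b)(n + log(a b / mu) + (n-1) log S)."""
        for model, S, K in random_models_points(rng, 10):
            st = intensives(model, S, K)
            alt = (
                st.mu
                / model.b
                * (
                    model.n
                    + math.log(model.a * model.b / st.mu)
                    + (model.n - 1) * math.log(S)
                )
            )
            assert st.T_evo == pytest.approx(alt, rel=1e-9, abs=1e-9 * st.U)


class TestGrandPotential:
    def test_reference_point_both_routes(self):
        U = 4 * math.e**1.5
        om_ext = grand_potential(MODEL, S=2.0, K=3.0)
        assert om_ext == pytest.approx(-U, rel=1e-12)
        st = intensives(MODEL, 2.0, 3.0)
        om_int = grand_potential(MODEL, T_evo=st.T_evo, mu=st.mu)
        assert om_int == pytest.approx(om_ext, rel=1e-9)

    def test_legendre_round_trip(self, rng):
        """Extensive -> intensive -> recovered entropy within 1e-8."""
        for model, S, K in random_models_points(rng, 20):
            st = intensives(model, S, K)
            S_rec = entropy_from_intensives(model, st.T_evo, st.mu)
            assert S_rec == pytest.approx(S, rel=1e-8)
            om_int = grand_potential(model, T_evo=st.T_evo, mu=st.mu)
            assert om_int == pytest.approx(st.Omega, rel=1e-8)

    def test_closed_form_identity(self, rng):
        """Omega = (1-n) S mu / b = (1-n) U wherever defined."""
        for model, S, K in random_models_points(rng, 10):
            st = intensives(model, S, K)
            assert st.Omega == pytest.approx((1 - model.n) * st.U, rel=1e-12)
            assert st.Omega == pytest.approx(
                (1 - model.n) * S * st.mu / model.b, rel=1e-12
            )

    def test_printed_closed_form_at_unit_scale(self, rng):
        """At a = 1 the explicit formula
        -(n-1)(mu/(e b))^(n/(n-1)) exp(bT/((n-1)mu)) matches."""
        for _ in range(10):
            model = PhenoModel(
                a=1.0, b=float(rng.uniform(0.3, 2.0)), n=float(rng.uniform(1.3, 3.0))
            )
            S, K = float(rng.uniform(0.5, 4.0)), float(rng.uniform(0.1, 4.0))
            st = intensives(model, S, K)
            n, b = model.n, model.b
            printed = -(n - 1) * (st.mu / (math.e * b)) ** (n / (n - 1)) * math.exp(
                b * st.T_evo / ((n - 1) * st.mu)
            )
            assert st.Omega == pytest.approx(printed, rel=1e-9)

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="supply"):
            grand_potential(MODEL, S=1.0)
        with pytest.raises(ValueError, match="mu"):
            grand_potential(MODEL, T_evo=1.0, mu=-1.0)


class TestFirstLaw:
    def test_first_law_second_order(self):
        rep = euler_first_law_check(MODEL, 2.0, 3.0, 1e-4, 1e-4)
        assert rep.residual < 1e-6 * abs(rep.dU_exact)

    def test_zero_increments(self):
        rep = euler_first_law_check(MODEL, 2.0, 3.0, 0.0, 0.0)
        assert rep.dU_exact == 0.0
        assert rep.dU_first_law == 0.0

    def test_euler_ratio_equals_n(self, rng):
        for model, S, K in random_models_points(rng, 10):
            rep = euler_first_law_check(model, S, K, 1e-5 * S, 1e-5 * K)
            assert rep.euler_ratio == pytest.approx(model.n, rel=1e-12)

    def test_large_increments_rejected(self):
        with pytest.raises(ValueError, match="increments"):
            euler_first_law_check(MODEL, 2.0, 3.0, 0.5, 0.0)


class TestPopulationLink:
    def test_trivial_K(self):
        assert K_required(PhenoModel(1, 1, 2), 1.0, math.e) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        model = PhenoModel(a=1.0, b=0.5, n=2.0)
        assert K_required(model, 2.0, math.e**3) == pytest.approx(12.0, rel=1e-12)

    def test_round_trip(self, rng):
        for model, S, K in random_models_points(rng, 10):
            Ne = Ne_of(model, S, K)
            assert K_required(model, S, Ne) == pytest.approx(K, rel=1e-12)
        with pytest.raises(ValueError, match="Ne"):
            K_required(MODEL, 1.0, 0.5)

    def test_population_loss_scaling(self):
        """U = <H> * Ne: the per-organism loss times exp(bK/S)."""
        model = PhenoModel(a=2.0, b=1.0, n=2.0)
        S, K = 2.0, 3.0
        Ne = Ne_of(model, S, K)
        mean_H = model.a * S**model.n  # per-organism loss at K = 0
        assert U_of(model, S, K) == pytest.approx(mean_H * Ne, rel=1e-12)


class TestCumulants:
    def test_constant_samples(self):
        spec = cumulants_from_samples([3.0] * 100, m=4)
        assert spec.cumulants[0] == 3.0
        assert all(abs(k) < 1e-12 for k in spec.cumulants[1:])

    def test_poisson_cumulants(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, size=100_000)
        spec = cumulants_from_samples(x, m=4)
        se1 = math.sqrt(2.0 / x.size)
        assert abs(spec.cumulants[0] - 2.0) < 3 * se1
        # var of k2 for Poisson ~ (kappa4 + 2 kappa2^2)/n
        se2 = math.sqrt((2.0 + 2 * 4.0) / x.size)
        assert abs(spec.cumulants[1] - 2.0) < 3 * se2

    def test_gaussian_third_cumulant_vanishes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, size=100_000)
        spec = cumulants_from_samples(x, m=3)
        se3 = math.sqrt(6.0 / x.size)  # var(k3) ≈ 6 sigma^6 / n
        assert abs(spec.cumulants[2]) < 3 * se3

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="10\\*m"):
            cumulants_from_samples(np.array([0.0, 1.0, 2.0]), m=2)

    def test_unbiased_variance_k_statistic(self):
        # k2 is the n-1 denominator variance, exactly
        x = np.arange(40.0)
        spec = cumulants_from_samples(x, m=2)
        assert spec.cumulants[1] == pytest.approx(np.var(x, ddof=1), rel=1e-12)

    def test_caps(self):
        with pytest.raises(ValueError, match="m > 10"):
            cumulants_from_samples(np.arange(200.0), m=11)


class TestReconstruction:
    def test_gaussian_exact_at_m2(self):
        spec = CumulantSpec(cumulants=(1.0, 1.0), T_evo=1.0, truncation=2)
        with pytest.warns(RuntimeWarning, match="converged"):
            # a two-term series always trips the last-term heuristic,
            # though the Gaussian CGF is exact at m = 2
            omega = reconstruct_grand_potential(spec, 0.5)
        assert omega == pytest.approx(-0.625)

    def test_poisson_closed_form(self):
        lam, mu, T = 2.0, 0.5, 1.0
        spec = CumulantSpec(cumulants=(lam,) * 10, T_evo=T, truncation=10)
        omega = reconstruct_grand_potential(spec, mu)
        assert omega == pytest.approx(-T * lam * math.expm1(mu / T), abs=1e-6)

    def test_zero_mu(self):
        spec = CumulantSpec(cumulants=(1.0, 2.0), T_evo=1.0, truncation=2)
        assert reconstruct_grand_potential(spec, 0.0) == 0.0

    def test_zero_temperature_rejected(self):
        spec = CumulantSpec(cumulants=(1.0,), T_evo=0.0, truncation=1)
        with pytest.raises(ValueError, match="T_evo"):
            reconstruct_grand_potential(spec, 0.5)
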