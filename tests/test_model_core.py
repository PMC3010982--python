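"""Unit and property tests for the single-cell bistable dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from myoswitch import model_core as mc
from myoswitch.errors import DomainError, ParameterError


class TestParams:
    def test_hill_exponent_is_fixed_at_two(self):
        with pytest.raises(ParameterError):
            mc.PhenotypeParams(n=3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"A": -1.0},
            {"B": 0.0},
            {"k_deg": 0.0},
            {"k_deg": 1.5},
            {"C_B": -0.1},
            {"A": float("nan")},
        ],
    )
    def test_invalid_kinetics_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            mc.PhenotypeParams(**kwargs)

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            mc.NoiseParams(N_int=-0.1)


class TestEffectiveB:
    @pytest.mark.parametrize(
        "B, C_B, R, expected",
        [
            (1.0, 0.0, 100.0, 1.0),     # zero coupling removes density dependence
            (1.0, 5.0, 10.0, 51.0),
            (1.0, 15.0, 100.0, 1501.0),  # strong-coupling example at medium concentration
        ],
    )
    def test_values(self, B, C_B, R, expected):
        assert mc.effective_B(B, C_B, R) == pytest.approx(expected)

    def test_strictly_increasing_in_R_when_coupled(self):
        Rs = np.linspace(0, 100, 50)
        vals = mc.effective_B(2.0, 3.0, Rs)
        assert np.all(np.diff(vals) > 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            mc.effective_B(1.0, 1.0, float("inf"))


class TestProductionRate:
    def test_zero_at_zero(self):
        assert mc.production_rate(0.0, 1.0, 1.0) == 0.0

    def test_half_saturation_point(self):
        for B_eff in (0.5, 1.0, 7.3):
            assert mc.production_rate(math.sqrt(B_eff), 2.0, B_eff) == pytest.approx(1.0)

    def test_rate_at_inflection_is_quarter_of_max(self):
        # the Hill inflection sits at P = sqrt(B_eff/3); the rate there is
        # A/4 independent of B_eff
        for A, B_eff in [(1.0, 1.0), (10.0, 50.0), (3.0, 400.0)]:
            P = math.sqrt(B_eff / 3.0)
            assert mc.production_rate(P, A, B_eff) == pytest.approx(A / 4.0)

    def test_negative_P_rejected(self):
        with pytest.raises(DomainError):
            mc.production_rate(-0.1, 1.0, 1.0)

    @given(st.floats(0.0, 1e4), st.floats(0.1, 100.0), st.floats(0.1, 1e4))
    def test_bounded_below_max(self, P, A, B_eff):
        assert 0.0 <= mc.production_rate(P, A, B_eff) < A


class TestClassification:
    def test_zero_is_low(self):
        assert mc.classify_phenotype(0.0, 1.0, 1.0) is mc.PhenotypeClass.LOW

    def test_twice_threshold_is_high(self):
        B_eff = 5.0
        P = 2.0 * math.sqrt(B_eff / 3.0)
        assert mc.classify_phenotype(P, 1.0, B_eff) is mc.PhenotypeClass.HIGH

    def test_boundary_ties_break_low(self):
        B_eff = 3.0
        P = math.sqrt(B_eff / 3.0)
        assert mc.classify_phenotype(P, 1.0, B_eff) is mc.PhenotypeClass.LOW

    def test_vectorised_matches_scalar(self, rng):
        Ps = rng.uniform(0, 10, size=200)
        B_eff = 7.0
        vec = mc.is_high(Ps, B_eff)
        scalar = [mc.classify_phenotype(p, 1.0, B_eff) is mc.PhenotypeClass.HIGH for p in Ps]
        assert list(vec) == scalar


class TestContextNoise:
    @pytest.mark.parametrize(
        "p_hat, d_hat, expected",
        [
            (1.0, 1.0, 0.0),    # matched high-P / high-density corner
            (0.0, 1.0, 0.3),    # mismatched low-P cell in a dense region
            (1.0, 0.0, 0.3),    # mismatched high-P cell in a sparse region
            (0.0, 0.0, 0.0),
            (0.5, 0.9, 0.15),   # saddle line: N_ext/2 regardless of density
        ],
    )
    def test_corner_and_saddle_values(self, p_hat, d_hat, expected):
        assert mc.context_noise_sd(p_hat, d_hat, 0.3) == pytest.approx(expected)

    def test_bilinear_on_grid(self):
        # exact equality with the paraboloid formula on an 11x11 grid
        p = np.linspace(0, 1, 11)
        d = np.linspace(0, 1, 11)
        P, D = np.meshgrid(p, d)
        got = mc.context_noise_sd(P, D, 2.0)
        expected = 2.0 * (1 + (2 * D - 1) * (1 - 2 * P)) / 2.0
        np.testing.assert_array_equal(got, expected)

    def test_domain_checked(self):
        with pytest.raises(DomainError):
            mc.context_noise_sd(1.2, 0.5, 1.0)


class TestFixedPoints:
    def test_three_states_against_quadratic_roots(self):
        # quadratic-root oracle: k P^2 - A P + k B_eff = 0
        A, B_eff, k = 1.0, 1.0, 0.2
        pts = mc.fixed_points(A, B_eff, k)
        disc = A * A - 4 * k * k * B_eff
        lo = (A - math.sqrt(disc)) / (2 * k)
        hi = (A + math.sqrt(disc)) / (2 * k)
        assert [p.stable for p in pts] == [True, False, True]
        assert pts[1].P == pytest.approx(lo)  # ~0.2087
        assert pts[2].P == pytest.approx(hi)  # ~4.7913
        assert pts[1].P == pytest.approx(0.2087, abs=1e-4)
        assert pts[2].P == pytest.approx(4.7913, abs=1e-4)

    def test_monostable_when_discriminant_negative(self):
        pts = mc.fixed_points(1.0, 10.0, 0.2)
        assert len(pts) == 1 and pts[0].P == 0.0 and pts[0].stable

    def test_double_root_at_boundary(self):
        A, k = 1.0, 0.2
        B_eff = A * A / (4 * k * k)
        pts = mc.fixed_points(A, B_eff, k)
        assert len(pts) == 2
        assert pts[1].P == pytest.approx(A / (2 * k))

    def test_bistability_boundary_scan(self):
        # bistability exists iff B_eff < A^2 / (4 k_deg^2)
        A, k = 10.0, 0.2
        boundary = A * A / (4 * k * k)
        for B_eff in [0.5 * boundary, 0.9 * boundary, 0.999 * boundary]:
            assert len(mc.fixed_points(A, B_eff, k)) == 3
        for B_eff in [1.001 * boundary, 1.5 * boundary]:
            assert len(mc.fixed_points(A, B_eff, k)) == 1


class TestStepPhenotype:
    def _quiet(self):
        return mc.NoiseParams(N_int=0.0, N_ext=0.0)

    def test_one_euler_step_by_hand(self, rng):
        # P=1, A=1, B_eff=1, k=0.2:  1 + 0.5 - 0.2 = 1.3
        pp = mc.PhenotypeParams(A=1.0, B=1.0, k_deg=0.2, C_B=0.0)
        state = mc.PhenotypeState(P=1.0)
        new = mc.step_phenotype(state, 1.0, pp, self._quiet(), 0.5, rng)
        assert new.P == pytest.approx(1.3)

    def test_zero_is_absorbing_without_noise(self, rng):
        pp = mc.PhenotypeParams(A=1.0, B=1.0, k_deg=0.2, C_B=0.0)
        state = mc.PhenotypeState(P=0.0)
        new = mc.step_phenotype(state, 1.0, pp, self._quiet(), 0.0, rng)
        assert new.P == 0.0

    def test_stable_fixed_points_are_invariant(self, rng):
        pp = mc.PhenotypeParams(A=1.0, B=1.0, k_deg=0.2, C_B=0.0)
        for fp in mc.fixed_points(pp.A, pp.B, pp.k_deg):
            state = mc.PhenotypeState(P=fp.P)
            new = mc.step_phenotype(state, pp.B, pp, self._quiet(), 0.3, rng)
            assert new.P == pytest.approx(fp.P, abs=1e-9)

    def test_noise_free_convergence_to_nearest_stable_point(self, rng):
        # initial P below the unstable threshold decays to 0; above it,
        # converges to the high state, both to 1e-6 within 1e4 steps
        pp = mc.PhenotypeParams(A=10.0, B=50.0, k_deg=0.2, C_B=0.0)
        pts = mc.fixed_points(pp.A, pp.B, pp.k_deg)
        p_minus, p_plus = pts[1].P, pts[2].P
        for P0, target in [
            (0.5 * p_minus, 0.0),
            (0.99 * p_minus, 0.0),
            (1.01 * p_minus, p_plus),
            (3 * p_plus, p_plus),
        ]:
            state = mc.PhenotypeState(P=P0)
            quiet = self._quiet()
            for _ in range(10_000):
                state = mc.step_phenotype(state, pp.B, pp, quiet, 0.5, rng)
            assert state.P == pytest.approx(target, abs=1e-6)

    @given(
        st.floats(0.0, 60.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 5.0),
        st.floats(0.0, 5.0),
        st.integers(0, 2**31 - 1),
    )
    def test_level_never_negative(self, P0, d_hat, n_int, n_ext, seed):
        # clamping contract under fuzzed updates
        pp = mc.PhenotypeParams(A=10.0, B=50.0, k_deg=0.2, C_B=0.0)
        noise = mc.NoiseParams(N_int=n_int, N_ext=n_ext)
        rng = np.random.default_rng(seed)
        state = mc.PhenotypeState(P=P0)
        for _ in range(20):
            state = mc.step_phenotype(state, pp.B, pp, noise, d_hat, rng)
            assert state.P >= 0.0


def test_switching_frequency_nondecreasing_in_intrinsic_noise():
    """More intrinsic noise can only speed conversion out of the low well."""
    pp = mc.PhenotypeParams(A=10.0, B=50.0, k_deg=0.2, C_B=0.0)
    fractions = []
    for n_int in (0.5, 1.5, 3.0):
        rng = np.random.default_rng(77)
        n = 300
        P = np.zeros(n)
        for _ in range(120):
            eps = rng.standard_normal(n) * n_int
            P = np.maximum(0.0, P + mc.production_rate(P, pp.A, pp.B) - pp.k_deg * P + eps)
        fractions.append(float(np.mean(mc.is_high(P, pp.B))))
    assert fractions == sorted(fractions)
    assert fractions[-1] > fractions[0]
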