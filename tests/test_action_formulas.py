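import numpy as np
import pytest
from scipy.optimize import minimize

import sispersist as sp
from sispersist.model_core import StagedModel
from sispersist.action_formulas import UnsupportedConfigurationError


class TestActionExplicit:
    def test_fig1_caption(self, fig1_model):
        res = sp.action_explicit(fig1_model)
        assert res.A == pytest.approx(0.0377, abs=5e-5)
        assert res.method == "explicit_infectivity"

    def test_fig3_caption(self, fig3_model):
        assert sp.action_explicit(fig3_model).A == pytest.approx(0.0110,
                                                                 abs=5e-5)

    def test_homogeneous_reduction(self):
        m = sp.validate_model([1.0], [1.0], [1.0], beta=1.5, gamma=1.0)
        assert sp.action_explicit(m).A == pytest.approx(
            sp.action_homogeneous(1.5), abs=1e-12)

    def test_infectivity_susceptibility_duality(self):
        v = np.array([1.6, 0.4])
        f = np.array([0.5, 0.5])
        m_inf = sp.validate_model(f, v, np.ones(2), beta=1.3, gamma=1.0)
        m_sus = sp.validate_model(f, np.ones(2), v, beta=1.3, gamma=1.0)
        assert sp.action_explicit(m_inf).A == pytest.approx(
            sp.action_explicit(m_sus).A, rel=1e-12)

    def test_both_heterogeneities_unsupported(self, both_het_model):
        with pytest.raises(UnsupportedConfigurationError):
            sp.action_explicit(both_het_model)


class TestHomogeneousFormulas:
    @pytest.mark.parametrize("r0,expected,tol", [
        (1.5, 0.0721, 5e-5),       # caption value
        (1.2, 0.0157, 5e-5),       # caption value
    ])
    def test_action_values(self, r0, expected, tol):
        assert sp.action_homogeneous(r0) == pytest.approx(expected, abs=tol)

    def test_action_vanishes_at_threshold(self):
        assert sp.action_homogeneous(1.0 + 1e-8) < 1e-15

    @pytest.mark.parametrize("r0,expected", [
        (2.0, 2.0 * np.sqrt(2 * np.pi)),
        (1.5, 6.0 * np.sqrt(2 * np.pi)),
    ])
    def test_prefactor_values(self, r0, expected):
        assert sp.prefactor_homogeneous(r0) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_prefactor_diverges_at_threshold(self):
        assert sp.prefactor_homogeneous(1.0 + 1e-8) > 1e10

    def test_subcritical_rejected(self):
        for fn in (sp.action_homogeneous, sp.prefactor_homogeneous):
            with pytest.raises(ValueError):
                fn(0.9)


class TestActionTilde:
    def test_homogeneous_hand_reduction(self):
        """With D = R0-1 and flat vectors the straight-line formula collapses
        to ((R0-1)/(2 R0)) ln R0."""
        r0 = 1.2
        m = sp.validate_model([1.0], [1.0], [1.0], beta=r0, gamma=1.0)
        expected = (r0 - 1.0) / (2.0 * r0) * np.log(r0)
        assert sp.action_tilde(m).A == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.01519, abs=5e-6)

    def test_near_threshold_agreement_with_bvp(self):
        m = sp.random_model(2, 1.05, "both", seed=1)
        A_bvp = sp.action_from_trajectory(sp.solve_heteroclinic(m)).A
        A_tilde = sp.action_tilde(m).A
        assert abs(A_tilde - A_bvp) / A_bvp < 0.05

    def test_swap_asymmetry_reported(self, both_het_model):
        res = sp.action_tilde(both_het_model)
        assert "A_swapped" in res.diagnostics
        assert res.diagnostics["swap_asymmetry"] == pytest.approx(
            res.A - res.diagnostics["A_swapped"])

    def test_warning_flag_above_regime(self, fig1_model):
        assert sp.action_tilde(fig1_model).diagnostics["near_threshold_warning"]


@pytest.fixture(scope="module")
def sus_model():
    """Susceptibility-heterogeneous model (lam = 1), R0 = 1.2."""
    return sp.validate_model([0.5, 0.5], [1, 1], [5 / 3, 1 / 3],
                             beta=1.2, gamma=1.0)


class TestPotentials:
    def test_potential_drop_equals_action(self, sus_model):
        A = sp.action_explicit(sus_model).A
        y_star = sp.endemic_equilibrium(sus_model)
        th_star = sp.momentum_equilibrium(sus_model)
        k = sus_model.k
        dV = (sp.potential_V_susceptible(sus_model, np.zeros(k))
              - sp.potential_V_susceptible(sus_model, y_star))
        dU = (sp.potential_U_susceptible(sus_model, np.zeros(k))
              - sp.potential_U_susceptible(sus_model, th_star))
        assert dV == pytest.approx(A, abs=1e-12)
        assert dU == pytest.approx(A, abs=1e-12)

    def test_boundary_value_at_origin(self, sus_model):
        assert sp.potential_V_susceptible(sus_model, np.zeros(2)) == \
            pytest.approx(float(np.sum(sus_model.f * np.log(sus_model.f))))

    def test_hamilton_jacobi_residual_interior(self, sus_model):
        """Finite-difference gradient of V plugged into H vanishes."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            y = rng.uniform(0.1, 0.9) * sp.endemic_equilibrium(sus_model)
            eps = 1e-6
            grad = np.array([
                (sp.potential_V_susceptible(sus_model, y + eps * e)
                 - sp.potential_V_susceptible(sus_model, y - eps * e))
                / (2 * eps)
                for e in np.eye(2)])
            assert abs(sp.hamiltonian(sus_model, y, grad)) < 1e-6

    def test_out_of_box_rejected(self, sus_model):
        with pytest.raises(ValueError):
            sp.potential_V_susceptible(sus_model, sus_model.f + 0.1)

    def test_legendre_offset_is_constant(self, sus_model):
        """sup_y {y.theta - V(y)} differs from the closed-form U by the
        theta-independent constant -sum f ln f (potentials matter only
        through differences)."""
        th_star = sp.momentum_equilibrium(sus_model)
        const = -float(np.sum(sus_model.f * np.log(sus_model.f)))
        for frac in (0.0, 0.35, 0.7):
            th = frac * th_star

            def neg(yv):
                return -(yv @ th - sp.potential_V_susceptible(sus_model, yv))

            r = minimize(neg, 0.4 * sp.endemic_equilibrium(sus_model),
                         bounds=[(1e-10, f - 1e-10) for f in sus_model.f],
                         method="L-BFGS-B", tol=1e-14)
            sup = -r.fun
            U = sp.potential_U_susceptible(sus_model, th)
            assert sup - U == pytest.approx(const, abs=1e-6)

    def test_infectivity_case_rejected(self, fig1_model):
        with pytest.raises(UnsupportedConfigurationError):
            sp.potential_V_susceptible(fig1_model, np.zeros(2))


class TestStagedPotentials:
    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_drop_independent_of_stage_count(self, sus_model, s):
        """Erlang infectious periods leave the action unchanged for
        susceptibility heterogeneity."""
        st = StagedModel(base=sus_model, s=s)
        eq = sp.staged_equilibrium(st)
        k = sus_model.k
        A = sp.action_explicit(sus_model).A
        dV = (sp.staged_potential_V(st, np.zeros((k, s)))
              - sp.staged_potential_V(st, eq.y_star_stages))
        dU = (sp.staged_potential_U(st, np.zeros((k, s)))
              - sp.staged_potential_U(st, eq.theta_star_stages))
        assert dV == pytest.approx(A, abs=1e-10)
        assert dU == pytest.approx(A, abs=1e-10)

    def test_s1_reduces_to_plain_potentials(self, sus_model):
        st = StagedModel(base=sus_model, s=1)
        y = np.array([0.05, 0.02])
        th = 0.5 * sp.momentum_equilibrium(sus_model)
        assert sp.staged_potential_V(st, y[:, None]) == pytest.approx(
            sp.potential_V_susceptible(sus_model, y), rel=1e-12)
        assert sp.staged_potential_U(st, th[:, None]) == pytest.approx(
            sp.potential_U_susceptible(sus_model, th), rel=1e-12)

    def test_homogeneous_staged_matches_k1_formula(self):
        """The single-group staged potential agrees with the k=1 reduction of
        the group formula at interior points."""
        m = sp.validate_model([1.0], [1.0], [1.0], beta=1.5, gamma=1.0)
        st = StagedModel(base=m, s=2)
        y = np.array([[0.08, 0.05]])
        # direct evaluation of the stage-resolved closed form, k=1
        r = m.beta / (2 * m.gamma)
        tot = y.sum()
        expected = (float(np.sum(y * (1 + np.log(y) - np.log(r))))
                    - tot * np.log(tot) + (1 - tot) * np.log(1 - tot))
        assert sp.staged_potential_V(st, y) == pytest.approx(expected,
                                                             rel=1e-12)


class TestHeterogeneityMonotonicity:
    def test_robin_hood_transfers_increase_action(self):
        """Flattening the heterogeneous vector (mean-preserving Robin-Hood
        transfer) can only increase the persistence exponent."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            k = int(rng.integers(2, 5))
            f = rng.dirichlet(np.full(k, 4.0))
            v = np.exp(rng.normal(0, 0.4, k))
            v = v / (f @ v)
            i, j = rng.choice(k, size=2, replace=False)
            if v[i] < v[j]:
                i, j = j, i
            gap_amount = sp.max_safe_amount(v, f, int(i), int(j)) \
                * rng.uniform(0.1, 1.0)
            x, xp = sp.robin_hood_pair(v, f, gap_amount, int(i), int(j))
            mode = "lam" if checked % 2 == 0 else "mu"
            beta = 1.3  # R0 = 1.3 with the flat partner vector
            if mode == "lam":
                m_more = sp.validate_model(f, x, np.ones(k), beta, 1.0)
                m_less = sp.validate_model(f, xp, np.ones(k), beta, 1.0,
                                           normalise=True)
            else:
                m_more = sp.validate_model(f, np.ones(k), x, beta, 1.0)
                m_less = sp.validate_model(f, np.ones(k), xp, beta, 1.0,
                                           normalise=True)
            assert sp.action_explicit(m_less).A >= \
                sp.action_explicit(m_more).A - 1e-12
            checked += 1

    def test_homogeneous_maximises_action(self):
        for seed in range(20):
            m = sp.random_model(3, 1.4, "infectivity" if seed % 2 else
                                "susceptibility", seed=seed)
            assert sp.action_explicit(m).A <= sp.action_homogeneous(1.4) + 1e-12

    def test_monotone_along_transfer_chain(self):
        f = np.array([0.25, 0.25, 0.25, 0.25])
        v = np.array([2.0, 1.2, 0.5, 0.3])
        actions = []
        for _ in range(4):
            m = sp.validate_model(f, v, np.ones(4), beta=1.25, gamma=1.0,
                                  normalise=True)
            actions.append(sp.action_explicit(m).A)
            i, j = int(np.argmax(v)), int(np.argmin(v))
            amount = min(0.02, 0.9 * sp.max_safe_amount(v, f, i, j))
            _, v = sp.robin_hood_pair(v, f, amount, i, j)
        assert np.all(np.diff(actions) >= -1e-12)
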