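"""Reaction rates, reduced ODE right-hand side, and the analytic Jacobian."""

import numpy as np
import pytest

import nfkb_btrcp as nb
from nfkb_btrcp.model import (
    NFKB_POOLS,
    ODE_SPECIES,
    SPECIES,
    _NUCLEAR,
    ConfigurationError,
    DomainError,
)

from conftest import random_conserved_state

TNF_ON = nb.Stimulus(tnf=1, btrcp_nM=1.0)
TNF_OFF = nb.Stimulus(tnf=0, btrcp_nM=1.0)


class TestReactionRates:
    def test_zero_state_only_constitutive_ikk_production(self, params):
        """With every species absent only de-novo IKK synthesis proceeds."""
        rates = nb.reaction_rates(nb.StateVector(np.zeros(15)), params, TNF_OFF)
        assert rates[0] > 0
        assert np.all(rates[1:] == 0)

    def test_rates_nonnegative_at_random_states(self, params):
        rng = np.random.default_rng(7)
        for _ in range(10):
            s = random_conserved_state(params, rng)
            assert np.all(nb.reaction_rates(s, params, TNF_ON) >= 0)

    def test_btrcp_zero_silences_ikb_degradation(self, params):
        """Reactions 8 and 10 vanish exactly without β-TrCP."""
        s = random_conserved_state(params, np.random.default_rng(1))
        r = nb.reaction_rates(s, params, nb.Stimulus(tnf=1, btrcp_nM=0.0))
        assert r[7] == 0.0 and r[9] == 0.0

    @pytest.mark.parametrize("level", [0.3, 1.7])
    def test_btrcp_scaling_is_linear(self, params, level):
        """rate(β-TrCP) = β-TrCP/1nM × base-model rate, reactions 8/10 only."""
        s = random_conserved_state(params, np.random.default_rng(2))
        r_base = nb.reaction_rates(s, params, nb.Stimulus(tnf=1, btrcp_nM=1.0))
        r = nb.reaction_rates(s, params, nb.Stimulus(tnf=1, btrcp_nM=level))
        assert r[7] == pytest.approx(level * r_base[7], rel=1e-12)
        assert r[9] == pytest.approx(level * r_base[9], rel=1e-12)
        others = [i for i in range(28) if i not in (7, 9)]
        np.testing.assert_allclose(r[others], r_base[others], rtol=0)

    def test_tnf_gates_activation_and_a20_inactivation(self, params):
        """Reactions 3 and 26 scale linearly with the TNF indicator."""
        s = random_conserved_state(params, np.random.default_rng(3))
        r_on = nb.reaction_rates(s, params, TNF_ON)
        r_off = nb.reaction_rates(s, params, TNF_OFF)
        assert r_off[2] == 0.0 and r_off[25] == 0.0
        assert r_on[2] > 0 and r_on[25] > 0
        others = [i for i in (0, 1, 3, 4, 5, 6, 7, 8, 9)]
        np.testing.assert_allclose(r_on[others], r_off[others], rtol=0)

    def test_negative_concentration_rejected(self, params):
        v = np.zeros(15)
        v[0] = -1.0
        with pytest.raises(DomainError, match="negative"):
            nb.reaction_rates(nb.StateVector(v), params, TNF_ON)


class TestOdeRhs:
    def test_nfkb_conservation_weighted_derivative_sum_is_zero(self, params):
        """The five NF-κB pools exchange material but never create it."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = random_conserved_state(params, rng)
            d = nb.species_derivatives(s, params, TNF_ON)
            tot = sum(
                (1.0 / params.kv if sp in _NUCLEAR else 1.0) * d[SPECIES.index(sp)]
                for sp in NFKB_POOLS
            )
            assert abs(tot) < 1e-12 * np.max(np.abs(d))

    def test_rhs_vanishes_at_unstimulated_steady_state(self, params, unstim_ss):
        d = nb.ode_rhs(unstim_ss, params, TNF_OFF)
        # 1e-10 µM/s residual bound on the internal scale -> nM/min
        assert np.max(np.abs(d)) < 1e-10 * 1e3 * 60

    def test_ikb_mrna_drives_ikb_protein_production(self, params, unstim_ss):
        """More IκB transcript strictly raises the IκB protein derivative."""
        d0 = nb.ode_rhs(unstim_ss, params, TNF_OFF)
        bumped = unstim_ss.values.copy()
        bumped[SPECIES.index("IkBat")] *= 2.0
        d1 = nb.ode_rhs(nb.StateVector(bumped), params, TNF_OFF)
        i = ODE_SPECIES.index("IkBa")
        assert d1[i] > d0[i]


class TestJacobian:
    def _fd_jacobian(self, state, params, stim):
        """Central finite differences of ode_rhs over the integrated species."""
        J = np.zeros((14, 14))
        for j, sp in enumerate(ODE_SPECIES):
            k = SPECIES.index(sp)
            h = 1e-6 * max(abs(state.values[k]), 1.0)
            for sgn in (+1, -1):
                v = state.values.copy()
                v[k] += sgn * h
                J[:, j] += sgn * nb.ode_rhs(nb.StateVector(v), params, stim) / (2 * h)
        return J

    def test_matches_finite_differences_at_random_states(self, params):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = random_conserved_state(params, rng)
            J = nb.jacobian_matrix(s, params, TNF_ON)
            F = self._fd_jacobian(s, params, TNF_ON)
            # entrywise 1e-4 relative, with a floor for FD rounding noise
            # (the rate laws are bilinear, so central differences are exact
            # up to floating-point cancellation)
            tol = 1e-4 * np.abs(F) + 1e-5 * np.max(np.abs(F))
            assert np.max(np.abs(J - F) - tol) <= 0

    def test_linear_degradation_on_diagonal_at_zero_state(self, params):
        """A species entering only linear decay shows −k_deg on its diagonal."""
        J = nb.jacobian_matrix(nb.StateVector(np.zeros(15)), params, TNF_OFF)
        i = ODE_SPECIES.index("cgent")
        # cgen mRNA decays with c3c (per second; Jacobian is per minute)
        assert J[i, i] == pytest.approx(-params.c3c * 60.0, rel=1e-12)
        # its only other dependence is transcription driven by nuclear NF-κB
        row = J[i].copy()
        row[i] = 0.0
        row[ODE_SPECIES.index("NFkBn")] = 0.0
        assert np.all(row == 0.0)
        assert J[i, ODE_SPECIES.index("NFkBn")] == pytest.approx(
            params.c1c * 60.0, rel=1e-12)

    def test_btrcp_zero_removes_degradation_coupling(self, params):
        """At β-TrCP = 0 the Jacobian equals the base form with t-rates zeroed."""
        s = random_conserved_state(params, np.random.default_rng(8))
        J0 = nb.jacobian_matrix(s, params, nb.Stimulus(tnf=1, btrcp_nM=0.0))
        J1 = nb.jacobian_matrix(s, params, TNF_ON)
        i_ikka = ODE_SPECIES.index("IKKa")
        i_tk = ODE_SPECIES.index("IKKa_IkBa")
        i_tkn = ODE_SPECIES.index("IKKa_IkBa_NFkB")
        # the t1/t2 couplings disappear ...
        assert J0[i_ikka, i_tk] == 0.0 and J0[i_ikka, i_tkn] == 0.0
        assert J0[i_tk, i_tk] == 0.0 and J0[i_tkn, i_tkn] == 0.0
        assert J1[i_tk, i_tk] < 0 and J1[i_tkn, i_tkn] < 0
        # ... and every entry not involving reactions 8/10 is untouched
        mask = np.ones((14, 14), dtype=bool)
        for (i, j) in [(i_ikka, i_tk), (i_ikka, i_tkn), (i_tk, i_tk),
                       (i_tkn, i_tkn)]:
            mask[i, j] = False
        np.testing.assert_array_equal(J0[mask], J1[mask])


class TestParameterSet:
    def test_missing_parameter_named_in_error(self, params):
        d = params.to_dict()
        d.pop("a1")
        with pytest.raises(ConfigurationError, match="a1"):
            nb.ParameterSet.from_dict(d)

    def test_extra_parameter_rejected(self, params):
        d = params.to_dict()
        d["k99"] = 1.0
        with pytest.raises(ConfigurationError, match="k99"):
            nb.ParameterSet.from_dict(d)

    def test_negative_rate_constant_rejected(self, params):
        d = params.to_dict()
        d["kdeg"] = -1.0
        with pytest.raises(ConfigurationError, match="kdeg"):
            nb.ParameterSet.from_dict(d)

    def test_state_conservation_validation(self, params, unstim_ss):
        unstim_ss.validate(params)  # consistent state passes
        v = unstim_ss.values.copy()
        v[SPECIES.index("NFkB")] += 5.0
        with pytest.raises(DomainError, match="conservation"):
            nb.StateVector(v).validate(params)
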