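"""Forward-model tests: dilution, equilibrium solvers, heats, fold ratios."""

import numpy as np
import pytest
from dataclasses import replace

from itcmix.models import (
    R_GAS,
    InvalidProtocolError,
    Parameters2C,
    ParametersEM,
    TitrationProtocol,
    cell_concentrations,
    ddg_to_fold,
    dilution_factors,
    equilibrium_2c,
    equilibrium_competitive,
    heats,
)

from oracles import complex_2c_bisection, complex_competitive_fixed_point


class TestDilution:
    def test_zero_injection_is_identity(self):
        p = TitrationProtocol([0.0], cell_volume=1e-3)
        assert dilution_factors(p)[0] == 1.0

    def test_closed_form_three_tenth_injections(self):
        p = TitrationProtocol([1e-4] * 3, cell_volume=1e-3)
        assert dilution_factors(p)[-1] == pytest.approx(0.9**3, rel=1e-12)

    def test_matches_sequential_product(self, protocol):
        d = dilution_factors(protocol)
        acc, expected = 1.0, []
        for dv in protocol.injection_volumes:
            acc *= 1.0 - dv / protocol.cell_volume
            expected.append(acc)
        assert np.allclose(d, expected, rtol=1e-14)
        assert np.all(np.diff(d) < 0) and np.all((d > 0) & (d <= 1))

    def test_injection_exceeding_cell_is_invalid(self):
        with pytest.raises(InvalidProtocolError):
            TitrationProtocol([2e-3], cell_volume=1e-3)


class TestCellConcentrations:
    def test_receptor_dilutes_by_dn(self):
        p = TitrationProtocol([1e-4] * 3, cell_volume=1e-3)
        states = cell_concentrations(p, R0=0.05e-3, Ls=1e-3, rho=0.5)
        assert states[-1].total_receptor == pytest.approx(0.05e-3 * 0.9**3)

    def test_rho_zero_gives_no_ligand1(self, protocol):
        for s in cell_concentrations(protocol, 0.05e-3, 1e-3, rho=0.0):
            assert s.total_ligand1 == 0.0
            assert s.total_ligand2 > 0.0

    def test_racemic_symmetry(self, protocol):
        for s in cell_concentrations(protocol, 0.05e-3, 1e-3, rho=0.5):
            assert s.total_ligand1 == pytest.approx(s.total_ligand2, rel=1e-14)

    def test_ligand_accumulates_receptor_decays(self, protocol):
        states = cell_concentrations(protocol, 0.05e-3, 1e-3, rho=0.5)
        rec = [s.total_receptor for s in states]
        lig = [s.total_ligand1 + s.total_ligand2 for s in states]
        assert np.all(np.diff(rec) < 0)
        assert np.all(np.diff(lig) > 0)


class TestEquilibrium2C:
    def test_no_ligand_means_no_complex(self):
        assert equilibrium_2c(5e-5, 0.0, 1e-6) == 0.0

    def test_tight_binding_limit_is_stoichiometric(self):
        rl = equilibrium_2c(0.05e-3, 0.2e-3, 1e-15)
        assert rl == pytest.approx(0.05e-3, rel=1e-9)

    def test_matches_bisection_oracle(self):
        rl = equilibrium_2c(5e-5, 1e-4, 1e-6)
        assert rl == pytest.approx(complex_2c_bisection(5e-5, 1e-4, 1e-6), rel=1e-10)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_2c(-1e-5, 1e-4, 1e-6)

    def test_admissible_root_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            Rt, Lt = rng.uniform(1e-7, 1e-3, 2)
            Kd = 10 ** rng.uniform(-9, -3)
            rl = equilibrium_2c(Rt, Lt, Kd)
            assert 0.0 <= rl <= min(Rt, Lt)


class TestEquilibriumCompetitive:
    def test_reduces_to_single_ligand(self):
        rl1, rl2 = equilibrium_competitive(5e-5, 1e-4, 0.0, 1e-6, 1e-5)
        assert rl2 == 0.0
        assert rl1 == pytest.approx(equilibrium_2c(5e-5, 1e-4, 1e-6), rel=1e-10)

    def test_symmetric_ligands(self):
        rl1, rl2 = equilibrium_competitive(5e-5, 3e-5, 3e-5, 1e-6, 1e-6)
        assert rl1 == pytest.approx(rl2, rel=1e-12)

    def test_matches_fixed_point_oracle(self):
        got = equilibrium_competitive(5e-5, 4e-5, 6e-5, 1e-8, 1e-5)
        want = complex_competitive_fixed_point(5e-5, 4e-5, 6e-5, 1e-8, 1e-5)
        assert got[0] == pytest.approx(want[0], rel=1e-8)
        assert got[1] == pytest.approx(want[1], rel=1e-8)

    def test_mass_balance_and_oracle_on_random_draws(self):
        """Analytic cubic vs iterative mass-action solver, 100 random draws."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            Rt = 10 ** rng.uniform(-6, -3)
            L1t = 10 ** rng.uniform(-7, -3)
            L2t = 10 ** rng.uniform(-7, -3)
            Kd1 = 10 ** rng.uniform(-9, -4)
            Kd2 = 10 ** rng.uniform(-9, -4)
            rl1, rl2 = equilibrium_competitive(Rt, L1t, L2t, Kd1, Kd2)
            o1, o2 = complex_competitive_fixed_point(Rt, L1t, L2t, Kd1, Kd2)
            assert rl1 == pytest.approx(o1, rel=1e-8, abs=1e-20)
            assert rl2 == pytest.approx(o2, rel=1e-8, abs=1e-20)
            # mass balance: R + RL1 + RL2 = Rt and mass action laws
            R = Rt - rl1 - rl2
            assert abs(R * (L1t - rl1) / Kd1 - rl1) / max(rl1, 1e-300) < 1e-8 or rl1 < 1e-18
            assert rl1 + rl2 <= Rt * (1 + 1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_competitive(5e-5, -1e-5, 1e-5, 1e-6, 1e-6)


class TestHeats:
    def test_zero_enthalpies_give_pure_offset(self, protocol):
        theta = ParametersEM(-11.5, 4.0, 0.0, 0.0, 5e-7, 0.05e-3, 1e-3, 0.5, 1e-6)
        q = heats(theta, protocol)
        assert np.allclose(q, 5e-7, atol=1e-18)

    def test_em_rho_one_equals_2c(self, protocol, truth):
        em = replace(truth, rho=1.0)
        tc = Parameters2C(truth.dG1, truth.dH1, truth.dH0, truth.R0, truth.Ls,
                          truth.sigma)
        assert np.allclose(heats(em, protocol), heats(tc, protocol), rtol=1e-10)

    def test_matches_loop_oracle_em(self, protocol, truth):
        from oracles import heats_loop

        def eq(Rt, L1t, L2t):
            Kd1 = np.exp(truth.dG1 / (R_GAS * protocol.temperature))
            Kd2 = np.exp((truth.dG1 + truth.ddG) / (R_GAS * protocol.temperature))
            return complex_competitive_fixed_point(Rt, L1t, L2t, Kd1, Kd2)

        vec = [truth.dG1, truth.ddG, truth.dH1, truth.dH2, truth.dH0,
               truth.R0, truth.Ls, truth.rho, truth.sigma]
        oracle = heats_loop(vec, "EM", protocol.injection_volumes,
                            protocol.cell_volume, protocol.temperature, eq)
        assert np.allclose(heats(truth, protocol), oracle, rtol=1e-7)

    def test_cumulative_heat_approaches_saturation(self, truth):
        """Total heat at saturation ≈ V0 * sum of enthalpies * receptor moles."""
        many = TitrationProtocol(np.full(60, 12e-6))
        q = heats(truth, many)
        total = q.sum() - many.n_injections * truth.dH0
        # at the end both ligands saturate the (diluted) receptor; sequential
        # displacement means total heat is bounded by dH1-driven binding and
        # exceeds the dH2-only bound
        d = np.prod(1 - many.injection_volumes / many.cell_volume)
        assert total < 0
        assert abs(total) < abs(truth.dH1 * 1000 * many.cell_volume * truth.R0)
        assert abs(total) > abs(truth.dH2 * 1000 * many.cell_volume * truth.R0 * d)

    def test_dh0_shift_is_exact(self, protocol, truth):
        q0 = heats(truth, protocol)
        q1 = heats(replace(truth, dH0=truth.dH0 + 1e-6), protocol)
        assert np.allclose(q1 - q0, 1e-6, atol=1e-18)

    def test_monotone_saturation_after_equivalence_2c(self, protocol):
        theta = Parameters2C(-9.0, -10.0, 0.0, 0.05e-3, 1e-3, 1e-6)
        q = np.abs(heats(theta, protocol))
        # equivalence point: ligand total passes receptor total
        d = dilution_factors(protocol)
        eq_idx = int(np.argmax(1e-3 * (1 - d) > 0.05e-3 * d))
        tail = q[eq_idx:]
        assert np.all(np.diff(tail) <= 1e-12)

    def test_model_parameter_mismatch(self, protocol, truth):
        with pytest.raises(ValueError):
            heats(truth, protocol, model="2C")


class TestFoldRatio:
    def test_zero_gap_is_unity(self):
        assert ddg_to_fold(0.0, 298.0) == 1.0

    @pytest.mark.parametrize(
        "ddg, expected, digits",
        [(0.15, 1.3, 1), (4.0, 858.0, 0)],
        ids=["small-gap", "large-gap"],
    )
    def test_printed_conversions(self, ddg, expected, digits):
        assert round(ddg_to_fold(ddg, 298.0), digits) == expected
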