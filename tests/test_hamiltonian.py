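"""Couplings, vibronic Hamiltonian assembly, diagonalization, mixing."""

import numpy as np
import pytest

from excitonuv.fixtures import make_degenerate_dimer
from excitonuv.geometry import ChromophoreSite
from excitonuv.hamiltonian import (ExcitonHamiltonian, assemble_hamiltonian,
                                   classify_mixing, coulomb_coupling_monopole,
                                   diagonalize, dipole_dipole_coupling)
from excitonuv.units import COULOMB_CM_ANG


def _mono(pairs):
    return [{"position": np.asarray(p, float), "charge": q} for p, q in pairs]


class TestMonopoleCoupling:
    def test_brute_force_double_sum(self, rng):
        a = _mono([(rng.normal(size=3), q) for q in (0.1, -0.04, -0.06)])
        b = _mono([(rng.normal(size=3) + 8.0, q) for q in (0.05, -0.05)])
        expected = 0.0
        for ma in a:
            for mb in b:
                r = np.linalg.norm(ma["position"] - mb["position"])
                expected += COULOMB_CM_ANG * ma["charge"] * mb["charge"] / r
        assert coulomb_coupling_monopole(a, b) == pytest.approx(expected)

    def test_zero_charges(self):
        a = _mono([((0, 0, 0), 0.0), ((1, 0, 0), 0.0)])
        b = _mono([((8, 0, 0), 0.1), ((9, 0, 0), -0.1)])
        assert coulomb_coupling_monopole(a, b) == 0.0

    def test_coincident_raises(self):
        a = _mono([((0, 0, 0), 0.1)])
        b = _mono([((0, 0, 0), -0.1)])
        with pytest.raises(ValueError):
            coulomb_coupling_monopole(a, b)

    def test_multipole_limit(self):
        """Separated +-q pairs converge on the point-dipole coupling."""
        q, d = 0.2, 1.0  # |mu| = 0.2 e*A = 0.9606 D along z
        mu = q * d / 0.2081943
        for R in (20.0, 50.0):
            a = _mono([((0, 0, +d / 2), q), ((0, 0, -d / 2), -q)])
            b = _mono([((R, 0, +d / 2), q), ((R, 0, -d / 2), -q)])
            vm = coulomb_coupling_monopole(a, b)
            vd = dipole_dipole_coupling([0, 0, mu], [0, 0, mu], [R, 0, 0])
            assert vm == pytest.approx(vd, rel=0.01)


class TestDipoleCoupling:
    def test_unit_case(self):
        # parallel unit dipoles perpendicular to R at 10 A: kappa = 1
        v = dipole_dipole_coupling([0, 0, 1], [0, 0, 1], [10, 0, 0])
        assert v == pytest.approx(5.034, abs=0.01)

    def test_head_to_tail(self):
        v_par = dipole_dipole_coupling([0, 0, 1], [0, 0, 1], [10, 0, 0])
        v_ht = dipole_dipole_coupling([1, 0, 0], [1, 0, 0], [10, 0, 0])
        assert v_ht == pytest.approx(-2.0 * v_par, rel=1e-9)

    def test_zero_separation(self):
        with pytest.raises(ValueError):
            dipole_dipole_coupling([0, 0, 1], [0, 0, 1], [0, 0, 0])


def _two_tyr_sites(tyr_params, separation=8.0):
    from excitonuv.geometry import attach_transitions

    sites = []
    for i in range(2):
        s = ChromophoreSite(f"A{i + 1}", "TYR",
                            np.array([separation * i, 0.0, 0.0]), np.eye(3))
        attach_transitions(s, tyr_params)
        sites.append(s)
    return sites


class TestAssemble:
    def test_fc_product_rule(self, tyr_params):
        """A 24.1 cm^-1 electronic Tyr-Tyr coupling becomes ~7 cm^-1
        between the two 0-0 vibronic lines (x 0.5386^2) in the
        single-ring-breathing-mode model."""
        import copy

        tyr_params = copy.deepcopy(tyr_params)
        tyr_params["transitions"]["L_b"]["modes"] = [[800.0, 990.0, "u"]]
        sites = _two_tyr_sites(tyr_params)
        H = assemble_hamiltonian(
            sites, vibronic_cutoff=3200.0,
            couplings={((0, "L_b"), (1, "L_b")): 24.1})
        i00 = [k for k, b in enumerate(H.basis)
               if b.site_index == 0 and b.label == "L_b"
               and b.level.quanta == (0,)][0]
        j00 = [k for k, b in enumerate(H.basis)
               if b.site_index == 1 and b.label == "L_b"
               and b.level.quanta == (0,)][0]
        assert H.matrix[i00, j00] == pytest.approx(24.1 * 0.5386 ** 2, abs=0.05)
        assert H.matrix[i00, j00] == pytest.approx(7.0, abs=0.1)

    def test_forster_mode_zeroes_interaromatic(self, tyr_params):
        sites = _two_tyr_sites(tyr_params)
        H = assemble_hamiltonian(sites, zero_classes=("TYR-TYR",),
                                 vibronic_labels=())
        off = H.matrix - np.diag(np.diag(H.matrix))
        assert np.all(off == 0.0)

    def test_single_site_diagonal(self, tyr_params):
        sites = _two_tyr_sites(tyr_params)[:1]
        H = assemble_hamiltonian(sites, vibronic_cutoff=3200.0)
        n_lb = sum(1 for b in H.basis if b.label == "L_b")
        assert n_lb == 9  # intra-site vibronic states uncoupled
        off = H.matrix - np.diag(np.diag(H.matrix))
        assert np.all(off == 0.0)

    def test_diagonal_energies(self, tyr_params):
        sites = _two_tyr_sites(tyr_params)
        H = assemble_hamiltonian(sites, vibronic_cutoff=3200.0)
        for k, b in enumerate(H.basis):
            assert H.matrix[k, k] == pytest.approx(b.energy)

    def test_round_trip(self, tyr_params, tmp_path):
        sites = _two_tyr_sites(tyr_params)
        H = assemble_hamiltonian(sites, vibronic_cutoff=1600.0)
        H.save(tmp_path / "h.txt", tmp_path / "h.json")
        H2 = ExcitonHamiltonian.load(tmp_path / "h.txt", tmp_path / "h.json")
        assert np.allclose(H.matrix, H2.matrix)
        assert all(a.level.quanta == b.level.quanta
                   and a.energy == pytest.approx(b.energy)
                   for a, b in zip(H.basis, H2.basis))


class TestDiagonalize:
    def test_degenerate_dimer_closed_form(self):
        H = make_degenerate_dimer(0.0, 7.0, energy=34_965.0)
        states = diagonalize(H)
        assert states[0].energy == pytest.approx(34_958.0)
        assert states[1].energy == pytest.approx(34_972.0)
        for st in states:
            assert np.allclose(np.abs(st.coefficients),
                               [0.70710678, 0.70710678], atol=1e-9)

    def test_detuned_dimer_coefficient(self):
        """Delta = 11.06, V = 7: the 0.90-coefficient boundary case."""
        H = make_degenerate_dimer(0.0, 7.0)
        M = H.matrix.copy()
        M[0, 0] += 11.06 / 2
        M[1, 1] -= 11.06 / 2
        for k, b in enumerate(H.basis):
            b.energy = M[k, k]
        H2 = ExcitonHamiltonian(H.basis, M)
        states = diagonalize(H2)
        assert np.abs(states[0].coefficients).max() == pytest.approx(0.900, abs=2e-3)

    def test_zero_coupling_localized(self):
        H = make_degenerate_dimer(30.0, 0.0)
        H.matrix[0, 0] += 50.0
        H.basis[0].energy += 50.0
        states = diagonalize(ExcitonHamiltonian(H.basis, H.matrix))
        for st in states:
            assert np.abs(st.coefficients).max() == pytest.approx(1.0)
            assert st.mixing_class == "localized"

    def test_dipole_strength_conserved(self, tyr_params):
        sites = _two_tyr_sites(tyr_params)
        H = assemble_hamiltonian(sites, vibronic_cutoff=3200.0)
        states = diagonalize(H)
        site_total = sum(np.dot(b.mu, b.mu) for b in H.basis)
        exc_total = sum(np.dot(st.mu, st.mu) for st in states)
        assert exc_total == pytest.approx(site_total, rel=1e-9)
        assert sum(st.energy for st in states) == pytest.approx(
            np.trace(H.matrix), rel=1e-12)


class TestClassifyMixing:
    def test_degenerate_is_strong(self):
        states = diagonalize(make_degenerate_dimer(20.0, 7.0))
        assert all(st.mixing_class == "strong" for st in states)

    @pytest.mark.parametrize("cmax, expected", [
        (0.80, "strong"), (0.90, "strong"), (0.95, "weak"),
        (0.9991, "localized")])
    def test_intervals(self, cmax, expected):
        from excitonuv.hamiltonian import ExcitonState

        c2 = cmax ** 2
        st = ExcitonState(0.0, np.array([cmax, np.sqrt(1 - c2)]),
                          np.zeros(3), np.zeros(3),
                          np.array([c2, 1 - c2]))
        assert classify_mixing(st) == expected
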