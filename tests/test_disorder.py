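"""Static disorder: sampling, mixing statistics, state filtering,
snapshot selection, fluctuation emulation."""

import numpy as np
import pytest
from scipy.stats import norm

from excitonuv.cd import CDSpectrum, default_grid
from excitonuv.disorder import (DisorderModel, ehef_emulator, filter_states,
                                mixing_fraction, read_shift_table,
                                run_ensemble, sample_site_energies,
                                select_snapshots, write_shift_table)
from excitonuv.fixtures import make_degenerate_dimer, make_reference_cd
from excitonuv.lineshape import SpectralDensity
from excitonuv.units import EV_CM


class TestSampling:
    def test_zero_sigma(self):
        sh = sample_site_energies(DisorderModel(0.0, 10, 1), 3)
        assert np.all(sh == 0.0)

    def test_moments(self):
        model = DisorderModel(100.0, 4000, 7)
        sh = sample_site_energies(model, 2)
        n = sh.size
        assert abs(sh.mean()) < 3 * 100.0 / np.sqrt(n)
        assert abs(sh.std() - 100.0) < 3 * 100.0 / np.sqrt(2 * n)

    def test_seed_reproducible(self):
        a = sample_site_energies(DisorderModel(100.0, 5, 11), 2)
        b = sample_site_energies(DisorderModel(100.0, 5, 11), 2)
        assert np.array_equal(a, b)

    def test_variance_literal_switch(self):
        m = DisorderModel(10_000.0, 5, 1, variance_literal=True)
        assert m.std == pytest.approx(100.0)


class TestMixingFraction:
    def test_degenerate_always_strong(self):
        H = make_degenerate_dimer(40.0, 7.0)
        assert mixing_fraction(H, DisorderModel(0.0, 50, 1)) == 100.0

    def test_uncoupled_never_strong(self):
        H = make_degenerate_dimer(40.0, 0.0)
        assert mixing_fraction(H, DisorderModel(100.0, 200, 1)) == 0.0

    def test_analytic_two_site_oracle(self):
        """Monte-Carlo strong-mixing fraction agrees with
        2 Phi(1.580 V / (sigma sqrt(2))) - 1 within 3 standard errors."""
        V, sigma, n = 7.0, 100.0, 10_000
        H = make_degenerate_dimer(40.0, V)
        mc = mixing_fraction(H, DisorderModel(sigma, n, 42)) / 100.0
        p = 2.0 * norm.cdf(1.5806 * V / (sigma * np.sqrt(2.0))) - 1.0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(mc - p) < 3.0 * se

    def test_monotone_in_coupling(self):
        model = DisorderModel(100.0, 2000, 5)
        fr = [mixing_fraction(make_degenerate_dimer(40.0, V), model)
              for V in (2.0, 7.0, 20.0)]
        assert fr[0] < fr[1] < fr[2]


class TestEnsemble:
    def test_zero_sigma_reduces_to_degenerate(self):
        H = make_degenerate_dimer(70.0, 7.0)
        sd = SpectralDensity(300.0, 85.0, [])
        kw = {"n_t": 128, "dt_fs": 4.0}
        res = run_ensemble(H, sd, DisorderModel(0.0, 3, 1),
                           response_kwargs=kw)
        assert res.fraction_strong_mixing == 100.0
        from excitonuv.response import response_2d
        direct = response_2d(H, sd, schemes=("xxxx",
                                             {"xxxx": 1.0, "xxyy": -3.0}), **kw)
        ref = next(iter(direct.values()))
        got = res.mean_maps[next(iter(res.mean_maps))]
        assert np.allclose(got.values, ref.values)
        assert res.relative_combo_intensity == pytest.approx(
            100.0 * list(direct.values())[1].max_abs() / ref.max_abs())

    def test_uncoupled_limit_zero_combo(self):
        H = make_degenerate_dimer(70.0, 0.0)
        sd = SpectralDensity(300.0, 85.0, [])
        res = run_ensemble(H, sd, DisorderModel(100.0, 4, 2),
                           response_kwargs={"n_t": 128, "dt_fs": 4.0})
        assert res.fraction_strong_mixing == 0.0
        assert res.relative_combo_intensity == pytest.approx(0.0, abs=1e-9)

    def test_seed_reproducible(self):
        H = make_degenerate_dimer(70.0, 7.0)
        sd = SpectralDensity(300.0, 85.0, [])
        kw = {"n_t": 64, "dt_fs": 6.0}
        r1 = run_ensemble(H, sd, DisorderModel(100.0, 3, 9), response_kwargs=kw)
        r2 = run_ensemble(H, sd, DisorderModel(100.0, 3, 9), response_kwargs=kw)
        m1 = r1.mean_maps[next(iter(r1.mean_maps))]
        m2 = r2.mean_maps[next(iter(r2.mean_maps))]
        assert np.array_equal(m1.values, m2.values)


class TestEhefEmulator:
    def test_pure_gaussian(self):
        out = ehef_emulator(4, 150.0, 100, outlier_rate=0.0, seed=3)
        assert not out["outlier_mask"].any()
        assert abs(out["shifts"].std() - 150.0) < 30.0
        assert out["meta"]["synthetic"] is True

    def test_all_outliers(self):
        out = ehef_emulator(2, 50.0, 200, outlier_rate=1.0,
                            outlier_scale=3.0 * EV_CM, seed=4)
        assert out["outlier_mask"].all()
        assert out["shifts"].std() > 10_000.0  # ~3 eV class shifts

    def test_seeded(self):
        a = ehef_emulator(3, 100.0, 10, 0.1, seed=5)["shifts"]
        b = ehef_emulator(3, 100.0, 10, 0.1, seed=5)["shifts"]
        assert np.array_equal(a, b)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            ehef_emulator(2, 100.0, 10, outlier_rate=1.5)

    def test_shift_table_round_trip(self, tmp_path):
        sh = ehef_emulator(3, 100.0, 5, seed=6)["shifts"]
        p = tmp_path / "shifts.tsv"
        write_shift_table(sh, p)
        back = read_shift_table(p)
        assert np.allclose(sh, back, atol=1e-6)


class TestFilterStates:
    def test_identity_without_outliers(self):
        H = make_degenerate_dimer(70.0, 7.0)
        H2 = filter_states(H, max_shift=1.0 * EV_CM,
                           nominal_energies=[b.energy for b in H.basis])
        assert H2.n == H.n

    def test_outlier_removed(self):
        H = make_degenerate_dimer(70.0, 7.0)
        nominal = [b.energy for b in H.basis]
        Hs = H.shifted([3.0 * EV_CM, 0.0])
        H2 = filter_states(Hs, max_shift=1.0 * EV_CM,
                           nominal_energies=nominal)
        assert H2.n == 1
        assert H2.basis[0].site_index == 1

    def test_type_filter(self, fixture_dir, all_params):
        from excitonuv.geometry import read_pdb
        from excitonuv.hamiltonian import assemble_hamiltonian
        from excitonuv.io import sites_with_parameters

        sites = sites_with_parameters(read_pdb(fixture_dir / "protein.pdb"),
                                      all_params)
        H = assemble_hamiltonian(sites, vibronic_labels=())
        H2 = filter_states(H, drop_types=("AMIDE",))
        kinds = {b.residue_type for b in H2.basis}
        assert kinds <= {"TYR", "PHE"}
        n_sites = len({b.site_index for b in H2.basis})
        assert n_sites == 8

    def test_empty_result_raises(self):
        H = make_degenerate_dimer(70.0, 7.0)
        with pytest.raises(ValueError):
            filter_states(H, drop_types=("TYR",))


class TestSelectSnapshots:
    def _spectra(self, n, rng):
        g = default_grid()
        return [CDSpectrum(g, rng.normal(size=g.size)) for _ in range(n)]

    def test_k_equals_n(self, rng):
        sp = self._spectra(5, rng)
        assert sorted(select_snapshots(sp, make_reference_cd(), k=5)) == list(range(5))

    def test_self_reference_ranks_first(self, rng):
        sp = self._spectra(10, rng)
        chosen = select_snapshots(sp, sp[7], k=3)
        assert chosen[0] == 7

    def test_counts_and_order(self, rng):
        from excitonuv.cd import cd_rmsd

        sp = self._spectra(50, rng)
        ref = make_reference_cd()
        chosen = select_snapshots(sp, ref, k=20)
        assert len(chosen) == 20
        dists = [cd_rmsd(sp[i], ref) for i in chosen]
        assert dists == sorted(dists)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            select_snapshots(self._spectra(3, rng), make_reference_cd(), k=4)
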