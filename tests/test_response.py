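"""2D response maps: peak structure, polarization combinations,
additivity, narrowband restriction."""

import numpy as np
import pytest

from excitonuv.fixtures import make_degenerate_dimer
from excitonuv.hamiltonian import ExcitonHamiltonian, SiteBasisState
from excitonuv.lineshape import SpectralDensity
from excitonuv.response import (Map2D, combine_polarizations,
                                narrowband_restrict, relative_intensity,
                                response_2d)
from excitonuv.vibronic import VibMode, VibronicLevel

LV = VibronicLevel((), 0.0, 1.0)
SD = SpectralDensity(300.0, 85.0, [])
SCHEMES = ("xxxx", {"xxxx": 1.0, "xxyy": -3.0})
FAST = dict(n_t=256, dt_fs=4.0)


def single_site(energy=34_965.0):
    b = [SiteBasisState(0, "L_b", LV, energy, np.array([1.1, 0, 0]),
                        np.zeros(3), None, np.zeros(3), "TYR")]
    return ExcitonHamiltonian(b, np.array([[energy]]))


class TestSingleChromophore:
    def test_single_diagonal_peak_and_combo_null(self):
        maps = response_2d(single_site(), SD, schemes=SCHEMES, **FAST)
        xxxx, combo = maps.values()
        assert combo.max_abs() == 0.0  # exact single-site cancellation
        i, j = np.unravel_index(np.argmax(xxxx.real), xxxx.real.shape)
        # one positive diagonal peak near the site energy (the overdamped
        # bath skews it to the red by a fraction of its reorganization)
        assert abs(xxxx.w1[i] - 34_965.0) < 300.0
        assert abs(xxxx.w3[j] - 34_965.0) < 400.0
        assert xxxx.real[i, j] > 0

    def test_nonzero_t2_rejected(self):
        with pytest.raises(NotImplementedError):
            response_2d(single_site(), SD, t2_fs=100.0, **FAST)

    def test_peak_at_eigenenergy_with_weak_bath(self):
        """With a weak bath the diagonal peak coincides with the
        eigenenergy within a grid step."""
        weak = SpectralDensity(15.0, 85.0, [])
        m = response_2d(single_site(), weak, schemes=("xxxx",),
                        n_t=512, dt_fs=2.0)["xxxx"]
        i, j = np.unravel_index(np.argmax(m.real), m.real.shape)
        step = m.w1[1] - m.w1[0]
        assert abs(m.w1[i] - 34_965.0) <= 1.5 * step + 15.0
        assert abs(m.w3[j] - 34_965.0) <= 1.5 * step + 15.0


class TestAdditivity:
    def test_uncoupled_pair_equals_single(self):
        """Two identical uncoupled Tyr give the single-Tyr map after the
        per-Tyr renormalization (cross pathways cancel exactly)."""
        b = [SiteBasisState(i, "L_b", LV, 34_965.0,
                            1.1 * np.array([np.cos(0.6 * i), np.sin(0.6 * i), 0]),
                            np.zeros(3), None, np.array([7.0 * i, 0, 0]), "TYR")
             for i in range(2)]
        H2 = ExcitonHamiltonian(b, np.diag([34_965.0, 34_965.0]))
        m2 = response_2d(H2, SD, schemes=("xxxx",), **FAST)["xxxx"]
        m1 = response_2d(single_site(), SD, schemes=("xxxx",), **FAST)["xxxx"]
        assert np.allclose(m2.values, m1.values,
                           atol=1e-10 * np.abs(m1.values).max())


class TestDimerCombo:
    def test_parallel_dimer_combo_dark(self):
        """Exactly parallel degenerate dipoles: one exciton carries all
        the oscillator strength, the combo map vanishes identically."""
        H = make_degenerate_dimer(0.0, 7.0)
        maps = response_2d(H, SD, schemes=SCHEMES, **FAST)
        _, combo = maps.values()
        assert combo.max_abs() == 0.0

    def test_angle_ordering(self):
        """The relative combo intensity at 70 deg strictly exceeds the
        10 deg one for the same coupling."""
        ratios = {}
        for ang in (10.0, 70.0):
            maps = response_2d(make_degenerate_dimer(ang, 7.0), SD,
                               schemes=SCHEMES, **FAST)
            xxxx, combo = maps.values()
            ratios[ang] = relative_intensity(combo, xxxx)
        assert ratios[70.0] > 5.0 * ratios[10.0]

    def test_map_scales_with_mu4(self):
        m1 = response_2d(make_degenerate_dimer(70.0, 7.0, mu=1.0), SD,
                         schemes=("xxxx",), **FAST)["xxxx"]
        m2 = response_2d(make_degenerate_dimer(70.0, 7.0, mu=2.0), SD,
                         schemes=("xxxx",), **FAST)["xxxx"]
        assert np.allclose(m2.values, 16.0 * m1.values, rtol=1e-9)


class TestVibronicProgression:
    def test_diagonal_peaks_of_single_tyr(self):
        """A single Tyr with the 800 cm^-1 mode shows diagonal peaks at
        the 0-0, 0-1 and 0-2 lines, the 0-1 line strongest."""
        sd = SpectralDensity(300.0, 85.0, [VibMode(800.0, 990.0, "u")])
        H = single_site(energy=34_965.0 + 990.0)  # vertical energy
        m = response_2d(H, sd, schemes=("xxxx",), n_t=512, dt_fs=2.0)["xxxx"]
        peaks = {}
        for tgt in (34_965.0, 35_765.0, 36_565.0):
            sel = (np.abs(m.w1 - tgt) < 250.0)
            sub = m.real[np.ix_(sel, sel)]
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            peaks[tgt] = (m.w1[sel][i], sub[i, j])
        for tgt, (pos, val) in peaks.items():
            assert abs(pos - tgt) < 120.0
            assert val > 0
        assert peaks[35_765.0][1] == max(v for _, v in peaks.values())


class TestCombineAndRestrict:
    def test_combine_weights(self):
        H = make_degenerate_dimer(70.0, 7.0)
        maps = response_2d(H, SD, schemes=("xxxx", "xxyy"), **FAST)
        a, b = maps["xxxx"], maps["xxyy"]
        c = combine_polarizations(a, b, (1.0, 0.0))
        assert np.allclose(c.values, a.values)
        c = combine_polarizations(a, b, (1.0, -3.0))
        assert np.allclose(c.values, a.values - 3.0 * b.values)
        # pathway-level combination agrees with map-level combination
        direct = response_2d(H, SD, schemes=({"xxxx": 1.0, "xxyy": -3.0},),
                             **FAST)
        assert np.allclose(next(iter(direct.values())).values, c.values,
                           atol=1e-12 * a.max_abs())

    def test_combine_grid_mismatch(self):
        H = make_degenerate_dimer(70.0, 7.0)
        a = response_2d(H, SD, schemes=("xxxx",), **FAST)["xxxx"]
        b = response_2d(H, SD, schemes=("xxxx",), n_t=128, dt_fs=4.0)["xxxx"]
        with pytest.raises(ValueError):
            combine_polarizations(a, b)

    def test_narrowband_window(self, tyr_params):
        from excitonuv.geometry import ChromophoreSite, attach_transitions
        from excitonuv.hamiltonian import assemble_hamiltonian

        sites = []
        for i in range(2):
            s = ChromophoreSite(f"A{i}", "TYR", np.array([8.0 * i, 0, 0]),
                                np.eye(3))
            attach_transitions(s, tyr_params)
            sites.append(s)
        H = assemble_hamiltonian(sites, vibronic_cutoff=3200.0)
        H00 = narrowband_restrict(H, 34_965.0, 400.0)
        assert H00.n == 2
        assert all(b.level.quanta == (0, 0) for b in H00.basis)
        # window covering everything is the identity
        Hall = narrowband_restrict(H, 45_000.0, 1e6)
        assert Hall.n == H.n
        with pytest.raises(ValueError):
            narrowband_restrict(H, 20_000.0, 10.0)

    def test_hdf5_round_trip(self, tmp_path):
        m = response_2d(single_site(), SD, schemes=("xxxx",), **FAST)["xxxx"]
        p = tmp_path / "map.h5"
        m.save_hdf5(p)
        m2 = Map2D.load_hdf5(p)
        assert np.allclose(m.values, m2.values)
        assert np.allclose(m.w1, m2.w1)
        assert m2.scheme == "xxxx"

    def test_threshold(self):
        m = response_2d(make_degenerate_dimer(70.0, 7.0), SD,
                        schemes=("xxxx",), **FAST)["xxxx"]
        t = m.apply_threshold(0.5)
        nz = np.abs(t.values.real) > 0
        assert nz.sum() < (np.abs(m.values.real) > 0).sum()
        assert np.abs(t.values.real[nz]).min() >= 0.5 * m.max_abs()


class TestLinearMarginalConsistency:
    def test_diagonal_projection_matches_linear_absorption(self):
        """Summing the 2D map over w1 gives a curve whose peak coincides
        with the linear absorption maximum."""
        from excitonuv.lineshape import evaluate_g, linear_absorption
        from excitonuv.units import fs_to_x

        m = response_2d(single_site(), SD, schemes=("xxxx",),
                        n_t=512, dt_fs=2.0)["xxxx"]
        proj = m.real.sum(axis=0)
        x = fs_to_x(2.0) * np.arange(512)
        gfun = lambda xx: evaluate_g(SD, 300.0, xx)
        nu, sig = linear_absorption([34_965.0], [1.0], [gfun], x)
        p2d = m.w3[np.argmax(proj)]
        plin = nu[np.argmax(sig)]
        assert abs(p2d - plin) < 60.0
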