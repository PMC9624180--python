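"""|E| normalization, the three-stage selection, Wilson fit, X and |X_m|."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sadsmar as s
from sadsmar import pipeline, preprocess
from sadsmar.gridfft import grid_shape
from sadsmar.preprocess import assign_shells, normalize_E, select_dset


def wilson_set(n=4000, seed=0, scale=1.0, spacegroup="P 1"):
    """Acentric Wilson-statistics amplitudes: |F|^2 exponential."""
    rng = np.random.default_rng(seed)
    # all hemisphere indices in a box, subsampled to n
    box = np.array([(h, k, l) for h in range(-17, 18)
                    for k in range(-17, 18) for l in range(1, 18)])
    if n > len(box):
        raise ValueError("n too large for index box")
    hkl = box[rng.choice(len(box), size=n, replace=False)]
    hkl = hkl[np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))]
    f = scale * np.sqrt(rng.exponential(100.0, len(hkl)))
    d = np.abs(rng.normal(0, 0.05 * 100.0**0.5, len(hkl)))
    return s.ReflectionSet(
        cell=gemmi.UnitCell(50, 50, 50, 90, 90, 90), spacegroup=spacegroup,
        wavelength=1.0, hkl=hkl, f_plus=f + d / 2, sig_plus=np.ones(len(hkl)),
        f_minus=f - d / 2, sig_minus=np.ones(len(hkl)))


class TestNormalizeE:
    def test_uniform_amplitudes_give_unit_E(self):
        f = np.full(200, 7.0)
        e = normalize_E(f, np.ones(200), np.zeros(200, dtype=int))
        np.testing.assert_allclose(e, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(1, 50, 300)
        sid = np.repeat(np.arange(3), 100)
        e1 = normalize_E(f, np.ones(300), sid)
        e2 = normalize_E(10 * f, np.ones(300), sid)
        np.testing.assert_allclose(e1, e2, rtol=1e-12)

    def test_wilson_fraction_below_ecut(self):
        refs = wilson_set(n=20000, seed=3)
        shells, sid = assign_shells(refs.s**2)
        e = normalize_E(refs.f_av, refs.epsilon, sid)
        frac = np.mean(e < 0.25)
        # acentric Wilson statistics: P(|E| < t) = 1 - exp(-t^2)
        assert frac == pytest.approx(1 - np.exp(-0.0625), abs=0.01)

    def test_mean_e2_unity_per_shell(self):
        refs = wilson_set(n=3000, seed=5)
        shells, sid = assign_shells(refs.s**2)
        e = normalize_E(refs.f_av, refs.epsilon, sid)
        for i in np.unique(sid):
            assert np.mean(e[sid == i] ** 2) == pytest.approx(1.0, abs=1e-9)


class TestSelectDset:
    def brute_force(self, d, sig, e, ecut, dfcut, outlier):
        keep = [i for i in range(len(d)) if e[i] >= ecut]
        keep = [i for i in keep if d[i] > dfcut * sig[i]]
        rms = np.sqrt(np.mean([d[i] ** 2 for i in keep]))
        return [i for i in keep if d[i] / rms <= outlier]

    def test_toy_list_matches_brute_force(self):
        d = np.array([10.0, 0.3, 4.0, 100.0, 5.0, 6.0])
        sig = np.ones(6)
        hkl = [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1]]
        f = np.full(6, 50.0)
        refs = s.ReflectionSet(cell=gemmi.UnitCell(30, 30, 30, 90, 90, 90),
                               spacegroup="P 1", wavelength=1.0, hkl=hkl,
                               f_plus=f + d / 2, sig_plus=sig / np.sqrt(2),
                               f_minus=f - d / 2, sig_minus=sig / np.sqrt(2))
        # |E| ~ 1 for all (equal |F|_av), so stage 1 keeps everything
        dset = select_dset(refs, ecut=0.25, dfcut=0.4, outlier=4.0)
        expected = self.brute_force(refs.d_abs, refs.sig_d,
                                    np.ones(6), 0.25, 0.4, 4.0)
        assert len(dset) == len(expected)
        assert dset.report["n_after_dfcut"] == 5   # the 0.3 reflection drops

    def test_below_ecut_removed_at_stage_one(self):
        refs = wilson_set(n=2000, seed=7)
        dset = select_dset(refs, ecut=0.25, dfcut=0.0, outlier=np.inf)
        shells, sid = assign_shells(refs.acentric().s**2)
        e = normalize_E(refs.acentric().f_av, refs.acentric().epsilon, sid)
        assert dset.report["n_after_ecut"] == np.sum(e >= 0.25)

    def test_zero_d_removed_by_dfcut(self):
        hkl = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        refs = s.ReflectionSet(cell=gemmi.UnitCell(30, 30, 30, 90, 90, 90),
                               spacegroup="P 1", wavelength=1.0, hkl=hkl,
                               f_plus=[10, 10, 10], sig_plus=[1, 1, 1],
                               f_minus=[10, 8, 12], sig_minus=[1, 1, 1])
        dset = select_dset(refs, ecut=0.0, dfcut=0.4, outlier=100.0)
        assert dset.report["n_after_dfcut"] == 2

    def test_filter_order_matters(self):
        """Outlier cut uses the r.m.s. over DFCUT survivors: on a set with
        many sub-DFCUT reflections, permuting the two stages changes the
        survivors, so the fixed order is observable."""
        n_small = 50
        d = np.concatenate([np.full(n_small, 0.1), [10.0, 50.0]])
        sig = np.ones(len(d))
        # specified order: rms over {10, 50} = 36.1 -> 50/36.1 < 4 kept
        keep_spec = self.brute_force(d, sig, np.ones(len(d)), 0.0, 0.4, 4.0)
        assert len(keep_spec) == 2
        # permuted order: rms over all = 7.3 -> 50/7.3 > 4 removed first
        rms_all = np.sqrt(np.mean(d**2))
        keep_perm = [i for i in range(len(d))
                     if d[i] / rms_all <= 4.0 and d[i] > 0.4 * sig[i]]
        assert len(keep_perm) != len(keep_spec)

    def test_empty_selection_advises_relaxation(self):
        refs = wilson_set(n=500, seed=9)
        with pytest.raises(ValueError, match="relax"):
            select_dset(refs, ecut=0.25, dfcut=1e9)


class TestWilsonFit:
    _cache = {}

    def _refs(self, b, seed):
        key = (b, seed)
        if key not in self._cache:
            _, refs, _ = s.make_fixture("se_like_small", noise_fraction=0.0,
                                        seed=seed, b_range=(b, b))
            self._cache[key] = refs
        return self._cache[key]

    def make_dset(self, b=15.0, seed=2022, scale=1.0):
        refs = self._refs(b, seed)
        if scale != 1.0:
            refs = s.ReflectionSet(cell=refs.cell, spacegroup=refs.spacegroup,
                                   wavelength=refs.wavelength, hkl=refs.hkl,
                                   f_plus=scale * refs.f_plus,
                                   sig_plus=scale * refs.sig_plus,
                                   f_minus=scale * refs.f_minus,
                                   sig_minus=scale * refs.sig_minus)
        dset = select_dset(refs)
        return dset

    def test_b_zero_data_fits_flat_line(self):
        dset = self.make_dset(b=0.0)
        k, b, diag = preprocess.fit_wilson_anomalous(dset, np.ones(8))
        assert abs(b) < 1.5   # slope ~ 0 within shell-statistics noise

    def test_recovers_b_within_ten_percent(self):
        dset = self.make_dset(b=15.0)
        k, b, _ = preprocess.fit_wilson_anomalous(dset, np.ones(8))
        assert b == pytest.approx(15.0, rel=0.10)

    def test_amplitude_doubling_scales_k_by_four(self):
        d1 = self.make_dset(b=15.0)
        d2 = self.make_dset(b=15.0, scale=2.0)
        k1, b1, _ = preprocess.fit_wilson_anomalous(d1, np.ones(8))
        k2, b2, _ = preprocess.fit_wilson_anomalous(d2, np.ones(8))
        assert k2 / k1 == pytest.approx(4.0, rel=1e-9)
        assert b2 == pytest.approx(b1, abs=1e-9)


class TestComputeX:
    def test_per_shell_mean_x2_is_unity(self):
        refs = wilson_set(n=3000, seed=11)
        dset = select_dset(refs)
        k, b, _ = preprocess.fit_wilson_anomalous(dset, np.ones(4))
        x = preprocess.compute_X(dset, k, b, np.ones(4))
        for sid in np.unique(dset.shell_id):
            assert np.mean(x[dset.shell_id == sid] ** 2) == pytest.approx(
                1.0, abs=1e-6)

    def test_equal_d_within_shell_gives_unit_x(self):
        hkl = [[0, 0, 1], [0, 1, 0], [1, 0, 0], [1, 1, 0]]
        refs = s.ReflectionSet(cell=gemmi.UnitCell(20, 20, 20, 90, 90, 90),
                               spacegroup="P 1", wavelength=1.0, hkl=hkl,
                               f_plus=[11, 11, 11, 11], sig_plus=[1] * 4,
                               f_minus=[9, 9, 9, 9], sig_minus=[1] * 4)
        dset = select_dset(refs, ecut=0.0)
        x = preprocess.compute_X(dset, 1.0, 0.0, np.ones(2))
        np.testing.assert_allclose(x, 1.0, atol=1e-12)

    def test_four_reflection_hand_computation(self):
        """X before renormalization is |D|/sqrt(K eps sum s''^2 e^{-2Bs^2});
        the shell rescale divides by the root-mean-square of those."""
        hkl = [[0, 0, 1], [0, 1, 0], [1, 0, 0], [1, 1, 0]]
        d_vals = np.array([2.0, 4.0, 6.0, 8.0])
        f = np.full(4, 50.0)
        refs = s.ReflectionSet(cell=gemmi.UnitCell(20, 20, 20, 90, 90, 90),
                               spacegroup="P 1", wavelength=1.0, hkl=hkl,
                               f_plus=f + d_vals / 2, sig_plus=[1] * 4,
                               f_minus=f - d_vals / 2, sig_minus=[1] * 4)
        dset = select_dset(refs, ecut=0.0)
        K, B, sdp = 2.0, 10.0, np.array([1.0, 0.5])
        x = preprocess.compute_X(dset, K, B, sdp)
        s2 = dset.refs.s**2
        raw = dset.d / np.sqrt(K * 1.0 * 1.25 * np.exp(-2 * B * s2))
        expected = raw / np.sqrt(np.mean(raw**2))
        np.testing.assert_allclose(x, expected, rtol=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_x_invariant_under_global_rescaling(self, scale):
        refs = wilson_set(n=1000, seed=13)
        refs2 = wilson_set(n=1000, seed=13, scale=scale)
        out = []
        for r in (refs, refs2):
            dset = select_dset(r)
            k, b, _ = preprocess.fit_wilson_anomalous(dset, np.ones(3))
            out.append(preprocess.compute_X(dset, k, b, np.ones(3)))
        np.testing.assert_allclose(out[0], out[1], rtol=1e-6)


class TestModulusModify:
    def grid_stuff(self):
        cell = gemmi.UnitCell(18, 18, 18, 90, 90, 90)
        hkl = s.unique_reflections(cell, "P 1", 3.0)
        return cell, hkl

    def test_zero_x_gives_zero_xm(self):
        cell, hkl = self.grid_stuff()
        xm = preprocess.modulus_modify(hkl, np.zeros(len(hkl)),
                                       np.zeros(len(hkl)), cell, 3.0)
        np.testing.assert_allclose(xm, 0.0, atol=1e-12)


    def test_point_atom_map_reproduces_amplitudes(self):
        """All-positive modulus synthesis: clipping is the identity, so
        |X_m| equals the input amplitudes."""
        cell, hkl = self.grid_stuff()
        delta = np.array([0.3, 0.4, 0.1])
        phases = np.angle(np.exp(2j * np.pi * (hkl @ delta)))
        amps = np.full(len(hkl), 1.0)
        # point atom gives a mostly-negative-free map only at low res;
        # verify against an independent dense FFT instead
        xm = preprocess.modulus_modify(hkl, amps, phases, cell, 3.0)
        shape = grid_shape(cell, 3.0)
        g = np.zeros(shape, dtype=complex)
        for (h, k, l), a, p in zip(hkl, amps, phases):
            g[h % shape[0], k % shape[1], l % shape[2]] = a * np.exp(1j * p)
            g[-h % shape[0], -k % shape[1], -l % shape[2]] = a * np.exp(-1j * p)
        rho = np.fft.fftn(g).real
        rho[rho < 0] = 0.0
        back = np.fft.ifftn(rho)
        expected = np.abs(np.array(
            [back[h % shape[0], k % shape[1], l % shape[2]] for h, k, l in hkl]))
        np.testing.assert_allclose(xm, expected, atol=1e-6 * max(1, expected.max()))

    def test_too_coarse_grid_rejected(self):
        cell, hkl = self.grid_stuff()
        with pytest.raises(ValueError, match="spacing"):
            preprocess.modulus_modify(hkl, np.ones(len(hkl)),
                                      np.zeros(len(hkl)), cell, 3.0,
                                      shape=(8, 8, 8))
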