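"""Filtering, referencing, artifact rejection, CSD and segmentation."""

import dataclasses

import numpy as np
import pytest
from scipy.special import eval_legendre

from bindnet import csd, design, preprocess as pre, simulate
from bindnet.containers import EpochSet, Montage, make_equidistant_montage


def _epochs_from_array(data, montage, srate=256.0, window=(-1000.0, 1000.0)):
    return EpochSet(data=data, srate=srate, window_ms=window, montage=montage)


def _sine_epochs(freq, montage, srate=256.0, amp=1.0):
    n = 512
    t = np.arange(n) / srate
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (len(montage), 1))[:, :, None]
    return _epochs_from_array(data, montage, srate)


class TestBandpass:
    @pytest.mark.parametrize("freq,kind", [(50.0, "stop"), (10.0, "pass")])
    def test_frequency_response(self, montage8, freq, kind):
        ep = _sine_epochs(freq, montage8)
        out = pre.bandpass(ep)
        # compare RMS in the central half to avoid filter edge transients
        sl = slice(128, 384)
        ratio = out.data[0, sl, 0].std() / ep.data[0, sl, 0].std()
        if kind == "stop":
            assert ratio < 0.01
        else:
            assert abs(ratio - 1.0) < 0.05

    def test_dc_removed(self, montage8):
        data = np.full((8, 512, 2), 7.0)
        out = pre.bandpass(_epochs_from_array(data, montage8))
        assert np.abs(out.data).max() < 0.5

    def test_cutoff_validation(self, montage8):
        ep = _sine_epochs(10.0, montage8, srate=32.0)
        with pytest.raises(ValueError):
            pre.bandpass(ep, pre.PreprocessConfig(resample_hz=32.0,
                                                  bp_high_hz=20.0))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            pre.PreprocessConfig(bp_low_hz=30.0, bp_high_hz=20.0)
        with pytest.raises(ValueError):
            pre.PreprocessConfig(reject_amp_uv=0.1, flat_uv=0.5)


class TestRereference:
    def test_mean_zero_and_idempotent(self, montage8):
        rng = np.random.default_rng(0)
        ep = _epochs_from_array(rng.standard_normal((8, 512, 3)), montage8)
        out = pre.rereference_average(ep)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        again = pre.rereference_average(out)
        assert np.allclose(out.data, again.data)

    def test_single_channel_zeros(self):
        m = make_equidistant_montage(1)
        ep = _epochs_from_array(np.ones((1, 512, 2)), m)
        assert np.allclose(pre.rereference_average(ep).data, 0.0)


class TestRejectArtifacts:
    def test_amplitude_rule(self, montage8):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 512, 3)) * 5
        data[2, 100, 1] = 200.0
        mask = pre.reject_artifacts(_epochs_from_array(data, montage8))
        assert list(mask.keep) == [True, False, True]
        assert mask.reason[1] == "amplitude"

    def test_flatline_rule(self, montage8):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((8, 512, 2)) * 5
        data[:, :, 0] = 0.0
        mask = pre.reject_artifacts(_epochs_from_array(data, montage8))
        assert not mask.keep[0] and mask.reason[0] == "flatline"
        assert mask.keep[1]

    def test_clean_generator_mostly_kept(self, epochs_full):
        ep, _ = epochs_full
        x = pre.rereference_average(pre.bandpass(ep))
        mask = pre.reject_artifacts(x)
        assert mask.keep.mean() >= 0.95

    def test_mask_consistency_enforced(self):
        with pytest.raises(ValueError):
            pre.RejectionMask(keep=np.array([True]), reason=["amplitude"])


class TestCsd:
    def test_uniform_potential_maps_to_zero(self, sphere_montage):
        u = np.full((len(sphere_montage), 5), 3.7)
        out = csd.apply_csd(u, sphere_montage)
        assert np.abs(out).max() < 1e-6 * 3.7

    def test_linearity(self, montage30):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((30, 10))
        w = rng.standard_normal((30, 10))
        lhs = csd.apply_csd(2.0 * v + 0.5 * w, montage30)
        rhs = 2.0 * csd.apply_csd(v, montage30) + 0.5 * csd.apply_csd(w, montage30)
        assert np.allclose(lhs, rhs, atol=1e-8 * np.abs(lhs).max())

    def test_harmonic_eigenfunction(self, sphere_montage):
        """A low-order zonal harmonic is an eigenfunction of the surface
        Laplacian: output ~ +l(l+1) x input (source sign convention), and
        its channel sum vanishes on a closed sphere sampling."""
        cos_th = np.cos(np.radians(np.asarray(sphere_montage.theta)))
        l = 3
        v = eval_legendre(l, cos_th)[:, None]
        out = csd.apply_csd(v, sphere_montage, head_radius_m=1.0)[:, 0]
        expect = l * (l + 1) * v[:, 0]
        alpha = out @ expect / (expect @ expect)
        assert 0.9 < alpha < 1.05  # ridge regularization attenuates slightly
        resid = np.linalg.norm(out - alpha * expect) / np.linalg.norm(out)
        assert resid < 0.02
        assert abs(out.sum()) < 0.02 * np.abs(out).max()

    def test_focal_source_sign_inversion(self, sphere_montage):
        """A focal positive potential produces a positive CSD at the focus
        surrounded by a negative return ring."""
        pos = sphere_montage.positions()
        ang = np.degrees(np.arccos(np.clip(pos @ pos[0], -1, 1)))
        v = np.exp(-0.5 * (ang / 25.0) ** 2)[:, None]
        out = csd.apply_csd(v, sphere_montage)[:, 0]
        assert out[0] > 0
        ring = (ang > 30) & (ang < 70)
        assert out[ring].mean() < 0

    def test_matches_mne_implementation(self, montage30):
        """Independent cross-check: identical spline parameters on the same
        spherical montage reproduce mne's CSD to machine precision (up to
        the microvolt/volt unit factor)."""
        mne = pytest.importorskip("mne")
        r = 0.095
        pos = montage30.positions() * r
        dig = mne.channels.make_dig_montage(
            ch_pos=dict(zip(montage30.names, pos)), coord_frame="head")
        info = mne.create_info(list(montage30.names), 256.0, "eeg")
        rng = np.random.default_rng(7)
        ang = np.degrees(np.arccos(np.clip(
            montage30.positions() @ montage30.positions()[3], -1, 1)))
        v = np.exp(-0.5 * (ang / 30.0) ** 2)[:, None] + \
            0.3 * rng.standard_normal((30, 1))
        raw = mne.io.RawArray(np.tile(v, (1, 5)) * 1e-6, info,
                              verbose="error")
        raw.set_montage(dig, verbose="error")
        ref = mne.preprocessing.compute_current_source_density(
            raw, stiffness=4, lambda2=1e-5, n_legendre_terms=50,
            sphere=(0.0, 0.0, 0.0, r), verbose="error").get_data()[:, 0]
        ours = csd.apply_csd(v, montage30, head_radius_m=r)[:, 0]
        assert np.allclose(ours, ref * 1e6, rtol=1e-8,
                           atol=1e-8 * np.abs(ours).max())

    def test_duplicate_positions_rejected(self):
        m = Montage(("a", "b"), np.array([10.0, 10.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            csd.apply_csd(np.ones((2, 1)), m)

    def test_units_flag(self, montage8):
        ep = _sine_epochs(10.0, montage8)
        out = pre.csd_transform(ep)
        assert out.units == "csd"
        with pytest.raises(ValueError):
            pre.csd_transform(out)  # not idempotent: refuses csd input


class TestBaseline:
    def test_constant_trial_zeroed(self, montage8):
        ep = _epochs_from_array(np.full((8, 512, 2), 4.2), montage8)
        assert np.allclose(pre.baseline_correct(ep).data, 0.0)

    def test_baseline_mean_exact_zero(self, epochs_clean):
        ep, _ = epochs_clean
        out = pre.baseline_correct(ep, (-200.0, 0.0))
        t = out.times_ms
        m = (t >= -200) & (t <= 0)
        assert np.abs(out.data[:, m, :].mean(axis=1)).max() < 1e-10

    def test_shift_equals_window_mean(self, montage8):
        ep = _sine_epochs(7.0, montage8)
        shifted = ep.copy_with(data=ep.data + 2.5)
        out = pre.baseline_correct(shifted, (-200.0, 0.0))
        t = ep.times_ms
        m = (t >= -200) & (t <= 0)
        expected = shifted.data - shifted.data[:, m, :].mean(axis=1, keepdims=True)
        assert np.allclose(out.data, expected)


class TestSplitConditions:
    def test_cell_sizes_full_design(self, montage8):
        trials = design.generate_behavior(design.generate_design(3, 0), seed=1)
        trials = [dataclasses.replace(t, correct=True) for t in trials]
        p = simulate.EegSimParams(coupling_strength_uv=0.0, noise_rms_uv=1.0)
        ep, _ = simulate.generate_eeg(trials, montage8, p, seed=2)
        cells = pre.split_conditions(ep)
        sizes = {k: v.n_trials for k, v in cells.items()}
        for rel in ("repeat", "alternate"):
            assert sizes[(0, rel)] == 24 and sizes[(3, rel)] == 24
            assert sizes[(1, rel)] == 72 and sizes[(2, rel)] == 72

    def test_incorrect_trials_excluded(self, montage8, trials128):
        p = simulate.EegSimParams(coupling_strength_uv=0.0, noise_rms_uv=1.0)
        ep, _ = simulate.generate_eeg(trials128, montage8, p, seed=3)
        cells = pre.split_conditions(ep, overlaps=(0, 3))
        n_correct = sum(t.correct and t.overlap in (0, 3) for t in trials128)
        assert sum(v.n_trials for v in cells.values()) == n_correct
        for cell in cells.values():
            assert all(t.correct for t in cell.trials)

    def test_all_rejected_raises(self, montage8, trials128):
        p = simulate.EegSimParams(coupling_strength_uv=0.0, noise_rms_uv=1.0)
        ep, _ = simulate.generate_eeg(trials128, montage8, p, seed=3)
        mask = pre.RejectionMask(keep=np.zeros(ep.n_trials, bool),
                                 reason=["amplitude"] * ep.n_trials)
        with pytest.raises(ValueError):
            pre.split_conditions(ep, mask)
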