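"""Quantification stages: dR2* conversion, AIF detection, cSVD, rCBV, Boxerman."""

import numpy as np
import pytest

from rcbvpipe.simulate import (AcquisitionSpec, KineticParams, apply_leakage,
                               concentration_to_signal, gamma_variate_curve)
from rcbvpipe.perfusion import (
    Aif,
    ConcentrationSeries,
    DeconvolutionConfig,
    DscSeries,
    boxerman_correct,
    compute_rcbv,
    csvd_deconvolve,
    detect_aif,
    quantify_subject,
    signal_to_delta_r2s,
)
from conftest import ARTERY_BLOCK


def _series_from_curves(curves: np.ndarray, spec: AcquisitionSpec
                        ) -> ConcentrationSeries:
    """Wrap an (n_vox, T) curve stack as a ConcentrationSeries on a flat grid."""
    n_vox, n_frames = curves.shape
    assert n_frames == spec.n_frames
    grid = spec.grid_shape
    assert int(np.prod(grid)) == n_vox
    return ConcentrationSeries(
        delta_r2s=curves.T.reshape((n_frames,) + grid),
        baseline_s0=np.full(grid, 1000.0),
        acquisition=spec,
        brain_mask=np.ones(grid, dtype=bool))


class TestSignalConversion:
    def test_constant_signal_gives_zero_concentration(self, acq):
        sig = np.full((acq.n_frames,) + acq.grid_shape, 800.0)
        dsc = DscSeries(sig, acq, np.ones(acq.grid_shape, bool))
        conc = signal_to_delta_r2s(dsc)
        assert np.allclose(conc.delta_r2s, 0.0)

    def test_closed_form_inversion(self, acq):
        sig = np.full((acq.n_frames,) + acq.grid_shape, 1000.0)
        sig[acq.n_baseline:] = 1000.0 * np.exp(-0.36)
        dsc = DscSeries(sig, acq, np.ones(acq.grid_shape, bool))
        conc = signal_to_delta_r2s(dsc)
        assert np.allclose(conc.delta_r2s[acq.n_baseline:], 10.0)

    def test_round_trip_with_signal_model(self, noisefree_subject):
        conc = signal_to_delta_r2s(noisefree_subject.dsc)
        spec = noisefree_subject.dsc.acquisition
        back = concentration_to_signal(conc.delta_r2s, 1000.0, spec.te)
        assert np.allclose(back, noisefree_subject.dsc.signal, rtol=1e-10)

    def test_nonpositive_s0_names_the_voxel(self, acq):
        sig = np.full((acq.n_frames,) + acq.grid_shape, 500.0)
        sig[:, 1, 2, 3] = 0.0
        dsc = DscSeries(sig, acq, np.ones(acq.grid_shape, bool))
        with pytest.raises(ValueError, match=r"\(1, 2, 3\)"):
            signal_to_delta_r2s(dsc)

    def test_baseline_floor(self, noisefree_subject):
        with pytest.raises(ValueError):
            signal_to_delta_r2s(noisefree_subject.dsc, n_baseline=2)


class TestAifDetection:
    def test_members_inside_planted_block(self, noisefree_subject):
        conc = signal_to_delta_r2s(noisefree_subject.dsc)
        aif = detect_aif(conc)
        assert set(aif.member_voxels) <= ARTERY_BLOCK
        assert len(aif.member_voxels) >= 8

    def test_members_inside_block_with_noise_and_leak(self, leaky_subject,
                                                      noisy_subject):
        for sub in (leaky_subject, noisy_subject):
            conc = signal_to_delta_r2s(sub.dsc)
            aif = detect_aif(conc)
            assert set(aif.member_voxels) <= ARTERY_BLOCK

    def test_detection_is_deterministic(self, noisy_subject):
        conc = signal_to_delta_r2s(noisy_subject.dsc)
        a = detect_aif(conc, random_state=7)
        b = detect_aif(conc, random_state=7)
        assert a.member_voxels == b.member_voxels
        assert np.array_equal(a.curve, b.curve)

    def test_earlier_population_wins(self):
        """Two planted populations differing only in t0: the detected first
        moment matches the earlier population within one frame."""
        spec = AcquisitionSpec(grid_shape=(1, 8, 8))
        t = spec.times
        early = gamma_variate_curve(KineticParams(t0=8 * spec.tr,
                                                  amplitude=10.0), t)
        late = gamma_variate_curve(KineticParams(t0=10 * spec.tr,
                                                 amplitude=10.0), t)
        curves = np.vstack([np.tile(early, (32, 1)), np.tile(late, (32, 1))])
        conc = _series_from_curves(curves, spec)
        aif = detect_aif(conc)

        def moment(c):
            return np.trapezoid(c * t, dx=spec.tr) / np.trapezoid(c, dx=spec.tr)

        assert abs(aif.first_moment - moment(early)) < spec.tr
        assert np.allclose(aif.curve, early)

    def test_too_few_candidates_raises(self):
        spec = AcquisitionSpec(grid_shape=(1, 2, 2))
        curves = np.tile(gamma_variate_curve(
            KineticParams(t0=10 * spec.tr, amplitude=5.0), spec.times), (4, 1))
        conc = _series_from_curves(curves, spec)
        with pytest.raises(ValueError, match="candidate"):
            detect_aif(conc, k_clusters=5)


class TestCsvdDeconvolution:
    dt = 0.5

    def _aif(self, beta=1.0):
        t = np.arange(0, 120, self.dt)
        curve = gamma_variate_curve(
            KineticParams(t0=10, beta=beta, amplitude=1.0), t)
        return Aif(curve=curve, member_voxels=[], first_moment=0.0), t

    def test_zero_tissue_gives_zero_cbf(self):
        aif, t = self._aif()
        cbf, _ = csvd_deconvolve(np.zeros(t.size), aif, self.dt)
        assert cbf == 0.0

    def test_exponential_residue_recovery(self):
        # discrete-consistent forward model; small threshold for the
        # noise-free regime where truncation bias is the only error source
        aif, t = self._aif()
        residue = 60.0 * np.exp(-t / 4.0)
        tissue = np.convolve(aif.curve, residue)[:t.size] * self.dt
        cbf, _ = csvd_deconvolve(tissue, aif, self.dt,
                                 DeconvolutionConfig(svd_threshold_frac=0.01))
        assert cbf == pytest.approx(60.0, rel=0.15)

    def test_delay_insensitivity(self):
        aif, t = self._aif()
        residue = 60.0 * np.exp(-t / 4.0)
        tissue = np.convolve(aif.curve, residue)[:t.size] * self.dt
        config = DeconvolutionConfig(svd_threshold_frac=0.01)
        base, _ = csvd_deconvolve(tissue, aif, self.dt, config)
        for shift in (1, 2, 3):
            shifted, _ = csvd_deconvolve(np.roll(tissue, shift), aif, self.dt,
                                         config)
            assert abs(shifted - base) / base < 0.05

    def test_impulse_residue_limit(self):
        # tissue = cbv * Ca: the residue collapses to an impulse of area cbv.
        # A delta needs the full spectrum, so the threshold is set below the
        # operator's condition floor (unregularized noise-free inversion).
        aif, t = self._aif()
        cbv = 2.0
        cbf, residue = csvd_deconvolve(
            cbv * aif.curve, aif, self.dt,
            DeconvolutionConfig(svd_threshold_frac=1e-6))
        assert cbf * self.dt == pytest.approx(cbv, rel=1e-6)
        assert residue.argmax() == 0

    def test_truncation_increases_underestimation(self):
        # the documented bias/threshold trade-off is monotone
        aif, t = self._aif()
        residue = 60.0 * np.exp(-t / 4.0)
        tissue = np.convolve(aif.curve, residue)[:t.size] * self.dt
        cbfs = [csvd_deconvolve(tissue, aif, self.dt,
                                DeconvolutionConfig(svd_threshold_frac=lam))[0]
                for lam in (0.01, 0.05, 0.10, 0.20)]
        assert all(a > b for a, b in zip(cbfs, cbfs[1:]))

    def test_degenerate_aif_rejected(self):
        aif = Aif(curve=np.zeros(100), member_voxels=[], first_moment=0.0)
        with pytest.raises(ValueError):
            csvd_deconvolve(np.ones(100), aif, self.dt)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DeconvolutionConfig(svd_threshold_frac=1.5)
        with pytest.raises(ValueError):
            DeconvolutionConfig(pad_factor=1)


class TestComputeRcbv:
    def test_aif_shaped_voxel_has_unit_rcbv(self, acq):
        curve = gamma_variate_curve(
            KineticParams(t0=10 * acq.tr, amplitude=15.0), acq.times)
        n_vox = int(np.prod(acq.grid_shape))
        conc = _series_from_curves(np.tile(curve, (n_vox, 1)), acq)
        aif = Aif(curve=curve, member_voxels=[], first_moment=0.0)
        rcbv = compute_rcbv(conc, aif)
        assert np.allclose(rcbv, 1.0)

    def test_zero_curve_gives_zero(self, acq):
        curve = gamma_variate_curve(
            KineticParams(t0=10 * acq.tr, amplitude=15.0), acq.times)
        n_vox = int(np.prod(acq.grid_shape))
        curves = np.tile(curve, (n_vox, 1))
        curves[0] = 0.0
        conc = _series_from_curves(curves, acq)
        rcbv = compute_rcbv(conc, Aif(curve=curve, member_voxels=[],
                                      first_moment=0.0))
        assert rcbv.ravel()[0] == 0.0

    def test_noise_free_parameter_recovery(self, noisefree_subject):
        """AUC-ratio rCBV vs ground-truth cbf*mtt: median |rel err| < 2%."""
        conc = signal_to_delta_r2s(noisefree_subject.dsc)
        aif = detect_aif(conc)
        rcbv = compute_rcbv(conc, aif)
        truth = noisefree_subject.truth.cbv_map
        medare = np.median(np.abs(rcbv - truth) / truth)
        assert medare < 0.02

    def test_snr50_parameter_recovery(self, noisy_subject):
        """At baseline SNR 50 the median |rel err| stays below 10%."""
        conc = signal_to_delta_r2s(noisy_subject.dsc)
        aif = detect_aif(conc)
        rcbv = compute_rcbv(conc, aif)
        truth = noisy_subject.truth.cbv_map
        medare = np.median(np.abs(rcbv - truth) / truth)
        assert medare < 0.10

    def test_negative_areas_floored_at_zero(self, acq):
        curve = gamma_variate_curve(
            KineticParams(t0=10 * acq.tr, amplitude=15.0), acq.times)
        n_vox = int(np.prod(acq.grid_shape))
        curves = np.tile(curve, (n_vox, 1))
        curves[5] = -curve
        conc = _series_from_curves(curves, acq)
        rcbv = compute_rcbv(conc, Aif(curve=curve, member_voxels=[],
                                      first_moment=0.0))
        assert rcbv.ravel()[5] == 0.0
        assert np.all(rcbv >= 0.0)


class TestBoxermanCorrection:
    def _model_consistent_series(self, acq, k1=1.0, k2=0.05):
        """All voxels share one curve; one 'tumor' voxel gets exact linear
        leakage against that same curve (= the corrector's reference)."""
        curve = gamma_variate_curve(
            KineticParams(t0=10 * acq.tr, amplitude=8.0), acq.times)
        n_vox = int(np.prod(acq.grid_shape))
        curves = np.tile(curve, (n_vox, 1))
        leaky = apply_leakage(curve, k1, k2, curve, acq.tr)
        curves[500] = leaky
        tumor = np.zeros(acq.grid_shape, bool)
        tumor.ravel()[500] = True
        return _series_from_curves(curves, acq), tumor, curve, leaky

    def test_exact_recovery_of_k1_k2(self, acq):
        conc, tumor, curve, _ = self._model_consistent_series(acq)
        corrected, k1, k2 = boxerman_correct(conc, tumor)
        assert k1.ravel()[500] == pytest.approx(1.0, abs=1e-9)
        assert k2.ravel()[500] == pytest.approx(0.05, abs=1e-9)
        rec = corrected.delta_r2s.reshape(acq.n_frames, -1)[:, 500]
        assert np.allclose(rec, curve, atol=1e-9)

    def test_no_leak_voxel_unchanged(self, acq):
        conc, tumor, curve, _ = self._model_consistent_series(acq, k2=0.0)
        corrected, k1, k2 = boxerman_correct(conc, tumor)
        assert np.allclose(k2, 0.0, atol=1e-10)
        assert np.allclose(corrected.delta_r2s, conc.delta_r2s, atol=1e-10)

    def test_correction_raises_rcbv_of_leaky_voxels(self, leaky_subject):
        conc = signal_to_delta_r2s(leaky_subject.dsc)
        aif = detect_aif(conc)
        corrected, _, _ = boxerman_correct(conc,
                                           leaky_subject.truth.tumor_mask)
        raw = compute_rcbv(conc, aif)
        fixed = compute_rcbv(corrected, aif)
        leaky = leaky_subject.truth.k2_map > 0
        assert np.all(fixed[leaky] >= raw[leaky])

    def test_bias_shrinks_for_all_tested_leak_rates(self, noisefree_subject):
        """Post-correction rCBV bias is strictly smaller in magnitude for
        every k2 in {0.01, 0.05, 0.1}."""
        sub = noisefree_subject
        acq = sub.dsc.acquisition
        conc = signal_to_delta_r2s(sub.dsc)
        aif = detect_aif(conc)
        tumor = sub.truth.tumor_mask
        flat = conc.delta_r2s.reshape(acq.n_frames, -1)
        ref = flat[:, ~tumor.ravel()].mean(axis=1)
        tumor_idx = np.flatnonzero(tumor.ravel())[:100]
        truth = sub.truth.cbv_map.ravel()[tumor_idx]
        for k2_true in (0.01, 0.05, 0.1):
            leaked = flat.copy()
            for i in tumor_idx:
                leaked[:, i] = apply_leakage(flat[:, i], 1.0, k2_true, ref,
                                             acq.tr)
            series = ConcentrationSeries(
                delta_r2s=leaked.reshape(conc.delta_r2s.shape),
                baseline_s0=conc.baseline_s0, acquisition=acq,
                brain_mask=conc.brain_mask)
            corrected, _, _ = boxerman_correct(series, tumor)
            pre = compute_rcbv(series, aif).ravel()[tumor_idx] - truth
            post = compute_rcbv(corrected, aif).ravel()[tumor_idx] - truth
            assert np.abs(post).mean() < np.abs(pre).mean()

    def test_needs_enough_reference_voxels(self, acq):
        conc, _, _, _ = self._model_consistent_series(acq)
        with pytest.raises(ValueError):
            boxerman_correct(conc, np.ones(acq.grid_shape, bool))


class TestQuantifySubject:
    def test_maps_are_finite_and_nonnegative(self, noisy_subject):
        maps, aif = quantify_subject(noisy_subject.dsc,
                                     noisy_subject.truth.tumor_mask)
        for vol in (maps.rcbv, maps.cbf, maps.mtt, maps.k1, maps.k2):
            assert np.all(np.isfinite(vol))
        assert np.all(maps.rcbv >= 0.0)
        assert len(aif.member_voxels) > 0

    def test_grid_mismatch_rejected(self, acq):
        sig = np.full((acq.n_frames, 4, 8, 8), 100.0)
        with pytest.raises(ValueError):
            DscSeries(sig, acq, np.ones((4, 8, 8), bool))
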