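"""Lagged correlation, peak/latency extraction, Fisher z, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcfmri import conditioning, lagmap, physio, synth
from adcfmri.contrast import FmriRun
from adcfmri.errors import DataError, ParameterError
from adcfmri.lagmap import (
    DEFAULT_LAGS,
    correlation_profile,
    fisher_z,
    lagged_correlation,
    normalize_latency,
    xcorr_map,
)


def _naive_lagged_r(ts, times, reg, lags):
    """Independent brute-force oracle: per-lag Pearson via np.corrcoef."""
    out = []
    for lag in lags:
        shifted = times - lag
        t0, t1 = reg.time_s[0], reg.time_s[-1]
        sel = (shifted >= t0) & (shifted <= t1)
        if sel.sum() < 2:
            out.append(np.nan)
            continue
        x = np.interp(shifted[sel], reg.time_s, reg.values)
        out.append(np.corrcoef(ts[sel], x)[0, 1])
    return np.asarray(out)


class TestLaggedCorrelation:
    def test_default_grid(self):
        assert DEFAULT_LAGS.size == 61
        assert DEFAULT_LAGS[0] == -30.0 and DEFAULT_LAGS[-1] == 0.0

    def test_self_correlation_at_zero_lag(self, breathhold_regressor):
        reg = breathhold_regressor
        times = np.arange(0.5, 190.0, 1.0)
        ts, _ = reg.sample(times)
        curve = lagged_correlation(ts, times, reg)
        assert curve.r[curve.lags_s == 0.0][0] == pytest.approx(1.0, abs=1e-12)

    def test_constructed_shift_recovered(self, breathhold_regressor):
        reg = breathhold_regressor
        times = np.arange(0.5, 190.0, 1.0)
        ts, _ = reg.sample(times + 15.0)  # signal leads the recording by 15 s
        curve = lagged_correlation(ts, times, reg)
        peak = curve.lags_s[np.nanargmax(curve.r)]
        assert peak == pytest.approx(-15.0, abs=0.5)

    def test_white_noise_max_r_bounded(self, breathhold_regressor):
        rng = np.random.default_rng(0)
        times = np.arange(0.5, 192.0, 1.0)
        maxima = [
            np.nanmax(np.abs(lagged_correlation(rng.standard_normal(times.size),
                                                times, breathhold_regressor).r))
            for _ in range(20)
        ]
        assert np.mean(np.asarray(maxima) < 0.35) >= 0.95

    def test_oracle_equivalence(self, breathhold_regressor):
        rng = np.random.default_rng(5)
        times = np.arange(0.5, 190.0, 1.0)
        ts = rng.standard_normal(times.size)
        curve = lagged_correlation(ts, times, breathhold_regressor)
        naive = _naive_lagged_r(ts, times, breathhold_regressor, curve.lags_s)
        assert np.allclose(curve.r, naive, atol=1e-10, equal_nan=True)

    @settings(deadline=None, max_examples=30)
    @given(
        scale=st.floats(0.1, 100.0),
        offset=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, scale, offset, breathhold_regressor):
        rng = np.random.default_rng(9)
        times = np.arange(0.5, 150.0, 1.0)
        ts = rng.standard_normal(times.size)
        base = lagged_correlation(ts, times, breathhold_regressor).r
        moved = lagged_correlation(scale * ts + offset, times, breathhold_regressor).r
        assert np.allclose(base, moved, atol=1e-10, equal_nan=True)


class TestFisherZ:
    def test_log_form_equivalence(self):
        r, n = 0.5, 192
        z = fisher_z(np.array([r]), np.array([n]))[0]
        log_form = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(n - 3)
        assert z == pytest.approx(log_form, rel=1e-12)
        assert z == pytest.approx(7.5516, abs=5e-4)

    def test_monotone_in_r_and_n(self):
        r = np.linspace(0.1, 0.9, 9)
        z = fisher_z(r, np.full(9, 100))
        assert np.all(np.diff(z) > 0)
        n = np.arange(10, 200, 10)
        z = fisher_z(np.full(n.size, 0.5), n)
        assert np.all(np.diff(z) > 0)


class TestXcorrMap:
    def test_noiseless_latency_recovery_on_grid(self, breathhold_co2, small_masks):
        _, truth = breathhold_co2
        driver = synth.vascular_driver(truth)
        reg = physio.process_co2(
            synth.generate_co2_trace(synth.generate_breathhold_paradigm(), seed=101)[0]
        )
        grid = (10, 10, 4)
        gt = synth.GroundTruth(
            vascular_amplitude=np.full(grid, 0.008),
            latency_field=np.where(small_masks["GM"], 2.0, 4.5),
            noise_sigma=0.0,
        )
        run = synth.generate_fmri_run("BOLD", gt, driver, 1.0, 192, masks=small_masks)
        xm = xcorr_map(run, reg)
        lat_gm = xm.latency_s[small_masks["GM"]]
        lat_wm = xm.latency_s[small_masks["WM"]]
        # every GM voxel shares one truth latency, likewise WM; the recovered
        # separation matches the 2.5 s truth on the 0.5 s grid
        assert np.unique(lat_gm).size == 1 and np.unique(lat_wm).size == 1
        assert lat_wm[0] - lat_gm[0] == pytest.approx(2.5, abs=0.5)

    def test_boundary_peak_invalidated(self, breathhold_regressor):
        reg = breathhold_regressor
        times = np.arange(0.5, 190.0, 1.0)
        ts, _ = reg.sample(times)  # true peak at lag 0, a grid extreme
        data = np.broadcast_to(ts, (2, 2, 1, times.size)).copy()
        run = FmriRun(data=data, TR_s=1.0, contrast="BOLD", volume_times_s=times)
        xm = xcorr_map(run, reg)
        assert not xm.valid.any()

    def test_empty_mask_rejected(self, breathhold_regressor):
        run = FmriRun(
            data=np.zeros((2, 2, 1, 50)), TR_s=1.0, contrast="BOLD",
            volume_times_s=np.arange(0.5, 50.0, 1.0),
        )
        with pytest.raises(ParameterError):
            xcorr_map(run, breathhold_regressor, mask=np.zeros((2, 2, 1), bool))

    def test_cohort_latency_error_bounded(self):
        """Across seeded noisy subjects (image SNR 20), the mean absolute
        voxel latency error stays within the 0.5 s lag grid."""
        errors = []
        for seed in range(10):
            paradigm = synth.generate_breathhold_paradigm()
            trace, truth = synth.generate_co2_trace(paradigm, seed=300 + seed)
            reg = physio.process_co2(trace)
            driver = synth.vascular_driver(truth)
            masks = synth.default_masks((6, 6, 2))
            gt = synth.GroundTruth(
                vascular_amplitude=np.full((6, 6, 2), 0.01),
                latency_field=np.where(masks["GM"], 2.0, 4.5),
                noise_sigma=25.0,
            )
            run = synth.generate_fmri_run(
                "BOLD", gt, driver, 1.0, 192, seed=seed, masks=masks
            )
            run = conditioning.condition_run(run)
            xm = xcorr_map(run, reg)
            sep = np.median(xm.latency_s[masks["WM"] & xm.valid]) - np.median(
                xm.latency_s[masks["GM"] & xm.valid]
            )
            errors.append(abs(sep - 2.5))
        assert np.mean(errors) <= 0.5


class TestNormalize:
    def test_constant_gm_latency_normalises_to_zero(self, breathhold_co2, small_masks):
        _, truth = breathhold_co2
        driver = synth.vascular_driver(truth)
        reg = physio.process_co2(
            synth.generate_co2_trace(synth.generate_breathhold_paradigm(), seed=101)[0]
        )
        gt = synth.GroundTruth(
            vascular_amplitude=np.full((10, 10, 4), 0.008),
            latency_field=np.full((10, 10, 4), 2.0),
            noise_sigma=0.0,
        )
        run = synth.generate_fmri_run("BOLD", gt, driver, 1.0, 192, masks=small_masks)
        xm = xcorr_map(run, reg)
        norm, shift = normalize_latency(xm, small_masks["GM"])
        sel = norm.valid & small_masks["GM"]
        assert np.all(norm.latency_s[sel] == 0.0)
        assert np.median(norm.latency_s[sel]) == 0.0

    def test_no_valid_gm_errors(self, breathhold_regressor):
        run = FmriRun(
            data=np.random.default_rng(0).random((2, 2, 1, 50)),
            TR_s=1.0, contrast="BOLD", volume_times_s=np.arange(0.5, 50.0, 1.0),
        )
        xm = xcorr_map(run, breathhold_regressor)
        xm.valid[:] = False
        with pytest.raises(DataError):
            normalize_latency(xm, np.ones((2, 2, 1), bool))


class TestProfile:
    def test_single_voxel_profile_equals_its_curve(self, bold_subject, breathhold_regressor):
        run, _, _ = bold_subject
        xm = xcorr_map(run, breathhold_regressor, keep_curves=True)
        sig = np.zeros(run.grid, dtype=bool)
        sig[5, 5, 2] = True
        prof = correlation_profile(run, breathhold_regressor, sig, xmap=xm)
        flat_index = np.nonzero(xm.mask.ravel())[0]
        row = np.searchsorted(flat_index, np.ravel_multi_index((5, 5, 2), run.grid))
        assert np.allclose(prof.mean_r.to_numpy(), xm.per_lag_r[row], equal_nan=True)

    def test_coherent_run_profile_peaks_near_shifted_zero(self, bold_subject, breathhold_regressor, small_masks):
        run, _, _ = bold_subject
        xm = xcorr_map(run, breathhold_regressor, keep_curves=True)
        sig = xm.valid & (xm.zmax > 3.09)
        prof = correlation_profile(
            run, breathhold_regressor, sig, gm_mask=small_masks["GM"], xmap=xm
        )
        peak_lag = prof.lag_s[prof.mean_r.idxmax()]
        assert abs(peak_lag) <= 2.0  # WM half peaks +2.5 s later than GM

    def test_pure_noise_profile_flat(self, breathhold_regressor):
        rng = np.random.default_rng(11)
        times = np.arange(0.5, 192.0, 1.0)
        data = rng.standard_normal((6, 6, 3, times.size))
        run = FmriRun(data=data, TR_s=1.0, contrast="BOLD", volume_times_s=times)
        xm = xcorr_map(run, breathhold_regressor, keep_curves=True)
        sig = np.ones(run.grid, dtype=bool)
        prof = correlation_profile(run, breathhold_regressor, sig, xmap=xm)
        assert prof.mean_r.max() - prof.mean_r.min() < 0.1

    def test_empty_significant_set_warns(self, bold_subject, breathhold_regressor):
        run, _, _ = bold_subject
        with pytest.warns(UserWarning):
            prof = correlation_profile(
                run, breathhold_regressor, np.zeros(run.grid, bool)
            )
        assert prof.empty
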