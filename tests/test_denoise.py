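import numpy as np
import pytest

from rsnbench.denoise import (
    Decomposition,
    DesignMatrix,
    TechniqueOptions,
    Volume4D,
    apply_technique,
    bandpass_filter,
    build_design_matrix,
    decompose_spatial_ica,
    label_noise_components,
    read_noise_label_file,
    regress_components_aggressive,
    regress_components_nonaggressive,
    regress_full,
    smooth_volume,
)
from rsnbench.motion import CensorMask, MotionTrace


def volume_from(data, tr=2.5):
    return Volume4D(data=data, voxel_size=(3.4, 3.4, 3.4), tr=tr)


def random_volume(rng, shape=(5, 5, 5, 60)):
    return volume_from(rng.normal(size=shape))


def make_trace(rng, t):
    return MotionTrace(params=rng.normal(scale=0.05, size=(t, 6)), tr=2.5)


class TestDesignMatrix:
    def test_column_counts_with_censoring_and_band(self, rng):
        t = 288
        keep = np.ones(t, dtype=bool)
        keep[:20] = False
        design = build_design_matrix(
            make_trace(rng, t),
            wm_ts=rng.normal(size=t),
            csf_ts=rng.normal(size=t),
            censor=CensorMask(keep=keep, cutoff_mm=0.5),
            detrend_order=3,
            passband=(0.009, 0.08),
        )
        assert design.count("spike") == 20
        assert design.count("drift") == 4
        assert design.count("motion") == 24
        assert design.count("tissue") == 2
        # out-of-band DFT bins at T=288, tr=2.5: in-band k = 7..57, so
        # 93 excluded frequencies -> 2*93 - 1 columns (no sine at Nyquist)
        assert design.count("frequency") == 185
        assert design.n_columns < t

    def test_minimal_design_size(self, rng):
        t = 60
        design = build_design_matrix(
            make_trace(rng, t),
            wm_ts=rng.normal(size=t),
            csf_ts=rng.normal(size=t),
            global_ts=rng.normal(size=t),
            detrend_order=3,
            passband=None,
        )
        assert design.n_columns == 24 + 2 + 1 + 4

    def test_overdetermined_design_rejected(self, rng):
        t = 40
        with pytest.raises(ValueError, match="columns"):
            build_design_matrix(
                make_trace(rng, t),
                wm_ts=rng.normal(size=t),
                csf_ts=rng.normal(size=t),
                detrend_order=3,
                passband=(0.009, 0.08),
            )

    def test_frequency_regression_implements_bandpass(self, rng):
        """After regressing the out-of-band columns, residual spectral power
        outside [0.009, 0.08] Hz is (numerically) zero."""
        t, tr = 288, 2.5
        design = build_design_matrix(
            make_trace(rng, t),
            wm_ts=rng.normal(size=t),
            csf_ts=rng.normal(size=t),
            detrend_order=3,
            passband=(0.009, 0.08),
        )
        y = rng.normal(size=(1, 1, 1, t))
        resid = regress_full(volume_from(y), design).data.ravel()
        freqs = np.fft.rfftfreq(t, d=tr)
        power = np.abs(np.fft.rfft(resid - resid.mean())) ** 2
        out_band = power[(freqs < 0.009) | (freqs > 0.08)][1:].sum()
        in_band = power[(freqs >= 0.009) & (freqs <= 0.08)].sum()
        assert out_band < 0.01 * in_band


class TestRegressFull:
    def test_matches_normal_equations_oracle(self, rng):
        """OLS residuals agree with an explicit (X'X)^-1 X'Y solve."""
        for _ in range(100):
            x = rng.normal(size=(50, 8))
            y = rng.normal(size=(50, 3))
            design = DesignMatrix(x, [f"c{i}" for i in range(8)], ["motion"] * 8)
            vol = volume_from(y.T.reshape(3, 1, 1, 50))
            out = regress_full(vol, design).data.reshape(3, 50).T
            xc = x - x.mean(0)
            yc = y - y.mean(0)
            beta = np.linalg.solve(xc.T @ xc, xc.T @ yc)
            expected = yc - xc @ beta + y.mean(0)
            assert np.allclose(out, expected, rtol=1e-8, atol=1e-8)

    def test_residual_orthogonal_and_idempotent(self, rng):
        vol = random_volume(rng)
        x = rng.normal(size=(60, 10))
        design = DesignMatrix(x, [f"c{i}" for i in range(10)], ["motion"] * 10)
        out = regress_full(vol, design)
        resid = out.data.reshape(-1, 60).T
        xc = x - x.mean(0)
        assert np.max(np.abs(xc.T @ (resid - resid.mean(0)))) < 1e-6
        again = regress_full(out, design)
        assert np.allclose(again.data, out.data, atol=1e-10)

    def test_series_in_span_zeroed(self, rng):
        x = rng.normal(size=(40, 3))
        coef = np.array([1.5, -2.0, 0.5])
        y = (x @ coef + 7.0).reshape(1, 1, 1, 40)
        design = DesignMatrix(x, list("abc"), ["motion"] * 3)
        out = regress_full(volume_from(y), design).data.ravel()
        assert np.allclose(out, y.mean(), atol=1e-10)

    def test_intercept_only_is_identity(self, rng):
        vol = random_volume(rng, (3, 3, 3, 30))
        design = DesignMatrix(np.ones((30, 1)), ["intercept"], ["drift"])
        out = regress_full(vol, design)
        assert np.allclose(out.data, vol.data, atol=1e-12)


class TestSpatialICA:
    @staticmethod
    def planted_volume(rng, c=3, shape=(8, 8, 8), t=80):
        """Temporally orthogonal sources with independent sparse spatial maps
        (voxelwise Laplacian loadings — the spatial-independence regime ICA
        is built for)."""
        tcs = np.linalg.qr(rng.normal(size=(t, c)))[0]
        maps = rng.laplace(size=(c, np.prod(shape)))
        data = (tcs @ maps).T.reshape(*shape, t) * 10.0
        data += 0.01 * rng.normal(size=data.shape)
        return volume_from(data), tcs

    def test_recovers_planted_components(self, rng):
        vol, tcs = self.planted_volume(rng)
        mask = np.ones(vol.grid_shape, dtype=bool)
        dec = decompose_spatial_ica(vol, mask, n_components=3, rng_seed=1)
        corr = np.abs(np.corrcoef(tcs.T, dec.mixing.T)[:3, 3:])
        # best match per planted source, up to sign and permutation
        assert np.all(corr.max(axis=1) > 0.95)
        assert not dec.noise_label.any()

    def test_deterministic_for_fixed_seed(self, rng):
        vol, _ = self.planted_volume(rng)
        mask = np.ones(vol.grid_shape, dtype=bool)
        a = decompose_spatial_ica(vol, mask, n_components=3, rng_seed=5)
        b = decompose_spatial_ica(vol, mask, n_components=3, rng_seed=5)
        assert np.array_equal(a.mixing, b.mixing)

    def test_too_many_components_rejected(self, rng):
        vol = random_volume(rng, (4, 4, 4, 20))
        with pytest.raises(ValueError):
            decompose_spatial_ica(
                vol, np.ones(vol.grid_shape, bool), n_components=20
            )

    def test_label_matching(self, rng):
        vol, tcs = self.planted_volume(rng)
        mask = np.ones(vol.grid_shape, dtype=bool)
        dec = decompose_spatial_ica(vol, mask, n_components=3, rng_seed=1)
        labels = label_noise_components(
            dec, noise_timecourses=tcs[:, :1], signal_timecourses=tcs[:, 1:]
        )
        assert labels.sum() == 1
        matched = int(np.argmax(labels))
        assert abs(np.corrcoef(dec.mixing[:, matched], tcs[:, 0])[0, 1]) > 0.95


class TestComponentRegression:
    @staticmethod
    def orthogonal_decomposition(rng, t=60, c=5):
        """Zero-mean, exactly orthogonal time courses (distinct DFT bins)."""
        k = np.arange(1, c + 1)
        phase = 2 * np.pi * np.outer(np.arange(t), k) / t
        mixing = np.where(k % 2 == 0, np.cos(phase), np.sin(phase))
        mixing = mixing / mixing.std(axis=0)
        labels = np.zeros(c, dtype=bool)
        labels[:2] = True
        return Decomposition(
            mixing=mixing, maps=rng.normal(size=(c, 10)), noise_label=labels
        )

    def test_orthogonal_mixing_makes_variants_equal(self, rng):
        """With mutually orthogonal component time courses, partial and full
        regression coincide (algebraic identity)."""
        dec = self.orthogonal_decomposition(rng)
        vol = random_volume(rng, (4, 4, 4, 60))
        aggr = regress_components_aggressive(vol, dec)
        nonaggr = regress_components_nonaggressive(vol, dec)
        assert np.allclose(aggr.data, nonaggr.data, rtol=1e-8, atol=1e-8)

    def test_projection_nesting(self, rng):
        """Aggressive residual variance <= non-aggressive, voxel by voxel."""
        for _ in range(20):
            t, c = 40, 4
            mixing = rng.normal(size=(t, c))
            mixing /= mixing.std(axis=0)
            labels = np.array([True, True, False, False])
            dec = Decomposition(mixing, rng.normal(size=(c, 5)), labels)
            vol = random_volume(rng, (3, 3, 3, t))
            va = regress_components_aggressive(vol, dec).data.var(axis=-1)
            vn = regress_components_nonaggressive(vol, dec).data.var(axis=-1)
            assert np.all(va <= vn + 1e-10)

    def test_shared_variance_is_protected(self, rng):
        """When a noise and a retained component are correlated, partial
        regression removes strictly less variance."""
        t = 80
        base = rng.normal(size=t)
        noise_tc = base + 0.3 * rng.normal(size=t)
        kept_tc = base + 0.3 * rng.normal(size=t)
        mixing = np.column_stack([noise_tc, kept_tc])
        mixing /= mixing.std(axis=0)
        dec = Decomposition(
            mixing, rng.normal(size=(2, 5)), np.array([True, False])
        )
        y = (2.0 * noise_tc + rng.normal(size=t)).reshape(1, 1, 1, t)
        vol = volume_from(y)
        va = regress_components_aggressive(vol, dec).data.var()
        vn = regress_components_nonaggressive(vol, dec).data.var()
        assert va < vn

    def test_all_noise_equals_aggressive(self, rng):
        mixing = rng.normal(size=(50, 3))
        mixing /= mixing.std(axis=0)
        dec = Decomposition(mixing, rng.normal(size=(3, 4)), np.ones(3, bool))
        vol = random_volume(rng, (2, 2, 2, 50))
        aggr = regress_components_aggressive(vol, dec)
        nonaggr = regress_components_nonaggressive(vol, dec)
        assert np.allclose(aggr.data, nonaggr.data, atol=1e-8)

    def test_pure_noise_signal_removed(self, rng):
        mixing = rng.normal(size=(50, 2))
        mixing /= mixing.std(axis=0)
        dec = Decomposition(mixing, rng.normal(size=(2, 4)), np.ones(2, bool))
        y = (mixing @ np.array([3.0, -1.0])).reshape(1, 1, 1, 50)
        out = regress_components_aggressive(volume_from(y), dec)
        assert np.allclose(out.data, y.mean(), atol=1e-8)

    def test_requires_noise_labels(self, rng):
        dec = self.orthogonal_decomposition(rng)
        dec.noise_label[:] = False
        with pytest.raises(ValueError):
            regress_components_aggressive(random_volume(rng, (2, 2, 2, 60)), dec)


class TestBandpass:
    def test_in_band_sine_preserved(self):
        t, tr = 288, 2.5
        f = 29 / (t * tr)  # an exact DFT bin inside the band (~0.040 Hz)
        x = np.sin(2 * np.pi * f * tr * np.arange(t))
        out = bandpass_filter(x, 0.009, 0.08, tr)
        assert np.sqrt(np.mean(out**2)) / np.sqrt(np.mean(x**2)) > 0.99

    def test_out_of_band_sine_suppressed(self):
        t, tr = 288, 2.5
        x = np.sin(2 * np.pi * 0.1 * tr * np.arange(t))  # 0.1 Hz = bin 72
        out = bandpass_filter(x, 0.009, 0.08, tr)
        assert np.sqrt(np.mean(out**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_constant_series_zeroed(self):
        out = bandpass_filter(np.full(100, 5.0), 0.009, 0.08, 2.5)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(10), 0.0001, 0.0002, 2.5)


class TestSmoothing:
    def test_preserves_mean_and_reduces_variance(self, rng):
        vol = random_volume(rng, (12, 12, 12, 5))
        sm = smooth_volume(vol, fwhm_mm=6.0)
        assert sm.data.mean() == pytest.approx(vol.data.mean(), rel=1e-6)
        assert sm.data.var() < vol.data.var()


class TestApplyTechnique:
    def test_unknown_technique(self, hf_subject, atlas24):
        with pytest.raises(ValueError, match="unknown technique"):
            apply_technique(hf_subject, "despike", atlas24, TechniqueOptions())

    def test_component_technique_needs_labels(self, hf_subject, atlas24):
        opts = TechniqueOptions(n_components=8)
        with pytest.raises(ValueError, match="noise_labels or noise_timecourses"):
            apply_technique(hf_subject, "aggressive_aroma", atlas24, opts)

    def test_censoring_output_shape_and_tdof(self, hf_subject, atlas24):
        out, report = apply_technique(
            hf_subject, "censoring", atlas24, TechniqueOptions()
        )
        assert out.data.shape == hf_subject.volume.data.shape
        assert report.source == "censoring"
        assert 0.0 <= report.fraction_lost < 0.5

    def test_aggressive_halves_edge_motion_correlation(
        self, hf_subject, atlas24, oracle_options
    ):
        """Component regression with oracle labels removes most of the
        FWD-locked edge artifact."""
        from rsnbench.motion import framewise_displacement

        fwd = framewise_displacement(hf_subject.motion)
        f = fwd - fwd.mean()

        def mean_abs_r(vol):
            y = vol.timeseries(atlas24.edge_mask)
            yc = y - y.mean(0)
            r = (f @ yc) / (np.linalg.norm(f) * np.linalg.norm(yc, axis=0))
            return np.abs(r).mean()

        before = mean_abs_r(hf_subject.volume)
        out, report = apply_technique(
            hf_subject, "aggressive_aroma", atlas24, oracle_options
        )
        assert mean_abs_r(out) < before / 2
        assert report.source == "components"
        assert report.n_lost >= 1


def test_noise_label_file(tmp_path):
    path = tmp_path / "labels.txt"
    path.write_text("1\n3\n7\n")
    labels = read_noise_label_file(path, n_components=8)
    assert labels.tolist() == [True, False, True, False, False, False, True, False]
    path.write_text("0\n")
    with pytest.raises(ValueError):
        read_noise_label_file(path, n_components=8)
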