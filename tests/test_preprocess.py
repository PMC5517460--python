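"""Preprocessing tests: Beer-Lambert inversion, ICA decomposition and the
three rejection criteria, subtractive denoising, filtering, duration bins."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from nirsnet import (
    ArtifactParams,
    CohortSpec,
    HemodynamicRecording,
    bandpass,
    classify_components,
    decompose,
    derive_hbr,
    mbll_convert,
    reconstruct_denoised,
    simulate_optical_density,
    simulate_run,
    truncate_bins,
)
from nirsnet.preprocess import ComponentDecomposition, spatial_kurtosis


def _rec(data, fs=5.0, **kw):
    return HemodynamicRecording("S01", "1", fs, data, **kw)


class TestMBLL:
    def test_zero_od_gives_zero_concentration(self):
        hbo, hbr = mbll_convert(np.zeros((2, 4, 50)), sampling_rate_hz=5.0)
        assert np.all(hbo.data == 0) and np.all(hbr.data == 0)

    def test_forward_inverse_round_trip(self):
        spec = CohortSpec(n_subjects=1, n_runs=1, n_channels=6,
                          duration_s=600.0, sampling_rate_hz=1.0, rng_seed=13,
                          artifact_params=ArtifactParams.none())
        hbo, _ = simulate_run(spec, 0, 0)
        hbr = derive_hbr(hbo, seed=13)
        od = simulate_optical_density(hbo, hbr)
        hbo2, hbr2 = mbll_convert(od, sampling_rate_hz=1.0)
        assert np.abs(hbo2.data - hbo.data).max() <= 1e-9 * np.abs(hbo.data).max()
        assert np.abs(hbr2.data - hbr.data).max() <= 1e-9 * np.abs(hbr.data).max()

    def test_linearity_in_od(self):
        rng = np.random.default_rng(0)
        od = rng.standard_normal((2, 3, 40))
        a1, b1 = mbll_convert(od, sampling_rate_hz=5.0)
        a2, b2 = mbll_convert(3.0 * od, sampling_rate_hz=5.0)
        assert_allclose(a2.data, 3.0 * a1.data, rtol=1e-12)
        assert_allclose(b2.data, 3.0 * b1.data, rtol=1e-12)


class TestDecompose:
    def test_rank_one_input_recovers_single_source(self, rng):
        t = np.arange(2000) / 5.0
        src = np.sign(np.sin(2 * np.pi * 0.031 * t)) * np.abs(rng.standard_normal(t.size))
        loadings = rng.uniform(0.5, 2.0, 12)
        rec = _rec(np.outer(loadings, src))
        d = decompose(rec, variance_retained=0.99)
        assert d.n_components == 1
        r = np.corrcoef(d.sources[0], src)[0, 1]
        assert abs(r) > 0.999

    def test_two_supergaussian_sources_unmixed(self, rng):
        n = 3000
        s1 = rng.laplace(size=n)
        s2 = rng.laplace(size=n)
        A = np.array([[1.0, 0.4], [0.6, 1.0], [0.3, -0.8], [-0.5, 0.7]])
        rec = _rec(A @ np.vstack([s1, s2]))
        d = decompose(rec, variance_retained=0.999)
        got = d.sources
        cors = np.abs(np.corrcoef(np.vstack([got, [s1, s2]]))[:2, 2:])
        # each true source matches some estimated component up to sign/permutation
        assert cors.max(axis=0).min() > 0.99

    def test_reconstruction_matches_retained_variance(self, clean_run):
        rec, _ = clean_run
        d = decompose(rec, variance_retained=0.99)
        resid = rec.data - d.reconstruct()
        assert resid.var() <= (1 - 0.99 + 0.005) * rec.data.var()

    def test_invalid_variance_rejected(self, clean_run):
        with pytest.raises(ValueError):
            decompose(clean_run[0], variance_retained=1.5)


def _manual_decomp(sources, mixing, fs=25.0):
    n_ch = mixing.shape[0]
    rec = _rec(mixing @ sources, fs=fs)
    return ComponentDecomposition(
        recording=rec, sources=np.asarray(sources, float),
        mixing=np.asarray(mixing, float), channel_means=np.zeros(n_ch),
        variance_retained=1.0)


class TestClassifyComponents:
    """Criteria checks on hand-built decompositions with known content."""

    def _sin(self, freq, fs=25.0, dur=600.0):
        t = np.arange(int(dur * fs)) / fs
        return np.sin(2 * np.pi * freq * t)

    def test_one_hz_component_is_out_of_band(self, rng):
        mixing = rng.standard_normal((10, 1)) * np.array([[2.0]])
        mixing[:5, 0] = 0.0  # focal map so only the spectral criterion fires
        d = _manual_decomp(self._sin(1.0)[None, :], mixing)
        d = classify_components(d, band=(0.01, 0.1))
        assert bool(d.criteria_flags["out_of_band"][0]) is True

    def test_in_band_component_is_not_out_of_band(self, rng):
        mixing = np.zeros((10, 1)); mixing[2, 0] = 1.0
        d = _manual_decomp(self._sin(0.05)[None, :], mixing)
        d = classify_components(d, band=(0.01, 0.1))
        assert bool(d.criteria_flags["out_of_band"][0]) is False

    def test_u_shape_component_flagged_temporal(self):
        t = np.linspace(-1, 1, 15000)
        u = t ** 2 + 0.02 * np.sin(2 * np.pi * 7 * t)
        mixing = np.zeros((10, 1)); mixing[4, 0] = 1.0
        d = _manual_decomp(u[None, :], mixing)
        d = classify_components(d, band=(0.01, 0.1))
        assert bool(d.criteria_flags["temporal_artifact"][0]) is True

    def test_jump_component_flagged_temporal(self, rng):
        x = 0.2 * np.sin(2 * np.pi * 0.05 * np.arange(15000) / 25.0)
        x += 0.02 * rng.standard_normal(x.size)
        x[7000:] += 5.0
        mixing = np.zeros((8, 1)); mixing[1, 0] = 1.0
        d = _manual_decomp(x[None, :], mixing)
        d = classify_components(d, band=(0.01, 0.1))
        assert bool(d.criteria_flags["temporal_artifact"][0]) is True

    def test_uniform_loading_flagged_dispersive_focal_not(self, rng):
        src = self._sin(0.05)
        uniform = 1.0 + 0.1 * rng.standard_normal(46)
        focal = np.zeros(46); focal[3] = 2.0; focal[11] = -1.0
        module = np.zeros(46); module[:11] = rng.standard_normal(11)
        d = _manual_decomp(
            np.vstack([src, src, src]), np.column_stack([uniform, focal, module]))
        d = classify_components(d, band=(0.01, 0.1))
        disp = d.criteria_flags["spatially_dispersive"]
        assert bool(disp[0]) is True      # global near-uniform map
        assert bool(disp[1]) is False     # focal map
        assert bool(disp[2]) is False     # module-confined map

    def test_flags_invariant_to_component_sign_and_scale(self, rng):
        src = self._sin(1.0) + 0.1 * rng.standard_normal(15000)
        mixing = rng.standard_normal((10, 1))
        d1 = classify_components(_manual_decomp(src[None, :], mixing))
        d2 = classify_components(_manual_decomp(-5.0 * src[None, :], mixing / -5.0))
        for key in ("temporal_artifact", "out_of_band", "spatially_dispersive"):
            assert np.array_equal(d1.criteria_flags[key], d2.criteria_flags[key])

    def test_label_is_noise_iff_any_flag(self, artifact_run):
        rec, _ = artifact_run
        d = classify_components(decompose(rec))
        any_flag = (d.criteria_flags["temporal_artifact"]
                    | d.criteria_flags["out_of_band"]
                    | d.criteria_flags["spatially_dispersive"])
        assert np.array_equal(d.labels == "noise", any_flag)

    def test_global_artifact_detected_via_spatial_criterion(self):
        # generator-labelled fixture: the injected global superficial
        # component must be flagged by the dispersive criterion once isolated
        spec = CohortSpec(n_subjects=4, n_runs=1, n_channels=46,
                          duration_s=600.0, sampling_rate_hz=5.0, rng_seed=31)
        hits = 0
        for s in range(4):
            rec, bundle = simulate_run(spec, s, 0)
            d = classify_components(decompose(rec))
            wave = [a for a in bundle.injected_artifacts if a[0] == "global"][0][3]
            u = wave.mean(axis=0)
            cors = np.abs([np.corrcoef(src, u)[0, 1] for src in d.sources])
            hits += bool(d.criteria_flags["spatially_dispersive"][int(np.argmax(cors))])
        assert hits >= 3

    def test_spatial_kurtosis_extremes(self):
        assert spatial_kurtosis(np.ones(46)) == pytest.approx(-2.0)
        focal = np.zeros(46); focal[0] = 1.0
        assert spatial_kurtosis(focal) > 10


class TestReconstructDenoised:
    def test_no_noise_labels_gives_identity(self, clean_run):
        rec, _ = clean_run
        d = decompose(rec)
        d = d.__class__(**{**d.__dict__,
                           "labels": np.array(["signal"] * d.n_components),
                           "criteria_flags": {}})
        out = reconstruct_denoised(d)
        assert np.array_equal(out.data, rec.data)

    def test_all_noise_rejected(self, clean_run):
        rec, _ = clean_run
        d = decompose(rec)
        d = d.__class__(**{**d.__dict__,
                           "labels": np.array(["noise"] * d.n_components),
                           "criteria_flags": {}})
        with pytest.raises(ValueError, match="all components"):
            reconstruct_denoised(d)

    def test_recompose_invariant_to_dropped_source_waveform(self, rng):
        sources = rng.standard_normal((3, 500))
        mixing = rng.standard_normal((6, 3))
        d1 = ComponentDecomposition(
            recording=_rec(mixing @ sources), sources=sources, mixing=mixing,
            channel_means=np.zeros(6), variance_retained=1.0)
        altered = sources.copy()
        altered[2] = rng.standard_normal(500)  # waveform of the dropped source
        d2 = ComponentDecomposition(
            recording=_rec(mixing @ altered), sources=altered, mixing=mixing,
            channel_means=np.zeros(6), variance_retained=1.0)
        keep = np.array([True, True, False])
        assert np.array_equal(d1.reconstruct(keep=keep), d2.reconstruct(keep=keep))

    def test_denoising_reduces_rmse_vs_ground_truth(self, artifact_run):
        rec, bundle = artifact_run
        den = reconstruct_denoised(classify_components(decompose(rec)))
        rmse_raw = np.sqrt(np.mean((rec.data - bundle.clean_signal) ** 2))
        rmse_den = np.sqrt(np.mean((den.data - bundle.clean_signal) ** 2))
        assert rmse_den < rmse_raw

    def test_denoising_preserves_shape_and_rate(self, artifact_run):
        rec, _ = artifact_run
        den = reconstruct_denoised(classify_components(decompose(rec)))
        assert den.data.shape == rec.data.shape
        assert den.sampling_rate_hz == rec.sampling_rate_hz


class TestBandpass:
    def _tone(self, freq, fs=25.0, dur=600.0):
        t = np.arange(int(dur * fs)) / fs
        data = np.vstack([np.sin(2 * np.pi * freq * t),
                          np.cos(2 * np.pi * freq * t)])
        return _rec(data, fs=fs)

    def test_one_hz_tone_attenuated(self):
        rec = self._tone(1.0)
        out = bandpass(rec, 0.01, 0.1)
        ratio = out.data.std() / rec.data.std()
        assert ratio <= 0.1

    def test_in_band_tone_preserved(self):
        rec = self._tone(0.05)
        out = bandpass(rec, 0.01, 0.1)
        # compare away from the record edges (zero-phase, but finite settling)
        sl = slice(2000, -2000)
        ratio = out.data[:, sl].std() / rec.data[:, sl].std()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_constant_removed(self):
        rec = _rec(np.full((2, 15000), 3.7), fs=25.0)
        out = bandpass(rec, 0.01, 0.1)
        assert np.abs(out.data).max() < 1e-6

    def test_short_record_rejected(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 200)), fs=5.0)
        with pytest.raises(ValueError, match="settling"):
            bandpass(rec, 0.01, 0.1)

    def test_high_edge_above_nyquist_rejected(self):
        rec = _rec(np.zeros((2, 5000)) + np.random.default_rng(0).standard_normal((2, 5000)), fs=0.15)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 0.01, 0.1)


class TestTruncateBins:
    def test_nineteen_prefix_windows(self, clean_run):
        rec, _ = clean_run
        wins = truncate_bins(rec)
        assert len(wins) == 19
        assert [w.duration_s for w in wins] == [60.0 + 30.0 * k for k in range(19)]
        for w in wins:
            assert w.n_samples == int(w.duration_s * rec.sampling_rate_hz)
        for a, b in zip(wins, wins[1:]):
            assert np.array_equal(b.data[:, : a.n_samples], a.data)

    def test_short_recording_rejected_with_available_maximum(self, clean_run):
        rec, _ = clean_run
        short = rec.with_data(rec.data[:, : int(200 * rec.sampling_rate_hz)])
        with pytest.raises(ValueError, match="200.0 s"):
            truncate_bins(short)


def test_component_report_table(artifact_run):
    from nirsnet.preprocess import component_report

    rec, _ = artifact_run
    d = classify_components(decompose(rec))
    rep = component_report(d)
    assert len(rep) == d.n_components
    assert set(rep.label.unique()) <= {"signal", "noise"}
    flagged = (rep.temporal_artifact | rep.out_of_band | rep.spatially_dispersive)
    assert np.array_equal(rep.label == "noise", flagged)
    assert rep.dominant_freq_hz.between(0, rec.sampling_rate_hz / 2).all()
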