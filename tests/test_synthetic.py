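"""Generator contracts: determinism, spectral structure, score link, artifacts."""

import numpy as np
import pytest

import eegscore as es
from eegscore.spectral import attach_scores

from conftest import TRUE_FEATURES, make_feature_matrix


def zero_amplitude_spec(**kw):
    amps = es.synthetic.default_band_amplitudes()
    for g in amps:
        for seg in amps[g]:
            for b in amps[g][seg]:
                amps[g][seg][b] = 0.0
    return es.CohortSpec(band_amplitudes=amps, **kw)


class TestGenerateRecording:
    def test_deterministic_and_index_sensitive(self):
        spec = es.CohortSpec(seed=5, n_text=2, n_video=1)
        a = es.generate_recording(spec, 0, "text")
        b = es.generate_recording(spec, 0, "text")
        c = es.generate_recording(spec, 1, "text")
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            es.generate_recording(es.CohortSpec(), 0, "audio")

    def test_session_layout(self, one_recording):
        labels = [(a.label, a.repetition) for a in one_recording.annotations]
        assert labels == [("EC", None), ("EO", None), ("LT", 1), ("LT", 2), ("LT", 3)]
        assert one_recording.segment("EO").n_samples == 30 * 256
        assert one_recording.segment("LT", 2).n_samples == 150 * 256

    def test_zero_alpha_amplitude_leaves_background_only(self):
        amps = es.synthetic.default_band_amplitudes()
        for g in amps:
            for seg in amps[g]:
                amps[g][seg]["alpha"] = 0.0
        spec = es.CohortSpec(seed=2, band_amplitudes=amps)
        rec = es.generate_recording(spec, 0, "video")
        seg = rec.segment_data("EO")
        win = int(rec.fs)
        n_win = seg.shape[1] // win
        spectra = np.abs(np.fft.rfft(seg[:, : n_win * win].reshape(8, n_win, win), axis=2)) ** 2
        mean_power = spectra.mean(axis=(0, 1))  # 1-Hz bins
        # no alpha peak: per-bin alpha power comparable to the band-gap bins around it
        alpha_bins = mean_power[8:12].mean()
        neighbor_bins = mean_power[[7, 12]].mean()
        assert alpha_bins < 2.0 * neighbor_bins

    def test_spectral_peaks_present_at_nonzero_bands(self, one_recording):
        """Each oscillation stands out above the local 1/f background."""
        fm_bands = es.window_band_power(one_recording.segment_data("EO"), one_recording.fs)
        zero = zero_amplitude_spec(seed=3, n_text=1, n_video=1)
        bg = es.generate_recording(zero, 0, "text")
        bg_bands = es.window_band_power(bg.segment_data("EO"), bg.fs)
        assert np.all(fm_bands.values.mean(axis=0) > bg_bands.values.mean(axis=0))

    def test_doubled_lt_alpha_normalizes_near_three(self):
        """Power scales as amplitude^2, so a 2x alpha amplitude during the
        learning task gives a baseline-normalized value of (4-1)/1 = 3."""
        amps = es.synthetic.default_band_amplitudes()
        for g in amps:
            amps[g]["EO"]["alpha"] = 20.0
            amps[g]["LT"]["alpha"] = 40.0
        spec = es.CohortSpec(
            seed=9,
            band_amplitudes=amps,
            background_rms=2.0,
            amplitude_jitter_global=0.0,
            amplitude_jitter_trait=0.0,
            amplitude_jitter_trait_channel=0.0,
            amplitude_jitter_state=0.0,
            amplitude_jitter_state_channel=0.0,
        )
        rec = es.generate_recording(spec, 0, "text")
        eo = es.window_band_power(rec.segment_data("EO"), rec.fs)
        lt = es.window_band_power(rec.segment_data("LT", 1), rec.fs)
        norm = es.normalize_power(lt, eo).mean_over_windows()
        alpha = norm[:, list(es.BAND_NAMES).index("alpha")]
        assert np.allclose(alpha, 3.0, rtol=0.10)


class TestGenerateScores:
    def test_constant_model(self, full_cohort):
        fm = full_cohort["fm"]
        spec = es.CohortSpec(
            seed=1, score_model=es.ScoreModel(("C3_alpha/theta",), (0.0,), 80.0, 0.0)
        )
        records = es.generate_scores(spec, fm)
        assert all(r.score == 80.0 for r in records)

    def test_unknown_feature_rejected(self, full_fm):
        spec = es.CohortSpec(score_model=es.ScoreModel(("C3_mu",), (1.0,), 0.0, 0.0))
        with pytest.raises(KeyError, match="C3_mu"):
            es.generate_scores(spec, full_fm)

    def test_deterministic(self, full_fm):
        spec = es.CohortSpec(seed=8)
        a = es.generate_scores(spec, full_fm)
        b = es.generate_scores(spec, full_fm)
        assert a == b

    def test_coefficient_recovery_within_sampling_theory(self, full_fm):
        """Fitted coefficients fall within 3 standard errors of truth at the
        OLS-theory rate (conditioning on one cohort's features, redrawing
        the score noise across 200 seeded replicates)."""
        model = es.ScoreModel(noise_sd=5.0)
        truth = np.array([model.intercept, *model.coefficients])
        ok = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = es.CohortSpec(seed=seed, score_model=model)
            fm = attach_scores(full_fm, es.generate_scores(spec, full_fm))
            X = fm[list(model.feature_names)].to_numpy()
            A = np.column_stack([np.ones(len(X)), X])
            y = fm["score"].to_numpy()
            fit = es.fit_normal_equation(X, y, model.feature_names)
            beta = np.array([fit.intercept, *fit.coefficients])
            resid = y - A @ beta
            sigma2 = resid @ resid / (len(y) - A.shape[1])
            se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))
            ok += bool(np.all(np.abs(beta - truth) <= 3 * se))
        assert ok / n_rep >= 0.95

    def test_noiseless_selection_ranks_true_features(self, noiseless_fm):
        """End-to-end causal path: with a deterministic score link the
        correlation stage flags both generating features as significant."""
        sel = es.correlation_select(noiseless_fm)
        assert set(TRUE_FEATURES) <= set(sel.significant["feature"])


class TestInjectArtifacts:
    def test_rate_zero_identity(self, one_recording):
        out, events = es.inject_artifacts(one_recording, rate=0.0, amplitude=30.0, seed=1)
        assert events == []
        assert np.array_equal(out.data, one_recording.data)

    def test_event_count_poisson(self, one_recording):
        """6 events/min over 3 x 150 s of learning task: 45 expected per
        recording; pooled count over 10 seeds inside the Poisson 99% band."""
        total = 0
        n_seeds = 10
        for seed in range(n_seeds):
            _, events = es.inject_artifacts(one_recording, rate=6.0, amplitude=30.0, seed=seed)
            total += len(events)
        expected = 45 * n_seeds
        half_width = 2.576 * np.sqrt(expected)
        assert expected - half_width <= total <= expected + half_width

    def test_injected_windows_are_loud(self, filtered_recording):
        """Each transient's own span is far louder than the clean signal
        on the channels it touches (> 5x RMS before any cleaning)."""
        dirty, events = es.inject_artifacts(filtered_recording, rate=6.0, amplitude=30.0, seed=4)
        clean_rms = np.sqrt(np.mean(filtered_recording.data**2))
        for e in events:
            span = dirty.data[list(e.channels), e.start_sample : e.end_sample]
            assert np.sqrt(np.mean(span**2)) > 5 * clean_rms

    def test_positions_cover_modified_samples(self, one_recording):
        dirty, events = es.inject_artifacts(one_recording, rate=6.0, amplitude=30.0, seed=2)
        changed = np.flatnonzero(np.any(dirty.data != one_recording.data, axis=0))
        covered = np.zeros(one_recording.n_samples, dtype=bool)
        for e in events:
            covered[e.start_sample : e.end_sample] = True
        assert np.all(covered[changed])
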