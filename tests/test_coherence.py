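import numpy as np
import pytest

from myocoh import SignalRecord
from myocoh.coherence import (
    BANDS,
    CoherenceSpectrum,
    ZDiffSpectrum,
    band_composite,
    confidence_level,
    effective_segments,
    extract_epochs,
    pooled_coherence,
    preprocess_eeg,
    z_difference,
)
from myocoh.records import TrialAnnotation

FS = 1000.0


class TestPreprocessEeg:
    def test_identical_channels_cancel_under_common_average(self, rng):
        x = rng.standard_normal(4000)
        rec = SignalRecord(np.column_stack([x, x]), FS, ["EEG_ipsi", "EEG_contra"])
        out = preprocess_eeg(rec)
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_common_average_rows_sum_to_zero(self, rng):
        rec = SignalRecord(rng.standard_normal((4000, 4)), FS,
                           ["EEG_ipsi", "EEG_contra", "other", "other"])
        out = preprocess_eeg(rec)
        np.testing.assert_allclose(out.samples.sum(axis=1), 0.0, atol=1e-9)

    def test_exclusion_changes_reference_exactly(self, rng):
        rec = SignalRecord(rng.standard_normal((4000, 3)), FS,
                           ["EEG_ipsi", "EEG_contra", "other"])
        dropped = preprocess_eeg(rec, bad_channels=["other"])
        # oracle: filter retained channels independently, subtract their mean
        manual = preprocess_eeg(
            SignalRecord(rec.samples[:, :2], FS, ["EEG_ipsi", "EEG_contra"])
        )
        np.testing.assert_allclose(dropped.samples, manual.samples, atol=1e-9)

    def test_all_excluded_rejected(self, rng):
        rec = SignalRecord(rng.standard_normal((100, 2)), FS, ["EEG_ipsi", "EEG_contra"])
        with pytest.raises(ValueError):
            preprocess_eeg(rec, bad_channels=[0, 1])


class TestPooledCoherence:
    def test_identical_signals_have_unit_coherence(self, rng):
        x = rng.standard_normal(8192)
        spec = pooled_coherence([x], [x], FS)
        assert np.allclose(spec.coherence, 1.0, atol=1e-9)

    def test_independent_noise_mostly_below_confidence_level(self, rng):
        x = rng.standard_normal(120_000)
        y = rng.standard_normal(120_000)
        spec = pooled_coherence([x], [y], FS)
        m = (spec.frequencies >= 5) & (spec.frequencies <= 100)
        frac = np.mean(spec.coherence[m] < spec.confidence_level)
        assert 0.88 <= frac <= 1.0

    def test_scaling_invariance(self, rng):
        x = rng.standard_normal(8192)
        y = rng.standard_normal(8192)
        a = pooled_coherence([x], [y], FS)
        b = pooled_coherence([5.0 * x], [0.1 * y], FS)
        np.testing.assert_allclose(a.coherence, b.coherence, rtol=1e-9)

    def test_segments_do_not_straddle_epochs(self, rng):
        # one long epoch vs the same data split in two: the split version
        # must not count segments across the boundary
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096)
        whole = pooled_coherence([x], [y], FS, overlap=0.0)
        split = pooled_coherence([x[:2048], x[2048:]], [y[:2048], y[2048:]], FS, overlap=0.0)
        assert whole.n_segments == split.n_segments == 8
        np.testing.assert_allclose(whole.coherence, split.coherence, atol=1e-12)

    def test_epoch_shorter_than_segment_rejected(self, rng):
        with pytest.raises(ValueError):
            pooled_coherence([rng.standard_normal(100)], [rng.standard_normal(100)], FS)

    def test_mismatched_epochs_rejected(self, rng):
        x = rng.standard_normal(1024)
        with pytest.raises(ValueError):
            pooled_coherence([x], [x[:512]], FS)
        with pytest.raises(ValueError):
            pooled_coherence([x], [x, x], FS)

    def test_effective_segments_no_overlap_is_raw_count(self):
        assert effective_segments([10, 5], 512, 0, "hann") == 15.0

    def test_effective_segments_overlap_shrinks_count(self):
        l_eff = effective_segments([100], 512, 384, "hann")
        assert 100 / 2.1 < l_eff < 100 / 1.7


class TestConfidenceLevel:
    def test_two_segments_gives_095(self):
        assert confidence_level(2) == pytest.approx(0.95)

    def test_l_21(self):
        assert confidence_level(21) == pytest.approx(1 - 0.05 ** (1 / 20))
        assert confidence_level(21) == pytest.approx(0.1391, abs=5e-4)

    def test_monotone_decreasing_to_zero(self):
        ls = np.array([2.0, 5.0, 20.0, 100.0, 1e5])
        cls = np.array([confidence_level(l) for l in ls])
        assert np.all(np.diff(cls) < 0)
        assert cls[-1] < 1e-4

    def test_l_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            confidence_level(1.0)


def make_spectrum(coh, L=60.0):
    freqs = np.arange(len(coh)) * (1000.0 / 512.0)
    return CoherenceSpectrum(freqs, np.asarray(coh, float), L, confidence_level(L), int(L))


class TestZDifference:
    def test_equal_spectra_give_zero(self):
        spec = make_spectrum(np.linspace(0.0, 0.8, 30))
        zd = z_difference(spec, spec)
        assert np.allclose(zd.z, 0.0)

    def test_sign_follows_coherence_change(self):
        pre = make_spectrum([0.2, 0.4, 0.4])
        post = make_spectrum([0.4, 0.4, 0.2])
        zd = z_difference(pre, post)
        assert zd.z[0] > 0 and zd.z[1] == 0 and zd.z[2] < 0

    def test_equal_l_matches_single_l_form(self):
        # with L_pre == L_post the two-sample denominator reduces to sqrt(1/L)
        pre = make_spectrum([0.2, 0.5], L=40.0)
        post = make_spectrum([0.3, 0.6], L=40.0)
        a = z_difference(pre, post, mode="two_sample")
        b = z_difference(pre, post, mode="single")
        np.testing.assert_allclose(a.z, b.z, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        pre = make_spectrum([0.2, 0.5])
        post = make_spectrum([0.2, 0.5, 0.7])
        with pytest.raises(ValueError):
            z_difference(pre, post)


class TestBandComposite:
    def test_four_unit_bins_give_two(self):
        zd = ZDiffSpectrum(np.array([13.0, 15.0, 17.0, 19.0]), np.ones(4), 60, 60, "two_sample")
        res = band_composite(zd, (12.0, 30.0), "beta")
        assert res.composite_z == pytest.approx(2.0)
        assert res.significant
        assert res.n_bins == 4

    def test_zero_bins_give_zero_not_significant(self):
        zd = ZDiffSpectrum(np.array([13.0, 15.0]), np.zeros(2), 60, 60, "two_sample")
        res = band_composite(zd, BANDS["beta"], "beta")
        assert res.composite_z == 0.0
        assert not res.significant

    def test_empty_band_rejected(self):
        zd = ZDiffSpectrum(np.array([13.0, 15.0]), np.zeros(2), 60, 60, "two_sample")
        with pytest.raises(ValueError):
            band_composite(zd, (40.0, 50.0))


class TestExtractEpochs:
    def test_epochs_follow_annotations(self, rng):
        n = 3000
        rec = SignalRecord(
            rng.standard_normal(n), 1000.0, ["ECR"],
            [TrialAnnotation("hold_plateau", 0.5, 1.5, 0),
             TrialAnnotation("hold_plateau", 2.0, 2.9, 1)],
        )
        epochs = extract_epochs(rec, "hold_plateau", "ECR")
        assert len(epochs) == 2
        assert len(epochs[0]) == 1000
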