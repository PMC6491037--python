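"""Envelope pipeline tests: segmentation arithmetic, filter response,
orthogonalization contract, Hilbert/conditioning oracles, CoV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envconn import (
    CohortDesign,
    SubjectRecording,
    bandpass,
    condition_envelope,
    cov_activity,
    hilbert_envelope,
    segment_and_concatenate,
    select_region_representative,
    simulate_subject,
    symmetric_orthogonalize,
)
from envconn.bands import ALPHA, BandSpec


def make_rec(data, fs=600.0):
    data = np.atleast_2d(data)
    return SubjectRecording(
        subject_id="s", group="control", data=data, sampling_rate=fs,
        node_labels=[f"n{i}" for i in range(data.shape[0])],
    )


class TestSegmentation:
    def test_no_rejection_is_identity(self, rng):
        rec = make_rec(rng.standard_normal((3, 6000)))
        out = segment_and_concatenate(rec, 2.0, [])
        assert np.array_equal(out.data, rec.data)

    def test_rejection_count_arithmetic(self, rng):
        # 300 s at 600 Hz in 2 s epochs: rejecting 5 of 150 leaves 145 x 1200.
        rec = make_rec(rng.standard_normal((2, 300 * 600)))
        out = segment_and_concatenate(rec, 2.0, [0, 10, 20, 30, 149])
        assert out.n_samples == 145 * 2 * 600
        assert out.metadata["n_epochs_retained"] == 145

    def test_retained_epochs_keep_order(self):
        data = np.arange(12, dtype=float).reshape(1, 12)
        out = segment_and_concatenate(make_rec(data, fs=2.0), 2.0, reject=[1])
        assert out.data.tolist() == [[0, 1, 2, 3, 8, 9, 10, 11]]

    def test_all_rejected_is_error(self, rng):
        rec = make_rec(rng.standard_normal((1, 1200)))
        with pytest.raises(ValueError, match="all epochs rejected"):
            segment_and_concatenate(rec, 2.0, [0])

    def test_nondividing_epoch_rejected(self, rng):
        rec = make_rec(rng.standard_normal((1, 1000)))
        with pytest.raises(ValueError, match="does not divide"):
            segment_and_concatenate(rec, 2.0, [])


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = bandpass(make_rec(np.zeros((2, 6000))), ALPHA)
        assert np.allclose(out.data, 0.0)

    def test_passband_tone_preserved(self):
        t = np.arange(0, 20, 1 / 600)
        rec = make_rec(np.sin(2 * np.pi * 10 * t))
        out = bandpass(rec, ALPHA)
        core = slice(600, -600)  # exclude filter edges
        rms_in = np.sqrt(np.mean(rec.data[0, core] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, core] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_stopband_tone_attenuated_20db(self):
        t = np.arange(0, 20, 1 / 600)
        rec = make_rec(np.sin(2 * np.pi * 50 * t))
        out = bandpass(rec, ALPHA)
        core = slice(600, -600)
        atten = 20 * np.log10(
            np.sqrt(np.mean(rec.data[0, core] ** 2))
            / np.sqrt(np.mean(out.data[0, core] ** 2))
        )
        assert atten >= 20

    def test_band_beyond_nyquist_is_error(self, rng):
        rec = make_rec(rng.standard_normal((1, 1000)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, BandSpec("HighGamma", 60.0, 140.0))


class TestRegionRepresentative:
    def test_single_channel(self):
        assert select_region_representative(np.ones((1, 50))) == 0

    def test_largest_sd_wins(self, rng):
        chans = np.vstack(
            [rng.standard_normal(500) * s for s in (1.0, 3.0, 2.0)]
        )
        assert select_region_representative(chans) == 1

    def test_exact_tie_lowest_index(self):
        row = np.sin(np.linspace(0, 20, 300))
        assert select_region_representative(np.vstack([row, row])) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            select_region_representative(np.empty((0, 10)))


class TestSymmetricOrthogonalize:
    def gram_ratio(self, y):
        g = y @ y.T
        return np.abs(g - np.diag(np.diag(g))).max() / np.diag(g).min()

    def test_orthogonal_input_is_fixed_point(self):
        t = np.arange(1000) / 100.0
        x = np.vstack(
            [np.sin(2 * np.pi * f * t) for f in (1.0, 2.0, 3.0)]
        )  # mutually orthogonal over whole periods
        y = symmetric_orthogonalize(x)
        # equal up to per-row scaling
        scale = np.einsum("ij,ij->i", y, x) / np.einsum("ij,ij->i", x, x)
        assert np.linalg.norm(y - scale[:, None] * x) < 1e-8 * np.linalg.norm(x)

    def test_gram_offdiagonal_vanishes(self, rng):
        x = rng.standard_normal((15, 4000))
        assert self.gram_ratio(symmetric_orthogonalize(x)) < 1e-8

    def test_correlated_input_still_orthogonalized(self, rng):
        base = rng.standard_normal((1, 3000))
        x = base + 0.3 * rng.standard_normal((8, 3000))
        assert self.gram_ratio(symmetric_orthogonalize(x)) < 1e-8

    def test_duplicate_rows_rejected(self, rng):
        row = rng.standard_normal(500)
        x = np.vstack([row, row, rng.standard_normal(500)])
        with pytest.raises(ValueError, match="rank deficient"):
            symmetric_orthogonalize(x)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="more samples than nodes"):
            symmetric_orthogonalize(rng.standard_normal((10, 10)))

    def test_closer_than_plain_qr(self, rng):
        # The symmetric solution should beat an asymmetric (order-dependent)
        # Gram-Schmidt orthogonalization in Frobenius distance to the input.
        x = rng.standard_normal((6, 800))
        y = symmetric_orthogonalize(x)
        q, r = np.linalg.qr(x.T)
        gs = (q * np.einsum("ij,ij->j", q, x.T)).T  # per-row LS rescale of GS basis
        assert np.linalg.norm(x - y) <= np.linalg.norm(x - gs) + 1e-9


class TestHilbertEnvelope:
    def test_constant_amplitude_tone(self):
        t = np.arange(0, 10, 1 / 600)
        env = hilbert_envelope(3.5 * np.sin(2 * np.pi * 10 * t))
        core = env[0, 300:-300]  # exclude 0.5 s edges
        assert np.all(np.abs(core - 3.5) / 3.5 < 0.01)

    def test_zero_signal(self):
        assert np.allclose(hilbert_envelope(np.zeros((2, 100))), 0.0)

    def test_homogeneity(self, rng):
        x = rng.standard_normal((2, 500))
        assert np.allclose(hilbert_envelope(4.0 * x), 4.0 * hilbert_envelope(x))


class TestConditionEnvelope:
    def test_trim_rule_300s(self):
        env = np.abs(np.random.default_rng(0).standard_normal((3, 300 * 600))) + 1
        out = condition_envelope(env, 600.0)
        assert out.n_samples == 295

    @pytest.mark.parametrize("duration", [7, 10, 33, 61])
    def test_trim_conservation(self, duration):
        env = np.ones((1, duration * 100))
        out = condition_envelope(env, 100.0)
        assert out.n_samples == duration - 5

    def test_spike_removed(self):
        env = np.ones((1, 20 * 100))
        env[0, 750] = 100.0
        out = condition_envelope(env, 100.0)
        assert out.env.max() / np.median(out.env) < 1.1

    def test_homogeneity(self, rng):
        env = np.abs(rng.standard_normal((2, 2000))) + 0.5
        a = condition_envelope(env, 100.0).env
        b = condition_envelope(3.0 * env, 100.0).env
        assert np.allclose(b, 3.0 * a)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            condition_envelope(np.ones((1, 600)), 100.0)


class TestCovActivity:
    def test_constant_envelope_zero_cov(self):
        es = condition_envelope(np.ones((2, 2000)), 100.0)
        assert np.allclose(cov_activity(es).cov, 0.0)

    def test_known_value(self):
        # envelope [1,3,1,3]: mean 2, sample sd 1.1547, CoV 0.5774
        from envconn.envelope import EnvelopeSet

        es = EnvelopeSet("s", ALPHA, np.array([[1.0, 3.0, 1.0, 3.0]]))
        assert cov_activity(es).cov[0] == pytest.approx(0.5773502691896257, abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        from envconn.envelope import EnvelopeSet

        rng = np.random.default_rng(5)
        env = np.abs(rng.standard_normal((3, 50))) + 0.1
        a = cov_activity(EnvelopeSet("s", ALPHA, env)).cov
        b = cov_activity(EnvelopeSet("s", ALPHA, scale * env)).cov
        assert np.allclose(a, b, rtol=1e-9)

    def test_zero_mean_rejected(self):
        from envconn.envelope import EnvelopeSet

        es = EnvelopeSet("s", ALPHA, np.zeros((1, 20)))
        with pytest.raises(ValueError, match="zero-mean"):
            cov_activity(es)


class TestLeakageRecoveryRegression:
    @pytest.mark.parametrize("leak", [0.0, 0.2, 0.4])
    def test_planted_correlation_survives_orthogonalization(self, leak):
        """Recovered Fisher z after orthogonalization stays near the target
        regardless of leakage strength."""
        from envconn import amplitude_correlation_matrix
        from envconn.envelope import subject_band_envelope

        base = np.eye(6)
        base[0, 1] = base[1, 0] = 0.6
        d = CohortDesign(
            n_case=1, n_control=1, n_nodes=6, duration=120.0, sampling_rate=200.0,
            bands=[ALPHA], base_envelope_corr={"Alpha": base},
            leakage_strength=leak, seed=17,
        )
        zs = [
            amplitude_correlation_matrix(
                subject_band_envelope(simulate_subject(d, "control", s), ALPHA),
                variance_normalize=False,
            ).z[0, 1]
            for s in range(12)
        ]
        assert abs(np.mean(zs) - np.arctanh(0.6)) < 0.15
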