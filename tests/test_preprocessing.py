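"""Filtering, referencing, resampling, epoching and template matching."""

import numpy as np
import pytest

from restalpha.montage import (
    CLUSTER_14_MONTAGE,
    DEFAULT_64_MONTAGE,
    TopographyTemplate,
    default_templates,
)
from restalpha.preprocessing import (
    ComponentSet,
    TemplateUnmatchedError,
    bandpass_filter,
    epoch_signal,
    match_templates,
    rereference_average,
    resample_signal,
    roi_time_series,
)
from restalpha.recording import MultichannelRecording
from restalpha.simulate import generate_subject, sample_subject_params
from tests_support_config import make_default_like_config


def tone_recording(freq, fs=500.0, duration=20.0, n_channels=2):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_channels, 1))
    labels = [f"C{i}" for i in range(n_channels)]
    return MultichannelRecording(data, fs, labels)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        rec = tone_recording(10.0)
        out = bandpass_filter(rec)
        mid = slice(2000, 8000)  # avoid edge transients
        ratio = np.std(out.data[0][mid]) / np.std(rec.data[0][mid])
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuation(self):
        rec = tone_recording(2.0)
        out = bandpass_filter(rec)
        mid = slice(2000, 8000)
        assert np.std(out.data[0][mid]) < 0.01 * np.std(rec.data[0][mid])

    def test_zero_phase(self):
        rng = np.random.default_rng(0)
        rec = MultichannelRecording(rng.standard_normal((1, 10000)), 500.0, ["Cz"])
        out = bandpass_filter(rec)
        x = bandpass_filter(out).data[0]  # compare two filtered versions
        y = out.data[0]
        lags = np.arange(-50, 51)
        xc = [np.dot(x[50:-50], y[50 + l:len(y) - 50 + l]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_low_rate_rejected(self):
        rec = tone_recording(10.0, fs=25.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec)


class TestRereference:
    def test_zero_mean_per_sample(self):
        rng = np.random.default_rng(1)
        rec = MultichannelRecording(rng.standard_normal((5, 100)), 500.0,
                                    [f"C{i}" for i in range(5)])
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        rec = MultichannelRecording(rng.standard_normal((4, 50)), 500.0,
                                    [f"C{i}" for i in range(4)])
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data)

    def test_balanced_pair_unchanged(self):
        rec = MultichannelRecording(np.array([[1.0] * 10, [-1.0] * 10]), 500.0,
                                    ["A", "B"])
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data, rec.data)


class TestResample:
    def test_downsample_preserves_tone(self):
        rec = tone_recording(10.0, fs=1000.0, duration=20.0, n_channels=1)
        out = resample_signal(rec, 500.0)
        from restalpha.spectral import compute_power_spectrum, detect_iaf, sgf_smooth
        from restalpha.preprocessing import epoch_series

        ps = sgf_smooth(compute_power_spectrum(epoch_series(out.data[0], 500.0), 500.0))
        assert detect_iaf(ps) == pytest.approx(10.0, abs=0.1)

    def test_identity_at_same_rate(self):
        rec = tone_recording(10.0)
        assert resample_signal(rec, 500.0) is rec

    def test_length_arithmetic(self):
        rec = MultichannelRecording(np.zeros((1, 120_000)), 1000.0, ["Cz"])
        out = resample_signal(rec, 500.0)
        assert out.n_samples == 60_000
        assert out.fs_hz == 500.0

    def test_upsampling_rejected_by_default(self):
        rec = tone_recording(10.0)
        with pytest.raises(ValueError):
            resample_signal(rec, 1000.0)
        assert resample_signal(rec, 1000.0, allow_upsample=True).n_samples == 20_000


class TestEpoching:
    @pytest.mark.parametrize(
        "duration_s, epoch_ms, expected",
        [(120.0, 2000.0, 60), (2.999, 2000.0, 1), (5.0, 2500.0, 2)],
    )
    def test_epoch_counts(self, duration_s, epoch_ms, expected):
        n = int(duration_s * 500)
        rec = MultichannelRecording(np.zeros((2, n)), 500.0, ["A", "B"])
        assert epoch_signal(rec, epoch_ms).n_epochs == expected

    def test_short_recording_rejected(self):
        rec = MultichannelRecording(np.zeros((1, 999)), 500.0, ["Cz"])
        with pytest.raises(ValueError):
            epoch_signal(rec, 2000.0)

    def test_channel_permutation_commutes(self):
        rng = np.random.default_rng(3)
        labels = ["A", "B", "C"]
        rec = MultichannelRecording(rng.standard_normal((3, 4000)), 500.0, labels)
        perm = [2, 0, 1]
        rec_p = MultichannelRecording(rec.data[perm], 500.0,
                                      [labels[i] for i in perm])
        direct = epoch_signal(rereference_average(rec_p)).data
        permuted = epoch_signal(rereference_average(rec)).data[:, perm, :]
        np.testing.assert_allclose(direct, permuted, atol=1e-12)


def _component_set(topo_columns, labels):
    topo = np.column_stack(topo_columns)
    acts = np.zeros((topo.shape[1], 10))
    return ComponentSet(topo, acts, list(labels), 500.0, provenance="synthetic-truth")


class TestTemplateMatching:
    def test_exact_match_selected(self):
        labels = list(DEFAULT_64_MONTAGE)
        templates = default_templates(labels)
        comps = _component_set([t.weights for t in templates], labels)
        sel = match_templates(comps, templates)
        assert all(len(v) == 1 for v in sel.values())
        assert sorted(j for v in sel.values() for j in v) == [0, 1, 2, 3]

    def test_sign_flip_and_scale_invariance(self):
        labels = list(DEFAULT_64_MONTAGE)
        templates = default_templates(labels)
        comps = _component_set(
            [-5.0 * t.weights for t in templates], labels
        )
        sel = match_templates(comps, templates)
        assert all(len(v) == 1 for v in sel.values())

    def test_unmatched_template_raises(self):
        labels = list(DEFAULT_64_MONTAGE)
        templates = default_templates(labels)
        rng = np.random.default_rng(0)
        comps = _component_set([rng.standard_normal(len(labels))], labels)
        with pytest.raises(TemplateUnmatchedError, match="S01"):
            match_templates(comps, templates, subject_id="S01")

    def test_top_three_rule(self):
        """Five components above threshold for one template: the three
        strongest are retained."""
        labels = list(DEFAULT_64_MONTAGE)
        template = default_templates(labels)[0]
        w = template.weights
        wc = w - w.mean()
        wc /= np.linalg.norm(wc)
        rng = np.random.default_rng(1)
        v = rng.standard_normal(len(labels))
        v -= v.mean()
        v -= (v @ wc) * wc
        v /= np.linalg.norm(v)
        rs = [0.95, 0.90, 0.85, 0.82, 0.81]
        cols = [r * wc + np.sqrt(1 - r**2) * v for r in rs]
        comps = _component_set(cols, labels)
        sel = match_templates(comps, [template])
        assert sel[template.name] == [0, 1, 2]

    def test_orthogonal_component_not_selected(self):
        labels = list(DEFAULT_64_MONTAGE)
        template = default_templates(labels)[0]
        w = template.weights
        wc = (w - w.mean()) / np.linalg.norm(w - w.mean())
        rng = np.random.default_rng(2)
        v = rng.standard_normal(len(labels))
        v -= v.mean()
        v -= (v @ wc) * wc
        comps = _component_set([w, v], labels)
        sel = match_templates(comps, [template])
        assert sel[template.name] == [0]


class TestRoiSeries:
    def test_single_source_both_modes_recover_it(self):
        cfg = make_default_like_config(background_uv=0.0, sensor_noise_uv=0.0)
        p = sample_subject_params(cfg, 1, seed=4)[0]
        rec = generate_subject(p, duration_s=20, montage=CLUSTER_14_MONTAGE,
                               keep_truth_components=True)
        comps = rec.meta["components"]
        bp = roi_time_series(components=comps, mode="backprojection")
        ca = roi_time_series(recording=rec, mode="cluster-average")
        for roi in ("posterior_L", "posterior_R"):
            assert abs(np.corrcoef(bp[roi], ca[roi])[0, 1]) > 0.9

    def test_cluster_average_of_identical_channels(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        rec = MultichannelRecording(np.tile(x, (14, 1)), 500.0,
                                    list(CLUSTER_14_MONTAGE))
        out = roi_time_series(recording=rec, mode="cluster-average")
        for roi_series in out.values():
            np.testing.assert_allclose(roi_series, x)

    def test_orthogonal_sources_stay_separate(self):
        rng = np.random.default_rng(6)
        left = rng.standard_normal(5000)
        right = rng.standard_normal(5000)
        from restalpha.simulate import project_to_scalp

        rec = project_to_scalp({"posterior_L": left, "posterior_R": right},
                               CLUSTER_14_MONTAGE, sensor_noise_uv=0.0)
        out = roi_time_series(recording=rec, mode="cluster-average")
        # weak residual correlation from the Gaussian spatial spread only
        r = np.corrcoef(out["posterior_L"], right)[0, 1]
        assert abs(r) < 0.3
        r_own = np.corrcoef(out["posterior_L"], left)[0, 1]
        assert r_own > 0.9

    def test_backprojection_requires_components(self):
        with pytest.raises(ValueError):
            roi_time_series(mode="backprojection")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            roi_time_series(mode="pca")
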