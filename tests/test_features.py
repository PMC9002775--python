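"""Segmentation, moment extraction, normalization and EDF round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from randnet.edf import quantization_step, read_edf, write_edf
from randnet.features import (
    CHANNELS_19,
    CHANNELS_21,
    EEGSegment,
    NormalizationParams,
    apply_normalizer,
    drop_channels,
    extract_features,
    fit_normalizer,
    segment_recording,
)


class TestSegmentation:
    @pytest.mark.parametrize("n_samples,expected", [
        (1500, 3),   # three whole seconds
        (499, 0),    # shorter than one window
        (2750, 5),   # trailing 250 samples dropped
    ])
    def test_window_counts(self, n_samples, expected):
        signal = np.zeros((19, n_samples))
        segs = segment_recording(signal, fs=500, labels=[0] * 6)
        assert len(segs) == expected
        for s in segs:
            assert s.data.shape == (19, 500)

    def test_windows_are_contiguous_and_labeled(self):
        signal = np.arange(2 * 1000, dtype=float).reshape(2, 1000)
        segs = segment_recording(signal, fs=500, labels=[3, 1],
                                 channel_names=["a", "b"])
        assert np.array_equal(segs[1].data, signal[:, 500:])
        assert [s.label for s in segs] == [3, 1]
        assert segs[1].t_start == 1.0

    def test_channel_count_enforced(self):
        with pytest.raises(ValueError, match="expected 19"):
            segment_recording(np.zeros((5, 500)), 500, [0],
                              expected_channels=19)


class TestDropChannels:
    def test_montage_reduces_to_19(self):
        signal = np.arange(21 * 10).reshape(21, 10).astype(float)
        out, names = drop_channels(signal, CHANNELS_21)
        assert out.shape[0] == 19
        assert names == CHANNELS_19
        # order of the survivors is preserved
        assert np.array_equal(out[0], signal[0])

    def test_idempotent_when_already_dropped(self):
        signal = np.zeros((19, 10))
        with pytest.warns(UserWarning, match="skipped"):
            out, names = drop_channels(signal, CHANNELS_19)
        assert out.shape == signal.shape and names == CHANNELS_19

    def test_empty_name_list_is_identity(self):
        signal = np.random.default_rng(0).normal(size=(3, 5))
        out, names = drop_channels(signal, ["x", "y", "z"], names=())
        assert np.array_equal(out, signal) and names == ["x", "y", "z"]


class TestMoments:
    def test_constant_channel_degenerate_moments(self):
        seg = EEGSegment(np.full((1, 500), 7.5), label=0, channel_names=["c"])
        vec = extract_features(seg)
        assert vec.values.tolist() == [0.0, 0.0, 0.0, 7.5]

    def test_two_point_symmetric_distribution(self):
        """Alternating -1/+1: mean 0, std 1, skew 0, excess kurtosis -2."""
        x = np.tile([-1.0, 1.0], 250)
        seg = EEGSegment(x[None, :], label=0, channel_names=["c"])
        std, kurt, skew, mean = extract_features(seg).values
        assert std == pytest.approx(1.0)
        assert kurt == pytest.approx(-2.0)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_feature_vector_length_is_four_per_channel(self, small_segments):
        vec = extract_features(small_segments[0])
        assert vec.values.shape == (76,)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.normal(0, 10, (5, 500))
        names = [f"c{i}" for i in range(5)]
        base = extract_features(
            EEGSegment(data, 0, channel_names=names)).values
        perm = rng.permutation(5)
        permuted = extract_features(
            EEGSegment(data[perm], 0,
                       channel_names=[names[i] for i in perm])).values
        assert np.allclose(permuted.reshape(5, 4), base.reshape(5, 4)[perm])

    def test_nan_names_the_channel(self):
        data = np.zeros((2, 500))
        data[1, 3] = np.nan
        seg = EEGSegment(data, 0, channel_names=["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            extract_features(seg)


class TestNormalization:
    def test_endpoints_and_midpoint(self, rng):
        X = rng.normal(0, 5, (30, 4))
        params = fit_normalizer(X)
        assert np.allclose(params.transform(params.x_min[None, :]), 0.0)
        assert np.allclose(params.transform(params.x_max[None, :]), 1.0)
        mid = (params.x_min + params.x_max) / 2
        assert np.allclose(params.transform(mid[None, :]), 0.5)

    def test_constant_feature_maps_to_zero(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        params = fit_normalizer(X)
        out = params.transform(X)
        assert np.all(out[:, 0] == 0.0)
        assert np.all(np.isfinite(out))

    def test_out_of_range_test_values_clipped(self):
        params = NormalizationParams(np.array([0.0]), np.array([1.0]))
        out = params.transform(np.array([[-5.0], [0.5], [9.0]]))
        assert out.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_apply_before_fit_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            apply_normalizer(None, np.zeros(3))

    @given(st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_on_training_data(self, seed):
        gen = np.random.default_rng(seed)
        X = gen.uniform(-10, 10, (15, 3))
        params = fit_normalizer(X)
        once = params.transform(X)
        again = NormalizationParams.fit(once).transform(once)
        assert np.allclose(once, again, atol=1e-12)


class TestEDF:
    def test_round_trip_within_quantization(self, tmp_path, rng):
        data = rng.normal(0, 50, (19, 1500))
        path = tmp_path / "rec.edf"
        write_edf(path, data, 500, CHANNELS_19)
        back, fs, names = read_edf(path)
        assert fs == 500 and names == CHANNELS_19
        steps = np.array([
            quantization_step(np.floor(data[c].min()), np.ceil(data[c].max()))
            for c in range(19)
        ])
        assert np.max(np.abs(back - data) / steps[:, None]) <= 1.0

    def test_constant_channel_round_trips_exactly(self, tmp_path):
        data = np.vstack([np.full(500, 12.0), np.zeros(500)])
        path = tmp_path / "const.edf"
        write_edf(path, data, 500, ["c1", "c2"])
        back, _, _ = read_edf(path)
        step = quantization_step(12.0, 13.0)
        assert np.max(np.abs(back[0] - 12.0)) <= step
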