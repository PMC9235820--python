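"""Epoch container I/O, resampling, component extraction, feature matrices."""

import numpy as np
import pytest

import megsurprise as ms
from megsurprise.epochs import from_mne_epochs  # noqa: F401  (optional-import surface)


def make_tensor(n=8, c=3, t=10, seed=0, times=None):
    rng = np.random.default_rng(seed)
    times = np.linspace(-200, 600, t) if times is None else times
    return ms.EpochTensor(
        data=rng.standard_normal((n, c, times.size)),
        times_ms=times,
        channel_names=[f"CH{i}" for i in range(c)],
        stimuli=(rng.random(n) < 0.3).astype(int),
    )


class TestHdf5RoundTrip:
    def test_lossless(self, tmp_path):
        tensor = make_tensor()
        path = tmp_path / "epochs.h5"
        ms.write_epochs(tensor, path)
        back = ms.read_epochs(path)
        assert np.array_equal(back.data, tensor.data)
        assert np.array_equal(back.times_ms, tensor.times_ms)
        assert back.channel_names == tensor.channel_names
        assert np.array_equal(back.stimuli, tensor.stimuli)
        assert back.kind == tensor.kind

    def test_missing_dataset_named_in_error(self, tmp_path):
        import h5py

        path = tmp_path / "broken.h5"
        tensor = make_tensor()
        ms.write_epochs(tensor, path)
        with h5py.File(path, "a") as f:
            del f["stimuli"]
        with pytest.raises(KeyError, match="stimuli"):
            ms.read_epochs(path)

    def test_default_synthetic_shape(self, tmp_path, default_tensor):
        path = tmp_path / "default.h5"
        ms.write_epochs(default_tensor, path)
        back = ms.read_epochs(path)
        assert (back.n_trials, back.n_channels, back.n_times) == (405, 20, 80)


class TestTensorValidation:
    def test_shape_mismatches_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="times_ms"):
            ms.EpochTensor(rng.standard_normal((4, 2, 5)), np.arange(4), ["a", "b"],
                           [0, 1, 0, 1])
        with pytest.raises(ValueError, match="channel names"):
            ms.EpochTensor(rng.standard_normal((4, 2, 5)), np.arange(5), ["a"],
                           [0, 1, 0, 1])
        with pytest.raises(ValueError, match="stimulus labels"):
            ms.EpochTensor(rng.standard_normal((4, 2, 5)), np.arange(5), ["a", "b"],
                           [0, 1])

    def test_non_increasing_times_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="strictly increasing"):
            ms.EpochTensor(rng.standard_normal((2, 1, 3)), [0.0, 0.0, 1.0], ["a"], [0, 1])


class TestResample:
    def test_downsample_to_80_spans_window(self):
        tensor = make_tensor(t=200)
        out = ms.resample_epochs(tensor, 80)
        assert out.n_times == 80
        assert out.times_ms[0] == tensor.times_ms[0]
        assert out.times_ms[-1] == tensor.times_ms[-1]

    def test_identity_when_counts_match(self):
        tensor = make_tensor(t=50)
        out = ms.resample_epochs(tensor, 50)
        assert np.array_equal(out.data, tensor.data)
        assert np.array_equal(out.times_ms, tensor.times_ms)

    def test_constant_signal_stays_constant(self):
        tensor = make_tensor(t=120)
        const = ms.EpochTensor(np.full_like(tensor.data, 3.5), tensor.times_ms,
                               tensor.channel_names, tensor.stimuli)
        out = ms.resample_epochs(const, 40)
        assert np.all(out.data == 3.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ms.resample_epochs(make_tensor(), 1)


class TestExtractComponents:
    def test_bypass_flips_kind(self, small_tensor):
        _, tensor = small_tensor
        out = ms.extract_components(tensor, tensor.n_channels, seed=0, bypass=True)
        assert out.kind == "component"
        assert np.array_equal(out.data, tensor.data)

    def test_recovers_mixed_sources(self):
        rng = np.random.default_rng(17)
        n, t = 40, 100
        s1 = np.sign(rng.standard_normal((n, t)))  # super-Gaussian source
        s2 = rng.uniform(-1, 1, (n, t))  # sub-Gaussian source
        mix = np.array([[1.0, 0.6], [0.4, 1.0]])
        data = np.einsum("ck,nkt->nct", mix, np.stack([s1, s2], axis=1))
        tensor = ms.EpochTensor(data, np.linspace(-200, 600, t), ["a", "b"],
                                (rng.random(n) < 0.3).astype(int))
        out = ms.extract_components(tensor, 2, seed=0)
        assert out.kind == "component"
        sources = np.stack([s1.ravel(), s2.ravel()])
        recovered = out.data.transpose(1, 0, 2).reshape(2, -1)
        corr = np.abs(np.corrcoef(np.vstack([sources, recovered]))[:2, 2:])
        # each true source matches one component up to sign/permutation
        assert corr.max(axis=1).min() > 0.95

    def test_component_input_rejected(self, small_tensor):
        _, tensor = small_tensor
        comp = ms.extract_components(tensor, tensor.n_channels, seed=0, bypass=True)
        with pytest.raises(ValueError, match="sensor"):
            ms.extract_components(comp, 2, seed=0)


class TestBuildFeatures:
    def test_entire_dimension_is_channels_times_samples(self):
        tensor = make_tensor(n=5, c=69, t=80)
        X = ms.build_features(tensor, ms.RegimeSpec(regime="entire"))
        assert X.values.shape == (5, 5520)

    def test_samples_regime_one_value_per_channel(self, small_tensor):
        _, tensor = small_tensor
        X = ms.build_features(tensor, ms.RegimeSpec(regime="samples", t_ms=0.0))
        assert X.values.shape == (tensor.n_trials, tensor.n_channels)

    def test_intervals_at_end_equals_entire(self, small_tensor):
        _, tensor = small_tensor
        Xi = ms.build_features(
            tensor, ms.RegimeSpec(regime="intervals", t_ms=float(tensor.times_ms[-1]))
        )
        Xe = ms.build_features(tensor, ms.RegimeSpec(regime="entire"))
        assert np.array_equal(Xi.values, Xe.values)

    def test_segments_partition_all_columns(self, small_tensor):
        _, tensor = small_tensor
        entire = ms.build_features(tensor, ms.RegimeSpec(regime="entire"))
        seen = []
        for name in ("baseline", "early", "middle", "late"):
            spec = ms.RegimeSpec(regime="segments", segment=name, t1_ms=100.0, t2_ms=350.0)
            seen.extend(ms.build_features(tensor, spec).feature_index)
        assert sorted(seen) == sorted(entire.feature_index)  # no overlap, no gap

    def test_channel_major_column_order(self, small_tensor):
        _, tensor = small_tensor
        X = ms.build_features(tensor, ms.RegimeSpec(regime="entire"))
        chans = [c for c, _ in X.feature_index]
        assert chans == sorted(chans)  # channel varies slowest
        manual = tensor.data[2].reshape(-1)
        assert np.array_equal(X.values[2], manual)

    def test_spatial_single_channel(self, small_tensor):
        _, tensor = small_tensor
        X = ms.build_features(tensor, ms.RegimeSpec(regime="spatial", channel="CH001"))
        assert X.values.shape == (tensor.n_trials, tensor.n_times)
        assert np.array_equal(X.values, tensor.data[:, 1, :])

    def test_errors(self, small_tensor):
        _, tensor = small_tensor
        with pytest.raises(ValueError, match="outside the epoch"):
            ms.build_features(tensor, ms.RegimeSpec(regime="samples", t_ms=900.0))
        with pytest.raises(KeyError, match="unknown channel"):
            ms.build_features(tensor, ms.RegimeSpec(regime="spatial", channel="nope"))
        with pytest.raises(ValueError, match="no samples"):
            # early segment collapses when t1 precedes the first post-onset sample
            ms.build_features(
                tensor,
                ms.RegimeSpec(regime="segments", segment="early", t1_ms=1e-6, t2_ms=350.0),
            )
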