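"""Power curves, segment boundaries, segment statistics, and spatial maps."""

import numpy as np
import pandas as pd
import pytest

import megsurprise as ms
from megsurprise.regimes import (
    Comparison,
    average_curves,
    bonferroni_threshold,
    spatial_measure_tests,
)


def curve_from(times, r2):
    return ms.PowerCurve(np.asarray(times, float), np.asarray(r2, float),
                         "samples", "shannon", (16.0,))


class TestDetectSegments:
    def test_constructed_curve_with_dip(self):
        # zero before 60 ms, max 0.2 at 200 ms, dip 0.01 at 350 ms, second bump later
        times = np.arange(-200.0, 601.0, 10.0)
        r2 = np.zeros_like(times)
        r2[times == 60] = 0.05
        r2[(times > 60) & (times < 350)] = 0.1
        r2[times == 200] = 0.2
        r2[times == 350] = 0.01
        r2[(times > 350)] = 0.08
        r2[times == 450] = 0.15
        bounds = ms.detect_segments(curve_from(times, r2))
        assert (bounds.t1_ms, bounds.t2_ms) == (60.0, 350.0)
        assert bounds.provenance == "detected"

    def test_flat_positive_curve_tie_rules(self):
        times = np.arange(-200.0, 601.0, 10.0)
        bounds = ms.detect_segments(curve_from(times, np.full_like(times, 0.1)))
        assert bounds.t1_ms == 10.0  # first strictly post-stimulus sample
        assert bounds.t2_ms == 250.0  # earliest tie in the dip window

    def test_zero_curve_rejected(self):
        times = np.arange(-200.0, 601.0, 10.0)
        with pytest.raises(ValueError, match="no detectable response"):
            ms.detect_segments(curve_from(times, np.zeros_like(times)))

    def test_baseline_power_is_ignored(self):
        # large pre-stimulus power must not drag t1 before onset
        times = np.arange(-200.0, 601.0, 10.0)
        r2 = np.where(times < 0, 0.5, 0.0)
        r2[times >= 200] = 0.2
        bounds = ms.detect_segments(curve_from(times, r2))
        assert bounds.t1_ms == 200.0

    def test_detected_t2_inside_dip_window(self, default_seq, default_tensor):
        curve = ms.samples_curve(default_tensor, default_seq, "shannon",
                                 w_grid=(16.0,), seed=0)
        bounds = ms.detect_segments(curve)
        assert 0 < bounds.t1_ms < bounds.t2_ms
        assert 250.0 <= bounds.t2_ms <= 400.0


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [(3, 0.0167), (12, 0.0042)])
    def test_thresholds_to_four_decimals(self, m, expected):
        assert round(bonferroni_threshold(0.05, m), 4) == expected

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestCompareSegments:
    def test_identical_powers_are_null(self):
        table = pd.DataFrame({"early": [0.1] * 6, "middle": [0.1] * 6, "late": [0.1] * 6})
        report = ms.compare_segments(table)
        assert report.anova_p == pytest.approx(1.0)
        assert not any(c.significant for c in report.comparisons)

    def test_strong_middle_effect_detected(self):
        rng = np.random.default_rng(0)
        n = 12
        table = pd.DataFrame({
            "early": 0.01 + 0.005 * rng.standard_normal(n),
            "middle": 0.5 + 0.05 * rng.standard_normal(n),
            "late": 0.05 + 0.02 * rng.standard_normal(n),
        })
        report = ms.compare_segments(table)
        assert report.anova_p < 0.0167
        by_label = {c.label: c for c in report.comparisons}
        assert by_label["early vs middle"].significant
        assert by_label["early vs middle"].corrected_threshold == pytest.approx(0.05 / 3)

    def test_unbalanced_table_rejected(self):
        table = pd.DataFrame({"early": [0.1, np.nan], "middle": [0.2, 0.3],
                              "late": [0.1, 0.2]})
        with pytest.raises(ValueError, match="unbalanced"):
            ms.compare_segments(table)

    def test_single_subject_rejected(self):
        table = pd.DataFrame({"early": [0.1], "middle": [0.2], "late": [0.1]})
        with pytest.raises(ValueError, match="replicates"):
            ms.compare_segments(table)


class TestCurves:
    def test_intervals_final_time_equals_entire(self, small_tensor):
        seq, tensor = small_tensor
        curve = ms.intervals_curve(tensor, seq, "shannon", w_grid=(16.0,), seed=0)
        X = ms.build_features(tensor, ms.RegimeSpec(regime="entire"))
        y = ms.surprise_series(seq, "shannon", 16.0)
        entire = ms.fit_decode(X, y, seed=0)
        assert curve.r2_values[-1] == pytest.approx(entire.r2, abs=1e-12)

    def test_curve_frame_and_average(self, small_tensor):
        seq, tensor = small_tensor
        c1 = ms.samples_curve(tensor, seq, "shannon", w_grid=(16.0,), seed=0)
        c2 = ms.samples_curve(tensor, seq, "shannon", w_grid=(16.0,), seed=1)
        avg = average_curves([c1, c2])
        assert np.allclose(avg.r2_values, (c1.r2_values + c2.r2_values) / 2)
        df = c1.to_frame()
        assert list(df.columns) == ["time_ms", "r2", "best_w"]
        assert len(df) == tensor.n_times


class TestSegmentPowers:
    def test_middle_encoding_dominates(self, default_seq, default_tensor):
        bounds = ms.SegmentBoundaries(150.0, 360.0, measure="shannon",
                                      provenance="user_supplied")
        powers = ms.segment_powers(default_tensor, default_seq, "shannon", bounds,
                                   w_grid=(16.0,), seed=0, n_permutations=19)
        mid = powers["middle"]
        assert mid.result.r2 > mid.chance.percentile(95)
        assert powers["baseline"].result.r2 < 0.05
        assert abs(powers["baseline"].result.r2 - powers["baseline"].chance.mean) < 0.1


class TestSpatialMap:
    def _loaded_tensor(self, seed, loadings):
        seq = ms.generate_oddball(150, 1.0 / 3.0, seed=seed)
        times = np.linspace(-200, 600, 20)
        s = ms.surprise_series(seq, "shannon", 16.0).values
        s = (s - s.mean()) / s.std()
        g = np.exp(-((times - 250.0) ** 2) / (2 * 50.0**2))
        rng = np.random.default_rng(seed + 1)
        data = (0.8 * s[:, None, None] * np.asarray(loadings)[None, :, None] * g[None, None, :]
                + rng.standard_normal((150, len(loadings), times.size)))
        tensor = ms.EpochTensor(data, times, [f"CH{i}" for i in range(len(loadings))],
                                seq.labels)
        return seq, tensor

    def test_loaded_channels_rank_highest(self):
        loadings = [0.0, 0.0, 0.0, 2.0, 2.0, 0.1]
        seq, tensor = self._loaded_tensor(31, loadings)
        table, stats = ms.spatial_map(tensor, seq, ["shannon"], w_grid=(16.0,), seed=0)
        assert stats is None
        top2 = set(table.nlargest(2, "r2")["channel"])
        assert top2 == {"CH3", "CH4"}

    def test_table_has_one_row_per_channel_per_measure(self):
        seq, tensor = self._loaded_tensor(32, [1.0, -1.0, 0.5])
        table, stats = ms.spatial_map(tensor, seq, ["shannon", "bayesian"],
                                      w_grid=(16.0,), seed=0)
        assert len(table) == 2 * tensor.n_channels
        assert set(table["measure"]) == {"shannon", "bayesian"}

    def test_replicated_input_yields_paired_tests(self):
        pairs = [self._loaded_tensor(40 + k, [1.5, 0.0]) for k in range(3)]
        seqs = [p[0] for p in pairs]
        tensors = [p[1] for p in pairs]
        table, stats = ms.spatial_map(tensors, seqs, ["shannon", "bayesian"],
                                      w_grid=(16.0,), seed=0)
        assert stats is not None
        assert stats.family_size == 2  # 1 measure pair x 2 channels
        assert all(isinstance(c, Comparison) for c in stats.comparisons)

    def test_single_replicate_tests_refused(self):
        seq, tensor = self._loaded_tensor(50, [1.0, 0.5])
        table, _ = ms.spatial_map(tensor, seq, ["shannon", "bayesian"],
                                  w_grid=(16.0,), seed=0)
        with pytest.raises(ValueError, match="replicates"):
            spatial_measure_tests(table)

    def test_component_tensor_rejected(self, small_tensor):
        seq, tensor = small_tensor
        comp = ms.extract_components(tensor, tensor.n_channels, seed=0, bypass=True)
        with pytest.raises(ValueError, match="sensor"):
            ms.spatial_map(comp, seq, ["shannon"], w_grid=(16.0,), seed=0)
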