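"""Temporal/spatial decoding-power analysis: curves, segment boundaries, statistics.

Workflow mirrored here:

1. Decode surprise at every single sample time (``samples_curve``) and for
   every accumulating interval from the epoch start (``intervals_curve``).
2. Partition the post-stimulus epoch into Early / Middle / Late segments from
   the samples curve (``detect_segments``): t1 is the first post-stimulus
   time whose decoding power reaches 10% of the post-stimulus maximum, and
   t2 is the minimum of the curve within [250, 400] ms (the dip between the
   middle and late response components).
3. Decode each segment and pair it with its permutation chance distribution
   (``segment_powers``); compare segments across replicates with a one-way
   repeated-measures ANOVA plus Bonferroni-corrected post-hoc paired t-tests
   (``compare_segments``).
4. Decode each channel separately from its full (or segment-restricted) time
   course to map where surprise is best read out (``spatial_map``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import ChanceDistribution, DecodingResult, chance_level, fit_decode
from .epochs import SEGMENT_NAMES, EpochTensor, RegimeSpec, build_features
from .surprise import surprise_series

__all__ = [
    "PowerCurve",
    "SegmentBoundaries",
    "SegmentPower",
    "Comparison",
    "StatsReport",
    "bonferroni_threshold",
    "samples_curve",
    "intervals_curve",
    "detect_segments",
    "segment_powers",
    "compare_segments",
    "spatial_map",
    "segment_study",
    "SegmentStudy",
]


@dataclass(frozen=True)
class PowerCurve:
    """Decoding power as a function of time for one temporal regime."""

    times_ms: np.ndarray
    r2_values: np.ndarray
    regime: str  # {"samples", "intervals"}
    measure: str
    w_grid: tuple[float, ...]
    best_w: np.ndarray | None = None
    replicate_curves: np.ndarray | None = None  # (n_replicates, n_times)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        object.__setattr__(self, "r2_values", np.asarray(self.r2_values, dtype=float))
        if self.times_ms.size != self.r2_values.size:
            raise ValueError("times and r2 values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times_ms, "r2": self.r2_values})
        if self.best_w is not None:
            df["best_w"] = self.best_w
        return df


@dataclass(frozen=True)
class SegmentBoundaries:
    """The (t1, t2) borders separating Early / Middle / Late segments."""

    t1_ms: float
    t2_ms: float
    measure: str | None = None
    provenance: str = "detected"  # {"detected", "user_supplied"}

    def __post_init__(self) -> None:
        if not 0 < self.t1_ms < self.t2_ms:
            raise ValueError("boundaries must satisfy 0 < t1 < t2")


@dataclass(frozen=True)
class SegmentPower:
    result: DecodingResult
    chance: ChanceDistribution

    @property
    def empirical_p(self) -> float:
        return self.chance.empirical_p(self.result.r2)


@dataclass(frozen=True)
class Comparison:
    label: str
    statistic: float
    p_value: float
    corrected_threshold: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_threshold


@dataclass(frozen=True)
class StatsReport:
    """A family of Bonferroni-corrected comparisons, optionally with an ANOVA."""

    comparisons: tuple[Comparison, ...]
    family_size: int
    alpha: float = 0.05
    correction: str = "bonferroni"
    anova_f: float | None = None
    anova_p: float | None = None

    @property
    def corrected_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.family_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contrast": c.label,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "corrected_threshold": c.corrected_threshold,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ]
        )


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    """Per-test significance threshold alpha / m."""
    if family_size < 1:
        raise ValueError("family size must be at least 1")
    return alpha / family_size


def _curve(tensor: EpochTensor, seq, measure: str, regime: str, w_grid,
           n_folds: int, seed: int) -> PowerCurve:
    w_grid = tuple(sorted(float(w) for w in w_grid))
    labels = {w: surprise_series(seq, measure, w) for w in w_grid}
    r2s = np.empty(tensor.n_times)
    best_ws = np.empty(tensor.n_times)
    for i, t in enumerate(tensor.times_ms):
        X = build_features(tensor, RegimeSpec(regime=regime, t_ms=float(t)))
        best_r2, best_w = -np.inf, w_grid[0]
        for w in w_grid:
            r2 = fit_decode(X, labels[w], n_folds=n_folds, seed=seed).r2
            if r2 > best_r2:
                best_r2, best_w = r2, w
        r2s[i], best_ws[i] = best_r2, best_w
    return PowerCurve(tensor.times_ms.copy(), r2s, regime, measure, w_grid, best_ws)


def samples_curve(tensor: EpochTensor, seq, measure: str, w_grid=(16.0,),
                  n_folds: int = 5, seed: int = 0) -> PowerCurve:
    """Decoding power of each single sample time (max over the w grid)."""
    return _curve(tensor, seq, measure, "samples", w_grid, n_folds, seed)


def intervals_curve(tensor: EpochTensor, seq, measure: str, w_grid=(16.0,),
                    n_folds: int = 5, seed: int = 0) -> PowerCurve:
    """Decoding power of the accumulating interval [epoch start, t]."""
    return _curve(tensor, seq, measure, "intervals", w_grid, n_folds, seed)


def average_curves(curves) -> PowerCurve:
    """Replicate-mean samples/intervals curve (boundaries are detected on it)."""
    curves = list(curves)
    times = curves[0].times_ms
    stack = np.vstack([c.r2_values for c in curves])
    return PowerCurve(times, stack.mean(axis=0), curves[0].regime, curves[0].measure,
                      curves[0].w_grid, replicate_curves=stack)


def detect_segments(curve: PowerCurve, *, dip_window_ms: tuple[float, float] = (250.0, 400.0)
                    ) -> SegmentBoundaries:
    """Derive (t1, t2) from a samples-regime decoding-power curve.

    t1: earliest post-stimulus time whose power reaches 10% of the
    post-stimulus maximum (baseline power is noise and is ignored).
    t2: time of minimum power within the dip window [250, 400] ms, earliest
    on ties — the trough separating the middle and late response components.
    """
    times, r2 = curve.times_ms, curve.r2_values
    post = times > 0
    if not post.any():
        raise ValueError("curve has no post-stimulus samples")
    peak = r2[post].max()
    if peak <= 0:
        raise ValueError("no detectable response: post-stimulus decoding power is nonpositive")
    t_post, r_post = times[post], r2[post]
    t1 = float(t_post[np.flatnonzero(r_post >= 0.10 * peak)[0]])
    in_dip = (times >= dip_window_ms[0]) & (times <= dip_window_ms[1])
    if not in_dip.any():
        raise ValueError(f"curve has no samples in the dip window {dip_window_ms} ms")
    t_dip, r_dip = times[in_dip], r2[in_dip]
    t2 = float(t_dip[np.argmin(r_dip)])  # argmin takes the earliest tie
    return SegmentBoundaries(t1_ms=t1, t2_ms=t2, measure=curve.measure, provenance="detected")


def segment_powers(tensor: EpochTensor, seq, measure: str,
                   boundaries: SegmentBoundaries, w_grid=(16.0,), n_folds: int = 5,
                   seed: int = 0, n_permutations: int = 100,
                   segments=SEGMENT_NAMES) -> dict[str, SegmentPower]:
    """Decode each named segment and pair it with its permutation chance band."""
    w_grid = tuple(sorted(float(w) for w in w_grid))
    labels = {w: surprise_series(seq, measure, w) for w in w_grid}
    out: dict[str, SegmentPower] = {}
    for name in segments:
        spec = RegimeSpec(regime="segments", segment=name,
                          t1_ms=boundaries.t1_ms, t2_ms=boundaries.t2_ms)
        X = build_features(tensor, spec)
        best, best_w = None, None
        for w in w_grid:
            res = fit_decode(X, labels[w], n_folds=n_folds, seed=seed)
            if best is None or res.r2 > best.r2:
                best, best_w = res, w
        chance = chance_level(X, labels[best_w], n_permutations=n_permutations,
                              n_folds=n_folds, seed=seed)
        out[name] = SegmentPower(result=best, chance=chance)
    return out


def _segment_table(table: pd.DataFrame, segments) -> pd.DataFrame:
    missing = [s for s in segments if s not in table.columns]
    if missing:
        raise ValueError(f"segment table lacks columns {missing}")
    sub = table[list(segments)]
    if sub.isna().any().any():
        raise ValueError("segment table is unbalanced (missing entries)")
    if len(sub) < 2:
        raise ValueError("need at least 2 replicates for segment comparison")
    return sub


def compare_segments(table: pd.DataFrame, *, alpha: float = 0.05,
                     segments=("early", "middle", "late")) -> StatsReport:
    """Repeated-measures ANOVA across segments plus post-hoc paired t-tests.

    ``table`` is wide: one row per subject/replicate, one column per segment.
    The post-hoc family is the three segment pairs, so the Bonferroni
    threshold is alpha/3 (0.0167 at alpha = 0.05).
    """
    from statsmodels.stats.anova import AnovaRM

    sub = _segment_table(table, segments)
    long = sub.reset_index(names="subject").melt(
        id_vars="subject", var_name="segment", value_name="r2"
    )
    # zero between-segment variance makes the RM-ANOVA F-ratio 0/0; report F=0, p=1
    if np.allclose(sub.to_numpy().var(axis=1), 0.0):
        f_val, p_val = 0.0, 1.0
    else:
        res = AnovaRM(long, depvar="r2", subject="subject", within=["segment"]).fit()
        f_val = float(res.anova_table["F Value"].iloc[0])
        p_val = float(res.anova_table["Pr > F"].iloc[0])

    pairs = list(itertools.combinations(segments, 2))
    threshold = bonferroni_threshold(alpha, len(pairs))
    comparisons = []
    for a, b in pairs:
        diff = sub[a].to_numpy() - sub[b].to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(sub[a], sub[b])
        comparisons.append(Comparison(f"{a} vs {b}", float(t), float(p), threshold))
    return StatsReport(comparisons=tuple(comparisons), family_size=len(pairs), alpha=alpha,
                       anova_f=f_val, anova_p=p_val)


def spatial_map(tensors, seqs, measures, w_grid=(16.0,), *,
                boundaries: SegmentBoundaries | None = None, segment: str | None = None,
                n_folds: int = 5, seed: int = 0, alpha: float = 0.05,
                ) -> tuple[pd.DataFrame, StatsReport | None]:
    """Per-channel decoding powers, optionally compared between measures.

    Each channel is decoded from its own time course (all samples, or a
    segment's samples when ``segment`` and ``boundaries`` are given), for
    every requested measure.  With multiple replicates (lists of tensors and
    sequences), measure pairs are compared per channel with paired t-tests
    across replicates; a single replicate yields no statistics.
    """
    if isinstance(tensors, EpochTensor):
        tensors, seqs = [tensors], [seqs]
    tensors, seqs = list(tensors), list(seqs)
    if len(tensors) != len(seqs):
        raise ValueError("need one stimulus sequence per epoch tensor")
    for tensor in tensors:
        if tensor.kind != "sensor":
            raise ValueError("spatial analysis expects sensor-space tensors")
    w_grid = tuple(sorted(float(w) for w in w_grid))
    measures = list(measures)

    rows = []
    for rep, (tensor, seq) in enumerate(zip(tensors, seqs)):
        labels = {(m, w): surprise_series(seq, m, w) for m in measures for w in w_grid}
        for ch in tensor.channel_names:
            spec = RegimeSpec(
                regime="spatial", channel=ch, segment=segment,
                t1_ms=None if boundaries is None else boundaries.t1_ms,
                t2_ms=None if boundaries is None else boundaries.t2_ms,
            )
            X = build_features(tensor, spec)
            for m in measures:
                best = max(
                    fit_decode(X, labels[(m, w)], n_folds=n_folds, seed=seed).r2
                    for w in w_grid
                )
                rows.append({"replicate": rep, "channel": ch, "measure": m, "r2": best})
    table = pd.DataFrame(rows)

    stats_report = None
    if len(tensors) > 1 and len(measures) > 1:
        stats_report = spatial_measure_tests(table, alpha=alpha)
    return table, stats_report


@dataclass(frozen=True)
class SegmentStudy:
    """Multi-replicate segment analysis: powers, chance, and both test families."""

    boundaries: SegmentBoundaries
    r2_table: pd.DataFrame  # replicate x segment decoding powers
    chance_table: pd.DataFrame  # replicate x segment permutation-chance means
    vs_chance: StatsReport  # paired t-tests r2 vs chance per segment
    between_segments: StatsReport  # RM-ANOVA + post-hoc over early/middle/late


def segment_study(datasets, measure: str, w_grid=(16.0,), *, n_folds: int = 5,
                  seed: int = 0, n_permutations: int = 10,
                  chance_segments=SEGMENT_NAMES, vs_chance_family: int = 12,
                  alpha: float = 0.05) -> SegmentStudy:
    """Segment decoding across subject-like replicates, with both test families.

    For each replicate (a (sequence, tensor) pair) the samples curve is
    computed; segment boundaries are detected once on the replicate-averaged
    curve; each replicate's four segments are then decoded and the segments
    in ``chance_segments`` get a permutation-chance mean.  Decoding powers
    are compared to chance with paired t-tests across replicates, Bonferroni
    corrected for a family of ``vs_chance_family`` tests (12 by default: the
    joint correction when three measures and four segments are examined), and
    early/middle/late are compared with :func:`compare_segments`.
    """
    datasets = list(datasets)
    curves = [samples_curve(tensor, seq, measure, w_grid, n_folds, seed)
              for seq, tensor in datasets]
    bounds = detect_segments(average_curves(curves))

    r2_rows, chance_rows = [], []
    for rep, (seq, tensor) in enumerate(datasets):
        powers = segment_powers(
            tensor, seq, measure, bounds, w_grid, n_folds, seed,
            n_permutations, segments=chance_segments,
        )
        extra = [s for s in SEGMENT_NAMES if s not in chance_segments]
        if extra:
            labels = {w: surprise_series(seq, measure, w) for w in w_grid}
            for name in extra:
                spec = RegimeSpec(regime="segments", segment=name,
                                  t1_ms=bounds.t1_ms, t2_ms=bounds.t2_ms)
                X = build_features(tensor, spec)
                best = max(
                    (fit_decode(X, labels[w], n_folds=n_folds, seed=seed) for w in w_grid),
                    key=lambda r: r.r2,
                )
                powers[name] = SegmentPower(best, ChanceDistribution(
                    np.array([np.nan]), 1, seed))
        r2_rows.append({name: powers[name].result.r2 for name in SEGMENT_NAMES})
        chance_rows.append({name: powers[name].chance.mean
                            for name in chance_segments})
    r2_table = pd.DataFrame(r2_rows)
    chance_table = pd.DataFrame(chance_rows)

    threshold = bonferroni_threshold(alpha, vs_chance_family)
    comparisons = []
    for name in chance_segments:
        diff = r2_table[name].to_numpy() - chance_table[name].to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(r2_table[name], chance_table[name])
        comparisons.append(Comparison(f"{name} vs chance", float(t), float(p), threshold))
    vs_chance = StatsReport(comparisons=tuple(comparisons),
                            family_size=vs_chance_family, alpha=alpha)
    between = compare_segments(r2_table, alpha=alpha)
    return SegmentStudy(bounds, r2_table, chance_table, vs_chance, between)


def spatial_measure_tests(table: pd.DataFrame, *, alpha: float = 0.05) -> StatsReport:
    """Paired t-tests between measure pairs, per channel, across replicates."""
    if table["replicate"].nunique() < 2:
        raise ValueError(
            "pairwise measure comparisons need at least 2 replicates "
            "(a single subject provides no sampling distribution)"
        )
    wide = table.pivot_table(index=["channel", "replicate"], columns="measure", values="r2")
    measures = list(wide.columns)
    channels = table["channel"].unique()
    pairs = list(itertools.combinations(measures, 2))
    family = len(pairs) * len(channels)
    threshold = bonferroni_threshold(alpha, family)
    comparisons = []
    for ch in channels:
        block = wide.xs(ch, level="channel")
        for a, b in pairs:
            diff = block[a].to_numpy() - block[b].to_numpy()
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(block[a], block[b])
            comparisons.append(Comparison(f"{a} vs {b} @ {ch}", float(t), float(p), threshold))
    return StatsReport(comparisons=tuple(comparisons), family_size=family, alpha=alpha)
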