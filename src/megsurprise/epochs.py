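"""Epoched data container, HDF5 I/O, component extraction, and feature matrices.

The in-memory container is :class:`EpochTensor`: trials x channels (or
independent components) x timepoints with a millisecond time axis and the
per-trial binary stimulus labels.  Feature matrices for the decoder are built
from it under five regimes:

``entire``
    every channel's full time course concatenated per trial (p' = C * T_s);
``samples``
    the C channel values at the single sample nearest a target time;
``intervals``
    all samples from the epoch start through the target time, all channels;
``segments``
    all channels restricted to a contiguous time band [start, end);
``spatial``
    one channel's time course (optionally restricted to a segment).

Columns are ordered channel-major (channel varies slowest), so column
``k`` maps to channel ``k // n_times_used`` — stable indices for inspecting
decoder coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "EpochTensor",
    "RegimeSpec",
    "FeatureMatrix",
    "SEGMENT_NAMES",
    "read_epochs",
    "write_epochs",
    "resample_epochs",
    "extract_components",
    "build_features",
    "from_mne_epochs",
]

SEGMENT_NAMES = ("baseline", "early", "middle", "late")


@dataclass(frozen=True)
class EpochTensor:
    """Trials x channels/components x timepoints, with ms time axis."""

    data: np.ndarray
    times_ms: np.ndarray
    channel_names: tuple[str, ...]
    stimuli: np.ndarray
    kind: str = "sensor"  # {"sensor", "component"}

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times_ms, dtype=float)
        stim = np.asarray(self.stimuli, dtype=np.uint8)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times_ms", times)
        object.__setattr__(self, "stimuli", stim)
        object.__setattr__(self, "channel_names", tuple(str(c) for c in self.channel_names))
        if data.ndim != 3:
            raise ValueError("data must be a 3-d tensor (trials, channels, timepoints)")
        n, c, t = data.shape
        if min(n, c, t) < 1:
            raise ValueError("all tensor dimensions must be >= 1")
        if times.size != t:
            raise ValueError(f"times_ms has {times.size} entries for {t} timepoints")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if len(self.channel_names) != c:
            raise ValueError(f"{len(self.channel_names)} channel names for {c} channels")
        if stim.size != n:
            raise ValueError(f"{stim.size} stimulus labels for {n} trials")
        if not np.isin(stim, (0, 1)).all():
            raise ValueError("stimuli must be binary (0/1)")
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite values")
        if self.kind not in ("sensor", "component"):
            raise ValueError(f"kind must be 'sensor' or 'component', got {self.kind!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class RegimeSpec:
    """Which temporal/spatial slice of the epochs feeds the decoder."""

    regime: str  # {"entire", "samples", "intervals", "segments", "spatial"}
    t_ms: float | None = None
    segment: str | None = None
    t1_ms: float | None = None
    t2_ms: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("entire", "samples", "intervals", "segments", "spatial"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime in ("samples", "intervals") and self.t_ms is None:
            raise ValueError(f"regime {self.regime!r} requires t_ms")
        if self.regime == "segments":
            if self.segment not in SEGMENT_NAMES:
                raise ValueError(f"segment must be one of {SEGMENT_NAMES}")
            if self.segment != "baseline" and (self.t1_ms is None or self.t2_ms is None):
                raise ValueError("segments regime requires boundaries t1_ms and t2_ms")
        if self.regime == "spatial" and self.channel is None:
            raise ValueError("spatial regime requires a channel name")


@dataclass(frozen=True)
class FeatureMatrix:
    """N x p' matrix of decoder features with a column -> (channel, time) map."""

    values: np.ndarray
    regime: RegimeSpec
    feature_index: tuple[tuple[str, float], ...] = field(repr=False, default=())

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def write_epochs(tensor: EpochTensor, path) -> None:
    """Write the tensor to an HDF5 container (lossless round-trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.data.astype(np.float64))
        f.create_dataset("times_ms", data=tensor.times_ms.astype(np.float64))
        f.create_dataset(
            "channel_names",
            data=np.array(tensor.channel_names, dtype=h5py.string_dtype("utf-8")),
        )
        f.create_dataset("stimuli", data=tensor.stimuli.astype(np.uint8))
        f.attrs["kind"] = tensor.kind


def read_epochs(path) -> EpochTensor:
    """Read an HDF5 epoch container written by :func:`write_epochs`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "times_ms", "channel_names", "stimuli"):
            if name not in f:
                raise KeyError(f"epoch file {path} is missing dataset {name!r}")
        names = tuple(
            c.decode("utf-8") if isinstance(c, bytes) else str(c) for c in f["channel_names"][()]
        )
        return EpochTensor(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            channel_names=names,
            stimuli=f["stimuli"][()],
            kind=f.attrs.get("kind", "sensor"),
        )


def resample_epochs(tensor: EpochTensor, n_samples: int) -> EpochTensor:
    """Decimate each epoch onto an evenly spaced grid over the same window.

    Plain decimation: each new grid time takes the nearest original sample
    (earlier sample on half-grid ties).  ``n_samples`` equal to the current
    sample count is the identity.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if n_samples > tensor.n_times:
        raise ValueError("cannot resample to more samples than the input has")
    new_times = np.linspace(tensor.times_ms[0], tensor.times_ms[-1], n_samples)
    idx = _nearest_indices(tensor.times_ms, new_times)
    return replace(tensor, data=tensor.data[:, :, idx], times_ms=tensor.times_ms[idx])


def _nearest_indices(grid: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the grid point nearest each target; earlier point on ties."""
    pos = np.searchsorted(grid, targets)
    pos = np.clip(pos, 1, grid.size - 1)
    left, right = grid[pos - 1], grid[pos]
    # strict '<' keeps the earlier sample when the target sits mid-grid
    choose_right = (right - targets) < (targets - left)
    return np.where(choose_right, pos, pos - 1)


def extract_components(tensor: EpochTensor, n_components: int, seed: int,
                       *, bypass: bool = False, max_iter: int = 500) -> EpochTensor:
    """Unmix sensors into independent components (FastICA over concatenated trials).

    Trials are concatenated along time into a (N*T_s) x C matrix, a fixed-point
    ICA estimates the unmixing, and per-trial component time courses are
    returned with ``kind="component"``.  ``bypass=True`` skips unmixing and
    relabels channels as components (useful for synthetic data that is already
    unmixed).
    """
    if tensor.kind != "sensor":
        raise ValueError("component extraction expects a sensor-space tensor")
    if bypass:
        return replace(tensor, kind="component")
    if not 1 <= n_components <= tensor.n_channels:
        raise ValueError("n_components must be between 1 and the channel count")
    from sklearn.decomposition import FastICA

    n, c, t = tensor.data.shape
    stacked = tensor.data.transpose(0, 2, 1).reshape(n * t, c)
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=max_iter,
                  whiten="unit-variance")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            sources = ica.fit_transform(stacked)
        except UserWarning as exc:  # sklearn warns on non-convergence
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations"
            ) from exc
    comp = sources.reshape(n, t, n_components).transpose(0, 2, 1)
    names = tuple(f"IC{i:03d}" for i in range(n_components))
    return EpochTensor(comp, tensor.times_ms, names, tensor.stimuli, kind="component")


def _segment_window(tensor: EpochTensor, spec: RegimeSpec) -> tuple[float, float]:
    """Half-open [start, end) window of a named segment; 'late' reaches past the last sample."""
    eps = 1e-9
    t1, t2 = spec.t1_ms, spec.t2_ms
    if spec.segment == "baseline":
        return (tensor.times_ms[0] - eps, 0.0)
    if spec.segment == "early":
        return (0.0, float(t1))
    if spec.segment == "middle":
        return (float(t1), float(t2))
    return (float(t2), tensor.times_ms[-1] + eps)


def build_features(tensor: EpochTensor, spec: RegimeSpec) -> FeatureMatrix:
    """Assemble the N x p' feature matrix for a regime (channel-major columns)."""
    times = tensor.times_ms

    if spec.regime == "entire":
        time_idx = np.arange(tensor.n_times)
        chan_idx = np.arange(tensor.n_channels)
    elif spec.regime == "samples":
        _check_t(times, spec.t_ms)
        time_idx = _nearest_indices(times, np.array([spec.t_ms]))
        chan_idx = np.arange(tensor.n_channels)
    elif spec.regime == "intervals":
        _check_t(times, spec.t_ms)
        last = _nearest_indices(times, np.array([spec.t_ms]))[0]
        time_idx = np.arange(last + 1)
        chan_idx = np.arange(tensor.n_channels)
    elif spec.regime == "segments":
        lo, hi = _segment_window(tensor, spec)
        time_idx = np.flatnonzero((times >= lo) & (times < hi))
        if time_idx.size == 0:
            raise ValueError(f"segment {spec.segment!r} window [{lo}, {hi}) contains no samples")
        chan_idx = np.arange(tensor.n_channels)
    else:  # spatial
        try:
            ch = tensor.channel_names.index(spec.channel)
        except ValueError:
            raise KeyError(f"unknown channel {spec.channel!r}") from None
        chan_idx = np.array([ch])
        if spec.segment is not None:
            lo, hi = _segment_window(tensor, spec)
            time_idx = np.flatnonzero((times >= lo) & (times < hi))
            if time_idx.size == 0:
                raise ValueError(f"segment {spec.segment!r} contains no samples")
        else:
            time_idx = np.arange(tensor.n_times)

    block = tensor.data[np.ix_(np.arange(tensor.n_trials), chan_idx, time_idx)]
    values = block.reshape(tensor.n_trials, chan_idx.size * time_idx.size)
    index = tuple(
        (tensor.channel_names[c], float(times[t])) for c in chan_idx for t in time_idx
    )
    return FeatureMatrix(values=values, regime=spec, feature_index=index)


def _check_t(times: np.ndarray, t_ms: float) -> None:
    if not (times[0] <= t_ms <= times[-1]):
        raise ValueError(f"t_ms={t_ms} lies outside the epoch [{times[0]}, {times[-1]}] ms")


def from_mne_epochs(epochs, stimuli) -> EpochTensor:
    """Convert an MNE Epochs object to the HDF5-backed container.

    Optional import hook: requires ``mne`` only when called.  Times are
    converted from seconds to ms; ``stimuli`` supplies the per-trial binary
    labels (MNE event codes are acquisition-specific).
    """
    data = epochs.get_data()
    return EpochTensor(
        data=data,
        times_ms=np.asarray(epochs.times) * 1000.0,
        channel_names=tuple(epochs.ch_names),
        stimuli=np.asarray(stimuli),
        kind="sensor",
    )
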