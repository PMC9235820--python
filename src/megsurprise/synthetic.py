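"""Synthetic oddball sequences and surprise-encoding epochs.

The generator emulates the study conditions the pipeline is designed for:
one oddball block of ~405 trials with deviant probability 1/3, epochs
spanning -200..600 ms at 80 samples, and an evoked component whose amplitude
is proportional to the theoretical surprise of each trial.  Every trial n,
channel c and time t receives::

    data(n, c, t) = L_c * (beta0 + beta1 * S(n)) * g(t) + eta(n, c, t)

where S is the chosen surprise series at the chosen integration coefficient
(z-scored across trials so ``beta1`` means the same thing for every measure),
g is an unnormalized Gaussian bump at (encode_center_ms, encode_width_ms),
L_c are seeded channel loadings with unit root-mean-square, and eta is
Gaussian noise, optionally AR(1) along time.  AR(1) innovations are scaled by
sqrt(1 - rho^2) so the stationary marginal standard deviation stays at
``noise_sd`` for any rho.

This is a deliberately minimal encoding model — no forward head model, no
1/f spectra, no artifacts — sufficient for the decoder to have a known
ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochTensor
from .surprise import MEASURES, surprise_series

__all__ = ["StimulusSequence", "SyntheticEpochSpec", "generate_oddball", "simulate_epochs",
           "replicate_datasets", "write_sequence_csv", "read_sequence_csv"]


@dataclass(frozen=True)
class StimulusSequence:
    """A binary oddball stream: 0 = standard (frequent), 1 = deviant (rare)."""

    labels: np.ndarray
    p_deviant: float
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.size < 1:
            raise ValueError("sequence must contain at least one trial")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if not 0.0 <= self.p_deviant <= 1.0:
            raise ValueError("p_deviant must lie in [0, 1]")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_deviants(self) -> int:
        return int(self.labels.sum())


def generate_oddball(T: int, p_deviant: float, seed: int) -> StimulusSequence:
    """Draw T i.i.d. Bernoulli(p_deviant) stimulus labels (seeded)."""
    if T < 1:
        raise ValueError("T must be a positive integer")
    if not 0.0 <= p_deviant <= 1.0:
        raise ValueError("p_deviant must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = (rng.random(T) < p_deviant).astype(int)
    return StimulusSequence(labels=labels, p_deviant=float(p_deviant), seed=seed)


def _default_times() -> np.ndarray:
    return np.linspace(-200.0, 600.0, 80)


@dataclass(frozen=True)
class SyntheticEpochSpec:
    """Parameters of the surprise-encoding epoch simulator.

    Defaults are the package's study conditions: 20 channels, 80 samples over
    [-200, 600] ms, encoding bump at 250 +/- 50 ms, unit noise with gain
    beta1 = 0.5 (signal-to-noise beta1/noise_sd = 0.5), mild AR(1) temporal
    correlation, Shannon surprise at w = 16 as the ground-truth label.
    """

    n_trials: int = 405
    n_channels: int = 20
    times_ms: np.ndarray = field(default_factory=_default_times)
    encode_center_ms: float = 250.0
    encode_width_ms: float = 50.0
    beta0: float = 0.0
    beta1: float = 0.5
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    loading_seed: int = 101
    noise_seed: int = 202
    true_measure: str = "shannon"
    true_w: float = 16.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", times)
        if times.size == 0:
            raise ValueError("times_ms must be nonempty")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if self.n_trials < 1 or self.n_channels < 1:
            raise ValueError("n_trials and n_channels must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.true_measure not in MEASURES:
            raise ValueError(f"true_measure must be one of {MEASURES}")
        if not self.true_w > 0:
            raise ValueError("true_w must be positive")
        lo = self.encode_center_ms - 2 * self.encode_width_ms
        hi = self.encode_center_ms + 2 * self.encode_width_ms
        if hi < 0 or lo > times[-1]:
            raise ValueError("encoding window does not intersect the post-stimulus interval")


def simulate_epochs(seq: StimulusSequence, spec: SyntheticEpochSpec = SyntheticEpochSpec()
                    ) -> EpochTensor:
    """Simulate surprise-encoding epochs for a stimulus sequence.

    Bitwise reproducible under fixed ``loading_seed`` and ``noise_seed``.
    With ``beta1 = 0`` the data is statistically independent of the surprise
    labels; with ``noise_sd = 0`` every channel/time value is an exact affine
    function of the surprise series wherever the bump is nonzero.
    """
    if len(seq) != spec.n_trials:
        spec = _with_trials(spec, len(seq))
    series = surprise_series(seq, spec.true_measure, spec.true_w)
    s = series.values
    sd = s.std()
    s = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)

    g = np.exp(-((spec.times_ms - spec.encode_center_ms) ** 2)
               / (2.0 * spec.encode_width_ms**2))

    load_rng = np.random.default_rng(spec.loading_seed)
    loadings = load_rng.standard_normal(spec.n_channels)
    loadings /= np.sqrt(np.mean(loadings**2))

    amp = spec.beta0 + spec.beta1 * s  # (N,)
    signal = amp[:, None, None] * loadings[None, :, None] * g[None, None, :]

    noise_rng = np.random.default_rng(spec.noise_seed)
    n, c, t = len(seq), spec.n_channels, spec.times_ms.size
    eps = noise_rng.standard_normal((n, c, t))
    if spec.ar1_rho > 0:
        rho = spec.ar1_rho
        noise = np.empty_like(eps)
        noise[:, :, 0] = eps[:, :, 0]
        scale = np.sqrt(1.0 - rho**2)
        for k in range(1, t):
            noise[:, :, k] = rho * noise[:, :, k - 1] + scale * eps[:, :, k]
    else:
        noise = eps
    data = signal + spec.noise_sd * noise

    names = tuple(f"CH{i:03d}" for i in range(c))
    return EpochTensor(data=data, times_ms=spec.times_ms, channel_names=names,
                       stimuli=seq.labels, kind="sensor")


def _with_trials(spec: SyntheticEpochSpec, n_trials: int) -> SyntheticEpochSpec:
    from dataclasses import replace

    return replace(spec, n_trials=n_trials)


def replicate_datasets(n_replicates: int, spec: SyntheticEpochSpec = SyntheticEpochSpec(),
                       base_seed: int = 0, p_deviant: float = 1.0 / 3.0,
                       ) -> list[tuple[StimulusSequence, EpochTensor]]:
    """Simulate independent subject-like replicates of the oddball study.

    Each replicate draws its own stimulus sequence and its own channel
    loadings and noise (seeds offset deterministically from ``base_seed``),
    emulating different participants run on the same protocol.
    """
    from dataclasses import replace

    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    out = []
    for r in range(n_replicates):
        seq = generate_oddball(spec.n_trials, p_deviant, seed=base_seed + 1000 * r)
        rspec = replace(spec, loading_seed=spec.loading_seed + 1000 * r,
                        noise_seed=spec.noise_seed + 1000 * r)
        out.append((seq, simulate_epochs(seq, rspec)))
    return out


def write_sequence_csv(seq: StimulusSequence, path) -> None:
    pd.DataFrame({"stimulus": seq.labels}).to_csv(path, index=False)


def read_sequence_csv(path, p_deviant: float = 1.0 / 3.0) -> StimulusSequence:
    df = pd.read_csv(path)
    if "stimulus" not in df.columns:
        raise ValueError(f"sequence CSV {path} lacks a 'stimulus' column")
    return StimulusSequence(labels=df["stimulus"].to_numpy(), p_deviant=p_deviant)
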