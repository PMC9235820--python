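"""Per-trial surprise series used as decoder labels.

Three quantifications of the surprise carried by each stimulus, all computed
from the ideal observer's factorized Beta beliefs:

* **Shannon surprise** — the "unlikeliness" of the stimulus: the negative log
  posterior-predictive probability of the observed transition.
* **Bayesian surprise** — the belief "update": KL divergence from the
  posterior belief to the prior belief, summed over the two Beta factors.
* **Confidence-corrected surprise** — the "unexpectedness" scaled by belief
  commitment: KL divergence from the current (prior) belief to the belief of
  a naive observer who holds a uniform prior and has seen only the most
  recent transition.

Values are in nats by default; switching to bits rescales every series by
1/ln 2, which is an affine relabelling and leaves any downstream decoding
R-squared unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma

from .observer import BeliefState, BeliefTrajectory, belief_trajectory, predictive_probability

__all__ = [
    "SurpriseSeries",
    "MEASURES",
    "kl_beta",
    "kl_belief",
    "shannon_surprise",
    "bayesian_surprise",
    "confidence_corrected_surprise",
    "surprise_series",
]

MEASURES = ("shannon", "bayesian", "confidence_corrected")


@dataclass(frozen=True)
class SurpriseSeries:
    """One surprise value per trial (the decoder label vector)."""

    values: np.ndarray
    measure: str
    w: float
    log_base: str = "e"  # {"e", "2"}

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size

    def in_bits(self) -> "SurpriseSeries":
        if self.log_base == "2":
            return self
        return SurpriseSeries(self.values / math.log(2.0), self.measure, self.w, "2")

    def to_frame(self, labels=None) -> pd.DataFrame:
        df = pd.DataFrame({"trial": np.arange(1, len(self) + 1), "surprise": self.values})
        if labels is not None:
            df.insert(1, "stimulus", np.asarray(getattr(labels, "labels", labels), dtype=int))
        return df


def kl_beta(a1: float, b1: float, a2: float, b2: float) -> float:
    """Closed-form KL(Beta(a1,b1) || Beta(a2,b2)).

    KL = ln B(a2,b2) - ln B(a1,b1) + (a1-a2) psi(a1) + (b1-b2) psi(b1)
         + (a2-a1+b2-b1) psi(a1+b1)
    """
    if min(a1, b1, a2, b2) <= 0:
        raise ValueError("Beta parameters must be positive")
    return float(
        betaln(a2, b2)
        - betaln(a1, b1)
        + (a1 - a2) * digamma(a1)
        + (b1 - b2) * digamma(b1)
        + (a2 - a1 + b2 - b1) * digamma(a1 + b1)
    )


def kl_belief(p: BeliefState, q: BeliefState) -> float:
    """KL divergence between two factorized beliefs (sum over Beta factors)."""
    return kl_beta(
        p.factor_given1.a, p.factor_given1.b, q.factor_given1.a, q.factor_given1.b
    ) + kl_beta(p.factor_given0.a, p.factor_given0.b, q.factor_given0.a, q.factor_given0.b)


def _naive_posterior(prev: int, curr: int) -> BeliefState:
    """Belief of a naive observer: uniform prior plus the single transition."""
    counts = {"n_0g0": 0.0, "n_1g0": 0.0, "n_0g1": 0.0, "n_1g1": 0.0}
    counts[f"n_{curr}g{prev}"] = 1.0
    from .observer import BetaParams

    return BeliefState(
        factor_given1=BetaParams(1.0 + counts["n_0g1"], 1.0 + counts["n_1g1"]),
        factor_given0=BetaParams(1.0 + counts["n_1g0"], 1.0 + counts["n_0g0"]),
    )


def _resolve_trajectory(seq, w: float, trajectory: BeliefTrajectory | None) -> BeliefTrajectory:
    if trajectory is not None:
        return trajectory
    return belief_trajectory(seq, w)


def shannon_surprise(seq, w: float, *, log_base: str = "e",
                     trajectory: BeliefTrajectory | None = None) -> SurpriseSeries:
    """Negative log predictive probability of each stimulus.

    Trial 1 has no preceding stimulus; its probability is taken to be 1/2, so
    the first value is ln 2 (one bit).
    """
    traj = _resolve_trajectory(seq, w, trajectory)
    labels = traj.labels
    vals = np.empty(labels.size)
    vals[0] = math.log(2.0)
    for t in range(1, labels.size):
        p = predictive_probability(traj.priors[t], int(labels[t - 1]), int(labels[t]))
        vals[t] = -math.log(p)
    return _based(SurpriseSeries(vals, "shannon", float(traj.w)), log_base)


def bayesian_surprise(seq, w: float, *, orientation: str = "posterior_prior",
                      log_base: str = "e",
                      trajectory: BeliefTrajectory | None = None) -> SurpriseSeries:
    """KL divergence between the beliefs after and before each stimulus.

    The default orientation is KL(posterior || prior); the reverse is
    available via ``orientation="prior_posterior"``.  Trial 1 updates nothing,
    so its value is 0.
    """
    if orientation not in ("posterior_prior", "prior_posterior"):
        raise ValueError(f"unknown orientation {orientation!r}")
    traj = _resolve_trajectory(seq, w, trajectory)
    vals = np.empty(len(traj))
    vals[0] = 0.0
    for t in range(1, len(traj)):
        if orientation == "posterior_prior":
            vals[t] = kl_belief(traj.posteriors[t], traj.priors[t])
        else:
            vals[t] = kl_belief(traj.priors[t], traj.posteriors[t])
    return _based(SurpriseSeries(vals, "bayesian", float(traj.w)), log_base)


def confidence_corrected_surprise(seq, w: float, *, orientation: str = "belief_naive",
                                  log_base: str = "e",
                                  trajectory: BeliefTrajectory | None = None) -> SurpriseSeries:
    """KL divergence between the current belief and a naive one-observation posterior.

    The naive observer starts from the uniform belief and incorporates only
    the most recent transition; a committed (peaked) prior that disagrees
    with the stimulus yields large surprise.  Trial 1 has no transition and
    its value is 0.
    """
    if orientation not in ("belief_naive", "naive_belief"):
        raise ValueError(f"unknown orientation {orientation!r}")
    traj = _resolve_trajectory(seq, w, trajectory)
    labels = traj.labels
    vals = np.empty(len(traj))
    vals[0] = 0.0
    for t in range(1, len(traj)):
        naive = _naive_posterior(int(labels[t - 1]), int(labels[t]))
        if orientation == "belief_naive":
            vals[t] = kl_belief(traj.priors[t], naive)
        else:
            vals[t] = kl_belief(naive, traj.priors[t])
    return _based(SurpriseSeries(vals, "confidence_corrected", float(traj.w)), log_base)


_MEASURE_FUNCS = {
    "shannon": shannon_surprise,
    "bayesian": bayesian_surprise,
    "confidence_corrected": confidence_corrected_surprise,
}


def surprise_series(seq, measure: str, w: float, *, log_base: str = "e",
                    trajectory: BeliefTrajectory | None = None) -> SurpriseSeries:
    """Compute the named surprise series (dispatch over the three measures)."""
    key = {"cc": "confidence_corrected"}.get(measure, measure)
    if key not in _MEASURE_FUNCS:
        raise ValueError(f"unknown surprise measure {measure!r}; expected one of {MEASURES}")
    return _MEASURE_FUNCS[key](seq, w, log_base=log_base, trajectory=trajectory)


def _based(series: SurpriseSeries, log_base: str) -> SurpriseSeries:
    if log_base == "e":
        return series
    if log_base == "2":
        return series.in_bits()
    raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
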