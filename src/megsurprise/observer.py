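"""Bayesian ideal observer over binary oddball sequences.

The observer assumes the stimulus stream (0 = standard, 1 = deviant) is
generated by a first-order Markov process and tracks the two free entries of
the 2x2 transition-probability matrix, theta_{0|1} and theta_{1|0}.  With a
uniform Beta(1,1) prior on each entry and (possibly leaky) transition counts
``n_{a|b}`` the posterior factorizes into two Beta distributions::

    p(theta | x_1..x_j) = Beta(1 + n_0|1, 1 + n_1|1) * Beta(1 + n_1|0, 1 + n_0|0)

Limited memory is modelled by leaky integration: at every trial all four
counts decay by ``exp(-1/w)`` before the observed transition adds 1, so a
transition observed ``lag`` trials ago carries weight ``exp(-lag/w)``.  The
integration coefficient ``w`` is the e-folding memory span in trials; as
``w -> inf`` the counts converge to plain integer tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TransitionCounts",
    "BetaParams",
    "BeliefState",
    "BeliefTrajectory",
    "update_counts",
    "belief_trajectory",
    "predictive_probability",
    "sequence_likelihood",
    "count_transitions",
]


def _check_binary(*codes: int) -> None:
    for c in codes:
        if c not in (0, 1):
            raise ValueError(f"stimulus codes must be 0 or 1, got {c!r}")


@dataclass(frozen=True)
class TransitionCounts:
    """Leaky transition counts n_{a|b} (stimulus ``a`` observed after ``b``).

    ``trial_index`` is the 1-based index of the last trial folded in; counts
    reflect all transitions up to and including that trial.
    """

    n_0g0: float = 0.0
    n_1g0: float = 0.0
    n_0g1: float = 0.0
    n_1g1: float = 0.0
    w: float = math.inf
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("integration coefficient w must be positive")
        for name in ("n_0g0", "n_1g0", "n_0g1", "n_1g1"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be nonnegative")


@dataclass(frozen=True)
class BetaParams:
    a: float
    b: float

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class BeliefState:
    """Factorized belief: Beta factors for theta_{0|1} and theta_{1|0}.

    ``factor_given1`` is Beta(1 + n_0|1, 1 + n_1|1), the belief about the
    probability of a standard following a deviant; ``factor_given0`` is
    Beta(1 + n_1|0, 1 + n_0|0), the belief about a deviant following a
    standard.
    """

    factor_given1: BetaParams
    factor_given0: BetaParams

    @classmethod
    def uniform(cls) -> "BeliefState":
        return cls(BetaParams(1.0, 1.0), BetaParams(1.0, 1.0))

    @classmethod
    def from_counts(cls, counts: TransitionCounts) -> "BeliefState":
        return cls(
            factor_given1=BetaParams(1.0 + counts.n_0g1, 1.0 + counts.n_1g1),
            factor_given0=BetaParams(1.0 + counts.n_1g0, 1.0 + counts.n_0g0),
        )


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial (prior, posterior) beliefs along a stimulus sequence.

    The prior at trial t reflects counts through trial t-1 (so it equals the
    posterior at t-1); the prior at trial 1 is the uniform belief, and the
    first stimulus induces no transition, so posterior(1) = prior(1).
    """

    labels: np.ndarray
    w: float
    priors: tuple[BeliefState, ...]
    posteriors: tuple[BeliefState, ...]
    counts: tuple[TransitionCounts, ...] = field(repr=False, default=())

    def __len__(self) -> int:
        return len(self.priors)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate Beta parameters per trial (CSV-exportable)."""
        rows = []
        for t, (pri, post) in enumerate(zip(self.priors, self.posteriors), 1):
            rows.append(
                {
                    "trial": t,
                    "stimulus": int(self.labels[t - 1]),
                    "prior_a_given1": pri.factor_given1.a,
                    "prior_b_given1": pri.factor_given1.b,
                    "prior_a_given0": pri.factor_given0.a,
                    "prior_b_given0": pri.factor_given0.b,
                    "post_a_given1": post.factor_given1.a,
                    "post_b_given1": post.factor_given1.b,
                    "post_a_given0": post.factor_given0.a,
                    "post_b_given0": post.factor_given0.b,
                }
            )
        return pd.DataFrame(rows)


def update_counts(counts: TransitionCounts, prev: int, curr: int) -> TransitionCounts:
    """Fold one transition ``prev -> curr`` into the leaky counts.

    Every count decays by ``exp(-1/w)``, then the observed transition gains
    weight 1.  This recursion gives a transition at lag ``k`` (most recent at
    lag 0) the weight ``exp(-k/w)``.
    """
    _check_binary(prev, curr)
    decay = math.exp(-1.0 / counts.w)
    new = {
        "n_0g0": counts.n_0g0 * decay,
        "n_1g0": counts.n_1g0 * decay,
        "n_0g1": counts.n_0g1 * decay,
        "n_1g1": counts.n_1g1 * decay,
    }
    new[f"n_{curr}g{prev}"] += 1.0
    return replace(counts, trial_index=counts.trial_index + 1, **new)


def belief_trajectory(labels, w: float) -> BeliefTrajectory:
    """Run the observer along a sequence, recording prior/posterior per trial.

    Parameters
    ----------
    labels : sequence of {0, 1} or StimulusSequence
        The oddball stimulus stream.
    w : float
        Leaky-integration e-folding span in trials; must be positive.
    """
    labels = np.asarray(getattr(labels, "labels", labels), dtype=int)
    if labels.size == 0:
        raise ValueError("stimulus sequence must be nonempty")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("stimulus labels must be binary (0/1)")
    if not w > 0:
        raise ValueError("integration coefficient w must be positive")

    counts = TransitionCounts(w=w, trial_index=1)
    priors: list[BeliefState] = []
    posteriors: list[BeliefState] = []
    count_states: list[TransitionCounts] = []

    belief = BeliefState.uniform()
    priors.append(belief)
    posteriors.append(belief)  # trial 1 carries no transition
    count_states.append(counts)
    for t in range(1, labels.size):
        priors.append(BeliefState.from_counts(counts))
        counts = update_counts(counts, int(labels[t - 1]), int(labels[t]))
        posteriors.append(BeliefState.from_counts(counts))
        count_states.append(counts)
    return BeliefTrajectory(
        labels=labels,
        w=float(w),
        priors=tuple(priors),
        posteriors=tuple(posteriors),
        counts=tuple(count_states),
    )


def predictive_probability(prior: BeliefState, prev: int, nxt: int) -> float:
    """Posterior-predictive probability of observing ``nxt`` after ``prev``.

    Uses the mean of the relevant Beta factor (Laplace rule), e.g.
    ``p(1|0) = (1 + n_1|0) / (2 + n_1|0 + n_0|0)``.  Complements sum to 1
    exactly: ``p(0|b) + p(1|b) = 1``.
    """
    _check_binary(prev, nxt)
    if prev == 0:
        p1 = prior.factor_given0.mean  # P(next=1 | prev=0)
        return p1 if nxt == 1 else 1.0 - p1
    p0 = prior.factor_given1.mean  # P(next=0 | prev=1)
    return p0 if nxt == 0 else 1.0 - p0


def count_transitions(labels) -> dict[str, int]:
    """Plain (unweighted) transition tallies n_{a|b} of a binary sequence."""
    labels = np.asarray(getattr(labels, "labels", labels), dtype=int)
    prev, curr = labels[:-1], labels[1:]
    return {
        "n_0g0": int(np.sum((prev == 0) & (curr == 0))),
        "n_1g0": int(np.sum((prev == 0) & (curr == 1))),
        "n_0g1": int(np.sum((prev == 1) & (curr == 0))),
        "n_1g1": int(np.sum((prev == 1) & (curr == 1))),
    }


def sequence_likelihood(labels, theta01: float, theta10: float) -> float:
    """Markov likelihood of a binary sequence given the transition parameters.

    Returns ``0.5 * theta01**n_0|1 * (1-theta01)**n_1|1 * theta10**n_1|0 *
    (1-theta10)**n_0|0`` with plain transition tallies; the probability of the
    first stimulus is taken to be 1/2.  A parameter at 0 or 1 paired with a
    positive exponent yields a likelihood of 0 rather than an error.
    """
    labels = np.asarray(getattr(labels, "labels", labels), dtype=int)
    if labels.size == 0:
        raise ValueError("stimulus sequence must be nonempty")
    if not (0.0 <= theta01 <= 1.0 and 0.0 <= theta10 <= 1.0):
        raise ValueError("transition probabilities must lie in [0, 1]")
    n = count_transitions(labels)

    def pw(base: float, expo: int) -> float:
        if expo == 0:
            return 1.0
        return base**expo  # 0**positive == 0.0, the degenerate-parameter case

    return (
        0.5
        * pw(theta01, n["n_0g1"])
        * pw(1.0 - theta01, n["n_1g1"])
        * pw(theta10, n["n_1g0"])
        * pw(1.0 - theta10, n["n_0g0"])
    )
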