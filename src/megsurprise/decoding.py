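"""Cross-validated sparse decoding of surprise from epoch features.

The decoder regresses a per-trial surprise series on an N x p' feature
matrix with L1-penalized (Lasso) linear regression.  Decoding power is the
fraction of held-out label variance explained (R-squared) under an outer
K-fold split (fivefold by default); within each training fold features are
standardized with that fold's statistics and the penalty weight is chosen by
an inner fivefold cross-validation over a logarithmic grid.  Held-out R2 may
be negative when the model fits worse than the fold-mean predictor.

Chance levels come from refitting the full pipeline on uniformly permuted
labels; because the decoding power depends on the observer's integration
coefficient w, `sweep_w` recomputes the labels for each w on a grid and
reports the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LassoCV
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .epochs import EpochTensor, FeatureMatrix, RegimeSpec, build_features
from .surprise import SurpriseSeries, surprise_series

__all__ = ["DecodingResult", "ChanceDistribution", "fit_decode", "sweep_w", "chance_level"]

# Inner penalty-selection grid: 15 log-spaced alphas down to 1e-2 * alpha_max.
N_ALPHAS = 15
ALPHA_EPS = 1e-2
LASSO_TOL = 1e-3
LASSO_MAX_ITER = 2000
INNER_FOLDS = 5


@dataclass(frozen=True)
class DecodingResult:
    """Decoding power of one regression, with its fold and penalty bookkeeping."""

    r2: float
    regime: RegimeSpec | None
    measure: str | None
    w: float | None
    n_folds: int
    seed: int
    fold_r2: tuple[float, ...] = ()
    chosen_alphas: tuple[float, ...] = field(repr=False, default=())
    n_trials: int = 0
    n_features: int = 0

    def to_dict(self) -> dict:
        d = {
            "r2": self.r2,
            "regime": self.regime.regime if self.regime is not None else None,
            "measure": self.measure,
            "w": self.w,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_r2": list(self.fold_r2),
            "chosen_alphas": list(self.chosen_alphas),
            "n_trials": self.n_trials,
            "n_features": self.n_features,
        }
        if self.regime is not None:
            for k in ("t_ms", "segment", "t1_ms", "t2_ms", "channel"):
                v = getattr(self.regime, k)
                if v is not None:
                    d[k] = v
        return d


@dataclass(frozen=True)
class ChanceDistribution:
    """Permutation sample of decoding powers under the label-independence null."""

    r2_samples: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "r2_samples", np.asarray(self.r2_samples, dtype=float))

    @property
    def mean(self) -> float:
        return float(self.r2_samples.mean())

    @property
    def sd(self) -> float:
        return float(self.r2_samples.std(ddof=1)) if self.n_permutations > 1 else 0.0

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.r2_samples, q))

    def empirical_p(self, observed: float) -> float:
        """(1 + #{chance >= observed}) / (n_permutations + 1)."""
        return float(
            (1 + int(np.sum(self.r2_samples >= observed))) / (self.n_permutations + 1)
        )


def _as_matrix(X) -> tuple[np.ndarray, RegimeSpec | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.regime
    return np.asarray(X, dtype=float), None


def _as_labels(y) -> tuple[np.ndarray, str | None, float | None]:
    if isinstance(y, SurpriseSeries):
        return y.values, y.measure, y.w
    return np.asarray(y, dtype=float), None, None


def fit_decode(X, y, n_folds: int = 5, seed: int = 0, *, pooled: bool = False) -> DecodingResult:
    """Nested-CV Lasso decoding power of labels ``y`` from features ``X``.

    Parameters
    ----------
    X : FeatureMatrix or array (N, p')
    y : SurpriseSeries or array (N,)
    n_folds : outer fold count (>= 2); the inner penalty CV is fivefold.
    seed : controls the outer/inner fold shuffles; the fit is deterministic
        given (X, y, n_folds, seed).
    pooled : if True, R2 is computed once over the pooled held-out
        predictions instead of per-fold averaging.
    """
    Xv, regime = _as_matrix(X)
    yv, measure, w = _as_labels(y)
    if Xv.ndim != 2:
        raise ValueError("X must be 2-d (trials x features)")
    if Xv.shape[0] != yv.size:
        raise ValueError(f"X has {Xv.shape[0]} rows but y has {yv.size} labels")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if Xv.shape[0] < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} trials for {n_folds}-fold decoding")
    if np.std(yv) == 0:
        raise ValueError("labels are degenerate (zero variance)")

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_r2: list[float] = []
    alphas: list[float] = []
    pooled_pred = np.empty_like(yv)
    for train, test in outer.split(Xv):
        scaler = StandardScaler().fit(Xv[train])
        Xtr = scaler.transform(Xv[train])
        Xte = scaler.transform(Xv[test])
        inner = KFold(n_splits=INNER_FOLDS, shuffle=True, random_state=seed)
        model = LassoCV(
            alphas=N_ALPHAS,
            eps=ALPHA_EPS,
            cv=inner,
            tol=LASSO_TOL,
            max_iter=LASSO_MAX_ITER,
        ).fit(Xtr, yv[train])
        pred = model.predict(Xte)
        pooled_pred[test] = pred
        fold_r2.append(float(r2_score(yv[test], pred)))
        alphas.append(float(model.alpha_))

    r2 = float(r2_score(yv, pooled_pred)) if pooled else float(np.mean(fold_r2))
    return DecodingResult(
        r2=r2,
        regime=regime,
        measure=measure,
        w=w,
        n_folds=n_folds,
        seed=seed,
        fold_r2=tuple(fold_r2),
        chosen_alphas=tuple(alphas),
        n_trials=Xv.shape[0],
        n_features=Xv.shape[1],
    )


def sweep_w(tensor: EpochTensor, seq, measure: str, spec: RegimeSpec, w_grid,
            n_folds: int = 5, seed: int = 0) -> tuple[list[DecodingResult], float]:
    """Decode at every integration coefficient on a grid; report the argmax.

    Labels are recomputed per w (the feature matrix is fixed by the regime).
    Ties break toward smaller w, scanning the grid in ascending order.
    """
    w_grid = sorted(float(w) for w in w_grid)
    if not w_grid:
        raise ValueError("w_grid must be nonempty")
    X = build_features(tensor, spec)
    results: list[DecodingResult] = []
    best_w, best_r2 = None, -np.inf
    for w in w_grid:
        y = surprise_series(seq, measure, w)
        res = fit_decode(X, y, n_folds=n_folds, seed=seed)
        results.append(res)
        if res.r2 > best_r2:  # strict: earlier (smaller) w wins ties
            best_w, best_r2 = w, res.r2
    return results, best_w


def chance_level(X, y, n_permutations: int = 100, n_folds: int = 5,
                 seed: int = 0) -> ChanceDistribution:
    """Permutation chance distribution of decoding power.

    Each iteration permutes the label vector uniformly at random (seeded) and
    reruns the full nested-CV decode; the identity permutation is not
    excluded.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    Xv, _ = _as_matrix(X)
    yv, _, _ = _as_labels(y)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(yv.size)
        samples[i] = fit_decode(Xv, yv[perm], n_folds=n_folds, seed=seed).r2
    return ChanceDistribution(r2_samples=samples, n_permutations=n_permutations, seed=seed)
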