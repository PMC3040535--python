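"""Binary classifiers and the bootstrap-aggregating ensemble.

The ensemble exists to cope with highly unbalanced site data: each round
draws a small class-balanced subsample (all or capped positives, a matched
number of negatives), trains a base learner on it, and prediction averages
the raw decision values across rounds.

Two base learners satisfy the classifier contract: a soft-margin linear SVM
and an adaptive-boosting ensemble of depth-1 threshold learners (stumps).
Both standardize feature columns using statistics stored in the model, are
deterministic given (data, seed), and serialize to plain JSON-compatible
dictionaries.
"""

from __future__ import annotations

import abc
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .errors import LayoutMismatchError, TrainingError


class BaseModel(abc.ABC):
    """Contract every base learner fulfils: deterministic real-valued
    decision function (higher = more positive-like) plus dict serialization."""

    mean: np.ndarray
    scale: np.ndarray

    @abc.abstractmethod
    def raw_decision(self, Z: np.ndarray) -> np.ndarray:
        """Decision values on already-standardized features."""

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self.raw_decision((X - self.mean) / self.scale)

    @abc.abstractmethod
    def to_dict(self) -> dict: ...

    @staticmethod
    def from_dict(d: dict) -> "BaseModel":
        kind = d["kind"]
        if kind == "svm":
            return LinearSvmModel._from_dict(d)
        if kind == "boosting":
            return StumpBoostModel._from_dict(d)
        raise ValueError(f"unknown base model kind {kind!r}")


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through unchanged
    return mean, scale


@dataclass
class LinearSvmModel(BaseModel):
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    scale: np.ndarray
    C: float = 1.0

    def raw_decision(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": "svm",
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "C": self.C,
        }

    @staticmethod
    def _from_dict(d: dict) -> "LinearSvmModel":
        return LinearSvmModel(
            coef=np.asarray(d["coef"], dtype=np.float64),
            intercept=float(d["intercept"]),
            mean=np.asarray(d["mean"], dtype=np.float64),
            scale=np.asarray(d["scale"], dtype=np.float64),
            C=float(d["C"]),
        )


@dataclass
class StumpBoostModel(BaseModel):
    """AdaBoost over depth-1 threshold learners.

    Each stump votes ``polarity`` if ``x[feature] > threshold`` else
    ``-polarity``; the decision value is the alpha-weighted vote sum.
    """

    stumps: list[tuple[int, float, int, float]]  # (feature, threshold, polarity, alpha)
    mean: np.ndarray
    scale: np.ndarray

    def raw_decision(self, Z: np.ndarray) -> np.ndarray:
        out = np.zeros(Z.shape[0], dtype=np.float64)
        for feat, thr, pol, alpha in self.stumps:
            out += alpha * np.where(Z[:, feat] > thr, pol, -pol)
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "boosting",
            "stumps": [list(s) for s in self.stumps],
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
        }

    @staticmethod
    def _from_dict(d: dict) -> "StumpBoostModel":
        return StumpBoostModel(
            stumps=[(int(f), float(t), int(p), float(a)) for f, t, p, a in d["stumps"]],
            mean=np.asarray(d["mean"], dtype=np.float64),
            scale=np.asarray(d["scale"], dtype=np.float64),
        )


def _best_stump(
    Z: np.ndarray, t: np.ndarray, w: np.ndarray
) -> tuple[int, float, int, float]:
    """Weighted-error-optimal stump; ties break by lowest feature index then
    lowest threshold, so the search is deterministic."""
    n, p = Z.shape
    best = (0, -np.inf, 1)
    best_err = np.inf
    for j in range(p):
        order = np.argsort(Z[:, j], kind="stable")
        zs = Z[order, j]
        tw = (t * w)[order]
        # err(threshold before position i, polarity +1) = w[t=+1, below] + w[t=-1, above]
        below_pos = np.concatenate([[0.0], np.cumsum(np.where(tw > 0, tw, 0.0))])
        below_neg = np.concatenate([[0.0], np.cumsum(np.where(tw < 0, -tw, 0.0))])
        total_pos = below_pos[-1]
        total_neg = below_neg[-1]
        # candidate split after index i-1 (i = 0..n); skip splits between equal values
        valid = np.ones(n + 1, dtype=bool)
        valid[1:n] = zs[1:] > zs[:-1]
        err_plus = below_pos + (total_neg - below_neg)  # predict +1 above threshold
        err_minus = below_neg + (total_pos - below_pos)
        for errs, pol in ((err_plus, 1), (err_minus, -1)):
            masked = np.where(valid, errs, np.inf)
            i = int(np.argmin(masked))
            if masked[i] < best_err - 1e-15:
                if i == 0:
                    thr = zs[0] - 1.0
                elif i == n:
                    thr = zs[-1] + 1.0
                else:
                    thr = 0.5 * (zs[i - 1] + zs[i])
                best = (j, float(thr), pol)
                best_err = float(masked[i])
    return best[0], best[1], best[2], best_err


def _train_boosting(Z: np.ndarray, y: np.ndarray, n_rounds: int) -> list:
    t = np.where(y > 0, 1.0, -1.0)
    n = len(t)
    w = np.full(n, 1.0 / n)
    stumps = []
    eps = 1e-12
    for _ in range(n_rounds):
        feat, thr, pol, _ = _best_stump(Z, t, w)
        h = np.where(Z[:, feat] > thr, pol, -pol)
        err = float(w[h != t].sum())
        err = min(max(err, eps), 1 - eps)
        alpha = 0.5 * np.log((1 - err) / err)
        stumps.append((feat, thr, pol, float(alpha)))
        w = w * np.exp(-alpha * t * h)
        w /= w.sum()
        if err <= eps:  # perfectly separated; further rounds are redundant
            break
    return stumps


DEFAULT_BOOSTING_ROUNDS = 50


def train_base(
    X: np.ndarray,
    y: np.ndarray,
    learner: str = "svm",
    seed: int = 0,
    C: float = 1.0,
    boosting_rounds: int = DEFAULT_BOOSTING_ROUNDS,
) -> BaseModel:
    """Train one base classifier on standardized features.

    Requires at least one example of each class.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    mean, scale = _standardize_fit(X)
    Z = (X - mean) / scale
    if learner == "svm":
        clf = LinearSVC(C=C, dual=False, tol=1e-6, max_iter=20000)
        clf.fit(Z, y.astype(int))
        coef = clf.coef_.ravel().astype(np.float64)
        intercept = float(clf.intercept_[0])
        if clf.classes_[1] != 1:  # ensure higher value => positive class
            coef, intercept = -coef, -intercept
        return LinearSvmModel(coef=coef, intercept=intercept, mean=mean, scale=scale, C=C)
    if learner == "boosting":
        stumps = _train_boosting(Z, y.astype(int), boosting_rounds)
        return StumpBoostModel(stumps=stumps, mean=mean, scale=scale)
    raise ValueError(f"unknown base learner {learner!r}")


# ---------------------------------------------------------------------------
# Bagging


@dataclass(frozen=True)
class BaggingConfig:
    n_rounds: int = 20
    positives_per_round: int = 2000
    negative_ratio: float = 1.0
    base_learner: str = "svm"
    seed: int = 0
    with_replacement: bool = False
    svm_C: float = 1.0
    boosting_rounds: int = DEFAULT_BOOSTING_ROUNDS

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "BaggingConfig":
        return BaggingConfig(**d)


@dataclass
class BaggingEnsemble:
    base_models: list[BaseModel]
    config: BaggingConfig
    feature_layout: tuple[tuple[str, int], ...]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "feature_layout": [list(b) for b in self.feature_layout],
            "base_models": [m.to_dict() for m in self.base_models],
        }

    @staticmethod
    def from_dict(d: dict) -> "BaggingEnsemble":
        return BaggingEnsemble(
            base_models=[BaseModel.from_dict(m) for m in d["base_models"]],
            config=BaggingConfig.from_dict(d["config"]),
            feature_layout=tuple((str(n), int(k)) for n, k in d["feature_layout"]),
        )


def train_bagging(
    X: np.ndarray,
    y: np.ndarray,
    config: BaggingConfig,
    feature_layout: tuple[tuple[str, int], ...] = (),
) -> BaggingEnsemble:
    """Train ``n_rounds`` base learners on balanced subsamples.

    Each round draws ``min(positives_per_round, |P|)`` positives and
    ``round(negative_ratio * that)`` negatives, without replacement by
    default; rounds differ only in the derived sampling seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0:
        raise TrainingError("no positive examples")
    n_pos = min(config.positives_per_round, len(pos_idx))
    n_neg = int(round(config.negative_ratio * n_pos))
    if not config.with_replacement and len(neg_idx) < n_neg:
        raise TrainingError(
            f"insufficient negatives: need {n_neg} per round, have {len(neg_idx)}"
        )
    models: list[BaseModel] = []
    for r in range(config.n_rounds):
        rng = np.random.default_rng([config.seed, r])
        p_sample = rng.choice(pos_idx, size=n_pos, replace=config.with_replacement)
        n_sample = rng.choice(neg_idx, size=n_neg, replace=config.with_replacement)
        idx = np.concatenate([p_sample, n_sample])
        models.append(
            train_base(
                X[idx],
                y[idx],
                learner=config.base_learner,
                seed=config.seed + r,
                C=config.svm_C,
                boosting_rounds=config.boosting_rounds,
            )
        )
    return BaggingEnsemble(
        base_models=models, config=config, feature_layout=tuple(feature_layout)
    )


def predict_bagging(ensemble: BaggingEnsemble, X: np.ndarray) -> np.ndarray:
    """Per-example arithmetic mean of the base decision values."""
    X = np.asarray(X, dtype=np.float64)
    expected = sum(n for _, n in ensemble.feature_layout)
    if ensemble.feature_layout and X.shape[1] != expected:
        raise LayoutMismatchError(
            f"feature matrix has {X.shape[1]} columns; model expects {expected} "
            f"({ensemble.feature_layout})"
        )
    values = np.stack([m.decision_values(X) for m in ensemble.base_models])
    return values.mean(axis=0)
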