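"""Intention-encoding model: regularized logistic regression of intention
on single-trial kinematic features, single-trial information indices,
per-variable contributions, and coefficient significance testing.

The positive class is 'pour' throughout: the model expresses
``P(intention = 'pour' | K) = sigmoid(beta . K + beta0)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import glmnet
from .config import RegularizationSpec
from .exceptions import FittingError, SchemaError
from .kinematics import (
    VARIABLES,
    FeatureMatrix,
    TrialFeatureVector,
    zscore_features,
)

POSITIVE_CLASS = "pour"
NEGATIVE_CLASS = "drink"


def _encode_labels(intentions) -> np.ndarray:
    labels = np.asarray(intentions)
    bad = set(np.unique(labels)) - {POSITIVE_CLASS, NEGATIVE_CLASS}
    if bad:
        raise SchemaError(f"unknown intention labels: {sorted(bad)}")
    return (labels == POSITIVE_CLASS).astype(float)


@dataclass
class EncodingModel:
    """Fitted encoding (or readout) logistic model with metadata."""

    weights: np.ndarray
    bias: float
    labels: list[tuple[str, int]]
    alpha: float
    lambda_min: float
    mean_: np.ndarray
    sd_: np.ndarray
    performance: float | None = None
    cv_performance: float | None = None
    degenerate: bool = False
    model_id: str = "encoding"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.labels),):
            raise SchemaError("weight vector length must equal feature count")

    # --- serialization (exact round-trip via repr of floats) -------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_id": self.model_id,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "labels": [[v, e] for v, e in self.labels],
            "alpha": self.alpha,
            "lambda_min": self.lambda_min,
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "performance": self.performance,
            "cv_performance": self.cv_performance,
            "degenerate": self.degenerate,
            "extra": self.extra,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EncodingModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            bias=d["bias"],
            labels=[(v, int(e)) for v, e in d["labels"]],
            alpha=d["alpha"],
            lambda_min=d["lambda_min"],
            mean_=np.asarray(d["mean"]),
            sd_=np.asarray(d["sd"]),
            performance=d.get("performance"),
            cv_performance=d.get("cv_performance"),
            degenerate=d.get("degenerate", False),
            model_id=d.get("model_id", "encoding"),
            extra=d.get("extra", {}),
        )

    # --- feature handling ------------------------------------------------
    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean_) / self.sd_

    def linear_predictor(self, vector: TrialFeatureVector | np.ndarray) -> float:
        if isinstance(vector, TrialFeatureVector):
            if vector.labels != self.labels:
                raise SchemaError("feature label mismatch")
            values = vector.values
        else:
            values = np.asarray(vector, dtype=float)
        return float(self.weights @ self.standardize(values) + self.bias)


@dataclass(frozen=True)
class SingleTrialIndex:
    """Sign-adjusted log-odds of correct encoding (or readout)."""

    prime_id: str
    value: float
    correct: bool


def _prepare(features: FeatureMatrix) -> FeatureMatrix:
    return features if features.zscored else zscore_features(features)


def fit_encoding(
    features: FeatureMatrix,
    intentions,
    reg: RegularizationSpec | None = None,
    groups: np.ndarray | None = None,
) -> EncodingModel:
    """Elastic-net logistic fit of intention on z-scored features.

    The penalty is chosen by leave-one-video-out cross-validated binomial
    deviance; the final model is refit on all trials at ``lambda_min``.
    """
    reg = reg or RegularizationSpec()
    y = _encode_labels(intentions)
    if np.unique(y).size < 2:
        raise FittingError("both intention classes must be present")
    zs = _prepare(features)
    if groups is None:
        groups = np.asarray(zs.prime_ids)
    cv = glmnet.cv_lambda_min(
        zs.values, y, groups, reg.alpha,
        lambdas=reg.lambdas, n_lambda=reg.n_lambda,
        lambda_min_ratio=reg.lambda_min_ratio,
    )
    beta, b0 = glmnet.fit_logistic_net(zs.values, y, reg.alpha, cv.lambda_min)
    model = EncodingModel(
        weights=beta,
        bias=b0,
        labels=list(zs.labels),
        alpha=reg.alpha,
        lambda_min=cv.lambda_min,
        mean_=zs.mean_,
        sd_=zs.sd_,
    )
    model.performance = encoding_performance(model, features, intentions)
    return model


def predict_intention(
    model: EncodingModel, vector: TrialFeatureVector | np.ndarray
) -> tuple[float, str]:
    """Probability of 'pour' and the argmax intention.

    Exact ties (p = 0.5) resolve to 'drink' deterministically.
    """
    eta = model.linear_predictor(vector)
    p = float(1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500))))
    return p, POSITIVE_CLASS if p > 0.5 else NEGATIVE_CLASS


def single_trial_encoding(
    model: EncodingModel, vector: TrialFeatureVector | np.ndarray, true_intention: str
) -> SingleTrialIndex:
    """Sign-adjusted log-odds of correct encoding.

    ``value = y * (beta . K + beta0)`` with y = +1 when the true intention
    is 'pour'; equivalently log(P(correct) / (1 - P(correct))).
    """
    if true_intention not in (POSITIVE_CLASS, NEGATIVE_CLASS):
        raise SchemaError(f"unknown intention: {true_intention}")
    eta = model.linear_predictor(vector)
    y = 1.0 if true_intention == POSITIVE_CLASS else -1.0
    value = y * eta
    pid = vector.prime_id if isinstance(vector, TrialFeatureVector) else ""
    return SingleTrialIndex(prime_id=pid, value=value, correct=value > 0)


def variable_contributions(
    model: EncodingModel,
    vector: TrialFeatureVector | np.ndarray,
    true_intention: str | None = None,
) -> dict[str, float]:
    """Per-variable scalar products within each variable's epoch subspace.

    Without ``true_intention`` the contributions sum to the bias-free
    linear predictor.  With it, the same sign adjustment as the
    single-trial index is applied, so positive values mark variables
    pushing toward the correct intention.
    """
    if isinstance(vector, TrialFeatureVector):
        if vector.labels != model.labels:
            raise SchemaError("feature label mismatch")
        values = vector.values
    else:
        values = np.asarray(vector, dtype=float)
    z = model.standardize(values)
    contrib = {v: 0.0 for v in VARIABLES}
    for (v, _e), w, k in zip(model.labels, model.weights, z):
        contrib[v] += float(w * k)
    if true_intention is not None:
        y = 1.0 if true_intention == POSITIVE_CLASS else -1.0
        contrib = {v: y * c for v, c in contrib.items()}
    return contrib


def _design_matrix(model: EncodingModel, features: FeatureMatrix) -> np.ndarray:
    """Model design values: already-standardized matrices pass through."""
    if features.zscored:
        return features.values
    return (features.values - model.mean_) / model.sd_


def encoding_performance(model: EncodingModel, features: FeatureMatrix, intentions) -> float:
    """Fraction of trials whose argmax intention matches the truth."""
    y = _encode_labels(intentions)
    if len(y) == 0:
        raise ValueError("empty trial set")
    eta = _design_matrix(model, features) @ model.weights + model.bias
    return float(np.mean((eta > 0) == y.astype(bool)))


def nested_cv_performance(
    features: FeatureMatrix,
    intentions,
    reg: RegularizationSpec | None = None,
) -> float:
    """Outer leave-one-video-out accuracy with inner penalty selection.

    Standardization parameters and ``lambda_min`` are computed inside each
    outer training fold only.
    """
    reg = reg or RegularizationSpec()
    y = _encode_labels(intentions)
    ids = np.asarray(features.prime_ids)
    videos = np.unique(ids)
    if videos.size < 3:
        raise ValueError("nested CV needs at least 3 videos")
    correct = np.zeros(len(y), dtype=bool)
    for v in videos:
        test = ids == v
        train = ~test
        train_fm = FeatureMatrix(
            values=features.values[train],
            prime_ids=list(ids[train]),
            labels=features.labels,
        )
        yt = y[train]
        if np.unique(yt).size < 2:
            correct[test] = (yt.mean() > 0.5) == y[test].astype(bool)
            continue
        zs = zscore_features(train_fm)
        cv = glmnet.cv_lambda_min(
            zs.values, yt, ids[train], reg.alpha,
            n_lambda=reg.n_lambda, lambda_min_ratio=reg.lambda_min_ratio,
        )
        beta, b0 = glmnet.fit_logistic_net(zs.values, yt, reg.alpha, cv.lambda_min)
        xt = (features.values[test] - zs.mean_) / zs.sd_
        correct[test] = ((xt @ beta + b0) > 0) == y[test].astype(bool)
    return float(correct.mean())


def permutation_test_weights(
    features: FeatureMatrix,
    labels01_or_intentions,
    reg: RegularizationSpec | None = None,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
    fast: bool = True,
) -> dict:
    """Permutation null for non-zero coefficients.

    Labels are shuffled, the model refit, and absolute coefficients pooled
    across all features and permutations into one null distribution; an
    observed non-zero coefficient is significant iff its absolute value
    exceeds the null's 95th percentile.  ``fast`` freezes the penalty at
    the observed ``lambda_min``; otherwise the penalty is re-selected per
    permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    reg = reg or RegularizationSpec()
    rng = rng or np.random.default_rng(0)
    try:
        y = _encode_labels(labels01_or_intentions)
    except SchemaError:
        y = glmnet._as01(labels01_or_intentions)
    zs = _prepare(features)
    groups = np.asarray(zs.prime_ids)
    cv = glmnet.cv_lambda_min(
        zs.values, y, groups, reg.alpha,
        n_lambda=reg.n_lambda, lambda_min_ratio=reg.lambda_min_ratio,
    )
    beta_obs, _ = glmnet.fit_logistic_net(zs.values, y, reg.alpha, cv.lambda_min)
    null = np.empty((n_perm, beta_obs.size))
    warm = (beta_obs, 0.0)
    for i in range(n_perm):
        yp = rng.permutation(y)
        if fast:
            bp, _ = glmnet.fit_logistic_net(zs.values, yp, reg.alpha, cv.lambda_min)
        else:
            cvp = glmnet.cv_lambda_min(
                zs.values, yp, groups, reg.alpha,
                n_lambda=reg.n_lambda, lambda_min_ratio=reg.lambda_min_ratio,
            )
            bp, _ = glmnet.fit_logistic_net(zs.values, yp, reg.alpha, cvp.lambda_min)
        null[i] = np.abs(bp)
    # the null distribution pools the non-zero permuted coefficients; with
    # sparse fits most permuted coefficients are exactly zero and a pooled
    # percentile over all of them would degenerate to 0
    pool = null.ravel()
    pool_nz = pool[pool > 0]
    threshold = float(np.percentile(pool_nz, 95)) if pool_nz.size else 0.0
    significant = (np.abs(beta_obs) > threshold) & (beta_obs != 0)
    return {
        "weights": beta_obs,
        "threshold_95": threshold,
        "significant": significant,
        "null_abs": null,
        "lambda_min": cv.lambda_min,
    }


def weight_stability_across_alpha(
    features: FeatureMatrix,
    intentions,
    alpha_grid,
    reference_alpha: float = 0.95,
    reg: RegularizationSpec | None = None,
) -> dict[float, float | None]:
    """Pearson correlation of weight vectors at each alpha vs the reference.

    Degenerate (all-zero / constant) weight vectors yield ``None``.
    """
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid must not be empty")
    base = reg or RegularizationSpec()
    ref = fit_encoding(features, intentions, replace(base, alpha=reference_alpha))
    out: dict[float, float | None] = {}
    for a in alpha_grid:
        m = fit_encoding(features, intentions, replace(base, alpha=a))
        w1, w2 = ref.weights, m.weights
        if np.std(w1) < 1e-15 or np.std(w2) < 1e-15:
            out[a] = None
        else:
            out[a] = float(np.corrcoef(w1, w2)[0, 1])
    return out
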