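"""Per-perceiver readout models of intention choice.

Readout models share machinery with the encoding model: an elastic-net
logistic regression, here of the perceiver's choice ('pour' positive) on
the z-scored features of the displayed prime, with leave-one-video-out
penalty selection (all repetitions of a video leave together).  On top of
that: single-trial readout indices, permuted-choice performance nulls,
readout/encoding alignment, pooled (surrogate-participant) models, and
the double-criterion detection of zero-readout primes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glmnet
from .config import RegularizationSpec
from .encoding import (
    NEGATIVE_CLASS,
    POSITIVE_CLASS,
    EncodingModel,
    SingleTrialIndex,
)
from .exceptions import SchemaError
from .kinematics import FeatureMatrix, zscore_features

REQUIRED_TRIAL_COLUMNS = ("perceiver_id", "prime_id", "repetition", "choice")


@dataclass
class ReadoutModel(EncodingModel):
    perceiver_id: str = ""


def _check_trials(trials: pd.DataFrame) -> None:
    missing = set(REQUIRED_TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise SchemaError(f"missing trial columns: {sorted(missing)}")
    dup = trials.duplicated(["perceiver_id", "prime_id", "repetition"])
    if dup.any():
        raise SchemaError("(perceiver, prime, repetition) must be unique")


def _design(
    trials: pd.DataFrame, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, FeatureMatrix]:
    """Row-align z-scored features with a perceiver's trials."""
    zs = features if features.zscored else zscore_features(features)
    pos = {p: i for i, p in enumerate(zs.prime_ids)}
    unknown = set(trials["prime_id"]) - set(pos)
    if unknown:
        raise SchemaError(f"trials reference unknown primes: {sorted(unknown)[:5]}")
    rows = [pos[p] for p in trials["prime_id"]]
    X = zs.values[rows]
    y = (trials["choice"].to_numpy() == POSITIVE_CLASS).astype(float)
    groups = trials["prime_id"].to_numpy()
    return X, y, groups, zs


def fit_readout(
    trials: pd.DataFrame,
    features: FeatureMatrix,
    reg: RegularizationSpec | None = None,
    perceiver_id: str | None = None,
) -> ReadoutModel:
    """Fit one perceiver's readout model on their choice trials.

    A perceiver who always made the same choice yields a degenerate model
    (zero weights, base-rate bias) flagged as such.
    """
    reg = reg or RegularizationSpec()
    _check_trials(trials)
    pids = trials["perceiver_id"].unique()
    if len(pids) != 1:
        raise SchemaError("fit_readout expects trials of exactly one perceiver")
    perceiver_id = perceiver_id or str(pids[0])
    X, y, groups, zs = _design(trials, features)
    if np.unique(y).size < 2:
        base = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        model = ReadoutModel(
            weights=np.zeros(X.shape[1]),
            bias=float(np.log(base / (1 - base))),
            labels=list(zs.labels),
            alpha=reg.alpha,
            lambda_min=np.inf,
            mean_=zs.mean_,
            sd_=zs.sd_,
            degenerate=True,
            model_id="readout",
            perceiver_id=perceiver_id,
        )
        model.performance = readout_performance(model, trials, features)
        return model
    cv = glmnet.cv_lambda_min(
        X, y, groups, reg.alpha,
        lambdas=reg.lambdas, n_lambda=reg.n_lambda,
        lambda_min_ratio=reg.lambda_min_ratio,
    )
    beta, b0 = glmnet.fit_logistic_net(X, y, reg.alpha, cv.lambda_min)
    model = ReadoutModel(
        weights=beta,
        bias=b0,
        labels=list(zs.labels),
        alpha=reg.alpha,
        lambda_min=cv.lambda_min,
        mean_=zs.mean_,
        sd_=zs.sd_,
        model_id="readout",
        perceiver_id=perceiver_id,
    )
    model.performance = readout_performance(model, trials, features)
    return model


def readout_performance(
    model: ReadoutModel, trials: pd.DataFrame, features: FeatureMatrix
) -> float:
    """Fraction of the perceiver's choices predicted by the model argmax."""
    X, y, _, _ = _design(trials, features)
    eta = X @ model.weights + model.bias
    return float(np.mean((eta > 0) == y.astype(bool)))


def single_trial_readout(
    model: ReadoutModel, vector, true_intention: str
) -> SingleTrialIndex:
    """Sign-adjusted log-odds of correct readout.

    ``value = y * (beta_read . K + b0)``, y = +1 iff the prime's true
    intention is 'pour'; positive values mark correct readout of the
    encoded intention.
    """
    if true_intention not in (POSITIVE_CLASS, NEGATIVE_CLASS):
        raise SchemaError(f"unknown intention: {true_intention}")
    eta = model.linear_predictor(vector)
    y = 1.0 if true_intention == POSITIVE_CLASS else -1.0
    value = y * eta
    pid = getattr(vector, "prime_id", "")
    return SingleTrialIndex(prime_id=pid, value=value, correct=value > 0)


def readout_indices(
    model: ReadoutModel, features: FeatureMatrix, intentions: dict[str, str]
) -> pd.DataFrame:
    """Single-trial readout index for every prime in the feature matrix."""
    zs = features if features.zscored else zscore_features(features)
    eta = zs.values @ model.weights + model.bias
    sign = np.array([1.0 if intentions[p] == POSITIVE_CLASS else -1.0 for p in zs.prime_ids])
    return pd.DataFrame(
        {
            "perceiver_id": model.perceiver_id,
            "prime_id": zs.prime_ids,
            "readout_index": sign * eta,
        }
    )


def readout_performance_null(
    trials: pd.DataFrame,
    features: FeatureMatrix,
    reg: RegularizationSpec | None = None,
    n_perm: int = 200,
    rng: np.random.Generator | None = None,
    fast: bool = True,
) -> dict:
    """Chance-level null for readout performance by permuting choices.

    Each permutation shuffles the perceiver's choice labels across trials,
    refits, and records the fraction of (permuted) choices predicted.
    ``fast`` freezes the penalty at the observed ``lambda_min``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    reg = reg or RegularizationSpec()
    rng = rng or np.random.default_rng(0)
    model = fit_readout(trials, features, reg)
    X, y, groups, _ = _design(trials, features)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        if np.unique(yp).size < 2:
            null[i] = max(yp.mean(), 1 - yp.mean())
            continue
        if fast and np.isfinite(model.lambda_min):
            bp, b0p = glmnet.fit_logistic_net(X, yp, reg.alpha, model.lambda_min)
        else:
            cvp = glmnet.cv_lambda_min(
                X, yp, groups, reg.alpha,
                n_lambda=reg.n_lambda, lambda_min_ratio=reg.lambda_min_ratio,
            )
            bp, b0p = glmnet.fit_logistic_net(X, yp, reg.alpha, cvp.lambda_min)
        null[i] = float(np.mean(((X @ bp + b0p) > 0) == yp.astype(bool)))
    observed = model.performance
    # mid-p percentile: the null is discrete (permutation preserves the
    # choice base rate, so degenerate models tie exactly)
    percentile = float(
        (np.sum(null < observed) + 0.5 * np.sum(null == observed)) / len(null)
    )
    return {
        "observed": observed,
        "null": null,
        "percentile": percentile,
        "model": model,
    }


def readout_encoding_alignment(
    readout_model: ReadoutModel,
    encoding_model: EncodingModel,
    per_prime_readout: pd.Series | None = None,
    per_prime_encoding: pd.Series | None = None,
) -> dict:
    """Cosine of the two weight vectors plus, optionally, the Spearman
    correlation between per-prime mean readout and encoding indices."""
    if readout_model.labels != encoding_model.labels:
        raise SchemaError("feature label mismatch")
    wr, we = readout_model.weights, encoding_model.weights
    nr, ne = np.linalg.norm(wr), np.linalg.norm(we)
    cosine = None if nr < 1e-15 or ne < 1e-15 else float(wr @ we / (nr * ne))
    out = {"cosine": cosine}
    if per_prime_readout is not None and per_prime_encoding is not None:
        joined = pd.concat(
            [per_prime_readout.rename("r"), per_prime_encoding.rename("e")], axis=1
        ).dropna()
        rho, p = stats.spearmanr(joined["r"], joined["e"])
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(p)
        out["n_primes"] = int(len(joined))
    return out


def fit_pooled_readout(
    trials: pd.DataFrame,
    features: FeatureMatrix,
    reg: RegularizationSpec | None = None,
    n_surrogates: int = 20,
    rng: np.random.Generator | None = None,
) -> list[ReadoutModel]:
    """Pooled readout models on surrogate participants.

    Trials of all perceivers are pooled with identity erased, then
    partitioned at random into ``n_surrogates`` pseudo-participants, each
    receiving exactly the original per-participant trial count.
    """
    _check_trials(trials)
    reg = reg or RegularizationSpec()
    rng = rng or np.random.default_rng(0)
    counts = trials.groupby("perceiver_id").size()
    if counts.nunique() != 1:
        raise SchemaError("perceivers must have equal trial counts for pooling")
    per = int(counts.iloc[0])
    if n_surrogates * per > len(trials):
        raise ValueError("not enough pooled trials for the requested surrogates")
    perm = rng.permutation(len(trials))
    models = []
    for s in range(n_surrogates):
        idx = perm[s * per : (s + 1) * per]
        sub = trials.iloc[idx].copy()
        sub["perceiver_id"] = f"surrogate_{s + 1:02d}"
        sub["repetition"] = np.arange(len(sub))  # identities erased
        models.append(fit_readout(sub, features, reg))
    return models


def identify_zero_readout_primes(
    trials: pd.DataFrame,
    features: FeatureMatrix,
    models: dict[str, ReadoutModel],
    intentions: dict[str, str],
    n_surrogate: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    fast: bool = True,
) -> pd.DataFrame:
    """Zero-readout primes by the double criterion.

    A prime qualifies iff (1) the exact two-sided binomial test of correct
    choices across all its trials vs 0.5 has p > ``alpha``, and (2) for
    every perceiver, the prime's absolute readout index does not exceed
    the 95th percentile of a surrogate null in which only that prime's
    choices are randomized (equal probability) and the readout model
    refit.  ``fast`` freezes the penalty at each perceiver's observed
    ``lambda_min``; the full mode re-selects it per surrogate.

    Returns one row per prime with the test outcomes and membership flag.
    """
    if n_surrogate < 100:
        raise ValueError("n_surrogate must be >= 100 (reference value 10000)")
    _check_trials(trials)
    rng = rng or np.random.default_rng(0)
    zs = features if features.zscored else zscore_features(features)
    pos = {p: i for i, p in enumerate(zs.prime_ids)}
    sign = {p: (1.0 if intentions[p] == POSITIVE_CLASS else -1.0) for p in zs.prime_ids}

    trials = trials.copy()
    trials["correct"] = (
        trials["choice"].to_numpy()
        == trials["prime_id"].map(intentions).to_numpy()
    )

    # criterion 1: pooled behavioral chance test per prime
    rows = []
    for prime, sub in trials.groupby("prime_id"):
        k, n = int(sub["correct"].sum()), len(sub)
        pval = stats.binomtest(k, n, 0.5).pvalue
        rows.append({"prime_id": prime, "n_trials": n, "n_correct": k, "binomial_p": float(pval)})
    report = pd.DataFrame(rows).set_index("prime_id")
    report["behavioral_chance"] = report["binomial_p"] > alpha

    # criterion 2: surrogate-model percentile, only for behavioral candidates
    report["surrogate_ok"] = False
    report["max_percentile_excess"] = np.nan
    candidates = report.index[report["behavioral_chance"]]
    by_perceiver = {pid: sub for pid, sub in trials.groupby("perceiver_id")}
    for prime in candidates:
        ok = True
        worst = -np.inf
        for pid, sub in by_perceiver.items():
            model = models[pid]
            X, y, groups, _ = _design(sub, zs)
            x_prime = zs.values[pos[prime]]
            obs = abs(
                float(x_prime @ model.weights + model.bias)
            )
            mask = (sub["prime_id"] == prime).to_numpy()
            if not mask.any():
                continue
            lam = model.lambda_min if np.isfinite(model.lambda_min) else None
            null = np.empty(n_surrogate)
            warm = (model.weights.copy(), model.bias)
            for s in range(n_surrogate):
                ys = y.copy()
                ys[mask] = rng.integers(0, 2, size=mask.sum()).astype(float)
                if fast and lam is not None:
                    bs, b0s = glmnet.fit_logistic_net(
                        X, ys, model.alpha, lam, warm=warm, tol=1e-8, max_outer=20
                    )
                else:
                    cvs = glmnet.cv_lambda_min(X, ys, groups, model.alpha)
                    bs, b0s = glmnet.fit_logistic_net(X, ys, model.alpha, cvs.lambda_min)
                null[s] = abs(float(x_prime @ bs + b0s))
            thr = np.percentile(null, 95)
            worst = max(worst, obs - thr)
            if obs > thr:
                ok = False
                break
        report.loc[prime, "surrogate_ok"] = ok
        report.loc[prime, "max_percentile_excess"] = worst
    report["zero_readout"] = report["behavioral_chance"] & report["surrogate_ok"]
    return report.reset_index()
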