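"""Trial-level statistical analyses of kinematic priming.

Exclusion rules, first-fixation quadrant classification, gamma/logistic/
cumulative-link mixed models linking single-trial information indices to
RTs, fixations and confidence, median-split and zero-vs-high priming
contrasts, pupil-baseline preprocessing and control models, Holm
correction, and correlation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.special import expit

from .exceptions import FittingError, SchemaError
from .mixed import MixedFitResult, ModelSpec, RandomTerm, fit_mixed, lrt

DEFAULT_RANDOM = (RandomTerm("participant_id"), RandomTerm("prime_id"))

RELEVANT_QUADRANT = {"drinking": ("top", "right"), "pouring": ("bottom", "left")}


# --------------------------------------------------------------------------
# exclusions

def apply_exclusions(
    trials: pd.DataFrame, rt_sd_threshold: float = 2.5, for_fixation: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Apply the trial-exclusion rules in order.

    1. incorrectly categorized trials are removed;
    2. RTs above the participant's mean + ``rt_sd_threshold`` SD (both
       computed on that participant's correct trials) are removed;
    3. for fixation analyses only, trials without an initial fixation on
       the probe (class 'none') are removed.

    Participants with fewer than 2 correct trials have an undefined SD:
    they are flagged in the report and skip rule 2 rather than being
    silently dropped.
    """
    n0 = len(trials)
    report: dict = {"n_input": n0, "flagged_participants": []}
    correct = trials[trials["accuracy"] == 1]
    report["n_removed_incorrect"] = n0 - len(correct)

    keep = np.ones(len(correct), dtype=bool)
    rts = correct["rt_ms"].to_numpy()
    for pid, sub in correct.groupby("participant_id"):
        loc = correct["participant_id"] == pid
        if len(sub) < 2:
            report["flagged_participants"].append(pid)
            continue
        thr = sub["rt_ms"].mean() + rt_sd_threshold * sub["rt_ms"].std(ddof=1)
        keep &= ~(loc.to_numpy() & (rts > thr))
    retained = correct[keep]
    report["n_removed_rt"] = int((~keep).sum())

    if for_fixation:
        m = retained["first_fixation_class"] != "none"
        report["n_removed_no_fixation"] = int((~m).sum())
        retained = retained[m]
    report["n_retained"] = len(retained)
    report["fraction_retained"] = len(retained) / n0 if n0 else np.nan
    return retained.reset_index(drop=True), report


# --------------------------------------------------------------------------
# fixations

def classify_first_fixation(
    fixation_xy: tuple[float, float],
    probe: str,
    image_size: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
) -> str:
    """Quadrant class of a first fixation on the probe image.

    The image is split into four equal quadrants; the task-relevant
    quadrant is top-right for the drinking probe (mouth-bottle
    interaction) and bottom-left for the pouring probe (bottle-glass
    interaction).  Screen coordinates have the y axis pointing down.
    Boundary convention: the vertical midline belongs to the right
    quadrants and the horizontal midline to the top quadrants (the image
    centre is therefore top-right).  Fixations outside the image are
    classified 'none'.
    """
    if probe not in RELEVANT_QUADRANT:
        raise SchemaError(f"unknown probe: {probe}")
    x, y = fixation_xy
    ox, oy = origin
    w, h = image_size
    if not (ox <= x <= ox + w and oy <= y <= oy + h):
        return "none"
    cx, cy = ox + w / 2.0, oy + h / 2.0
    quadrant = ("top" if y <= cy else "bottom", "right" if x >= cx else "left")
    displayed = RELEVANT_QUADRANT[probe]
    other = RELEVANT_QUADRANT["pouring" if probe == "drinking" else "drinking"]
    if quadrant == displayed:
        return "relevant-displayed"
    if quadrant == other:
        return "relevant-nondisplayed"
    return "other"


# --------------------------------------------------------------------------
# index joins

def _join_index(trials: pd.DataFrame, index: pd.DataFrame, index_col: str = "index") -> pd.DataFrame:
    """Join a per-(participant, prime) or per-prime index onto trials."""
    df = trials.copy()
    if "participant_id" in index.columns or "perceiver_id" in index.columns:
        idx = index.rename(columns={"perceiver_id": "participant_id"})
        key = ["participant_id", "prime_id"]
    else:
        idx = index
        key = ["prime_id"]
    value_cols = [c for c in idx.columns if c not in key]
    if len(value_cols) != 1:
        raise SchemaError("index table must carry exactly one value column")
    idx = idx.rename(columns={value_cols[0]: index_col})
    out = df.merge(idx, on=key, how="left", validate="many_to_one")
    if out[index_col].isna().any():
        missing = out.loc[out[index_col].isna(), key].drop_duplicates()
        raise SchemaError(f"index missing for retained trials: {missing.head().to_dict('records')}")
    return out


# --------------------------------------------------------------------------
# information-by-congruency models

FULL_TERMS = (
    "probe", "congruency", "index",
    "probe:congruency", "probe:index", "congruency:index",
    "probe:congruency:index",
)


def congruency_information_model(
    trials: pd.DataFrame,
    index: pd.DataFrame,
    response: str = "rt",
    random: tuple[RandomTerm, ...] = DEFAULT_RANDOM,
) -> dict:
    """Response ~ probe x congruency x information index, mixed model.

    For RTs (gamma-identity) reports the per-congruency slopes of RT on
    the index; for fixations (binomial-logit) additionally computes
    marginal predicted probabilities and a Wald test of equality of the
    congruency effect on the probability scale at low/high index.
    The returned LRT tests the congruency-by-index product term.
    """
    df = _join_index(trials, index)
    if response == "rt":
        df = df.rename(columns={"rt_ms": "y"})
        family = "gamma-identity"
    elif response == "fixation":
        df = df.assign(y=(df["first_fixation_class"] == "relevant-displayed").astype(int))
        family = "binomial-logit"
    else:
        raise SchemaError("response must be 'rt' or 'fixation'")
    spec = ModelSpec("y", family, fixed=FULL_TERMS, random=random)
    full = fit_mixed(spec, df)
    reduced = fit_mixed(spec.drop_fixed("congruency:index"), df)
    test = lrt(full, reduced)

    names = full.fixed_names
    b = dict(zip(names, full.coef))
    slope_cong = b.get("index", 0.0) + b.get("congruency[congruent]:index", 0.0)
    slope_incong = b.get("index", 0.0) - b.get("congruency[congruent]:index", 0.0)
    out = {
        "fit": full,
        "reduced": reduced,
        "lrt": test,
        "slope_congruent": float(slope_cong),
        "slope_incongruent": float(slope_incong),
    }
    if response == "fixation":
        out["marginal"] = _marginal_fixation_effects(full, df)
    return out


def _marginal_fixation_effects(fit: MixedFitResult, df: pd.DataFrame) -> dict:
    """Congruency effects on the probability scale at low/high index, and
    a Wald test of their equality (delta method on the fitted fixed
    effects)."""
    lo, hi = np.percentile(df["index"], [25, 75])
    grid = pd.DataFrame(
        [
            {"probe": p, "congruency": c, "index": v}
            for v in (lo, hi)
            for c in ("congruent", "incongruent")
            for p in ("drinking", "pouring")
        ]
    )
    X = fit.eta_gradient(grid)
    eta = X @ fit.coef
    p = expit(eta)
    # average over probes within (index level, congruency)
    def cell(v, c):
        m = (grid["index"] == v) & (grid["congruency"] == c)
        return p[m.to_numpy()].mean(), X[m.to_numpy()].mean(axis=0) * (
            p[m.to_numpy()] * (1 - p[m.to_numpy()])
        ).mean()

    effects = {}
    grads = {}
    for tag, v in (("low", lo), ("high", hi)):
        (p_c, g_c), (p_i, g_i) = cell(v, "congruent"), cell(v, "incongruent")
        effects[tag] = p_c - p_i
        grads[tag] = g_c - g_i
    gdiff = grads["high"] - grads["low"]
    var = float(gdiff @ fit.vcov @ gdiff)
    delta = effects["high"] - effects["low"]
    z = delta / np.sqrt(var) if var > 0 else np.nan
    return {
        "effect_low": float(effects["low"]),
        "effect_high": float(effects["high"]),
        "difference": float(delta),
        "wald_z": float(z),
        "wald_p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        "index_low": float(lo),
        "index_high": float(hi),
    }


# --------------------------------------------------------------------------
# stratified priming effects

def _stratified_priming(df: pd.DataFrame, response: str, random) -> dict:
    family = "gamma-identity" if response == "rt" else "binomial-logit"
    ycol = "rt_ms" if response == "rt" else "fix01"
    if response == "fixation":
        df = df.assign(fix01=(df["first_fixation_class"] == "relevant-displayed").astype(int))
    df = df.rename(columns={ycol: "y"})
    spec = ModelSpec(
        "y", family,
        fixed=("probe", "congruency", "stratum", "congruency:stratum"),
        random=random,
    )
    full = fit_mixed(spec, df)
    reduced = fit_mixed(spec.drop_fixed("congruency:stratum"), df)
    test = lrt(full, reduced)
    strata = sorted(df["stratum"].unique())

    out_effects = {}
    for s in strata:
        grid = pd.DataFrame(
            [
                {"probe": p, "congruency": c, "stratum": s}
                for c in ("congruent", "incongruent")
                for p in ("drinking", "pouring")
            ]
        )
        X = full.eta_gradient(grid)
        eta = X @ full.coef
        mask_i = (grid["congruency"] == "incongruent").to_numpy()
        if family == "gamma-identity":
            val_i, val_c = eta[mask_i].mean(), eta[~mask_i].mean()
            g = X[mask_i].mean(axis=0) - X[~mask_i].mean(axis=0)
        else:
            p = expit(eta)
            val_i, val_c = p[mask_i].mean(), p[~mask_i].mean()
            g = (X[mask_i] * (p[mask_i] * (1 - p[mask_i]))[:, None]).mean(axis=0) - (
                X[~mask_i] * (p[~mask_i] * (1 - p[~mask_i]))[:, None]
            ).mean(axis=0)
        var = float(g @ full.vcov @ g)
        eff = float(val_i - val_c)
        se = float(np.sqrt(var)) if var > 0 else np.nan
        z = eff / se if se and np.isfinite(se) else np.nan
        out_effects[s] = {
            "effect": eff,
            "se": se,
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        }
    return {"fit": full, "effects": out_effects, "difference_lrt": test}


def median_split_priming(
    trials: pd.DataFrame,
    index: pd.DataFrame,
    response: str = "rt",
    random: tuple[RandomTerm, ...] = DEFAULT_RANDOM,
) -> dict:
    """Priming effect (incongruent - congruent) in low- vs high-index
    strata split at the median across all trials and participants."""
    df = _join_index(trials, index)
    med = float(df["index"].median())
    if df["index"].nunique() < 2:
        raise FittingError("median split undefined: all index values identical")
    df = df.assign(stratum=np.where(df["index"] > med, "high", "low"))
    out = _stratified_priming(df, response, random)
    out["median"] = med
    pvals = [out["effects"][s]["p"] for s in ("low", "high")]
    out["holm_adjusted"] = dict(zip(("low", "high"), holm_bonferroni(pvals)))
    return out


def zero_vs_high_readout_contrast(
    trials: pd.DataFrame,
    zero_primes: list[str],
    high_primes: list[str],
    response: str = "rt",
    random: tuple[RandomTerm, ...] = DEFAULT_RANDOM,
) -> dict:
    """Priming within zero-readout vs high-readout primes and their
    contrast, from a mixed model with congruency x readout-level."""
    if not zero_primes or not high_primes:
        raise FittingError("both readout strata must be non-empty")
    df = trials[trials["prime_id"].isin(set(zero_primes) | set(high_primes))].copy()
    df["stratum"] = np.where(df["prime_id"].isin(set(zero_primes)), "zero", "high")
    if df["stratum"].nunique() < 2:
        raise FittingError("one of the readout strata has no retained trials")
    return _stratified_priming(df, response, random)


# --------------------------------------------------------------------------
# confidence

def confidence_readout_model(
    choice_trials: pd.DataFrame,
    index: pd.DataFrame,
    random: tuple[RandomTerm, ...] = (RandomTerm("participant_id"),),
    index_grid: np.ndarray | None = None,
) -> dict:
    """Cumulative-link mixed model of (collapsed) confidence on the
    single-trial information index."""
    trials = choice_trials
    if "participant_id" not in trials.columns:
        trials = trials.rename(columns={"perceiver_id": "participant_id"})
    elif "perceiver_id" in trials.columns:
        trials = trials.drop(columns=["perceiver_id"])
    if "confidence" not in trials.columns:
        raise SchemaError("confidence column required")
    df = _join_index(trials, index)
    spec = ModelSpec("confidence", "cumulative-logit", fixed=("index",), random=random)
    full = fit_mixed(spec, df)
    reduced = fit_mixed(spec.drop_fixed("index"), df)
    test = lrt(full, reduced)
    if index_grid is None:
        index_grid = np.linspace(df["index"].quantile(0.05), df["index"].quantile(0.95), 25)
    slope = full.coef[full.fixed_names.index("index")]
    cuts = full.cutpoints
    eta = slope * np.asarray(index_grid)
    cum = expit(cuts[:, None] - eta[None, :])  # P(Y <= j)
    probs = np.vstack([cum[0], np.diff(cum, axis=0), 1 - cum[-1]])
    return {
        "fit": full,
        "lrt": test,
        "coefficient": float(slope),
        "index_grid": np.asarray(index_grid),
        "category_probs": probs,
    }


# --------------------------------------------------------------------------
# pupil

def pupil_baseline(
    trace: np.ndarray,
    sample_rate: float,
    prime_onset_index: int | None = None,
    window_s: float = 1.0,
    cutoff_hz: float = 10.0,
) -> float | None:
    """Baseline pupil diameter over the window preceding prime onset.

    Blink gaps (NaNs) are linearly interpolated, the trace is smoothed
    with a first-order low-pass filter (10 Hz cutoff), and the mean over
    the 1-s pre-prime window is returned.  A fully missing window yields
    ``None`` (trial flagged).
    """
    x = np.asarray(trace, dtype=float).copy()
    n = len(x)
    if prime_onset_index is None:
        prime_onset_index = n
    w = int(round(window_s * sample_rate))
    start = prime_onset_index - w
    if start < 0:
        raise ValueError("trace does not cover the pre-prime window")
    window = slice(start, prime_onset_index)
    if np.all(np.isnan(x[window])):
        return None
    good = ~np.isnan(x)
    if not good.any():
        return None
    x = np.interp(np.arange(n), np.nonzero(good)[0], x[good])
    b, a = signal.butter(1, cutoff_hz, fs=sample_rate)
    x = signal.lfilter(b, a, x, zi=signal.lfilter_zi(b, a) * x[0])[0]
    return float(np.mean(x[window]))


def zscore_within_participant(df: pd.DataFrame, column: str = "baseline_pupil") -> pd.DataFrame:
    out = df.copy()
    grp = out.groupby("participant_id")[column]
    sd = grp.transform("std")
    centered = out[column] - grp.transform("mean")
    # constant-within-participant baselines standardize to zero
    out[column + "_z"] = np.where(sd > 0, centered / sd.replace(0, np.nan), 0.0)
    return out


def pupil_control_model(
    trials: pd.DataFrame,
    index: pd.DataFrame,
    random: tuple[RandomTerm, ...] = DEFAULT_RANDOM,
) -> dict:
    """RT model with congruency x index x pupil product terms; reports
    whether the congruency-by-index interaction survives pupil inclusion."""
    df = _join_index(trials, index)
    df = zscore_within_participant(df)
    df = df.rename(columns={"rt_ms": "y", "baseline_pupil_z": "pupil"})
    base_terms = ("congruency", "index", "congruency:index")
    full_terms = base_terms + (
        "pupil", "congruency:pupil", "index:pupil", "congruency:index:pupil",
    )
    base = fit_mixed(ModelSpec("y", "gamma-identity", fixed=base_terms, random=random), df)
    full = fit_mixed(ModelSpec("y", "gamma-identity", fixed=full_terms, random=random), df)
    reduced = fit_mixed(
        ModelSpec(
            "y", "gamma-identity",
            fixed=tuple(t for t in full_terms if t != "congruency:index"),
            random=random,
        ),
        df,
    )
    test = lrt(full, reduced)
    key = "congruency[congruent]:index"
    b_base = dict(zip(base.fixed_names, base.coef))[key]
    se_base = dict(zip(base.fixed_names, base.se))[key]
    b_full = dict(zip(full.fixed_names, full.coef))[key]
    return {
        "fit": full,
        "base_fit": base,
        "interaction_lrt": test,
        "interaction_base": float(b_base),
        "interaction_with_pupil": float(b_full),
        "shift_in_se": float(abs(b_full - b_base) / se_base) if se_base else np.nan,
    }


# --------------------------------------------------------------------------
# generic tests

def holm_bonferroni(pvalues) -> list[float]:
    """Holm's step-down adjustment, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def correlation_test(x, y, method: str = "pearson") -> dict:
    """Correlation with a two-sided p-value.

    Pearson uses the Student-t test with n-2 df; Spearman uses the
    asymptotic t approximation on rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise ValueError("correlation undefined for constant input")
    n = x.size
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return {"r": float(r), "p": float(p), "n": n}
    if method == "spearman":
        rho = float(stats.spearmanr(x, y).statistic)
        if abs(rho) >= 1.0:
            return {"r": rho, "p": 0.0, "n": n}
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
        return {"r": rho, "p": p, "n": n}
    raise ValueError("method must be 'pearson' or 'spearman'")
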