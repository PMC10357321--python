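"""Synthetic reach-to-grasp primes, perceivers, and behavioral sessions.

The generator emulates the statistical structure the downstream analyses
assume, with known ground truth for parameter recovery:

* 30+30 reach-to-pour / reach-to-drink primes whose intention differences
  are smooth time-varying offsets growing toward movement end, injected
  only into the configured variables (by default wrist height, wrist
  horizontal trajectory, and dorsum-plane y);
* perceivers whose readout vectors are the encoding direction restricted
  to a readout subspace, scaled by heterogeneous gains;
* forced-choice sessions (choice, confidence, RT) from a logistic
  observer with lapses;
* primed-categorization sessions where RTs (gamma, identity-link mean)
  and first fixations carry a readout-by-congruency interaction, plus
  priming-independent pupil baselines.

Channel model: wrist velocity is a raised-cosine bell starting/ending
below the 20 mm/s movement threshold; the remaining channels are smooth
base profiles plus Gaussian-process variability sampled on a common
normalized-time grid.  Effect amplitudes are calibrated so that the
configured value is the standardized mean difference (Cohen's d) of the
movement-averaged channel between intentions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CHANNEL_SD, GeneratorConfig
from .exceptions import ConfigurationError, GenerationError
from .kinematics import (
    VARIABLES,
    FeatureMatrix,
    KinematicTrajectory,
    build_feature_matrix,
    feature_labels,
    zscore_features,
)

INTENTIONS = ("pour", "drink")  # 'pour' is the positive class throughout
PROBES = {"pour": "pouring", "drink": "drinking"}

_GRID = np.linspace(0.0, 1.0, 101)
_VEL_FLOOR = 5.0  # mm/s at movement endpoints, below the 20 mm/s threshold

# smooth base profiles, shared across primes (functions of normalized time)
_BASES = {
    "W_H": lambda t: 80.0 + 90.0 * expit((t - 0.55) / 0.12),
    "W_HT": lambda t: 250.0 - 70.0 * expit((t - 0.5) / 0.15),
    "G_A": lambda t: 20.0 + 70.0 * expit((t - 0.45) / 0.15),
    "T_X": lambda t: 40.0 + 10.0 * np.sin(np.pi * t),
    "T_Y": lambda t: 30.0 - 5.0 * t,
    "T_Z": lambda t: 20.0 + 0.0 * t,
    "I_X": lambda t: 65.0 + 8.0 * np.sin(np.pi * t),
    "I_Y": lambda t: -25.0 + 4.0 * t,
    "I_Z": lambda t: 22.0 + 0.0 * t,
    "FP_X": lambda t: 0.3 + 0.1 * t,
    "FP_Y": lambda t: 0.6 - 0.1 * t,
    "FP_Z": lambda t: 0.55 + 0.0 * t,
    "DP_X": lambda t: 0.25 + 0.05 * t,
    "DP_Y": lambda t: 0.62 + 0.0 * t,
    "DP_Z": lambda t: 0.5 - 0.05 * t,
}


def _gp_chol(length_scale: float, jitter: float = 1e-10) -> np.ndarray:
    d = _GRID[:, None] - _GRID[None, :]
    k = np.exp(-0.5 * (d / length_scale) ** 2)
    return np.linalg.cholesky(k + jitter * np.eye(len(_GRID)))


def _mean_correlation(length_scale: float) -> float:
    """Mean pairwise correlation of the GP over the full normalized grid.

    This is the variance-reduction factor of the movement-time average,
    used to calibrate injected effect amplitudes.
    """
    d = _GRID[:, None] - _GRID[None, :]
    return float(np.exp(-0.5 * (d / length_scale) ** 2).mean())


def _epoch_mean_correlation(length_scale: float, n_epochs: int) -> np.ndarray:
    """Per-epoch variance-reduction factor of the epoch-time average."""
    edges = np.minimum((_GRID * n_epochs).astype(int), n_epochs - 1)
    k = np.exp(-0.5 * ((_GRID[:, None] - _GRID[None, :]) / length_scale) ** 2)
    out = np.empty(n_epochs)
    for e in range(n_epochs):
        sel = edges == e
        out[e] = k[np.ix_(sel, sel)].mean()
    return out


def effect_time_course(t: np.ndarray) -> np.ndarray:
    """Intention-difference profile: accrues steeply toward movement end
    (prospective information is concentrated late in the reach),
    normalized to unit mean over the movement."""
    return 7.0 * t**6


@dataclass
class GroundTruth:
    """Known generative quantities, for parameter recovery."""

    true_encoding_direction: np.ndarray  # unit 64-vector, z-scored feature space
    intentions: dict[str, str]  # prime_id -> intention
    true_readout_vectors: np.ndarray | None = None  # (n_perceivers, 64)
    readout_gains: np.ndarray | None = None
    true_priming_gain: float | None = None  # ms per log-odds unit
    true_fixation_gain: float | None = None  # logit units per log-odds unit
    labels: list[tuple[str, int]] = field(default_factory=feature_labels)

    def to_dict(self) -> dict:
        return {
            "true_encoding_direction": self.true_encoding_direction.tolist(),
            "intentions": self.intentions,
            "true_readout_vectors": None
            if self.true_readout_vectors is None
            else self.true_readout_vectors.tolist(),
            "readout_gains": None
            if self.readout_gains is None
            else self.readout_gains.tolist(),
            "true_priming_gain": self.true_priming_gain,
            "true_fixation_gain": self.true_fixation_gain,
            "labels": [[v, e] for v, e in self.labels],
        }


@dataclass
class PrimeSet:
    trajectories: list[KinematicTrajectory]
    intentions: np.ndarray  # aligned with trajectories, values in INTENTIONS
    ground_truth: GroundTruth

    @property
    def prime_ids(self) -> list[str]:
        return [t.prime_id for t in self.trajectories]


@dataclass
class Perceivers:
    vectors: np.ndarray  # (n_perceivers, 64) readout vectors (z-scored space)
    gains: np.ndarray
    ids: list[str]


def _epoch_means_of(fn, n_epochs: int = 4) -> np.ndarray:
    edges = np.minimum((_GRID * n_epochs).astype(int), n_epochs - 1)
    vals = fn(_GRID)
    return np.array([vals[edges == e].mean() for e in range(n_epochs)])


def true_encoding_direction(config: GeneratorConfig, n_epochs: int = 4) -> np.ndarray:
    """Standardized per-feature intention effects, unit-normalized.

    Components are proportional to the effect size of each (variable,
    epoch) feature after pooled z-scoring; variables outside the effect
    profile are exactly zero.
    """
    d_e = _epoch_means_of(effect_time_course, n_epochs)
    v_avg = _mean_correlation(config.gp_length_scale)
    v_ep = _epoch_mean_correlation(config.gp_length_scale, n_epochs)
    direction = np.zeros(len(VARIABLES) * n_epochs)
    for iv, v in enumerate(VARIABLES):
        e_v = config.effect_profile.get(v, 0.0)
        if e_v == 0.0:
            continue
        # per-epoch effect in within-class SD units of the epoch feature
        raw = e_v * np.sqrt(v_avg) * d_e / np.sqrt(v_ep)
        # pooled (both-class) z-scoring shrinks features with large effects
        direction[iv * n_epochs : (iv + 1) * n_epochs] = raw / np.sqrt(1 + raw**2 / 4)
    n = np.linalg.norm(direction)
    return direction / n if n > 0 else direction


def generate_primes(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> PrimeSet:
    """Generate the kinematic prime set with known encoding ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chol_slow = _gp_chol(config.gp_length_scale)
    chol_fast = _gp_chol(0.02)
    v_avg = _mean_correlation(config.gp_length_scale)
    lo, hi = config.duration_range

    trajectories, labels, intent_map = [], [], {}
    for intent in INTENTIONS:
        y = 1.0 if intent == "pour" else -1.0
        for k in range(config.n_primes_per_intention):
            pid = f"{intent}_{k + 1:02d}"
            duration = rng.uniform(lo, hi)
            n = int(round(duration * config.sample_rate)) + 1
            t = np.linspace(0.0, 1.0, n)
            channels = {}
            # wrist velocity: raised-cosine bell, endpoints below threshold
            amp = max(rng.normal(900.0, CHANNEL_SD["W_V"]), 400.0)
            bell = 0.5 * (1.0 - np.cos(2.0 * np.pi * _GRID))
            v = _VEL_FLOOR + (amp - _VEL_FLOOR) * bell
            e_wv = config.effect_profile.get("W_V", 0.0)
            if e_wv:
                # taper so endpoints stay below the movement threshold
                v += y * 0.5 * e_wv * CHANNEL_SD["W_V"] * np.sqrt(v_avg) \
                    * effect_time_course(_GRID) * bell
            v += chol_fast @ rng.standard_normal(len(_GRID)) \
                * config.trajectory_noise_sd * 10.0
            channels["W_V"] = np.clip(np.interp(t, _GRID, v), 0.0, None)

            for var in VARIABLES:
                if var == "W_V":
                    continue
                sd = CHANNEL_SD[var]
                x = _BASES[var](_GRID).astype(float).copy()
                x += sd * (chol_slow @ rng.standard_normal(len(_GRID)))
                x += config.trajectory_noise_sd * sd \
                    * (chol_fast @ rng.standard_normal(len(_GRID)))
                e_v = config.effect_profile.get(var, 0.0)
                if e_v:
                    x += y * 0.5 * e_v * sd * np.sqrt(v_avg) * effect_time_course(_GRID)
                x = np.interp(t, _GRID, x)
                if var == "G_A":
                    x = np.clip(x, 0.0, None)
                channels[var] = x
            trajectories.append(
                KinematicTrajectory(
                    prime_id=pid, sample_rate=config.sample_rate, channels=channels
                )
            )
            labels.append(intent)
            intent_map[pid] = intent

    gt = GroundTruth(
        true_encoding_direction=true_encoding_direction(config),
        intentions=intent_map,
        true_priming_gain=config.rt_priming_gain_ms_per_logodds,
        true_fixation_gain=config.fixation_priming_gain,
    )
    return PrimeSet(trajectories=trajectories, intentions=np.array(labels), ground_truth=gt)


def generate_perceivers(
    config: GeneratorConfig,
    encoding_direction: np.ndarray,
    rng: np.random.Generator | None = None,
    n_epochs: int = 4,
) -> Perceivers:
    """Per-perceiver readout vectors: the encoding direction restricted to
    the readout subspace, scaled by a perceiver gain, plus perceiver noise
    (noise scales with the gain so zero-gain perceivers read nothing)."""
    if not config.readout_subspace:
        raise ConfigurationError("readout_subspace must not be empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    mask = np.array(
        [v in config.readout_subspace for v, _ in feature_labels(n_epochs)], dtype=float
    )
    base = np.asarray(encoding_direction, dtype=float) * mask
    glo, ghi = config.readout_gain_range
    gains = rng.uniform(glo, ghi, size=config.n_perceivers)
    noise = rng.standard_normal((config.n_perceivers, base.size)) * mask
    vectors = gains[:, None] * (base[None, :] + config.readout_noise_sd * noise)
    return Perceivers(
        vectors=vectors,
        gains=gains,
        ids=[f"P{i + 1:02d}" for i in range(config.n_perceivers)],
    )


def prime_features(primes: PrimeSet, n_epochs: int = 4) -> FeatureMatrix:
    """Raw (non-standardized) feature matrix of a prime set."""
    return build_feature_matrix(primes.trajectories, n_epochs=n_epochs)


def true_predictors(
    primes: PrimeSet, perceivers: Perceivers, n_epochs: int = 4
) -> pd.DataFrame:
    """Ground-truth linear predictor and sign-adjusted readout index per
    (perceiver, prime), from z-scored features and the true readout vectors."""
    feats = zscore_features(prime_features(primes, n_epochs))
    z = feats.values
    pred = z @ perceivers.vectors.T  # (n_primes, n_perceivers)
    sign = np.where(primes.intentions == "pour", 1.0, -1.0)
    rows = []
    for j, pid in enumerate(perceivers.ids):
        rows.append(
            pd.DataFrame(
                {
                    "perceiver_id": pid,
                    "prime_id": feats.prime_ids,
                    "predictor": pred[:, j],
                    "true_readout": sign * pred[:, j],
                    "true_intention": primes.intentions,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_discrimination(
    primes: PrimeSet,
    perceivers: Perceivers,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forced-choice sessions: choice ~ Bernoulli(sigmoid(readout · z)),
    lapse-mixed toward 0.5; confidence is the ordinal bin of the absolute
    linear predictor; repetitions per prime per perceiver from config."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    table = true_predictors(primes, perceivers)
    thresholds = np.asarray(config.confidence_thresholds)
    out = []
    for rep in range(1, config.n_discrimination_reps + 1):
        block = table.copy()
        p_pour = expit(block["predictor"].to_numpy())
        lapse = rng.random(len(block)) < config.lapse_rate
        p_eff = np.where(lapse, 0.5, p_pour)
        choice_pour = rng.random(len(block)) < p_eff
        # ordinal confidence: latent = |predictor| + logistic noise, cut at
        # the configured thresholds (a cumulative-logit process with unit
        # coefficient on the absolute predictor)
        latent = np.abs(block["predictor"].to_numpy()) + rng.logistic(size=len(block))
        conf = np.searchsorted(thresholds, latent) + 1
        mean_rt = np.clip(1000.0 - 60.0 * np.abs(block["predictor"]), 300.0, None)
        rt = rng.gamma(10.0, mean_rt / 10.0)
        block["repetition"] = rep
        block["choice"] = np.where(choice_pour, "pour", "drink")
        block["confidence"] = conf
        block["rt_ms"] = rt
        out.append(block)
    df = pd.concat(out, ignore_index=True)
    df["correct"] = (df["choice"] == df["true_intention"]).astype(int)
    return df[
        ["perceiver_id", "prime_id", "repetition", "choice", "confidence",
         "rt_ms", "true_intention", "correct", "predictor", "true_readout"]
    ]


def simulate_priming_session(
    primes: PrimeSet,
    perceivers: Perceivers,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Primed-categorization sessions with a readout-by-congruency effect.

    RT ~ Gamma with identity-link mean
    ``rt_base + probe_effect -/+ gain * s`` (congruent/incongruent), where
    ``s`` is the ground-truth signed readout index of the prime for that
    perceiver.  First fixations are Bernoulli on the logit scale with the
    mirrored interaction; pupil baselines are AR(1) noise independent of
    everything else.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    pred = true_predictors(primes, perceivers)
    pred = pred.set_index(["perceiver_id", "prime_id"])
    prime_ids = primes.prime_ids
    intent = dict(zip(prime_ids, primes.intentions))
    n_trials = config.n_priming_trials
    n_congruent = int(round(config.congruent_fraction * n_trials))
    gain = config.rt_priming_gain_ms_per_logodds
    shape = config.rt_gamma_shape

    rows = []
    for pid in perceivers.ids:
        reps = int(np.ceil(n_trials / len(prime_ids)))
        seq = np.tile(prime_ids, reps)[:n_trials]
        rng.shuffle(seq)
        congruent = np.zeros(n_trials, dtype=bool)
        congruent[rng.permutation(n_trials)[:n_congruent]] = True
        # AR(1) pupil baseline, unit stationary SD
        phi = 0.5
        eps = rng.standard_normal(n_trials) * np.sqrt(1 - phi**2)
        pupil = np.empty(n_trials)
        prev = rng.standard_normal()
        for i in range(n_trials):
            prev = phi * prev + eps[i]
            pupil[i] = prev
        for i in range(n_trials):
            prime = seq[i]
            pi = intent[prime]
            probe_int = pi if congruent[i] else ("drink" if pi == "pour" else "pour")
            s = float(pred.loc[(pid, prime), "true_readout"])
            probe_term = config.rt_probe_effect_ms * (1.0 if probe_int == "pour" else -1.0)
            mu = config.rt_base_ms + probe_term + (-gain if congruent[i] else gain) * s
            if mu <= 0:
                raise GenerationError(
                    f"non-positive mean RT ({mu:.1f} ms); reduce gains or raise rt_base_ms"
                )
            rt = rng.gamma(shape, mu / shape)
            logit = config.fixation_base_logit + config.fixation_priming_gain * s * (
                1.0 if congruent[i] else -1.0
            )
            if rng.random() < expit(logit):
                fix = "relevant-displayed"
            else:
                fix = rng.choice(
                    ["relevant-nondisplayed", "other", "none"], p=[0.25, 0.6, 0.15]
                )
            rows.append(
                (
                    pid, prime, pi, PROBES[probe_int],
                    "congruent" if congruent[i] else "incongruent",
                    rt, int(rng.random() >= config.error_rate), fix, pupil[i],
                    i * 3 // n_trials + 1,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "prime_id", "prime_intention", "probe", "congruency",
            "rt_ms", "accuracy", "first_fixation_class", "baseline_pupil", "block",
        ],
    )
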