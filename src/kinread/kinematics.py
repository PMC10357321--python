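"""Single-trial kinematic feature extraction.

Turns per-trial kinematic time series (16 named channels) into the
64-dimensional feature vectors used by the encoding and readout models:
movement bounds from a wrist-velocity threshold, linear resampling to
normalized movement time, epoch averaging, and train-referenced
z-scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MovementDetectionError, SchemaError

#: Canonical channel order.  Feature vectors are laid out variable-major:
#: all epochs of VARIABLES[0], then all epochs of VARIABLES[1], ...
VARIABLES: tuple[str, ...] = (
    "W_V",   # wrist velocity (mm/s)
    "W_H",   # wrist height: z-component of the wrist (mm)
    "W_HT",  # wrist horizontal trajectory: transverse x-component (mm)
    "G_A",   # grip aperture: thumb-tip to index-tip distance (mm)
    "T_X", "T_Y", "T_Z",     # thumb tip, hand-local frame (mm)
    "I_X", "I_Y", "I_Z",     # index tip, hand-local frame (mm)
    "FP_X", "FP_Y", "FP_Z",  # finger-plane unit-normal components
    "DP_X", "DP_Y", "DP_Z",  # dorsum-plane unit-normal components
)

N_VARIABLES = len(VARIABLES)
DEFAULT_N_EPOCHS = 4
VELOCITY_THRESHOLD_MM_S = 20.0

#: Number of evenly spaced points used when resampling to normalized
#: movement time before epoch averaging.
N_RESAMPLE = 101


def feature_labels(n_epochs: int = DEFAULT_N_EPOCHS) -> list[tuple[str, int]]:
    """Canonical ``(variable, epoch)`` label order; epochs are 1-based."""
    return [(v, e) for v in VARIABLES for e in range(1, n_epochs + 1)]


@dataclass
class KinematicTrajectory:
    """One reach: 16 named channels on a shared time base."""

    prime_id: str
    sample_rate: float
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        missing = set(VARIABLES) - set(self.channels)
        if missing:
            raise SchemaError(f"missing channels: {sorted(missing)}")
        lengths = {len(np.asarray(c)) for c in self.channels.values()}
        if len(lengths) != 1:
            raise SchemaError("channels must share one time base")
        (n,) = lengths
        if n < 10:
            raise SchemaError("trajectory must have at least 10 samples")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name in ("W_V", "G_A"):
            if np.any(self.channels[name] < 0):
                raise SchemaError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.channels["W_V"])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format CSV layout: prime_id, time_s, variable, value."""
        t = np.arange(self.n_samples) / self.sample_rate
        rows = []
        for v in VARIABLES:
            rows.append(
                pd.DataFrame(
                    {
                        "prime_id": self.prime_id,
                        "time_s": t,
                        "variable": v,
                        "value": self.channels[v],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class MovementBounds:
    onset_index: int
    offset_index: int
    threshold: float = VELOCITY_THRESHOLD_MM_S


@dataclass
class TrialFeatureVector:
    prime_id: str
    values: np.ndarray
    labels: list[tuple[str, int]] = field(default_factory=feature_labels)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise SchemaError(
                f"expected {len(self.labels)} features, got {self.values.shape}"
            )


@dataclass
class FeatureMatrix:
    """Trials-by-features matrix with optional standardization reference."""

    values: np.ndarray
    prime_ids: list[str]
    labels: list[tuple[str, int]]
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    zscored: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise SchemaError("feature matrix shape does not match labels")
        if len(self.prime_ids) != self.values.shape[0]:
            raise SchemaError("one prime_id per row required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def row(self, prime_id: str) -> np.ndarray:
        return self.values[self.prime_ids.index(prime_id)]

    def to_csv(self, path: str | Path) -> None:
        cols = [f"{v}@{e}" for v, e in self.labels]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "prime_id", self.prime_ids)
        df.to_csv(path, index=False)
        sidecar = {
            "labels": [[v, e] for v, e in self.labels],
            "zscored": self.zscored,
            "mean": None if self.mean_ is None else self.mean_.tolist(),
            "sd": None if self.sd_ is None else self.sd_.tolist(),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        labels = [(v, int(e)) for v, e in meta["labels"]]
        return cls(
            values=df[[f"{v}@{e}" for v, e in labels]].to_numpy(),
            prime_ids=df["prime_id"].astype(str).tolist(),
            labels=labels,
            mean_=None if meta["mean"] is None else np.asarray(meta["mean"]),
            sd_=None if meta["sd"] is None else np.asarray(meta["sd"]),
            zscored=bool(meta["zscored"]),
        )


def detect_movement_bounds(
    velocity: np.ndarray, threshold: float = VELOCITY_THRESHOLD_MM_S
) -> MovementBounds:
    """Movement onset/offset from a velocity threshold.

    Onset is the first sample with velocity above ``threshold``; offset is
    the first sample after onset with velocity below it.
    """
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise SchemaError("velocity must be finite and non-negative")
    above = np.nonzero(v > threshold)[0]
    if above.size == 0:
        raise MovementDetectionError("no movement detected")
    onset = int(above[0])
    below = np.nonzero(v[onset:] < threshold)[0]
    if below.size == 0:
        raise MovementDetectionError("no offset detected")
    offset = int(onset + below[0])
    return MovementBounds(onset_index=onset, offset_index=offset, threshold=threshold)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise SchemaError(f"degenerate geometry: undefined {what}")
    return v / n


REQUIRED_MARKERS = ("wrist", "thumb_tip", "index_tip", "radius", "phalanx")


def compute_kinematic_variables(
    markers: dict[str, np.ndarray], sample_rate: float, prime_id: str = "trial"
) -> KinematicTrajectory:
    """Derive the 16 channels from 3-D marker trajectories.

    Hand-local frame convention (the source description leaves it open):
    origin at the wrist marker; x-axis along radius->phalanx; z-axis is
    the unit normal of the wrist/radius/phalanx (dorsum) plane; y = z x x.
    """
    missing = set(REQUIRED_MARKERS) - set(markers)
    if missing:
        raise SchemaError(f"missing markers: {sorted(missing)}")
    m = {k: np.asarray(v, dtype=float) for k, v in markers.items()}
    wrist, thumb, index = m["wrist"], m["thumb_tip"], m["index_tip"]
    radius, phalanx = m["radius"], m["phalanx"]

    vel = np.gradient(wrist, axis=0) * sample_rate
    w_v = np.linalg.norm(vel, axis=1)
    w_h = wrist[:, 2]
    w_ht = wrist[:, 0]
    g_a = np.linalg.norm(thumb - index, axis=1)

    # hand-local frame
    xax = _unit(phalanx - radius, "hand x-axis")
    dorsum_normal = _unit(
        np.cross(radius - wrist, phalanx - wrist), "dorsum-plane normal"
    )
    yax = _unit(np.cross(dorsum_normal, xax), "hand y-axis")
    zax = np.cross(xax, yax)
    rot = np.stack([xax, yax, zax], axis=-1)  # (T, 3, 3), columns = axes

    def to_local(p):
        return np.einsum("tij,ti->tj", rot, p - wrist)

    thumb_l = to_local(thumb)
    index_l = to_local(index)
    finger_normal_g = _unit(np.cross(thumb - wrist, index - wrist), "finger-plane normal")
    finger_l = np.einsum("tij,ti->tj", rot, finger_normal_g)
    dorsum_l = np.einsum("tij,ti->tj", rot, dorsum_normal)

    channels = {
        "W_V": w_v, "W_H": w_h, "W_HT": w_ht, "G_A": g_a,
        "T_X": thumb_l[:, 0], "T_Y": thumb_l[:, 1], "T_Z": thumb_l[:, 2],
        "I_X": index_l[:, 0], "I_Y": index_l[:, 1], "I_Z": index_l[:, 2],
        "FP_X": finger_l[:, 0], "FP_Y": finger_l[:, 1], "FP_Z": finger_l[:, 2],
        "DP_X": dorsum_l[:, 0], "DP_Y": dorsum_l[:, 1], "DP_Z": dorsum_l[:, 2],
    }
    return KinematicTrajectory(prime_id=prime_id, sample_rate=sample_rate, channels=channels)


def epoch_average(
    trajectory: KinematicTrajectory,
    bounds: MovementBounds,
    n_epochs: int = DEFAULT_N_EPOCHS,
) -> TrialFeatureVector:
    """Average each channel over equal epochs of normalized movement time.

    The onset..offset segment is linearly resampled at ``N_RESAMPLE``
    evenly spaced points of normalized time; epoch ``k`` averages the
    half-open interval [(k-1)/n, k/n), the last epoch closed at 1.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    on, off = bounds.onset_index, bounds.offset_index
    if not (0 <= on < off < trajectory.n_samples):
        raise ValueError("bounds do not fit the trajectory")
    if off - on + 1 < 2:
        raise ValueError("movement segment too short")
    t_norm = np.linspace(0.0, 1.0, N_RESAMPLE)
    src = np.linspace(0.0, 1.0, off - on + 1)
    if N_RESAMPLE < n_epochs:
        raise ValueError("more epochs than resampled points")
    edges = np.minimum((t_norm * n_epochs).astype(int), n_epochs - 1)
    values = np.empty(N_VARIABLES * n_epochs)
    for iv, v in enumerate(VARIABLES):
        seg = trajectory.channels[v][on : off + 1]
        res = np.interp(t_norm, src, seg)
        for e in range(n_epochs):
            values[iv * n_epochs + e] = res[edges == e].mean()
    return TrialFeatureVector(
        prime_id=trajectory.prime_id, values=values, labels=feature_labels(n_epochs)
    )


def build_feature_matrix(
    trajectories: list[KinematicTrajectory],
    n_epochs: int = DEFAULT_N_EPOCHS,
    threshold: float = VELOCITY_THRESHOLD_MM_S,
) -> FeatureMatrix:
    """Movement bounds + epoch averaging for a set of trajectories."""
    vecs = []
    for traj in trajectories:
        bounds = detect_movement_bounds(traj.channels["W_V"], threshold)
        vecs.append(epoch_average(traj, bounds, n_epochs))
    return FeatureMatrix(
        values=np.stack([v.values for v in vecs]),
        prime_ids=[v.prime_id for v in vecs],
        labels=feature_labels(n_epochs),
    )


def zscore_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize columns with the sample SD (ddof=1), storing parameters.

    Held-out trials are transformed with :func:`transform_features` using
    the parameters stored here.
    """
    if matrix.n_trials < 2:
        raise ValueError("z-scoring needs at least 2 trials")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    bad = np.nonzero(sd < 1e-12)[0]
    if bad.size:
        names = [f"{matrix.labels[i][0]}@{matrix.labels[i][1]}" for i in bad]
        raise ValueError(f"zero-variance feature(s): {names}")
    return replace(
        matrix,
        values=(matrix.values - mean) / sd,
        mean_=mean,
        sd_=sd,
        zscored=True,
        prime_ids=list(matrix.prime_ids),
    )


def transform_features(matrix: FeatureMatrix, reference: FeatureMatrix) -> FeatureMatrix:
    """Apply a training set's standardization to held-out trials."""
    if reference.mean_ is None or reference.sd_ is None:
        raise ValueError("reference matrix carries no standardization parameters")
    if reference.labels != matrix.labels:
        raise SchemaError("feature label mismatch")
    return replace(
        matrix,
        values=(matrix.values - reference.mean_) / reference.sd_,
        mean_=reference.mean_.copy(),
        sd_=reference.sd_.copy(),
        zscored=True,
        prime_ids=list(matrix.prime_ids),
    )
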