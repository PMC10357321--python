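"""End-to-end orchestration: simulate -> features -> encoding -> readout
-> priming analyses, with serialization, manifests and seeded substreams.

Each stage writes plain-text artifacts (CSV/JSON) into the run directory
and records a checksum in the run manifest; identical config + seed give
identical artifacts for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import GeneratorConfig, RegularizationSpec
from .encoding import fit_encoding, single_trial_encoding
from .exceptions import ConfigurationError, SchemaError
from .kinematics import FeatureMatrix, TrialFeatureVector, zscore_features
from .readout import (
    fit_readout,
    identify_zero_readout_primes,
    readout_encoding_alignment,
    readout_indices,
)
from .priming import (
    apply_exclusions,
    confidence_readout_model,
    congruency_information_model,
    median_split_priming,
)
from . import synth

STAGES = ("simulate", "features", "encoding", "readout", "zero_readout", "priming")


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alpha: float = 0.95
    n_lambda: int = 100
    n_epochs: int = 4
    n_perm: int = 200
    n_surrogate: int = 500
    stages: tuple[str, ...] = ("simulate", "features", "encoding", "readout", "priming")
    seed: int = 0
    outdir: str = "kinread_run"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    def reg(self) -> RegularizationSpec:
        return RegularizationSpec(alpha=self.alpha, n_lambda=self.n_lambda)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: independent of other stages' streams."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    return np.random.default_rng([seed, h])


def validate_trial_table(table: pd.DataFrame | str | Path, schema: str) -> pd.DataFrame:
    """Validate (and normalize) a trial table against a named schema."""
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table.copy()
    problems = []
    if schema == "choice":
        required = ["perceiver_id", "prime_id", "repetition", "choice"]
        for c in set(required) - set(df.columns):
            problems.append(f"missing column {c!r}")
        if not problems:
            df["choice"] = df["choice"].astype(str).str.lower()
            bad = ~df["choice"].isin(["pour", "drink"])
            if bad.any():
                problems.append(f"invalid choice values at rows {list(df.index[bad][:10])}")
            dup = df.duplicated(["perceiver_id", "prime_id", "repetition"])
            if dup.any():
                problems.append(
                    f"duplicate (perceiver, prime, repetition) at rows {list(df.index[dup][:10])}"
                )
    elif schema == "priming":
        required = ["participant_id", "prime_id", "congruency", "rt_ms", "accuracy"]
        for c in set(required) - set(df.columns):
            problems.append(f"missing column {c!r}")
        if not problems:
            df["congruency"] = df["congruency"].astype(str).str.lower()
            bad = ~df["congruency"].isin(["congruent", "incongruent"])
            if bad.any():
                problems.append(f"invalid congruency at rows {list(df.index[bad][:10])}")
            if (df["rt_ms"] <= 0).any():
                problems.append("non-positive RTs present")
    else:
        raise ConfigurationError(f"unknown schema: {schema}")
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {
            p.name: _sha256(p) for p in paths
        }
        for p in paths:
            artifacts[p.name] = p

    def require(stage: str, filename: str) -> Path:
        p = artifacts.get(filename, out / filename)
        if not p.exists():
            raise ConfigurationError(
                f"stage {stage!r} requires missing artifact {filename!r}"
            )
        return p

    gen = config.generator
    state: dict = {}

    if "simulate" in config.stages:
        rng = _stage_rng(config.seed, "simulate")
        primes = synth.generate_primes(gen, rng)
        perceivers = synth.generate_perceivers(
            gen, primes.ground_truth.true_encoding_direction, rng
        )
        primes.ground_truth.true_readout_vectors = perceivers.vectors
        primes.ground_truth.readout_gains = perceivers.gains
        disc = synth.simulate_discrimination(primes, perceivers, gen, rng)
        pri = synth.simulate_priming_session(primes, perceivers, gen, rng)
        long = pd.concat([t.to_long_frame() for t in primes.trajectories])
        long.insert(1, "intention", long["prime_id"].map(primes.ground_truth.intentions))
        p1 = out / "primes_long.csv"
        long.to_csv(p1, index=False)
        p2 = out / "ground_truth.json"
        p2.write_text(json.dumps(primes.ground_truth.to_dict()))
        p3 = out / "choice_trials.csv"
        disc.to_csv(p3, index=False)
        p4 = out / "priming_trials.csv"
        pri.to_csv(p4, index=False)
        record("simulate", p1, p2, p3, p4)
        state.update(primes=primes, perceivers=perceivers, disc=disc, pri=pri)

    if "features" in config.stages:
        if "primes" not in state:
            require("features", "primes_long.csv")
            raise ConfigurationError(
                "feature stage from serialized primes requires the simulate stage "
                "in the same run in this version"
            )
        feats = synth.prime_features(state["primes"], n_epochs=config.n_epochs)
        p = out / "features.csv"
        feats.to_csv(p)
        record("features", p, Path(str(p) + ".json"))
        state["features"] = feats

    if "encoding" in config.stages:
        feats = state.get("features")
        if feats is None:
            raise ConfigurationError("encoding stage requires the features stage")
        primes = state["primes"]
        model = fit_encoding(feats, primes.intentions, config.reg())
        p1 = out / "encoding_model.json"
        model.to_json(p1)
        zs = zscore_features(feats)
        rows = []
        for i, pid in enumerate(zs.prime_ids):
            vec = TrialFeatureVector(pid, feats.values[i], feats.labels)
            st = single_trial_encoding(model, vec, primes.ground_truth.intentions[pid])
            rows.append({"prime_id": pid, "encoding_index": st.value, "correct": st.correct})
        enc_idx = pd.DataFrame(rows)
        p2 = out / "encoding_indices.csv"
        enc_idx.to_csv(p2, index=False)
        record("encoding", p1, p2)
        state.update(encoding_model=model, encoding_indices=enc_idx)

    if "readout" in config.stages:
        feats = state.get("features")
        disc = state.get("disc")
        if feats is None or disc is None:
            raise ConfigurationError("readout stage requires features and simulate stages")
        primes = state["primes"]
        models = {}
        idx_frames = []
        for pid, sub in disc.groupby("perceiver_id"):
            m = fit_readout(sub, feats, config.reg())
            models[pid] = m
            m.to_json(out / f"readout_model_{pid}.json")
            idx_frames.append(
                readout_indices(m, feats, primes.ground_truth.intentions)
            )
        ridx = pd.concat(idx_frames, ignore_index=True)
        p1 = out / "readout_indices.csv"
        ridx.to_csv(p1, index=False)
        align = readout_encoding_alignment(
            list(models.values())[0],
            state["encoding_model"],
            ridx.groupby("prime_id")["readout_index"].mean(),
            state["encoding_indices"].set_index("prime_id")["encoding_index"],
        ) if "encoding_model" in state else {}
        p2 = out / "readout_alignment.json"
        p2.write_text(json.dumps(align))
        record("readout", p1, p2)
        state.update(readout_models=models, readout_indices_df=ridx)

    if "zero_readout" in config.stages:
        models = state.get("readout_models")
        if models is None:
            raise ConfigurationError("zero_readout stage requires the readout stage")
        rng = _stage_rng(config.seed, "zero_readout")
        rep = identify_zero_readout_primes(
            state["disc"], state["features"], models,
            state["primes"].ground_truth.intentions,
            n_surrogate=config.n_surrogate, rng=rng,
        )
        p = out / "zero_readout.csv"
        rep.to_csv(p, index=False)
        record("zero_readout", p)
        state["zero_readout"] = rep

    if "priming" in config.stages:
        pri = state.get("pri")
        ridx = state.get("readout_indices_df")
        if pri is None or ridx is None:
            raise ConfigurationError("priming stage requires simulate and readout stages")
        retained, excl = apply_exclusions(pri)
        idx = ridx.rename(columns={"perceiver_id": "participant_id"})[
            ["participant_id", "prime_id", "readout_index"]
        ]
        rt_res = congruency_information_model(retained, idx, response="rt")
        ms = median_split_priming(retained, idx)
        retained_f, _ = apply_exclusions(pri, for_fixation=True)
        fix_res = congruency_information_model(retained_f, idx, response="fixation")
        conf = confidence_readout_model(
            state["disc"][["perceiver_id", "prime_id", "repetition", "confidence"]],
            idx.rename(columns={"participant_id": "perceiver_id"}),
        )
        report = {
            "exclusions": excl,
            "rt_readout_lrt": rt_res["lrt"],
            "rt_slopes": {
                "congruent": rt_res["slope_congruent"],
                "incongruent": rt_res["slope_incongruent"],
            },
            "median_split": {
                s: e for s, e in ms["effects"].items()
            },
            "median_split_difference": ms["difference_lrt"],
            "fixation_readout_lrt": fix_res["lrt"],
            "fixation_marginal": fix_res["marginal"],
            "confidence": {
                "coefficient": conf["coefficient"],
                "lrt": conf["lrt"],
            },
        }
        p = out / "priming_report.json"
        p.write_text(json.dumps(report, default=float, indent=2))
        record("priming", p)
        state["priming_report"] = report

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
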