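# kinread

Single-trial kinematic encoding/readout modelling and kinematic-priming
analyses for reach-to-grasp movements, with a fully synthetic data
generator for parameter recovery.

The package implements a complete pipeline:

1. **Synthetic data** (`kinread.synth`) — reach-to-pour / reach-to-drink
   kinematic primes (16 channels, raised-cosine wrist-velocity bell,
   smooth Gaussian-process variability, intention effects injected as
   late-growing offsets in configurable variables), simulated perceivers
   with heterogeneous readout vectors, forced-choice sessions (choice,
   confidence, RT) and primed-categorization sessions (RTs, first
   fixations, pupil baselines) with known ground truth.
2. **Feature extraction** (`kinread.kinematics`) — movement bounds from a
   20 mm/s wrist-velocity threshold, epoch averaging over normalized
   movement time (16 variables x 4 epochs = 64 features), train-referenced
   z-scoring.
3. **Encoding model** (`kinread.encoding`) — elastic-net logistic
   regression (alpha = 0.95) of intention on features, penalty chosen by
   leave-one-video-out cross-validated deviance; single-trial sign-adjusted
   log-odds indices, per-variable contributions, permutation tests for
   coefficients, nested CV, alpha-robustness checks.
4. **Readout models** (`kinread.readout`) — per-perceiver elastic-net
   logistic models of intention choice, permuted-choice performance nulls,
   readout/encoding alignment, pooled (surrogate-participant) models, and
   zero-readout prime detection by a behavioral + surrogate double
   criterion.
5. **Priming statistics** (`kinread.priming`, `kinread.mixed`) — trial
   exclusions, first-fixation quadrant classification, gamma-identity /
   binomial-logit / cumulative-logit mixed-effects models (in-house
   Laplace-approximation ML with crossed random effects), LRTs, BIC-based
   random-effects selection, marginal-effect Wald tests, median-split and
   zero-vs-high priming contrasts, pupil-baseline preprocessing and control
   models, Holm correction, correlation tests.
6. **Pipeline & CLI** (`kinread.pipeline`, `kinread.cli`) — seeded,
   manifest-tracked end-to-end runs writing plain-text artifacts.

The elastic-net logistic solver (`kinread.glmnet`) is a numba-jitted
coordinate-descent implementation (warm-started penalty paths, grouped CV)
validated against scikit-learn; it is what makes the permutation and
surrogate analyses tractable.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (index
identities, contribution partition, encoding/readout parameter recovery,
zero-readout detection, priming-model power and null calibration,
mixed-model recovery, deterministic utilities).

## CLI

```sh
kinread simulate         --seed 1 --out run1        # synthetic sessions
kinread fit-encoding     --seed 1 --out run1
kinread fit-readout      --seed 1 --out run1
kinread zero-readout     --seed 1 --out run1        # surrogate nulls (slow)
kinread analyze-priming  --seed 1 --out run1        # full pipeline
kinread report           --out run1                 # plain-text summary
```

All commands accept `--config <yaml>` (see `kinread.pipeline.RunConfig`),
`--n-epochs`, `--alpha`, `--n-perm`, `--log-level`. Artifacts are CSV/JSON
(long-format prime trajectories, feature matrices with JSON sidecars,
model weights, trial tables, analysis report) plus a `manifest.json` with
per-artifact checksums; identical config + seed reproduce identical
artifacts.

## Library example

```python
from kinread.config import GeneratorConfig, RegularizationSpec
from kinread import synth
from kinread.encoding import fit_encoding
from kinread.readout import fit_readout

cfg = GeneratorConfig(seed=1)
primes = synth.generate_primes(cfg)
perceivers = synth.generate_perceivers(
    cfg, primes.ground_truth.true_encoding_direction
)
features = synth.prime_features(primes)
choices = synth.simulate_discrimination(primes, perceivers, cfg)

encoding = fit_encoding(features, primes.intentions)
readout = fit_readout(
    choices[choices.perceiver_id == "P01"], features
)
print(encoding.performance, readout.performance)
```
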