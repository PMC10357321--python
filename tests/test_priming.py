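import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

from kinread.config import GeneratorConfig
from kinread.exceptions import FittingError
from kinread import priming, synth
from kinread.priming import (
    apply_exclusions,
    classify_first_fixation,
    confidence_readout_model,
    congruency_information_model,
    correlation_test,
    holm_bonferroni,
    median_split_priming,
    pupil_baseline,
    pupil_control_model,
    zero_vs_high_readout_contrast,
    zscore_within_participant,
)


def _trials(rng, n_participants=4, n=80, rt_mean=600.0, rt_sd=40.0):
    rows = []
    for p in range(n_participants):
        for i in range(n):
            rows.append(
                {
                    "participant_id": f"p{p}",
                    "prime_id": f"v{i % 20}",
                    "congruency": "congruent" if i % 4 else "incongruent",
                    "probe": "pouring" if i % 2 else "drinking",
                    "rt_ms": float(rng.normal(rt_mean, rt_sd)),
                    "accuracy": 1,
                    "first_fixation_class": "other",
                    "baseline_pupil": float(rng.normal()),
                }
            )
    return pd.DataFrame(rows)


class TestExclusions:
    def test_clean_dataset_no_exclusions(self, rng):
        df = _trials(rng)
        retained, rep = apply_exclusions(df)
        assert rep["n_removed_incorrect"] == 0
        assert rep["n_removed_rt"] == 0
        assert len(retained) == len(df)

    def test_single_outlier_removed(self, rng):
        df = _trials(rng, n_participants=1, n=200)
        mean, sd = df["rt_ms"].mean(), df["rt_ms"].std(ddof=1)
        df.loc[0, "rt_ms"] = mean + 3.5 * sd
        retained, rep = apply_exclusions(df)
        assert rep["n_removed_rt"] >= 1
        assert df.loc[0, "rt_ms"] not in retained["rt_ms"].values

    def test_brute_force_rule_order_oracle(self, rng):
        df = _trials(rng, n_participants=3, n=150)
        df["accuracy"] = (rng.random(len(df)) > 0.1).astype(int)
        df.loc[rng.random(len(df)) < 0.05, "rt_ms"] = rng.normal(900, 50)
        df.loc[rng.random(len(df)) < 0.1, "first_fixation_class"] = "none"
        retained, _ = apply_exclusions(df, for_fixation=True)

        # independent reimplementation, rules in order
        step1 = df[df["accuracy"] == 1]
        keep = []
        for _, row in step1.iterrows():
            sub = step1[step1["participant_id"] == row["participant_id"]]
            thr = sub["rt_ms"].mean() + 2.5 * sub["rt_ms"].std(ddof=1)
            keep.append(row["rt_ms"] <= thr)
        step2 = step1[np.array(keep)]
        step3 = step2[step2["first_fixation_class"] != "none"]
        assert len(retained) == len(step3)
        assert np.allclose(
            sorted(retained["rt_ms"]), sorted(step3["rt_ms"])
        )

    def test_idempotent(self, rng):
        df = _trials(rng, n_participants=3, n=150)
        df["accuracy"] = (rng.random(len(df)) > 0.1).astype(int)
        r1, _ = apply_exclusions(df)
        r2, _ = apply_exclusions(r1)
        assert len(r1) == len(r2)

    def test_tiny_participant_flagged(self, rng):
        df = _trials(rng, n_participants=2, n=50)
        df.loc[df["participant_id"] == "p1", "accuracy"] = 0
        df.loc[df[df.participant_id == "p1"].index[0], "accuracy"] = 1
        _, rep = apply_exclusions(df)
        assert "p1" in rep["flagged_participants"]


class TestFixationClassification:
    SIZE = (1280.0, 800.0)

    def test_pouring_bottom_left_displayed(self):
        assert classify_first_fixation((100, 700), "pouring", self.SIZE) == "relevant-displayed"

    def test_pouring_top_right_nondisplayed(self):
        assert classify_first_fixation((1200, 100), "pouring", self.SIZE) == "relevant-nondisplayed"

    def test_drinking_top_right_displayed(self):
        assert classify_first_fixation((1200, 100), "drinking", self.SIZE) == "relevant-displayed"

    def test_centre_belongs_top_right(self):
        centre = (640.0, 400.0)
        assert classify_first_fixation(centre, "drinking", self.SIZE) == "relevant-displayed"
        assert classify_first_fixation(centre, "pouring", self.SIZE) == "relevant-nondisplayed"

    def test_other_quadrants(self):
        assert classify_first_fixation((100, 100), "pouring", self.SIZE) == "other"
        assert classify_first_fixation((1200, 700), "pouring", self.SIZE) == "other"

    def test_outside_image(self):
        assert classify_first_fixation((-5, 100), "pouring", self.SIZE) == "none"


class TestHolm:
    def test_m2_stepdown(self):
        assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single(self):
        assert holm_bonferroni([0.2]) == [0.2]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    def test_brute_force_oracle(self, rng):
        def oracle(ps):
            m = len(ps)
            order = np.argsort(ps, kind="stable")
            adj = np.zeros(m)
            prev = 0.0
            for rank, i in enumerate(order):
                val = min(1.0, (m - rank) * ps[i])
                prev = max(prev, val)
                adj[i] = prev
            return adj

        for _ in range(200):
            ps = rng.random(rng.integers(1, 10))
            assert np.allclose(holm_bonferroni(ps), oracle(ps))


class TestCorrelation:
    def test_pearson_linear(self):
        x = np.arange(10.0)
        out = correlation_test(x, 2 * x + 1, "pearson")
        assert out["r"] == pytest.approx(1.0)

    def test_spearman_monotone(self):
        x = np.linspace(0, 5, 20)
        out = correlation_test(x, np.exp(x), "spearman")
        assert out["r"] == pytest.approx(1.0)

    def test_null_band(self):
        inside = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            out = correlation_test(r.normal(size=1000), r.normal(size=1000))
            inside += abs(out["r"]) < 0.08
        assert inside >= 38

    def test_constant_error(self):
        with pytest.raises(ValueError):
            correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_matches_t_approximation(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        out = correlation_test(x, y, "spearman")
        rho = stats.spearmanr(x, y).statistic
        t = rho * np.sqrt(48 / (1 - rho**2))
        assert out["p"] == pytest.approx(2 * stats.t.sf(abs(t), 48))


class TestPupil:
    def test_constant_trace_dc_gain(self):
        tr = np.full(3000, 4.0)
        assert pupil_baseline(tr, 1000.0, 3000) == pytest.approx(4.0, abs=1e-9)

    def test_blink_gap_linear_interpolation(self):
        tr = np.linspace(2.0, 6.0, 2000)
        with_gap = tr.copy()
        with_gap[300:400] = np.nan
        # the gap lies on a straight line, so interpolation restores it and
        # the baseline matches the gap-free trace
        b1 = pupil_baseline(with_gap, 1000.0, 2000)
        b2 = pupil_baseline(tr, 1000.0, 2000)
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_first_order_attenuation(self, rng):
        fs, f0 = 1000.0, 25.0
        t = np.arange(8000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        b, a = signal.butter(1, 10.0, fs=fs)
        y = signal.lfilter(b, a, x)
        gain = y[4000:].std() / x[4000:].std()
        expected = 1 / np.sqrt(1 + (f0 / 10.0) ** 2)
        assert abs(gain - expected) / expected < 0.10
        # and the pipeline filter reduces white-noise variance
        noise = rng.normal(size=4000)
        filtered_mean = pupil_baseline(noise, fs, 4000, window_s=2.0)
        assert filtered_mean is not None

    def test_fully_missing_window_flagged(self):
        tr = np.full(1500, np.nan)
        assert pupil_baseline(tr, 1000.0, 1500) is None

    def test_zscore_constant_participant(self):
        df = pd.DataFrame(
            {"participant_id": ["a"] * 3 + ["b"] * 3,
             "baseline_pupil": [1.0, 1.0, 1.0, 1.0, 2.0, 3.0]}
        )
        out = zscore_within_participant(df)
        assert np.allclose(out.loc[out.participant_id == "a", "baseline_pupil_z"], 0.0)


@pytest.fixture(scope="module")
def session():
    cfg = GeneratorConfig(seed=13, n_perceivers=6, n_priming_trials=120)
    primes = synth.generate_primes(cfg)
    per = synth.generate_perceivers(cfg, primes.ground_truth.true_encoding_direction)
    trials = synth.simulate_priming_session(primes, per, cfg)
    index = synth.true_predictors(primes, per)[["perceiver_id", "prime_id", "true_readout"]]
    disc = synth.simulate_discrimination(primes, per, cfg)
    return {"cfg": cfg, "primes": primes, "per": per, "trials": trials,
            "index": index, "disc": disc}


class TestCongruencyInformationModel:
    def test_rt_interaction_and_sign_pattern(self, session):
        retained, _ = apply_exclusions(session["trials"])
        res = congruency_information_model(retained, session["index"], response="rt")
        assert res["lrt"]["p"] < 0.05
        assert res["slope_congruent"] < res["slope_incongruent"]

    def test_fixation_marginal_effects(self, session):
        retained, _ = apply_exclusions(session["trials"], for_fixation=True)
        res = congruency_information_model(retained, session["index"], response="fixation")
        assert "marginal" in res
        m = res["marginal"]
        # stronger congruency advantage at high readout
        assert m["effect_high"] > m["effect_low"]

    def test_missing_index_error(self, session):
        retained, _ = apply_exclusions(session["trials"])
        idx = session["index"].iloc[:10]
        with pytest.raises(Exception, match="index missing"):
            congruency_information_model(retained, idx, response="rt")


class TestMedianSplit:
    def test_high_exceeds_low(self, session):
        retained, _ = apply_exclusions(session["trials"])
        out = median_split_priming(retained, session["index"])
        assert out["effects"]["high"]["effect"] > out["effects"]["low"]["effect"]

    def test_stratum_sizes_balanced(self, session):
        retained, _ = apply_exclusions(session["trials"])
        df = priming._join_index(retained, session["index"])
        med = df["index"].median()
        high = (df["index"] > med).sum()
        low = (df["index"] <= med).sum()
        ties = (df["index"] == med).sum()
        assert abs(high - low) <= ties + 1

    def test_constant_index_error(self, session):
        retained, _ = apply_exclusions(session["trials"])
        idx = session["index"].copy()
        idx["true_readout"] = 1.0
        with pytest.raises(FittingError):
            median_split_priming(retained, idx)


class TestZeroVsHigh:
    def test_empty_stratum_error(self, session):
        retained, _ = apply_exclusions(session["trials"])
        with pytest.raises(FittingError):
            zero_vs_high_readout_contrast(retained, [], ["pour_01"])

    def test_contrast_runs(self, session):
        retained, _ = apply_exclusions(session["trials"])
        primes = session["primes"].prime_ids
        out = zero_vs_high_readout_contrast(retained, primes[:10], primes[30:40])
        assert set(out["effects"]) == {"zero", "high"}


class TestConfidenceModel:
    def test_positive_coefficient(self, session):
        cm = confidence_readout_model(
            session["disc"][["perceiver_id", "prime_id", "repetition", "confidence"]],
            session["index"],
        )
        assert cm["coefficient"] > 0
        assert cm["lrt"]["p"] < 0.05

    def test_top_category_monotone(self, session):
        cm = confidence_readout_model(
            session["disc"][["perceiver_id", "prime_id", "repetition", "confidence"]],
            session["index"],
        )
        top = cm["category_probs"][-1]
        assert np.all(np.diff(top) >= -1e-12)


class TestPupilControl:
    def test_all_zero_pupil_reduces_to_base(self, session):
        retained, _ = apply_exclusions(session["trials"])
        retained = retained.copy()
        retained["baseline_pupil"] = 0.0
        out = pupil_control_model(retained, session["index"])
        assert abs(out["interaction_with_pupil"] - out["interaction_base"]) < 1e-3

    def test_independent_pupil_small_shift(self, session):
        retained, _ = apply_exclusions(session["trials"])
        out = pupil_control_model(retained, session["index"])
        assert out["shift_in_se"] < 1.0
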