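"""Generator tests: determinism, configured-median recovery, round-trips."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fingercue.conditions import CONDITIONS
from fingercue.synthetic_data import (
    GeneratorConfig,
    default_condition_effects,
    generate_experiment,
    read_trials,
    validate_trials,
    write_trials,
)
from fingercue.trial_qc import apply_qc


def zero_noise_config(**kw):
    effects = {k: 0.0 for k in default_condition_effects()}
    base = dict(
        condition_effect=effects,
        subject_baseline_sd=0.0,
        trial_noise_sd=0.0,
        sense_dy_jitter=0.0,
        dz_jitter=0.0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerateExperiment:
    def test_shape_and_keys(self, default_config):
        table = generate_experiment(default_config, 3, seed=1)
        assert len(table) == 10 * 6 * 6
        keys = table[["subject_id", "experiment", "condition", "repetition"]]
        assert not keys.duplicated().any()
        assert set(table["condition"]) == set(CONDITIONS)

    def test_degenerate_config_gives_zero_errors(self):
        table = generate_experiment(zero_noise_config(), 1)
        assert np.allclose(table["hold_dy"] - table["sense_dy"], 0.0)

    def test_deterministic_given_config_and_seed(self, default_config):
        a = generate_experiment(default_config, 2, seed=42)
        b = generate_experiment(default_config, 2, seed=42)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        write_trials(a, buf_a)
        write_trials(b, buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_null_and_fn_only_force_invariants(self, exp1_trials):
        null = exp1_trials[exp1_trials["condition"] == "NULL"]
        assert (null[["thumb_fn", "index_fn", "thumb_ft", "index_ft"]] == 0).all().all()
        fn = exp1_trials[exp1_trials["condition"] == "FN_ONLY"]
        assert (fn[["thumb_ft", "index_ft"]] == 0).all().all()
        assert (fn[["thumb_fn", "index_fn"]] > 0).all().all()

    def test_compliant_when_noncompliance_rate_zero(self, exp1_trials):
        flagged = apply_qc(exp1_trials)
        assert flagged["qc_pass"].all()

    def test_noncompliance_rate_produces_violations(self, default_config):
        cfg = GeneratorConfig(noncompliance_rate=0.3)
        flagged = apply_qc(generate_experiment(cfg, 1, seed=3))
        frac_fail = 1.0 - flagged["qc_pass"].mean()
        assert 0.15 < frac_fail < 0.45

    def test_median_recovery_at_large_n(self):
        """Pooled over 200 subjects the error median hits the configured 9.2 mm."""
        cfg = GeneratorConfig(n_subjects=200)
        table = generate_experiment(cfg, 1, seed=11)
        cell = table[table["condition"] == "TUP_IDN"]
        med = np.median(cell["hold_dy"] - cell["sense_dy"])
        assert abs(med - 9.2) < 0.5

    def test_effect_shift_moves_median_by_delta(self):
        """Raising one condition effect by delta shifts the error median by delta."""
        effects = default_condition_effects()
        shifted = dict(effects)
        shifted[(1, "TUP_IDN")] = effects[(1, "TUP_IDN")] + 4.0
        meds = []
        for eff in (effects, shifted):
            cfg = GeneratorConfig(n_subjects=400, condition_effect=eff)
            table = generate_experiment(cfg, 1, seed=5)
            cell = table[table["condition"] == "TUP_IDN"]
            meds.append(np.median(cell["hold_dy"] - cell["sense_dy"]))
        assert meds[1] - meds[0] == pytest.approx(4.0, abs=0.3)

    def test_symmetric_noise_has_vanishing_skew(self):
        cfg = GeneratorConfig(n_subjects=300, subject_baseline_sd=0.0)
        table = generate_experiment(cfg, 2, seed=9)
        cell = table[table["condition"] == "NULL"]
        errors = (cell["hold_dy"] - cell["sense_dy"]).to_numpy()
        assert abs(stats.skew(errors)) < 0.15

    @pytest.mark.parametrize("family,sign", [("right-skewed", 1), ("left-skewed", -1)])
    def test_skewed_families_keep_median_zero(self, family, sign):
        cfg = GeneratorConfig(
            n_subjects=300, subject_baseline_sd=0.0, noise_family=family
        )
        table = generate_experiment(cfg, 2, seed=9)
        cell = table[table["condition"] == "NULL"]
        errors = (cell["hold_dy"] - cell["sense_dy"]).to_numpy()
        assert abs(np.median(errors)) < 0.25
        assert np.sign(stats.skew(errors)) == sign

    def test_unknown_experiment_rejected(self, default_config):
        with pytest.raises(ValueError, match="experiment"):
            generate_experiment(default_config, 4)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_subjects": 0},
            {"noncompliance_rate": 1.5},
            {"subject_baseline_sd": -1.0},
            {"noise_family": "uniform"},
            {"reps_per_condition": {1: 0, 2: 5, 3: 6}},
        ],
    )
    def test_invalid_config_names_offending_field(self, bad):
        with pytest.raises(ValueError, match=next(iter(bad))):
            GeneratorConfig(**bad)


class TestCsvRoundTrip:
    def test_empty_table_round_trips(self, exp1_trials, tmp_path):
        empty = exp1_trials.iloc[0:0]
        path = tmp_path / "empty.csv"
        write_trials(empty, path)
        back = read_trials(path)
        assert len(back) == 0
        assert list(back.columns) == list(empty.columns)

    def test_full_table_round_trips_exactly(self, exp1_trials, tmp_path):
        path = tmp_path / "t.csv"
        flagged = apply_qc(exp1_trials)
        write_trials(flagged, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(back, flagged)

    def test_missing_column_rejected(self, exp1_trials, tmp_path):
        path = tmp_path / "t.csv"
        exp1_trials.drop(columns=["hold_dy"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="hold_dy"):
            read_trials(path)

    def test_duplicate_key_rejected(self, exp1_trials, tmp_path):
        path = tmp_path / "t.csv"
        dup = pd.concat([exp1_trials, exp1_trials.iloc[:1]], ignore_index=True)
        write_trials(dup, path)
        with pytest.raises(ValueError, match="duplicate"):
            read_trials(path)

    def test_non_numeric_rejected(self, exp1_trials, tmp_path):
        path = tmp_path / "t.csv"
        bad = exp1_trials.copy()
        bad["hold_dy"] = bad["hold_dy"].astype(object)
        bad.loc[0, "hold_dy"] = "oops"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_trials(path)

    def test_null_force_breach_read_but_flagged(self, exp1_trials, tmp_path):
        bad = exp1_trials.copy()
        idx = bad.index[bad["condition"] == "NULL"][0]
        bad.loc[idx, "thumb_fn"] = 4.5
        path = tmp_path / "t.csv"
        write_trials(bad, path)
        back = read_trials(path)  # must not raise
        breaches = validate_trials(back)
        assert any("NULL" in b for b in breaches)

    def test_config_yaml_round_trip(self, tmp_path, default_config):
        path = tmp_path / "cfg.yaml"
        default_config.to_yaml(path)
        again = GeneratorConfig.from_yaml(path)
        assert again == default_config
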