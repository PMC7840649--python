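"""Generator contracts: design structure, determinism, MAR, calibration."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from meanbands.design import GROUPS, GROUP_SIZES, ITEM_COUNTS
from meanbands.outcome_prep import item_columns, poms
from meanbands.trial_synth import (
    ConfigurationError,
    MissingnessParams,
    SimConfig,
    calibration_report,
    cronbach_alpha,
    default_outcome_params,
    generate_trial,
    latent_to_ordinal,
    load_config,
    save_config,
)

ALL_ITEM_COLS = [c for o, k in ITEM_COUNTS.items() for c in item_columns(o, k)]


class TestLatentToOrdinal:
    @pytest.mark.parametrize("latent, expected", [
        (-5.0, 1),   # below every threshold
        (5.0, 4),    # above every threshold
        (1.5, 3),    # thresholds (0, 1, 2): two crossed
        (0.5, 2),
    ])
    def test_counting(self, latent, expected):
        assert latent_to_ordinal(latent, (0.0, 1.0, 2.0)) == expected

    def test_non_ascending_thresholds_rejected(self):
        with pytest.raises(ValueError):
            latent_to_ordinal(0.0, (0.0, 0.0, 1.0))

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(-10, 10), t1=st.floats(-3, 3), gap=st.floats(0.1, 3))
    def test_matches_threshold_count(self, x, t1, gap):
        thr = (t1, t1 + gap, t1 + 2 * gap)
        assert latent_to_ordinal(x, thr) == 1 + sum(x > t for t in thr)


class TestGenerateTrial:
    def test_default_cell_counts_match_design(self):
        table = generate_trial(SimConfig(seed=5))
        counts = table[table.wave == 0].groupby(
            ["condition", "sex", "cohort"]).size()
        for (cond, sex, cohort), n in GROUP_SIZES.items():
            assert counts[(cond, sex, cohort)] == n
        assert counts[("DM", "F", 3)] == 444

    def test_schools_nested_in_condition(self, tiny_sim_config):
        table = generate_trial(tiny_sim_config)
        per_school = table.groupby("school_id")["condition"].nunique()
        assert (per_school == 1).all()

    def test_no_missingness_config_is_complete(self, complete_sim_config):
        table = generate_trial(complete_sim_config)
        assert not table[ALL_ITEM_COLS].isna().any().any()
        assert set(table[ALL_ITEM_COLS].stack().unique()) <= {1.0, 2.0, 3.0, 4.0}

    def test_deterministic_from_seed(self, tiny_sim_config):
        a = generate_trial(tiny_sim_config)
        b = generate_trial(tiny_sim_config)
        pd.testing.assert_frame_equal(a, b)
        c = generate_trial(replace(tiny_sim_config, seed=99))
        assert not a[ALL_ITEM_COLS].equals(c[ALL_ITEM_COLS])

    def test_masking_only_removes_values(self, tiny_sim_config):
        masked, complete = generate_trial(tiny_sim_config, keep_complete=True)
        obs = masked[ALL_ITEM_COLS].notna().to_numpy()
        mv = masked[ALL_ITEM_COLS].to_numpy()
        cv = complete[ALL_ITEM_COLS].to_numpy()
        assert np.array_equal(mv[obs], cv[obs])
        assert obs.mean() < 1.0  # something was actually masked

    def test_cell_means_converge_to_trajectories(self):
        # noiseless-measurement configuration: no school or item noise, one
        # cell of 10,000 students, no covariate effects
        params = replace(default_outcome_params("sv_victimization"),
                         school_icc=0.0, person_share=1.0, wave_share=0.0)
        sizes = {g: (10_000 if g == ("SC", "F", 3) else 1) for g in GROUPS}
        cfg = SimConfig(
            n_schools_dm=1, n_schools_sc=1, group_sizes=sizes,
            outcomes={"sv_victimization": params},
            covariates=replace(SimConfig().covariates,
                               witness_beta=0.0, age_beta=0.0),
            missingness=MissingnessParams.none(), seed=7,
        )
        table = generate_trial(cfg)
        cell = table[(table.condition == "SC") & (table.sex == "F")
                     & (table.cohort == 3)]
        scores = poms(cell["sv_victimization_i1"].to_numpy())
        for wave in range(6):
            target = params.trajectories[("SC", "F", 3)][wave]
            obs = scores[cell.wave == wave]
            se = obs.std(ddof=1) / np.sqrt(len(obs))
            assert abs(obs.mean() - target) < 3 * se + 1e-9

    def test_latent_school_icc_recovered(self):
        params = replace(default_outcome_params("sh_victimization"),
                         school_icc=0.3, person_share=0.5, wave_share=0.1)
        cfg = SimConfig(
            group_sizes={g: 120 for g in GROUPS},
            outcomes={"sh_victimization": params},
            covariates=replace(SimConfig().covariates,
                               witness_beta=0.0, age_beta=0.0),
            missingness=MissingnessParams.none(), seed=3,
        )
        table, _, latents = generate_trial(cfg, keep_complete=True,
                                           keep_latent=True)
        base = latents["sh_victimization"]  # (students, waves)
        students = table[table.wave == 0].reset_index(drop=True)
        df = pd.DataFrame({"school": students["school_id"],
                           "y": base.mean(axis=1)})
        grand = df["y"].mean()
        between = df.groupby("school")["y"].mean().var(ddof=1)
        total = df["y"].var(ddof=1)
        # between-school share of the latent propensity (person+school part)
        icc = between / total
        expected = 0.3 / (0.3 + 0.5 + 0.1 / 6)  # wave noise averages 6 waves
        assert abs(icc - expected) < 0.12

    def test_mar_missingness_ignores_response_value(self, rng):
        cfg = SimConfig(group_sizes={g: 150 for g in GROUPS}, seed=11)
        masked, complete = generate_trial(cfg, keep_complete=True)
        col = "sh_victimization_i1"
        miss = masked[col].isna().to_numpy().astype(float)
        y = complete[col].to_numpy()
        X = np.column_stack([
            np.ones(len(miss)),
            masked["witness_violence"].to_numpy(),
            masked["age"].to_numpy() - 11.93,
            (y - y.mean()) / y.std(),
        ])
        from sklearn.linear_model import LogisticRegression
        fitted = LogisticRegression(C=1e8, fit_intercept=False).fit(X, miss)
        witness_coef = fitted.coef_[0][1]
        response_coef = fitted.coef_[0][3]
        assert abs(witness_coef) > 0.1          # MAR driver is present
        assert abs(response_coef) < 0.08        # held response value is not

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_schools_dm=0).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(group_sizes={("SC", "F", 3): 0}).validate()


class TestCalibrationReport:
    def test_single_item_outcome_has_no_alpha(self, tiny_sim_config):
        rep = calibration_report(generate_trial(tiny_sim_config))
        assert rep["alpha"]["sv_perpetration"] is None
        assert rep["alpha"]["sh_victimization"] is not None

    def test_duplicated_noiseless_items_reach_alpha_one(self):
        params = replace(default_outcome_params("sh_victimization"),
                         n_items=3, school_icc=0.0, person_share=0.9,
                         wave_share=0.1)  # item share = 0: identical items
        cfg = SimConfig(
            n_schools_dm=2, n_schools_sc=2,
            group_sizes={g: 50 for g in GROUPS},
            outcomes={"sh_victimization": params},
            missingness=MissingnessParams.none(), seed=2,
        )
        rep = calibration_report(generate_trial(cfg), {"sh_victimization": 3})
        alphas = [a for a in rep["alpha"]["sh_victimization"].values()
                  if not np.isnan(a)]
        assert alphas and all(a > 0.999 for a in alphas)

    def test_alpha_of_constant_matrix_is_nan(self):
        assert np.isnan(cronbach_alpha(np.ones((10, 3))))

    def test_alpha_matches_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        common = rng.normal(0, 1, 200)
        items = np.column_stack([common + rng.normal(0, 0.8, 200)
                                 for _ in range(5)])
        ours = cronbach_alpha(items)
        theirs = pingouin.cronbach_alpha(
            data=pd.DataFrame(items))[0]
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_all_missing_outcome_reported_not_raised(self, tiny_sim_config):
        table = generate_trial(tiny_sim_config)
        table[item_columns("sv_perpetration", 1)] = np.nan
        rep = calibration_report(table)
        assert np.isnan(rep["prevalence"]["sv_perpetration"])


def test_config_yaml_round_trip(tmp_path, tiny_sim_config):
    path = tmp_path / "sim.yaml"
    save_config(tiny_sim_config, path)
    loaded = load_config(path)
    assert loaded.group_sizes == tiny_sim_config.group_sizes
    assert loaded.outcomes.keys() == tiny_sim_config.outcomes.keys()
    p0 = tiny_sim_config.outcomes["sv_perpetration"]
    p1 = loaded.outcomes["sv_perpetration"]
    assert p1.thresholds == pytest.approx(p0.thresholds)
    assert p1.trajectories[("SC", "F", 3)] == pytest.approx(
        p0.trajectories[("SC", "F", 3)])
    pd.testing.assert_frame_equal(generate_trial(loaded),
                                  generate_trial(tiny_sim_config))
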