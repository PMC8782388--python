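"""Synthetic cohort generator: screening, randomization, dynamics."""

import numpy as np
import pandas as pd
import pytest

from egowave.model import ConfigError, DomainError, FLAGS
from egowave.simulate import (
    SimConfig,
    apply_nonresponse,
    followup_recent_drink_prevalence,
    generate_cohort,
    generate_dataset,
    randomize,
    screen_eligibility,
)


class TestScreening:
    @pytest.mark.parametrize(
        "audit,dast,gender,eligible",
        [
            (4, 0, "male", True),  # men's alcohol threshold
            (3, 0, "male", False),
            (3, 0, "female", True),  # women's threshold is one lower
            (2, 0, "female", False),
            (0, 3, "male", True),  # DAST strictly greater than 2
            (0, 2, "male", False),
            (0, 0, "female", False),
        ],
    )
    def test_thresholds(self, audit, dast, gender, eligible):
        assert screen_eligibility(audit, dast, gender) is eligible

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(DomainError):
            screen_eligibility(13, 0, "male")
        with pytest.raises(DomainError):
            screen_eligibility(0, 11, "male")

    def test_eligibility_yield_matches_configured_screeners(self):
        """The contacted->randomized yield should track the closed-form
        eligibility probability implied by the screener score distributions
        (analogous to a 49-of-149 recruitment yield)."""
        cfg = SimConfig()
        p_audit_m = sum(cfg.audit_c_pmf[4:])
        p_audit_f = sum(cfg.audit_c_pmf[3:])
        p_dast = sum(cfg.dast_pmf[3:])
        p_elig = cfg.prob_male * (1 - (1 - p_audit_m) * (1 - p_dast)) + (
            1 - cfg.prob_male
        ) * (1 - (1 - p_audit_f) * (1 - p_dast))
        yields = []
        for seed in range(40):
            ego, _, _ = generate_cohort(SimConfig(tie_density=0.0), seed=3000 + seed)
            yields.append(len(ego))
        expected = 149 * p_elig
        se = np.sqrt(149 * p_elig * (1 - p_elig) / 40)
        assert abs(np.mean(yields) - expected) < 3 * se
        assert abs(expected - 49) < 3  # the configured distributions target ~49


class TestRandomization:
    def test_complete_blocks_balance_exactly(self):
        genders = ["male"] * 4 + ["female"] * 4
        arms = randomize(genders, block_size=4, seed=5)
        for g in ("male", "female"):
            sub = [a for a, gg in zip(arms, genders) if gg == g]
            assert sub.count("intervention") == 2 and sub.count("control") == 2

    @pytest.mark.parametrize("n_male,n_female", [(7, 3), (13, 2), (1, 1), (10, 0)])
    def test_incomplete_final_block_bound(self, n_male, n_female):
        genders = ["male"] * n_male + ["female"] * n_female
        arms = randomize(genders, block_size=4, seed=9)
        for g, n in (("male", n_male), ("female", n_female)):
            sub = [a for a, gg in zip(arms, genders) if gg == g]
            assert abs(sub.count("intervention") - sub.count("control")) <= 2

    def test_same_seed_same_assignment(self):
        genders = ["male"] * 9 + ["female"] * 6
        a1 = randomize(genders, 4, seed=77)
        a2 = randomize(genders, 4, seed=77)
        assert list(a1) == list(a2)

    def test_odd_block_size_rejected(self):
        with pytest.raises(ConfigError):
            randomize(["male", "female"], block_size=3)


class TestGeneration:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        from egowave.io import Cohort, write_cohort

        cfg = SimConfig(seed=123)
        for d in ("a", "b"):
            write_cohort(Cohort(*generate_dataset(cfg)), tmp_path / d)
        for name in ("ego.csv", "alter.csv", "tie.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_frozen_dynamics_reproduce_baseline(self):
        """Retention 1 and zero transition rates freeze each network: the
        follow-up tables must equal the baseline tables, ties included."""
        cfg = SimConfig(
            n_randomized=30,
            retention_prob={"control": 1.0, "intervention": 1.0},
            stopping_rate={f: 0.0 for f in FLAGS},
            starting_rate={f: 0.0 for f in FLAGS},
            arm_effect_recent_drink=0.0,
        )
        _, alt, tie = generate_cohort(cfg, seed=11)
        base = alt[alt.wave == "baseline"].drop(columns="wave").reset_index(drop=True)
        fu = alt[alt.wave == "followup"].drop(columns="wave").reset_index(drop=True)
        pd.testing.assert_frame_equal(base, fu)
        tb = tie[tie.wave == "baseline"].drop(columns="wave").reset_index(drop=True)
        tf = tie[tie.wave == "followup"].drop(columns="wave").reset_index(drop=True)
        pd.testing.assert_frame_equal(tb, tf)

    def test_recent_implies_ever_everywhere(self, big_tables):
        _, alt, _ = big_tables
        for fam in ("drink", "drug", "influence", "emo", "info", "tang"):
            assert not (alt[f"{fam}_recent"] & ~alt[f"{fam}_ever"]).any()

    def test_prevalences_recovered_within_3se(self):
        cfg = SimConfig(n_randomized=600, arm_effect_recent_drink=0.0, tie_density=0.0)
        _, alt, _ = generate_cohort(cfg, seed=71)
        base = alt[alt.wave == "baseline"]
        n = len(base)
        assert n >= 10_000
        for flag, p in dict(cfg.baseline_flag_prevalences).items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(base[flag].mean() - p) < 3 * se, flag

    def test_configured_arm_effect_is_realized(self):
        """The follow-up recent-drinking proportion differs between arms by
        the configured amount, up to Monte-Carlo error."""
        from egowave.composition import composition_table

        cfg = SimConfig(n_randomized=2000, tie_density=0.0)
        ego, alt, _ = generate_cohort(cfg, seed=31)
        comp = composition_table(alt[alt.wave == "followup"]).merge(
            ego[["ego_id", "arm"]], on="ego_id"
        )
        by_arm = comp.groupby("arm")["prop_drink_recent"]
        diff = by_arm.mean()["intervention"] - by_arm.mean()["control"]
        mc_se = np.sqrt(sum(by_arm.var() / by_arm.count()))
        assert abs(diff - cfg.arm_effect_recent_drink) < 3 * mc_se + 0.005


class TestNonresponse:
    def test_mcar_rate(self):
        cfg = SimConfig(
            n_randomized=4000,
            nonresponse_covariate_strength={"income": 0.0, "site": 0.0},
            tie_density=0.0,
        )
        ego, _, _ = generate_cohort(cfg, seed=4)
        out = apply_nonresponse(ego, cfg, seed=np.random.default_rng(5))
        rate = 1 - out["responded_followup"].mean()
        assert abs(rate - cfg.nonresponse_rate) < 3 * np.sqrt(
            cfg.nonresponse_rate * (1 - cfg.nonresponse_rate) / len(out)
        )

    def test_default_conditions_give_about_84pct_response(self):
        cfg = SimConfig(n_randomized=5000, tie_density=0.0)
        ego, _, _ = generate_cohort(cfg, seed=8)
        out = apply_nonresponse(ego, cfg, seed=np.random.default_rng(9))
        assert abs(out["responded_followup"].mean() - (1 - 8 / 49)) < 0.02

    def test_income_selection_direction(self):
        """A negative income coefficient on dropout leaves responders
        richer than nonresponders."""
        cfg = SimConfig(
            n_randomized=3000,
            nonresponse_covariate_strength={"income": -1.5, "site": 0.0},
            tie_density=0.0,
        )
        ego, _, _ = generate_cohort(cfg, seed=12)
        out = apply_nonresponse(ego, cfg, seed=np.random.default_rng(13))
        resp = out[out.responded_followup]["income"].mean()
        nonresp = out[~out.responded_followup]["income"].mean()
        assert resp > nonresp

    def test_nonresponder_followup_rows_stripped(self, default_tables):
        ego, alt, tie = default_tables
        nonresp = set(ego.loc[~ego.responded_followup, "ego_id"])
        assert nonresp  # default rate ~16% should hit someone at n~49
        assert not ((alt.wave == "followup") & alt.ego_id.isin(nonresp)).any()
        assert not ((tie.wave == "followup") & tie.ego_id.isin(nonresp)).any()


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(tie_density=1.5)

    def test_recent_exceeding_ever_prevalence_rejected(self):
        prev = dict(SimConfig().baseline_flag_prevalences)
        prev["drink_recent"] = prev["drink_ever"] + 0.1
        with pytest.raises(ConfigError, match="drink"):
            SimConfig(baseline_flag_prevalences=prev)

    def test_missing_prevalence_key_named(self):
        prev = dict(SimConfig().baseline_flag_prevalences)
        del prev["tang_recent"]
        with pytest.raises(ConfigError, match="tang_recent"):
            SimConfig(baseline_flag_prevalences=prev)

    def test_odd_block_size_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(block_size=5)

    def test_closed_form_followup_prevalence_has_headroom(self):
        """Sanity on the calibration inputs: the control follow-up
        recent-drinking prevalence must exceed |default arm effect|."""
        cfg = SimConfig()
        assert followup_recent_drink_prevalence(cfg, "control") >= -cfg.arm_effect_recent_drink
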