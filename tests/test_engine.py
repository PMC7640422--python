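import numpy as np
import pytest

from nipt_bia.config import default_config
from nipt_bia.engine import (
    CalibrationAnchors,
    _draw_cohort,
    _mean_current_tallies,
    calibrate,
    run_experiment,
    simulate_replicate,
    simulate_replicate_agents,
)


def mean_tally(results, arm, key):
    return float(np.mean([getattr(r, arm).tallies[key] for r in results]))


class TestSimulateReplicate:
    def test_same_seed_is_bit_identical(self, small_cfg):
        cohort = _draw_cohort(small_cfg, 5)
        a = simulate_replicate(small_cfg, "contingent", cohort, 17)
        b = simulate_replicate(small_cfg, "contingent", cohort, 17)
        assert a.tallies == b.tallies
        assert a.ledger.cost_sums == b.ledger.cost_sums

    def test_zero_uptake_bills_nothing(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.strategy.uptake_screening = 0.0
        cohort = _draw_cohort(cfg, 5)
        res = simulate_replicate(cfg, "current", cohort, 17)
        assert res.ledger.total == 0.0
        assert res.tallies["participants"] == 0
        # natural course still plays out
        assert res.tallies["live_births"] > 0

    def test_terminal_states_partition_cohort(self, small_cfg):
        cohort = _draw_cohort(small_cfg, 5)
        for arm in ("current", "contingent"):
            res = simulate_replicate(small_cfg, arm, cohort, 3)
            t = res.tallies
            total = (
                t["spontaneous_losses"]
                + t["voluntary_terminations"]
                + t["procedure_losses"]
                + t["ds_terminations"]
                + t["live_births"]
            )
            assert total == cohort.n
            assert t["pre_offer_exits"] + t["decliners"] + t["accepted_offer"] == cohort.n

    def test_current_arm_never_uses_nipt(self, small_cfg):
        cohort = _draw_cohort(small_cfg, 5)
        res = simulate_replicate(small_cfg, "current", cohort, 3)
        assert res.tallies["nipt_attempts"] == 0
        assert res.tallies["nipt_women"] == 0

    def test_amnio_only_after_positive_screen(self, small_cfg):
        cohort = _draw_cohort(small_cfg, 5)
        for arm in ("current", "contingent"):
            res = simulate_replicate(small_cfg, arm, cohort, 3)
            assert res.tallies["amniocenteses"] <= res.tallies["screen_positives"]

    def test_contingent_arm_slashes_invasive_testing(self, small_cfg):
        results = run_experiment(small_cfg, 10, 5)
        cur = mean_tally(results, "current", "amniocenteses")
        con = mean_tally(results, "contingent", "amniocenteses")
        assert con < 0.1 * cur  # the central mechanism: >90% fewer invasive tests

    def test_counselling_and_termination_accounting(self, small_cfg):
        results = run_experiment(small_cfg, 40, 5)
        for arm in ("current", "contingent"):
            confirmed = mean_tally(results, arm, "confirmed_ds")
            counselling = mean_tally(results, arm, "counselling")
            terms = mean_tally(results, arm, "ds_terminations")
            assert counselling <= confirmed
            assert counselling > 0.95 * confirmed  # one week of attrition at most
            # over replicates the termination/counselling ratio approaches the uptake
            n = sum(getattr(r, arm).tallies["counselling"] for r in results)
            se = np.sqrt(0.9 * 0.1 / n)
            assert abs(terms / counselling - 0.9) < 4 * se

    def test_unknown_arm_rejected(self, small_cfg):
        cohort = _draw_cohort(small_cfg, 5)
        with pytest.raises(ValueError, match="unknown arm"):
            simulate_replicate(small_cfg, "both", cohort, 3)


class TestRunExperiment:
    def test_single_replicate(self, small_cfg):
        results = run_experiment(small_cfg, 1, 9)
        assert len(results) == 1

    def test_shared_mode_equalizes_screening_rows(self, small_cfg):
        for r in run_experiment(small_cfg, 5, 9):
            assert r.current.ledger.cost_sums["sips_test"] == (
                r.contingent.ledger.cost_sums["sips_test"]
            )
            assert r.current.ledger.cost_sums["program_admin"] == (
                r.contingent.ledger.cost_sums["program_admin"]
            )

    def test_master_seed_reproducibility(self, small_cfg):
        a = run_experiment(small_cfg, 4, 21)
        b = run_experiment(small_cfg, 4, 21)
        for ra, rb in zip(a, b):
            assert ra.current.tallies == rb.current.tallies
            assert ra.contingent.tallies == rb.contingent.tallies

    def test_independent_mode_inflates_difference_variance(self, small_cfg):
        shared = small_cfg.copy()
        indep = small_cfg.copy()
        indep.cohort_sharing = "independent_per_arm"
        reps = 40

        def diffs(cfg):
            return np.array(
                [
                    r.contingent.ledger.total - r.current.ledger.total
                    for r in run_experiment(cfg, reps, 13)
                ]
            )

        assert diffs(indep).var() > 2.0 * diffs(shared).var()


class TestAgentReference:
    def test_agent_and_vectorized_paths_agree_statistically(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.population.base_population_total = 60_000
        cohort = _draw_cohort(cfg, 3)
        n_vec, n_agent = 30, 10
        vec = [simulate_replicate(cfg, "contingent", cohort, s).tallies for s in range(n_vec)]
        agent = [
            simulate_replicate_agents(cfg, "contingent", cohort, s).tallies
            for s in range(n_agent)
        ]
        for key in (
            "participants",
            "screen_positives",
            "nipt_attempts",
            "amniocenteses",
            "spontaneous_losses",
            "voluntary_terminations",
            "live_births",
        ):
            v = np.mean([t[key] for t in vec])
            a = np.mean([t[key] for t in agent])
            # binomial-scale noise on both sides; compare at 4 combined SE
            se = np.sqrt(max(v, 1.0) / n_vec + max(v, 1.0) / n_agent)
            extra = 0.02 * v  # allowance for count-level binomial variance terms
            assert abs(v - a) < 4 * se + extra, key

    def test_agent_path_conserves_nipt_attempt_billing(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.population.base_population_total = 40_000
        cohort = _draw_cohort(cfg, 3)
        res = simulate_replicate_agents(cfg, "contingent", cohort, 11)
        # every billed NIPT attempt appears in the ledger exactly once
        assert res.ledger.counts["nipt_test"] == res.tallies["nipt_attempts"]


class TestCalibrate:
    def test_matching_config_returns_unchanged_knobs(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.population.base_population_total = 400_000
        cfg.population.prevalence_scale = 4.0
        anchors_seed = np.random.SeedSequence([cfg.master_seed % (2**31), 909])
        seeds = anchors_seed.spawn(24)
        means = _mean_current_tallies(
            cfg, seeds, ("participants", "counselling", "amniocenteses")
        )
        anchors = CalibrationAnchors(
            pregnancies=cfg.population.base_population_total
            * cfg.population.overall_pregnancy_rate,
            participants=means["participants"],
            confirmed_ds_current=means["counselling"],
            amnios_current=means["amniocenteses"],
            rel_tolerance=0.10,
            n_replicates=24,
        )
        calibrated, record = calibrate(cfg, anchors)
        assert calibrated.natural_history.termination_total == pytest.approx(
            cfg.natural_history.termination_total, rel=0.05
        )
        assert calibrated.tests.sips.false_positive_rate == pytest.approx(
            cfg.tests.sips.false_positive_rate, rel=0.05
        )

    def test_recovers_known_false_positive_rate(self, small_cfg):
        # simulate anchors from a known FPR, perturb, calibrate, recover
        truth = small_cfg.copy()
        truth.population.base_population_total = 400_000
        truth.population.prevalence_scale = 4.0
        truth.tests.sips.false_positive_rate = 0.04
        anchors_seed = np.random.SeedSequence([truth.master_seed % (2**31), 909])
        seeds = anchors_seed.spawn(24)
        means = _mean_current_tallies(
            truth, seeds, ("participants", "counselling", "amniocenteses")
        )
        perturbed = truth.copy()
        perturbed.tests.sips.false_positive_rate = 0.02
        anchors = CalibrationAnchors(
            pregnancies=truth.population.base_population_total
            * truth.population.overall_pregnancy_rate,
            participants=means["participants"],
            confirmed_ds_current=means["counselling"],
            amnios_current=means["amniocenteses"],
            rel_tolerance=0.10,
            n_replicates=24,
        )
        calibrated, record = calibrate(perturbed, anchors)
        assert calibrated.tests.sips.false_positive_rate == pytest.approx(0.04, rel=0.05)

    def test_unreachable_anchor_raises_with_its_name(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.population.base_population_total = 200_000
        anchors = CalibrationAnchors(
            pregnancies=200_000 * 0.0595,
            participants=10 * 200_000,  # impossible
            amnios_current=100.0,
            confirmed_ds_current=10.0,
            n_replicates=8,
        )
        with pytest.raises(ValueError, match="participants"):
            calibrate(cfg, anchors)

    def test_knob_monotonicity_on_coarse_grid(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.population.base_population_total = 300_000
        seeds = np.random.SeedSequence(77).spawn(12)
        participants = []
        for total in (0.05, 0.20, 0.35):
            trial = cfg.copy()
            trial.natural_history.termination_total = total
            participants.append(
                _mean_current_tallies(trial, seeds, ("participants",))["participants"]
            )
        assert participants[0] > participants[1] > participants[2]
        amnios = []
        for fpr in (0.01, 0.04, 0.08):
            trial = cfg.copy()
            trial.tests.sips.false_positive_rate = fpr
            amnios.append(
                _mean_current_tallies(trial, seeds, ("amniocenteses",))["amniocenteses"]
            )
        assert amnios[0] < amnios[1] < amnios[2]
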