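import numpy as np
import pytest

from nipt_bia.cohort import Woman
from nipt_bia.config import StrategyConfig, TestProfile, TestsConfig
from nipt_bia.pathways import (
    offer_screening,
    run_amniocentesis,
    run_nipt,
    run_sips,
    step_pathway,
)


def make_woman(ds=False, week=12, **kw):
    return Woman(id=0, maternal_age=35, ds_affected=ds, current_week=week, **kw)


class TestOfferScreening:
    def test_certain_uptake_always_accepts(self, rng):
        assert all(offer_screening(make_woman(), 1.0, rng) for _ in range(100))
        assert not any(offer_screening(make_woman(), 0.0, rng) for _ in range(100))

    def test_acceptance_frequency(self, rng):
        n = 100_000
        acc = sum(offer_screening(make_woman(), 0.5, rng) for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < 3 * se


class TestRunSips:
    def test_perfect_test_classifies_exactly(self, rng):
        perfect = TestProfile("sips", 1.0, 0.0)
        assert run_sips(make_woman(ds=True), perfect, rng).result == "positive"
        assert run_sips(make_woman(ds=False), perfect, rng).result == "negative"

    @pytest.mark.parametrize("ds,p", [(True, 0.85), (False, 0.033)])
    def test_positive_frequency_matches_operating_characteristics(self, ds, p, rng):
        profile = TestProfile("sips", 0.85, 0.033)
        n = 100_000
        w = make_woman(ds=ds)
        pos = sum(run_sips(w, profile, rng).result == "positive" for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(pos / n - p) < 3 * se

    def test_rejects_terminal_pregnancy(self, rng):
        w = make_woman()
        w.set_terminal("spontaneous_loss")
        with pytest.raises(ValueError, match="terminal"):
            run_sips(w, TestProfile("sips", 0.85, 0.033), rng)


class TestRunNipt:
    def test_no_failure_means_single_attempt(self, rng):
        profile = TestProfile("nipt", 0.999, 0.001, failure_rate=0.0)
        assert all(run_nipt(make_woman(), profile, rng).attempts == 1 for _ in range(200))

    def test_expected_attempts_is_one_plus_failure_rate(self, rng):
        # attempts are capped at 2, so E[attempts] = 1 + f exactly
        f = 0.02
        profile = TestProfile("nipt", 0.999, 0.001, failure_rate=f)
        n = 100_000
        attempts = [run_nipt(make_woman(ds=True), profile, rng).attempts for _ in range(n)]
        se = np.sqrt(f * (1 - f) / n)
        assert abs(np.mean(attempts) - (1 + f)) < 3 * se

    def test_double_failure_frequency(self, rng):
        f = 0.2  # inflated failure rate for statistical power
        profile = TestProfile("nipt", 0.999, 0.001, failure_rate=f)
        n = 50_000
        ft = sum(run_nipt(make_woman(), profile, rng).result == "failed_twice" for _ in range(n))
        p = f * f
        se = np.sqrt(p * (1 - p) / n)
        assert abs(ft / n - p) < 3 * se


class TestRunAmniocentesis:
    def test_riskless_procedure_confirms_ds_exactly(self, rng):
        cfg = StrategyConfig(amnio_loss_risk=0.0, fluid_leak_risk=0.0)
        w = make_woman(ds=True, week=16)
        records = run_amniocentesis(w, cfg, rng)
        assert [r.kind for r in records] == ["amniocentesis"]
        assert records[0].payload == "ds_confirmed"
        assert w.pathway_state == "confirmed" and w.confirmed_week == 16

        w2 = make_woman(ds=False, week=16)
        recs2 = run_amniocentesis(w2, cfg, rng)
        assert recs2[0].payload == "no_ds" and w2.pathway_state == "closed"

    def test_certain_loss_ends_every_pregnancy(self, rng):
        cfg = StrategyConfig(amnio_loss_risk=1.0)
        for _ in range(50):
            w = make_woman(ds=True, week=16)
            records = run_amniocentesis(w, cfg, rng)
            assert w.pregnancy_state == "procedure_loss"
            assert any(r.kind == "procedure_loss" for r in records)
            # the loss pre-empts the diagnosis
            assert records[0].payload is None

    def test_complication_frequencies(self, rng):
        cfg = StrategyConfig(amnio_loss_risk=0.0011, fluid_leak_risk=0.01)
        n = 100_000
        losses = leaks = 0
        for _ in range(n):
            w = make_woman(ds=False, week=16)
            recs = run_amniocentesis(w, cfg, rng)
            losses += w.pregnancy_state == "procedure_loss"
            leaks += any(r.kind == "fluid_leak_hospitalization" for r in recs)
        for count, p in ((losses, 0.0011), (leaks, 0.01)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(count / n - p) < 3 * se


class TestStepPathway:
    def full_cfg(self, **kw):
        defaults = dict(
            uptake_screening=1.0,
            uptake_nipt=1.0,
            uptake_amnio=1.0,
            uptake_ds_termination=1.0,
            amnio_loss_risk=0.0,
            fluid_leak_risk=0.0,
        )
        defaults.update(kw)
        return StrategyConfig(**defaults)

    def walk(self, woman, cfg, tests, strategy, rng, weeks=range(10, 25)):
        events = []
        for week in weeks:
            if not woman.ongoing:
                break
            woman.current_week = week
            events += step_pathway(woman, cfg, tests, week, rng, strategy)
        return events

    def test_current_arm_affected_woman_full_pathway(self, rng):
        cfg = self.full_cfg()
        tests = TestsConfig(sips=TestProfile("sips", 1.0, 0.0, 0.0, 108.60))
        woman = make_woman(ds=True, week=10)
        events = self.walk(woman, cfg, tests, "current", rng)
        assert [e.kind for e in events] == [
            "sips_test",
            "amniocentesis",
            "genetic_counselling",
            "ds_termination",
        ]
        assert [e.week for e in events] == [15, 16, 17, 17]
        assert woman.pregnancy_state == "ds_termination"

    def test_current_arm_screen_negative_closes_pathway(self, rng):
        cfg = self.full_cfg()
        tests = TestsConfig(sips=TestProfile("sips", 1.0, 0.0, 0.0, 108.60))
        woman = make_woman(ds=False, week=10)
        events = self.walk(woman, cfg, tests, "current", rng)
        assert [e.kind for e in events] == ["sips_test"]
        assert woman.pathway_state == "closed"
        assert woman.screen_positive is False

    def test_contingent_arm_routes_through_nipt(self, rng):
        cfg = self.full_cfg()
        tests = TestsConfig(
            sips=TestProfile("sips", 1.0, 0.0, 0.0, 108.60),
            nipt=TestProfile("nipt", 1.0, 0.0, 0.0, 795.0),
        )
        woman = make_woman(ds=True, week=10)
        events = self.walk(woman, cfg, tests, "contingent", rng)
        assert [e.kind for e in events] == [
            "sips_test",
            "nipt_test",
            "amniocentesis",
            "genetic_counselling",
            "ds_termination",
        ]
        # NIPT drawn at the result week; amniocentesis at the NIPT result week
        assert [e.week for e in events] == [15, 16, 17, 18, 18]

    def test_nipt_retest_path_and_double_failure(self, rng):
        cfg = self.full_cfg()
        tests = TestsConfig(
            sips=TestProfile("sips", 1.0, 0.0, 0.0, 108.60),
            nipt=TestProfile("nipt", 1.0, 0.0, 1.0, 795.0),  # always no-call
        )
        woman = make_woman(ds=True, week=10)
        events = self.walk(woman, cfg, tests, "contingent", rng)
        assert [e.kind for e in events] == ["sips_test", "nipt_test", "nipt_retest"]
        assert woman.pathway_state == "closed"  # no further testing
        assert woman.ongoing

    def test_direct_choice_routes_straight_to_amnio(self, rng):
        cfg = self.full_cfg(p_direct_invasive=1.0, uptake_nipt=0.0)
        tests = TestsConfig(sips=TestProfile("sips", 1.0, 0.0, 0.0, 108.60))
        woman = make_woman(ds=True, week=10)
        events = self.walk(woman, cfg, tests, "contingent_with_choice", rng)
        kinds = [e.kind for e in events]
        assert "nipt_test" not in kinds
        assert kinds[1] == "amniocentesis"
        assert events[1].week == 16  # same week as the screen result

    def test_milestone_cannot_run_twice(self, rng):
        cfg = self.full_cfg()
        tests = TestsConfig()
        woman = make_woman(week=12)
        step_pathway(woman, cfg, tests, 12, rng, "current")
        woman.pathway_state = "start"  # simulate a buggy caller rewinding state
        with pytest.raises(ValueError, match="twice"):
            step_pathway(woman, cfg, tests, 12, rng, "current")
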