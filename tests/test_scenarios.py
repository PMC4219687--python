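"""Scenario construction: levelling, donor selection, zero rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import build, exposure_frame, mortality_frame, rr_frame
from pafineq.scenarios import (ScenarioSpec, build_best_practice,
                               build_upward_levelling, resolve_donors,
                               rr_weighted_exposure, run_scenario,
                               select_best_practice)

RR = np.array([1.0, 1.3, 2.0])


class TestRrWeightedExposure:
    def test_reference_only_population(self):
        assert rr_weighted_exposure([1.0, 0.0, 0.0], RR) == pytest.approx(1.0)

    def test_hand_sum(self):
        assert rr_weighted_exposure([0.3, 0.3, 0.4], RR) == pytest.approx(1.49)

    def test_equal_weighted_sums_tie(self):
        a = rr_weighted_exposure([0.5, 0.0, 0.5], RR)            # 1.5
        b = rr_weighted_exposure([0.0, 1.0, 0.0],
                                 np.array([1.0, 1.5, 2.0]))      # 1.5
        assert a == pytest.approx(b)


class TestUpwardLevelling:
    def test_low_and_mid_receive_high_distribution(self, toy_dataset):
        mort, exp, rr = toy_dataset
        cf = build_upward_levelling(exp, rr, "A", "men", "smoking")
        high = exp.distributions("A", "men", "high", "smoking")
        assert cf.dist[("A", "men", "low")] == pytest.approx(high)
        assert cf.dist[("A", "men", "mid")] == pytest.approx(high)
        assert cf.dist[("A", "men", "high")] == pytest.approx(high)
        assert cf.clamped[("A", "men")] is False

    def test_reverse_gradient_sets_clamp(self, reverse_dataset):
        mort, exp, rr = reverse_dataset
        # weighted exposure: low 1.26 < high 1.39 -> premise inverted
        cf = build_upward_levelling(exp, rr, "A", "men", "smoking")
        assert cf.clamped[("A", "men")] is True

    def test_missing_high_stratum_is_na(self, toy_dataset):
        mort, exp, rr = toy_dataset
        cf = build_upward_levelling(exp, rr, "Z", "men", "smoking")
        assert ("Z", "men") in cf.missing

    def test_run_reports_zero_for_reverse_gradient(self, reverse_dataset):
        mort, exp, rr = reverse_dataset
        res = run_scenario(mort, exp, rr,
                           ScenarioSpec("upward_levelling", "smoking"))
        row = res.for_population("A", "men")
        assert row["clamped"]
        assert row["paf_low"] == 0.0
        assert row["delta_rd"] == 0.0
        assert row["rel_reduction_pct"] == 0.0
        assert row["paf_low_unclamped"] < 0

    def test_no_exposure_inequality_means_no_reduction(self, uniform_dataset):
        mort, exp, rr = uniform_dataset
        res = run_scenario(mort, exp, rr,
                           ScenarioSpec("upward_levelling", "smoking"))
        assert res.summary["paf_low"].abs().max() == pytest.approx(0.0)
        assert res.summary["delta_rd"].abs().max() == pytest.approx(0.0)

    def test_high_educated_rate_never_changes(self, toy_dataset):
        mort, exp, rr = toy_dataset
        res = run_scenario(mort, exp, rr,
                           ScenarioSpec("upward_levelling", "smoking"))
        s = res.summary
        assert s["rate_high_cf"].to_numpy() == pytest.approx(
            s["rate_high_obs"].to_numpy(), abs=1e-12)

    def test_delta_rd_equals_weighted_low_rate_drop(self, toy_dataset):
        mort, exp, rr = toy_dataset
        res = run_scenario(mort, exp, rr,
                           ScenarioSpec("upward_levelling", "smoking"))
        det = res.detail
        for (pop, sex), _ in res.summary.groupby(["population", "sex"]):
            w = mort.standard_weights(pop, sex)
            d = det[(det["population"] == pop) & (det["sex"] == sex)
                    & (det["education"] == "low")
                    & (det["age_group"] != "30-79")]
            drop = float((w * d["rate_obs"].to_numpy()
                          * d["paf"].to_numpy()).sum())
            row = res.for_population(pop, sex)
            assert row["delta_rd"] == pytest.approx(drop, abs=1e-12)


def three_population_exposure():
    """Gradients small/medium/large for A/B/C; same high distribution."""
    high = [0.5, 0.3, 0.2]
    dists = {}
    for pop, g in (("A", 0.02), ("B", 0.10), ("C", 0.20)):
        dists[(pop, "high")] = high
        dists[(pop, "mid")] = [0.5 - g / 2, 0.3, 0.2 + g / 2]
        dists[(pop, "low")] = [0.5 - g, 0.3, 0.2 + g]
    return exposure_frame(dists, populations=("A", "B", "C"))


class TestBestPracticeSelection:
    def test_smallest_levelled_paf_wins(self):
        mort, exp, rr = build(mortality_frame(("A", "B", "C")),
                              three_population_exposure(), rr_frame())
        assert select_best_practice(mort, exp, rr, "men", "smoking") == "A"

    def test_high_exposure_above_median_is_ineligible(self):
        # A has the smallest gradient but a very exposed high-educated group
        high = [0.5, 0.3, 0.2]
        dists = {("A", "high"): [0.1, 0.2, 0.7],
                 ("A", "mid"): [0.09, 0.2, 0.71],
                 ("A", "low"): [0.08, 0.2, 0.72]}
        for pop, g in (("B", 0.10), ("C", 0.20)):
            dists[(pop, "high")] = high
            dists[(pop, "mid")] = [0.5 - g / 2, 0.3, 0.2 + g / 2]
            dists[(pop, "low")] = [0.5 - g, 0.3, 0.2 + g]
        mort, exp, rr = build(mortality_frame(("A", "B", "C")),
                              exposure_frame(dists, populations=("A", "B", "C")),
                              rr_frame())
        assert select_best_practice(mort, exp, rr, "men", "smoking") == "B"

    def test_single_population_selects_itself(self, toy_dataset):
        mort, exp, rr = toy_dataset
        assert select_best_practice(mort, exp, rr, "men", "smoking") == "A"

    def test_selection_deterministic(self):
        mort, exp, rr = build(mortality_frame(("A", "B", "C")),
                              three_population_exposure(), rr_frame())
        picks = {select_best_practice(mort, exp, rr, "men", "smoking")
                 for _ in range(3)}
        assert picks == {"A"}

    def test_override_honoured(self):
        mort, exp, rr = build(mortality_frame(("A", "B", "C")),
                              three_population_exposure(), rr_frame())
        donors = resolve_donors(mort, exp, rr, "smoking",
                                overrides={"men": "C"})
        assert donors["men"] == "C"
        assert donors["women"] == "A"


class TestBestPracticeScenario:
    def _run(self, donors=None):
        mort, exp, rr = build(mortality_frame(("A", "B", "C")),
                              three_population_exposure(), rr_frame())
        spec = ScenarioSpec("best_practice", "smoking",
                            donors=donors or {"men": "A", "women": "A"})
        return run_scenario(mort, exp, rr, spec)

    def test_self_donation_is_fixed_point(self):
        res = self._run()
        row = res.for_population("A", "men")
        assert row["status"] == "ref"
        assert row["delta_rd"] == pytest.approx(0.0, abs=1e-12)
        assert row["paf_low"] == pytest.approx(0.0, abs=1e-12)

    def test_donor_with_smaller_gradient_reduces_inequality(self):
        res = self._run()
        row = res.for_population("C", "men")
        assert row["delta_rd"] > 0
        assert not row["clamped"]
        # donor's high equals target's high -> high group untouched
        assert row["paf_high"] == pytest.approx(0.0, abs=1e-14)

    def test_negative_reduction_propagates_unclamped(self):
        # donor C has the *larger* gradient: target A's inequality widens
        res = self._run(donors={"men": "C", "women": "C"})
        row = res.for_population("A", "men")
        assert row["delta_rd"] < 0
        assert not row["clamped"]

    def test_donor_worse_high_triggers_clamp(self):
        high = [0.5, 0.3, 0.2]
        dists = {("A", "high"): high, ("A", "mid"): [0.45, 0.3, 0.25],
                 ("A", "low"): [0.4, 0.3, 0.3],
                 # donor: tiny gradient but a less favourable high group
                 ("D", "high"): [0.3, 0.3, 0.4],
                 ("D", "mid"): [0.3, 0.3, 0.4],
                 ("D", "low"): [0.29, 0.3, 0.41]}
        mort, exp, rr = build(mortality_frame(("A", "D")),
                              exposure_frame(dists, populations=("A", "D")),
                              rr_frame())
        spec = ScenarioSpec("best_practice", "smoking",
                            donors={"men": "D", "women": "D"})
        res = run_scenario(mort, exp, rr, spec)
        row = res.for_population("A", "men")
        assert row["clamped"]
        assert row["delta_rd"] == 0.0
        assert row["rel_reduction_pct"] == 0.0

    def test_equivalence_with_upward_levelling_on_constructed_donor(self):
        # donor low == donor high == target high: best practice must equal
        # upward levelling for the target
        high = [0.5, 0.3, 0.2]
        dists = {("T", "high"): high, ("T", "mid"): [0.45, 0.3, 0.25],
                 ("T", "low"): [0.35, 0.3, 0.35],
                 ("D", "high"): high, ("D", "mid"): high, ("D", "low"): high}
        mort, exp, rr = build(mortality_frame(("T", "D")),
                              exposure_frame(dists, populations=("T", "D")),
                              rr_frame())
        up = run_scenario(mort, exp, rr,
                          ScenarioSpec("upward_levelling", "smoking"))
        bp = run_scenario(mort, exp, rr,
                          ScenarioSpec("best_practice", "smoking",
                                       donors={"men": "D", "women": "D"}))
        for sex in ("men", "women"):
            u = up.for_population("T", sex)
            b = bp.for_population("T", sex)
            assert b["delta_rd"] == pytest.approx(u["delta_rd"], abs=1e-12)
            assert b["paf_low"] == pytest.approx(u["paf_low"], abs=1e-12)

    def test_unresolved_donors_rejected(self, toy_dataset):
        mort, exp, rr = toy_dataset
        with pytest.raises(Exception, match="donor"):
            run_scenario(mort, exp, rr,
                         ScenarioSpec("best_practice", "smoking"))

    def test_missing_exposure_propagates_as_na(self):
        df = pd.concat([three_population_exposure(),
                        exposure_frame({"low": [0.4, 0.6], "mid": [0.5, 0.5],
                                        "high": [0.6, 0.4]},
                                       populations=("A", "B", "C", "Z"),
                                       risk_factor="inactivity",
                                       categories=["active", "sedentary"])])
        mort, exp, rr = build(mortality_frame(("A", "B", "C", "Z")), df,
                              rr_frame())
        res = run_scenario(mort, exp, rr,
                           ScenarioSpec("upward_levelling", "smoking"))
        row = res.for_population("Z", "men")
        assert row["status"] == "na"
        assert np.isnan(row["paf_low"])
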