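"""Tornado, probabilistic sensitivity analysis, CEAC and threshold search."""

import dataclasses

import numpy as np
import pytest

from rectalcea import (
    EconomicSettings,
    ceac,
    compare,
    evaluate_strategy,
    one_way_tornado,
    run_psa,
    threshold_pd_cost,
    threshold_pd_cost_closed_form,
)


class TestTornado:
    def test_dfs_utility_most_influential(self, scrt, lccrt, settings):
        """The DFS-state utility tops the tornado ranking."""
        entries = one_way_tornado(scrt, lccrt, settings)
        assert entries[0].parameter.startswith("u_dfs")
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_zero_range_collapses_all_bars(self, scrt, lccrt, settings):
        entries = one_way_tornado(scrt, lccrt, settings, rel_range=0.0)
        assert all(e.range == pytest.approx(0.0, abs=1e-9) for e in entries)

    def test_cost_parameter_linearity(self, scrt, lccrt, settings):
        """A cost enters the NMB linearly, so the low/high midpoint equals
        the base incremental NMB."""
        base = compare(
            evaluate_strategy(scrt, settings),
            evaluate_strategy(lccrt, settings),
            settings.wtp,
        ).nmb_incremental
        entries = {e.parameter: e for e in one_way_tornado(scrt, lccrt, settings)}
        e = entries["cost_pd_cycle"]
        assert 0.5 * (e.nmb_low + e.nmb_high) == pytest.approx(base, abs=1e-6)

    def test_invalid_range(self, scrt, lccrt, settings):
        with pytest.raises(ValueError):
            one_way_tornado(scrt, lccrt, settings, rel_range=1.5)


class TestPSA:
    def test_degenerate_spread_reproduces_base_case(self, scrt, lccrt, settings):
        psa = run_psa(scrt, lccrt, settings, n_trials=5, seed=0, rel_range=0.0)
        base = evaluate_strategy(scrt, settings)
        assert np.allclose(psa.costs["SCRT"], base.cost_total)
        assert np.allclose(psa.effects["SCRT"], base.qalm_total)

    def test_seed_reproducibility(self, scrt, lccrt, settings):
        kwargs = dict(n_trials=8, n_individuals=500, seed=11, mode="microsimulation")
        a = run_psa(scrt, lccrt, settings, **kwargs)
        b = run_psa(scrt, lccrt, settings, **kwargs)
        for name in a.strategies:
            assert np.array_equal(a.costs[name], b.costs[name])
            assert np.array_equal(a.effects[name], b.effects[name])

    def test_different_seeds_differ(self, scrt, lccrt, settings):
        a = run_psa(scrt, lccrt, settings, n_trials=8, seed=1)
        b = run_psa(scrt, lccrt, settings, n_trials=8, seed=2)
        assert not np.array_equal(a.costs["SCRT"], b.costs["SCRT"])

    def test_sampling_means_match_base(self, scrt, lccrt, settings):
        """Moment-matched distributions keep the Monte-Carlo mean near the
        base case."""
        psa = run_psa(scrt, lccrt, settings, n_trials=400, seed=3)
        base = evaluate_strategy(scrt, settings)
        se = psa.costs["SCRT"].std(ddof=1) / np.sqrt(psa.n_trials)
        assert abs(psa.costs["SCRT"].mean() - base.cost_total) < 4 * se + 0.02 * base.cost_total

    def test_microsimulation_agrees_with_cohort(self, scrt, settings):
        """Averaged individual paths converge on the deterministic cohort."""
        from rectalcea import simulate_individuals

        rng = np.random.default_rng(7)
        runs = [
            simulate_individuals(scrt, settings, 10_000, rng).qalm_total
            for _ in range(8)
        ]
        cohort = evaluate_strategy(scrt, settings).qalm_total
        se = np.std(runs, ddof=1) / np.sqrt(len(runs))
        assert abs(np.mean(runs) - cohort) < 3 * se + 1e-9

    def test_uniform_sampling_alternative(self, scrt, lccrt, settings):
        psa = run_psa(scrt, lccrt, settings, n_trials=50, seed=4, sampling="uniform")
        # uniform(base*0.8, base*1.2) draws stay inside the band
        assert psa.costs["SCRT"].min() > 0
        with pytest.raises(ValueError):
            run_psa(scrt, lccrt, settings, n_trials=2, sampling="cauchy")

    def test_invalid_mode_and_trials(self, scrt, lccrt, settings):
        with pytest.raises(ValueError):
            run_psa(scrt, lccrt, settings, n_trials=0)
        with pytest.raises(ValueError):
            run_psa(scrt, lccrt, settings, n_trials=2, mode="quantum")


class TestCEAC:
    def test_degenerate_base_case_prefers_comparator_at_wtp(self, scrt, lccrt, settings):
        """At the base case the ICER exceeds the WTP, so the cheaper
        comparator is cost-effective with probability 1."""
        psa = run_psa(scrt, lccrt, settings, n_trials=3, seed=0, rel_range=0.0)
        curve = ceac(psa, [settings.wtp])
        assert curve.probability["LCCRT"][0] == 1.0
        assert curve.probability["SCRT"][0] == 0.0

    def test_limits_of_the_wtp_axis(self, scrt, lccrt, settings):
        psa = run_psa(scrt, lccrt, settings, n_trials=100, seed=5)
        curve = ceac(psa, [0.0, 1e9])
        frac_cheaper = np.mean(psa.costs["SCRT"] < psa.costs["LCCRT"])
        assert curve.probability["SCRT"][0] == pytest.approx(frac_cheaper)
        frac_better = np.mean(psa.effects["SCRT"] > psa.effects["LCCRT"])
        assert curve.probability["SCRT"][1] == pytest.approx(frac_better)

    def test_probabilities_sum_to_one_with_ties_split(self, scrt, settings):
        psa = run_psa(scrt, scrt.replace(name="CLONE"), settings, n_trials=4,
                      seed=0, rel_range=0.0)
        curve = ceac(psa, [0.0, 2370.47, 5000.0])
        total = sum(curve.probability.values())
        assert np.allclose(total, 1.0)
        assert np.allclose(curve.probability["SCRT"], 0.5)  # exact ties split

    def test_empty_grid_rejected(self, scrt, lccrt, settings):
        psa = run_psa(scrt, lccrt, settings, n_trials=2, seed=0)
        with pytest.raises(ValueError):
            ceac(psa, [])


class TestThreshold:
    def test_crosses_wtp_near_published_value(self, scrt, lccrt, settings):
        thr = threshold_pd_cost(scrt, lccrt, settings, (0.0, 4920.50))
        assert thr == pytest.approx(1920.0, rel=0.02)

    def test_wtp_at_base_icer_returns_base_pd_cost(self, scrt, lccrt, settings):
        icer = compare(
            evaluate_strategy(scrt, settings),
            evaluate_strategy(lccrt, settings),
            settings.wtp,
        ).icer
        s = dataclasses.replace(settings, wtp=icer)
        thr = threshold_pd_cost(scrt, lccrt, s, (0.0, 6000.0))
        assert thr == pytest.approx(4920.50, abs=0.02)

    def test_bisection_matches_closed_form(self, scrt, lccrt, settings):
        thr = threshold_pd_cost(scrt, lccrt, settings, (0.0, 4920.50))
        closed = threshold_pd_cost_closed_form(scrt, lccrt, settings)
        assert thr == pytest.approx(closed, abs=0.01)

    def test_no_root_in_bracket(self, scrt, lccrt, settings):
        with pytest.raises(ValueError, match="cross"):
            threshold_pd_cost(scrt, lccrt, settings, (4000.0, 4920.50))
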