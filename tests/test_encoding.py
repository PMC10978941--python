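"""Binwise regression, coding history, instructed filter, categorisation."""

import numpy as np
import pandas as pd
import pytest

from pmdarith import encoding, synth
from pmdarith import task as T
from pmdarith.population import BinnedPopulation


class TestBinSpikeCounts:
    def _trials(self, n=2):
        return synth.balanced_decoding_trials(reps=1, seed=0).head(n).reset_index(drop=True)

    def test_half_open_bin_convention(self):
        trials = self._trials(1)
        preop = trials.at[0, "t_preop_on"]
        spikes = [[np.array([preop + 99.9, preop + 100.0])]]
        pop = encoding.bin_spike_counts(spikes, trials)
        assert pop.counts[0, 0, 0] == 1 and pop.counts[0, 0, 1] == 1

    def test_counts_conserved(self, rng):
        trials = self._trials(2)
        preop = trials.at[0, "t_preop_on"]
        spikes = [[np.sort(rng.uniform(preop, preop + 2400, 50)) for _ in range(2)]]
        pop = encoding.bin_spike_counts(spikes, trials)
        assert pop.counts.sum(axis=2).tolist() == [[50, 50]]

    def test_go_aligned_operation_bins(self):
        trials = self._trials(1)
        go = trials.at[0, "t_go"]
        spikes = [[np.array([go + 0.0, go + 699.9])]]
        pop = encoding.bin_spike_counts(spikes, trials)
        assert pop.counts[0, 0, 17] == 1 and pop.counts[0, 0, 23] == 1

    def test_trials_missing_events_dropped(self):
        trials = self._trials(2)
        trials.loc[1, "t_go"] = np.nan
        spikes = [[np.array([]), np.array([])]]
        pop = encoding.bin_spike_counts(spikes, trials)
        assert pop.n_trials == 1


class TestBinwiseRegression:
    def test_noiseless_coefficients_equal_mean_contrasts(self):
        """On exact planted rates the fitted coefficients equal the planted
        level differences (dummy regressors are orthogonal when balanced)."""
        trials = synth.balanced_decoding_trials(reps=5, seed=1)
        prof = synth.CellProfile(
            cell_id=0, baseline_rate=10.0,
            effects={"arithmetic": (0.5, (0, 2400)), "hand": (0.2, (0, 2400))})
        rates = synth._rate_matrix(prof, trials, T.DEFAULT_TIMELINE)
        counts = rates[None] * 0.1  # exact expected counts, no Poisson noise
        pop = BinnedPopulation(counts, trials)
        reg = encoding.binwise_regression(pop)
        # addition 15 vs subtraction 5 modulated by hand +/-2: with balanced
        # factors the arithmetic contrast is 10 spikes/s, hand contrast 4
        ai = reg.factors.index("arithmetic")
        hi = reg.factors.index("hand")
        si = reg.factors.index("step")
        assert np.allclose(reg.coef[0, :, ai + 1], 10.0, atol=1e-8)
        assert np.allclose(reg.coef[0, :, hi + 1], 4.0, atol=1e-8)
        assert np.allclose(reg.coef[0, :, si + 1], 0.0, atol=1e-8)

    def test_constant_counts_give_no_flags(self):
        trials = synth.balanced_decoding_trials(reps=3, seed=1)
        pop = BinnedPopulation(np.ones((2, len(trials), 24)), trials)
        reg = encoding.binwise_regression(pop)
        assert not reg.flags.any()
        assert np.allclose(reg.coef[:, :, 1:], 0.0)

    def test_planted_cell_power(self):
        """An arithmetic-only cell at gain 0.5 / baseline 10 / 20 per condition
        is flagged in at least one preoperational bin in >=90% of cells."""
        trials = synth.balanced_decoding_trials(reps=20, seed=2)
        spec = synth.PopulationSpec(n_cells=100, fractions={"arith_pure": 1.0})
        pop, _ = synth.simulate_population_spikes(spec, trials, seed=3)
        reg = encoding.binwise_regression(pop, bins=range(7))
        ai = reg.factors.index("arithmetic")
        hit = reg.flags[:, 1:, ai].any(axis=1)  # planted window starts at 100 ms
        assert hit.mean() >= 0.9

    def test_null_alpha_calibration_loose(self, null_small):
        reg = encoding.binwise_regression(null_small.pop)
        rate = reg.flags.mean()
        assert 0.005 < rate < 0.02

    def test_starved_factor_reported_nan(self):
        trials = synth.balanced_decoding_trials(reps=3, seed=1)
        trials = trials[trials["step"] == 1].reset_index(drop=True)
        pop = BinnedPopulation(np.ones((1, len(trials), 24)), trials)
        reg = encoding.binwise_regression(pop)
        si = reg.factors.index("step")
        assert np.isnan(reg.pvals[:, :, si]).all()
        assert not reg.flags[:, :, si].any()


def _manual_reg(flag_spec, n_cells=1, n_bins=24):
    """BinRegressionResult with flags set from {(cell, bin, factor_idx)}."""
    factors = ("arithmetic", "hand", "step", "stimulus_type")
    flags = np.zeros((n_cells, n_bins, 4), dtype=bool)
    for c, b, f in flag_spec:
        flags[c, b, f] = True
    pvals = np.where(flags, 0.001, 0.5)
    coef = np.zeros((n_cells, n_bins, 5))
    return encoding.BinRegressionResult(coef, pvals, flags, factors, 0.01,
                                        np.arange(n_cells), np.arange(n_bins))


class TestCodingHistory:
    def test_single_bin_significance_enters_history(self):
        hist = encoding.build_coding_history(_manual_reg({(0, 3, 0)}))
        assert hist.factors_at(0, "preop") == {"arithmetic"}

    def test_cumulative_union_across_periods(self):
        spec = {(0, b, 0) for b in range(7)} | {(0, b, 1) for b in range(17, 24)}
        hist = encoding.build_coding_history(_manual_reg(spec))
        assert hist.factors_at(0, "preop") == {"arithmetic"}
        assert hist.factors_at(0, "operation") == {"arithmetic", "hand"}
        assert hist.factors_at(0, "operation", cumulative=False) == {"hand"}

    def test_no_flags_empty_history(self):
        hist = encoding.build_coding_history(_manual_reg(set()))
        assert hist.factors_at(0, "operation") == frozenset()

    def test_stimulus_type_never_enters(self):
        hist = encoding.build_coding_history(_manual_reg({(0, 2, 3)}))
        assert hist.factors_at(0, "preop") == frozenset()

    def test_histories_monotone(self, paper_like_encoding):
        cum = paper_like_encoding["hist"].cumulative
        assert (cum[:, 1:, :] >= cum[:, :-1, :]).all()

    def test_dominant_rule_keeps_majority_factor(self):
        spec = {(0, b, 0) for b in range(5)} | {(0, 6, 1)}
        hist = encoding.build_coding_history(_manual_reg(spec), rule="dominant")
        assert hist.factors_at(0, "preop") == {"arithmetic"}


class TestInstructedFilter:
    def test_comparison_only_cells_excluded(self, paper_like_small,
                                            paper_like_encoding):
        truth = paper_like_small.ground_truth
        sel = paper_like_encoding["selective"]
        comparison = truth["category"] == "comparison_only"
        leak = sel[comparison].mean()
        assert leak < 0.2  # only alpha-level leakage through 7 bins

    def test_both_task_coders_retained(self, paper_like_small,
                                       paper_like_encoding):
        truth = paper_like_small.ground_truth
        sel = paper_like_encoding["selective"]
        planted = truth["arithmetic_selective"].to_numpy()
        assert sel[planted].mean() >= 0.9

    def test_null_retention_matches_closed_form(self):
        """A null candidate passes the 7-bin filter with probability
        1 - (1 - 0.01)^7 = 6.8%."""
        trials = synth.balanced_decoding_trials(reps=20, seed=7)
        trials["task"] = T.TASK_INSTRUCTED
        trials["instruction"] = np.where(trials["arithmetic"] == T.ADDITION,
                                         T.PLUS, T.MINUS)
        spec = synth.PopulationSpec(n_cells=800, fractions={})
        pop, _ = synth.simulate_population_spikes(spec, trials, seed=8)
        ireg = encoding.regress_instruction(pop)
        sel, _ = encoding.instructed_task_filter(np.ones(800, bool), ireg)
        expected = 1 - 0.99 ** 7
        se = np.sqrt(expected * (1 - expected) / 800)
        assert abs(sel.mean() - expected) < 3 * se

    def test_unevaluable_cells_not_selective(self):
        reg = encoding.BinRegressionResult(
            np.zeros((2, 7, 2)), np.full((2, 7, 1), np.nan),
            np.zeros((2, 7, 1), bool), ("instruction",), 0.01,
            np.arange(2), np.arange(7))
        sel, unev = encoding.instructed_task_filter(np.ones(2, bool), reg)
        assert not sel.any() and unev.all()


class TestCategorise:
    def test_overlapping_memberships_counted(self):
        spec = {(0, 2, 0), (0, 3, 1)}
        hist = encoding.build_coding_history(_manual_reg(spec))
        tab, counts = encoding.categorize_cells(hist)
        assert counts["arithmetic_related"] == 1
        assert counts["hand_related"] == 1

    def test_recovery_against_ground_truth(self, paper_like_small,
                                           paper_like_encoding):
        truth = paper_like_small.ground_truth
        hist = paper_like_encoding["hist"]
        tab, counts = encoding.categorize_cells(
            hist, paper_like_encoding["selective"])
        planted = int(truth["arithmetic_selective"].sum())
        assert abs(counts["arithmetic_selective"] - planted) <= 0.15 * planted

    def test_null_counts_at_alpha_level(self, null_small):
        reg = encoding.binwise_regression(null_small.pop)
        hist = encoding.build_coding_history(reg)
        tab, counts = encoding.categorize_cells(hist)
        # per-cell false-positive rate over 7 preop bins ~ 1-(0.99)^7 = 6.8%
        for key in ("arithmetic_related", "hand_related", "step_related"):
            assert counts[key] < 0.15 * counts["total"]


class TestPeriodTracking:
    def test_static_code_drop_is_only_alpha_accumulation(self):
        """With a constant planted code, exclusivity is lost only through
        binwise false positives of the any-bin rule: the drop must match the
        closed-form accumulation rate 1 - (1-alpha)^(extra bin x factor
        tests), not a planted transition."""
        ds = synth.make_fixture_dataset("static_code", seed=3, n_cells=60)
        reg = encoding.binwise_regression(ds.pop)
        hist = encoding.build_coding_history(reg)
        tr = encoding.period_selectivity_tracking(
            hist, np.ones(ds.pop.n_cells, bool))
        assert tr["exclusive_start"] > 0
        b, c = tr["discordant"]
        assert c == 0  # cumulative histories cannot regain exclusivity
        expected = 1 - 0.99 ** (17 * 2)  # delay2+operation bins, hand & step
        se = np.sqrt(expected * (1 - expected) / tr["exclusive_start"])
        assert abs(b / tr["exclusive_start"] - expected) < 3.5 * se

    def test_per_period_coding_is_static(self):
        ds = synth.make_fixture_dataset("static_code", seed=3, n_cells=40)
        reg = encoding.binwise_regression(ds.pop)
        hist = encoding.build_coding_history(reg)
        ai = list(hist.factors).index("arithmetic")
        # the planted arithmetic code is present in every period for nearly
        # every cell (non-cumulative view)
        assert hist.per_period[:, :, ai].mean() > 0.95

    def test_transition_cells_lose_exclusivity(self, paper_like_encoding):
        tr = encoding.period_selectivity_tracking(
            paper_like_encoding["hist"], paper_like_encoding["selective"])
        assert tr["fraction_end"] < tr["fraction_start"]
        assert tr["mcnemar_p"] < 0.01

    def test_single_transition_cell_example(self):
        spec = {(0, 2, 0), (0, 20, 1)}
        hist = encoding.build_coding_history(_manual_reg(spec))
        assert hist.exclusive_arithmetic("preop")[0]
        assert not hist.exclusive_arithmetic("operation")[0]
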