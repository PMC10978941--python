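"""ROC selectivity, confidence ellipses, relative variance, quadrant bias."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmdarith import roc, synth
from pmdarith import task as T


def auc_oracle(pos, neg):
    """Exhaustive pair enumeration."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_complete_separation(self):
        assert roc.auc_mann_whitney([5, 6, 7], [1, 2, 3]) == 1.0

    def test_identical_lists(self):
        assert roc.auc_mann_whitney([2, 2, 3], [2, 2, 3]) == 0.5

    def test_tied_example(self):
        assert roc.auc_mann_whitney([2, 3], [1, 3]) == 0.625

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc.auc_mann_whitney([], [1, 2])

    @settings(derandomize=True, max_examples=300)
    @given(
        pos=st.lists(st.integers(0, 6), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 6), min_size=1, max_size=8),
    )
    def test_matches_exhaustive_enumeration(self, pos, neg):
        assert roc.auc_mann_whitney(pos, neg) == pytest.approx(
            auc_oracle(pos, neg), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        pos=st.lists(st.integers(0, 9), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 9), min_size=1, max_size=8),
    )
    def test_class_complement_symmetry(self, pos, neg):
        assert roc.auc_mann_whitney(pos, neg) == pytest.approx(
            1.0 - roc.auc_mann_whitney(neg, pos), abs=1e-12)


@pytest.fixture(scope="module")
def planted():
    trials = synth.balanced_decoding_trials(reps=15, seed=4)
    profiles = [synth.CellProfile(
        cell_id=0, baseline_rate=10.0,
        effects={"arithmetic": (0.8, (300, 1200))})]
    pop, _ = synth.simulate_population_spikes(profiles, trials, seed=4)
    return roc.roc_trajectories(pop)


class TestTrajectories:

    def test_deviation_inside_planted_window(self, planted):
        ai = planted.factor_index("arithmetic")
        inside = planted.auc[0, ai, 3:12]
        outside = planted.auc[0, ai, 15:]
        assert (inside > 0.8).all()
        assert np.abs(outside - 0.5).max() < 0.2

    def test_other_factors_flat(self, planted):
        hi = planted.factor_index("hand")
        assert np.abs(planted.auc[0, hi] - 0.5).max() < 0.2

    def test_label_flip_maps_auc_to_complement(self):
        trials = synth.balanced_decoding_trials(reps=10, seed=5)
        spec = synth.PopulationSpec(n_cells=4, fractions={"arith_pure": 1.0})
        pop, _ = synth.simulate_population_spikes(spec, trials, seed=5)
        t1 = roc.roc_trajectories(pop)
        flipped = pop.trials.copy()
        flipped["arithmetic"] = flipped["arithmetic"].map(
            {T.ADDITION: T.SUBTRACTION, T.SUBTRACTION: T.ADDITION})
        pop.trials = flipped
        t2 = roc.roc_trajectories(pop)
        ai = t1.factor_index("arithmetic")
        assert np.allclose(t2.auc[:, ai], 1.0 - t1.auc[:, ai], atol=1e-12)

    def test_null_cells_centre_on_half(self, null_small):
        traj = roc.roc_trajectories(null_small.pop)
        assert abs(np.nanmean(traj.auc) - 0.5) < 0.01


class TestConfidenceEllipse:
    def test_known_covariance_eigenstructure(self, rng):
        pts = rng.normal(size=(4000, 2)) * [2.0, 1.0]
        fit = roc.fit_confidence_ellipse(pts)
        assert fit.theta_deg < 5 or fit.theta_deg > 175
        assert fit.axis_ratio == pytest.approx(2.0, rel=0.07)

    def test_diagonal_cloud_at_45_degrees(self, rng):
        x = rng.normal(size=3000)
        pts = np.column_stack([x, x + rng.normal(scale=0.05, size=3000)])
        fit = roc.fit_confidence_ellipse(pts)
        assert fit.theta_deg == pytest.approx(45.0, abs=2.0)

    def test_axis_swap_reflects_theta(self, rng):
        pts = rng.normal(size=(500, 2)) * [3.0, 1.0]
        a = roc.fit_confidence_ellipse(pts)
        b = roc.fit_confidence_ellipse(pts[:, ::-1])
        assert a.theta_deg == pytest.approx(90.0 - b.theta_deg, abs=1e-8)
        assert a.axis_ratio == pytest.approx(b.axis_ratio)

    def test_isotropic_cloud_ratio_near_one(self, rng):
        pts = rng.normal(size=(500, 2))
        fit = roc.fit_confidence_ellipse(pts)
        assert fit.axis_ratio < 1.1

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        fit = roc.fit_confidence_ellipse(pts)
        assert fit.degenerate
        assert fit.theta_deg == pytest.approx(np.degrees(np.arctan(2)), abs=1e-6)

    def test_contour_level_constant(self):
        assert roc.CHI2_95_2DF == pytest.approx(5.991, abs=1e-3)


class TestRelativeVariance:
    def _traj(self, auc):
        auc = np.asarray(auc, float)[:, None, :]
        return roc.ROCTrajectory(auc, np.arange(auc.shape[0]), ("arithmetic",),
                                 {"arithmetic": 10}, {"arithmetic": 10})

    def test_constant_variance_gives_ones(self, rng):
        base = rng.normal(0.5, 0.1, size=(50, 1))
        auc = np.repeat(base, 24, axis=1)
        rv = roc.relative_variance(self._traj(auc), "arithmetic")
        assert np.allclose(rv, 1.0)

    def test_scale_invariance(self, rng):
        auc = rng.normal(0.5, 0.1, size=(40, 24))
        rv1 = roc.relative_variance(self._traj(auc), "arithmetic")
        rv2 = roc.relative_variance(self._traj(0.5 + 2 * (auc - 0.5)), "arithmetic")
        assert np.allclose(rv1, rv2)

    def test_series_mean_is_exactly_one(self, rng):
        auc = rng.normal(0.5, 0.1, size=(40, 24))
        rv = roc.relative_variance(self._traj(auc), "arithmetic")
        assert np.mean(rv) == pytest.approx(1.0, abs=1e-12)

    def test_argmax_ordering_matches_transition_schedule(
            self, paper_like_small, paper_like_encoding):
        sel = np.flatnonzero(paper_like_encoding["selective"])
        traj = roc.roc_trajectories(paper_like_small.pop, cells=sel)
        order = [int(np.nanargmax(roc.relative_variance(traj, f)))
                 for f in ("arithmetic", "hand", "step")]
        assert order[0] < order[1] < order[2]


class TestSimultaneousCoders:
    def test_planted_dual_coders_selected(self):
        trials = synth.balanced_decoding_trials(reps=15, seed=6)
        spec = synth.PopulationSpec(n_cells=100,
                                    fractions={"arith_hand_sim": 1.0})
        pop, _ = synth.simulate_population_spikes(spec, trials, seed=6)
        coders = roc.select_simultaneous_coders(
            pop, np.arange(100), n_perm=300, seed=6)
        assert coders["selected"].mean() >= 0.9

    def test_null_selection_rate_is_conjunction_of_alphas(self, null_small):
        coders = roc.select_simultaneous_coders(
            null_small.pop, np.arange(null_small.pop.n_cells),
            n_perm=300, seed=7)
        # expected rate ~ 0.05^2 = 0.25%: 0-3 of 200 cells
        assert coders["selected"].sum() <= 4

    def test_deterministic_under_seed(self, null_small):
        a = roc.select_simultaneous_coders(
            null_small.pop, np.arange(40), n_perm=100, seed=9)
        b = roc.select_simultaneous_coders(
            null_small.pop, np.arange(40), n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestQuadrantTimecourse:
    def _traj_and_coders(self, auc_a, auc_h):
        n = auc_a.shape[0]
        auc = np.stack([auc_a, auc_h], axis=1)
        traj = roc.ROCTrajectory(auc, np.arange(n), ("arithmetic", "hand"),
                                 {"arithmetic": 10, "hand": 10},
                                 {"arithmetic": 10, "hand": 10})
        coders = pd.DataFrame({"cell_id": np.arange(n),
                               "selected": np.ones(n, bool)})
        return traj, coders

    def test_exact_half_excluded_from_partition(self):
        auc_a = np.full((10, 3), 0.8)
        auc_h = np.full((10, 3), 0.8)
        auc_h[0, 1] = 0.5  # tied cell drops out of bin 1 only
        traj, coders = self._traj_and_coders(auc_a, auc_h)
        qt = roc.quadrant_fraction_timecourse(coders, traj)
        tab = qt.per_bin.set_index(["bin", "hand"])
        assert tab.loc[(0, T.RIGHT), "n"] == 10
        assert tab.loc[(1, T.RIGHT), "n"] == 9

    def test_small_groups_skipped(self):
        auc_a = np.full((3, 2), 0.7)
        auc_h = np.full((3, 2), 0.7)
        traj, coders = self._traj_and_coders(auc_a, auc_h)
        qt = roc.quadrant_fraction_timecourse(coders, traj, min_cells=5)
        assert qt.per_bin["p"].isna().all()

    def test_snarc_coupling_recovered_in_simultaneous_coders(self):
        """With fully SNARC-coupled simultaneous coders the addition fraction
        is high among right-hand coders and low among left-hand coders, and
        both series are significant."""
        trials = synth.balanced_decoding_trials(reps=15, seed=8)
        spec = synth.PopulationSpec(n_cells=80, snarc_fraction=1.0,
                                    fractions={"arith_hand_sim": 1.0})
        pop, _ = synth.simulate_population_spikes(spec, trials, seed=8)
        coders = roc.select_simultaneous_coders(pop, np.arange(80),
                                                n_perm=300, seed=8)
        traj = roc.roc_trajectories(pop)
        qt = roc.quadrant_fraction_timecourse(coders, traj)
        assert qt.summary[T.RIGHT]["series_p"] < 0.01
        assert qt.summary[T.LEFT]["series_p"] < 0.01
        overlap = qt.per_bin[(qt.per_bin["bin"].between(4, 16))
                             & qt.per_bin["p"].notna()]
        right = overlap[overlap["hand"] == T.RIGHT]["fraction_addition"]
        left = overlap[overlap["hand"] == T.LEFT]["fraction_addition"]
        assert (right > 0.5).all() and (left < 0.5).all()

    def test_uncoupled_population_stays_at_chance(self):
        trials = synth.balanced_decoding_trials(reps=15, seed=9)
        spec = synth.PopulationSpec(n_cells=80, snarc_fraction=0.0,
                                    fractions={"arith_hand_sim": 1.0})
        pop, _ = synth.simulate_population_spikes(spec, trials, seed=9)
        coders = roc.select_simultaneous_coders(pop, np.arange(80),
                                                n_perm=300, seed=9)
        traj = roc.roc_trajectories(pop)
        qt = roc.quadrant_fraction_timecourse(coders, traj)
        for hand in (T.RIGHT, T.LEFT):
            n_sig = qt.summary[hand]["significant_bins"]
            n = qt.summary[hand]["n_bins"]
            # within 99% binomial bounds of the 5% per-bin alpha
            from scipy import stats
            assert n_sig <= stats.binom.ppf(0.995, n, 0.05) + 1
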