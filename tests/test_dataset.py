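import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from dpsepsis.cohort import CohortConfig, generate_cohort
from dpsepsis.dataset import (
    ActionGrid,
    DegenerateGridError,
    SplitError,
    StateNormalizer,
    assign_rewards,
    build_transitions,
    discretize_action,
    fit_action_grid,
    flatten_action,
    split_cohort,
    stratify_sofa,
)


def _records_with_doses(iv, vp):
    cohort = generate_cohort(CohortConfig(n_patients=1, n_windows=len(iv), seed=0))
    r = cohort[0]
    r.iv_dose = np.asarray(iv, dtype=float)
    r.vp_dose = np.asarray(vp, dtype=float)
    return [r]


class TestActionGrid:
    def test_uniform_1_to_100_quartiles(self):
        # empirical quartiles of {1..100}: linear-interpolation values
        doses = np.arange(1.0, 101.0)
        recs = _records_with_doses(doses, doses)
        grid = fit_action_grid(recs)
        np.testing.assert_allclose(grid.iv_quartiles, [25.75, 50.5, 75.25])

    def test_identical_distributions_give_identical_cuts(self):
        doses = np.array([3.0, 9.0, 1.0, 7.0, 5.0, 0.0])
        grid = fit_action_grid(_records_with_doses(doses, doses))
        np.testing.assert_array_equal(grid.iv_quartiles, grid.vp_quartiles)

    def test_degenerate_doses_rejected(self):
        same = np.full(6, 2.5)
        with pytest.raises(DegenerateGridError):
            fit_action_grid(_records_with_doses(same, same))
        zero = np.zeros(6)
        with pytest.raises(DegenerateGridError):
            fit_action_grid(_records_with_doses(zero, zero))

    def test_cuts_must_increase(self):
        with pytest.raises(DegenerateGridError):
            ActionGrid(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestDiscretize:
    grid = ActionGrid(np.array([10.0, 20.0, 30.0]), np.array([0.1, 0.2, 0.3]))

    @pytest.mark.parametrize(
        "iv,vp,expected",
        [
            (0.0, 0.0, (0, 0)),          # no treatment
            (1e9, 1e9, (4, 4)),          # beyond the top quartile
            (10.0, 0.1, (1, 1)),         # on a cut point -> lower bin
            (10.5, 0.25, (2, 3)),
            (5.0, 0.05, (1, 1)),
        ],
    )
    def test_bins(self, iv, vp, expected):
        assert discretize_action(iv, vp, self.grid) == expected

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            discretize_action(-1.0, 0.0, self.grid)

    def test_flat_index(self):
        assert flatten_action(2, 3) == 13
        assert flatten_action(0, 0) == 0
        assert flatten_action(4, 4) == 24

    def test_training_bins_near_equally_populated(self, small_mdp):
        """Nonzero training doses land in bins 1..4 at ~25% each by
        construction of empirical quartiles."""
        ts = small_mdp["train"]
        for bins in (ts.iv_bins, ts.vp_bins):
            nz = bins[bins > 0]
            freq = np.bincount(nz, minlength=5)[1:] / nz.size
            np.testing.assert_allclose(freq, 0.25, atol=0.02)


class TestRewards:
    def _record(self, survived, n_windows=5):
        r = generate_cohort(CohortConfig(n_patients=1, n_windows=max(n_windows, 2), seed=0))[0]
        r.survived = survived
        if n_windows < r.n_windows:
            r.features = r.features[:n_windows]
        return r

    def test_terminal_only(self):
        r = assign_rewards(self._record(True, 5))
        np.testing.assert_array_equal(r, [0, 0, 0, 0, 15])
        r = assign_rewards(self._record(False, 5))
        np.testing.assert_array_equal(r, [0, 0, 0, 0, -15])

    def test_single_window(self):
        np.testing.assert_array_equal(assign_rewards(self._record(True, 1)), [15.0])


class TestSplit:
    def test_sizes_and_partition(self, small_cohort):
        cohort, _ = small_cohort
        train, test = split_cohort(cohort, 0.8, seed=0)
        assert len(train) == round(0.8 * len(cohort))
        assert len(train) + len(test) == len(cohort)
        train_ids = {r.patient_id for r in train}
        test_ids = {r.patient_id for r in test}
        assert not train_ids & test_ids

    def test_determinism_and_minimal_case(self, small_cohort):
        cohort, _ = small_cohort
        a1, _ = split_cohort(cohort, 0.8, seed=5)
        a2, _ = split_cohort(cohort, 0.8, seed=5)
        assert [r.patient_id for r in a1] == [r.patient_id for r in a2]
        t, s = split_cohort(cohort[:2], 0.5, seed=0)
        assert len(t) == 1 and len(s) == 1

    def test_errors(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(SplitError):
            split_cohort(cohort, 1.5, seed=0)
        with pytest.raises(SplitError):
            split_cohort(cohort[:1], 0.5, seed=0)


class TestStratify:
    @pytest.mark.parametrize(
        "sofa,stratum",
        [(0, "low"), (3, "low"), (4, "low"), (5, "medium"), (10, "medium"),
         (15, "medium"), (16, "high"), (24, "high")],
    )
    def test_strata(self, sofa, stratum):
        assert stratify_sofa(sofa) == stratum

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stratify_sofa(-1)


class TestBuildTransitions:
    def test_counts_and_reward_conservation(self, small_mdp):
        ts = small_mdp["train"]
        n_windows = sum(r.n_windows for r in small_mdp["train_records"])
        assert len(ts) == n_windows
        # exactly one terminal, |reward| = 15, per patient; zero elsewhere
        for pid in np.unique(ts.patient_ids.astype(str))[:20]:
            m = ts.patient_ids == pid
            assert ts.terminal[m].sum() == 1
            nz = ts.rewards[m][ts.rewards[m] != 0]
            assert nz.size == 1 and abs(nz[0]) == 15
        assert np.all(ts.rewards[~ts.terminal] == 0)

    def test_training_states_are_z_scored(self, small_mdp):
        X = small_mdp["train"].states
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0), 1, atol=1e-9)

    def test_unfit_normalizer_rejected(self, small_mdp):
        with pytest.raises(NotFittedError):
            build_transitions(small_mdp["train_records"], small_mdp["grid"], StateNormalizer())

    def test_csv_round_trip(self, tmp_path, small_mdp):
        ts = small_mdp["test"]
        path = tmp_path / "transitions.csv"
        ts.to_csv(path)
        from dpsepsis.dataset import TransitionSet

        back = TransitionSet.from_csv(path)
        np.testing.assert_allclose(back.states, ts.states, rtol=1e-12)
        np.testing.assert_array_equal(back.actions, ts.actions)
        np.testing.assert_array_equal(back.terminal, ts.terminal)

    def test_single_transition_view(self, small_mdp):
        ts = small_mdp["train"]
        t0 = ts[0]
        assert t0.action == flatten_action(t0.iv_bin, t0.vp_bin)
        assert not t0.terminal and t0.next_state is not None
        last = ts[int(np.flatnonzero(ts.terminal)[0])]
        assert last.terminal and last.next_state is None
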