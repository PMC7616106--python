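"""Linear z-score subtype model: trajectories, likelihood, fitting, assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cpfe_progression import simulate, sustain
from cpfe_progression.config import CohortConfig
from cpfe_progression.errors import ConfigurationError, ValidationError
from cpfe_progression.grouping import BIOMARKER_COLS

from oracles import naive_marginal_loglik, naive_trajectory


def tiny_zm(z_rows, grids, z_max=None):
    grids = tuple(np.asarray(g, dtype=float) for g in grids)
    names = tuple(f"b{i}" for i in range(len(grids)))
    if z_max is None:
        z_max = [g[-1] for g in grids]
    return sustain.ZScoreMatrix(np.atleast_2d(z_rows), names, grids, np.asarray(z_max, float))


class TestComputeZscores:
    def test_division_by_interobserver_sd(self):
        df = pd.DataFrame({c: [0.0] for c in BIOMARKER_COLS})
        df[BIOMARKER_COLS[0]] = 15.0
        sd_map = {c: 5.0 for c in BIOMARKER_COLS}
        zm = sustain.compute_zscores(df, sd_map)
        assert zm.z[0, 0] == pytest.approx(3.0)
        assert zm.z[0, 1] == 0.0

    def test_nonpositive_sd_rejected(self):
        df = pd.DataFrame({c: [1.0] for c in BIOMARKER_COLS})
        sd_map = {c: 5.0 for c in BIOMARKER_COLS}
        sd_map[BIOMARKER_COLS[3]] = 0.0
        with pytest.raises(ConfigurationError, match=BIOMARKER_COLS[3]):
            sustain.compute_zscores(df, sd_map)

    def test_default_grid_is_integer_up_to_q95(self, rng):
        df = pd.DataFrame(
            {c: rng.uniform(0, 12, 200) for c in BIOMARKER_COLS}
        )
        zm = sustain.compute_zscores(df, {c: 5.0 for c in BIOMARKER_COLS})
        for g, m in zip(zm.event_grids, zm.z_max):
            assert list(g) == list(range(1, int(m) + 1))


class TestRestrictToEmphysema:
    def test_zero_emphysema_subject_excluded(self, small_cohort):
        _, patients, _, _ = small_cohort
        patients = patients.copy()
        emph_cols = [c for c in BIOMARKER_COLS if c.startswith("emphysema")]
        patients.loc[patients.index[:5], emph_cols] = 0.0
        out = sustain.restrict_to_emphysema(patients, patients)
        assert not set(patients["subject_id"].iloc[:5]) & set(out["subject_id"])

    def test_all_emphysematous_is_identity(self, small_cohort):
        _, patients, _, _ = small_cohort
        pos = patients[(patients[[c for c in BIOMARKER_COLS if "emphysema" in c]] > 0).any(axis=1)]
        out = sustain.restrict_to_emphysema(pos, pos)
        assert len(out) == len(pos)

    def test_empty_cohort(self):
        empty = pd.DataFrame(columns=["subject_id"] + list(BIOMARKER_COLS))
        assert sustain.restrict_to_emphysema(empty, empty).empty


class TestTrajectory:
    def test_stage_zero_is_zero_everywhere(self, rng):
        zm = tiny_zm(np.zeros((1, 3)), [[1, 2], [1], [1, 2, 3]])
        order = sustain.random_valid_ordering(zm, rng)
        T = sustain.trajectory_matrix(zm, order)
        assert np.all(T[0] == 0.0)

    def test_anchor_points_hit_grid_values(self, rng):
        zm = tiny_zm(np.zeros((1, 3)), [[1, 2], [1], [1, 2, 3]])
        order = sustain.random_valid_ordering(zm, rng)
        T = sustain.trajectory_matrix(zm, order)
        for pos, ev in enumerate(order, start=1):
            b = zm.event_biomarker[ev]
            assert T[pos, b] == pytest.approx(zm.event_z[ev])

    def test_no_terminal_ramp_when_zmax_equals_last_grid(self):
        # single biomarker, events z=(1,2) at stages 1,2 of a 2-event sequence
        zm = tiny_zm(np.zeros((1, 1)), [[1, 2]], z_max=[2])
        assert sustain.trajectory_value(zm, np.array([0, 1]), 2, 0) == pytest.approx(2.0)
        assert sustain.trajectory_value(zm, np.array([0, 1]), 1, 0) == pytest.approx(1.0)

    def test_terminal_ramp_when_zmax_exceeds_last_grid(self):
        # two biomarkers so the last event need not sit at stage N
        zm = tiny_zm(np.zeros((1, 2)), [[1, 2], [1]], z_max=[3, 1])
        order = np.array([0, 1, 2])  # b0:z1, b0:z2 at stage 2, b1:z1 at stage 3
        T = sustain.trajectory_matrix(zm, order)
        assert T[2, 0] == pytest.approx(2.0)
        assert T[3, 0] == pytest.approx(3.0)  # ramp 2 -> z_max over stages 2..3

    def test_out_of_range_stage_rejected(self):
        zm = tiny_zm(np.zeros((1, 1)), [[1]])
        with pytest.raises(ValidationError):
            sustain.trajectory_value(zm, np.array([0]), 2, 0)

    def test_matches_naive_interpolation_oracle(self, rng):
        zm = tiny_zm(np.zeros((1, 3)), [[1, 2], [1, 2, 3], [1]], z_max=[4, 3, 2])
        for _ in range(10):
            order = sustain.random_valid_ordering(zm, rng)
            T = sustain.trajectory_matrix(zm, order)
            for k in range(zm.n_events + 1):
                expected = naive_trajectory(
                    order, zm.event_biomarker, zm.event_z, zm.z_max, 3, k
                )
                np.testing.assert_allclose(T[k], expected, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_stage(self, seed):
        rng = np.random.default_rng(seed)
        zm = tiny_zm(np.zeros((1, 4)), [[1, 2], [1], [1, 2, 3], [1, 2]], z_max=[3, 2, 3, 2])
        order = sustain.random_valid_ordering(zm, rng)
        T = sustain.trajectory_matrix(zm, order)
        assert np.all(np.diff(T, axis=0) >= -1e-12)


class TestSubjectLogLikelihood:
    def test_two_term_hand_enumeration(self):
        # 1 biomarker, 1 event at z=1, z_max=1, sigma=1, observation 0
        zm = tiny_zm([[0.0]], [[1]])
        ll = sustain.subject_log_likelihood(zm, np.array([0]), 1.0)
        expected = np.log(0.5 * (norm.pdf(0, 0, 1) + norm.pdf(0, 1, 1)))
        assert ll[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_oracle_on_random_data(self, rng):
        zm = tiny_zm(rng.uniform(0, 3, (6, 3)), [[1, 2], [1], [1, 2, 3]], z_max=[3, 2, 3])
        sigma = np.array([1.0, 0.7, 1.3])
        for _ in range(5):
            order = sustain.random_valid_ordering(zm, rng)
            got = sustain.subject_log_likelihood(zm, order, sigma)
            expected = naive_marginal_loglik(
                zm.z, order, zm.event_biomarker, zm.event_z, zm.z_max, sigma
            )
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_stage_posterior_concentrates_at_small_sigma(self):
        zm0 = tiny_zm(np.zeros((1, 2)), [[1, 2], [1]], z_max=[2, 1])
        order = np.array([0, 2, 1])
        k = 2
        obs = sustain.trajectory_matrix(zm0, order)[k]
        zm = tiny_zm(obs, [[1, 2], [1]], z_max=[2, 1])
        cache = sustain._LikelihoodCache(zm, np.full(2, 0.05))
        stage_ll = cache.stage_loglik(order)[0]
        post = np.exp(stage_ll - stage_ll.max())
        post /= post.sum()
        assert post.argmax() == k
        assert post[k] > 0.99

    def test_identical_rows_identical_loglik(self, rng):
        row = rng.uniform(0, 2, 3)
        zm = tiny_zm(np.vstack([row, row]), [[1], [1, 2], [1]])
        order = sustain.random_valid_ordering(zm, rng)
        ll = sustain.subject_log_likelihood(zm, order)
        assert ll[0] == ll[1]


class TestFitSustain:
    def test_noiseless_single_subtype_recovers_generating_order(self):
        cfg = CohortConfig(
            n_subjects=300, seed=5, subtype_fractions=(1.0,), z_noise_sd=0.0,
            z_max=1.0, non_cpfe_fraction=0.0,
        )
        patients, _, truth = simulate.generate_cohort(cfg)
        zm = sustain.compute_zscores(
            patients, cfg.biomarker_sd_map, z_max=[1.0] * 12
        )
        gen_order = simulate.default_event_orderings(cfg)[0]
        model = sustain.fit_sustain(zm, 1, n_startpoints=8, mcmc_iterations=1000, seed=0)
        assert sustain.ordering_kendall_tau(model.orderings[0], gen_order) == pytest.approx(1.0)

    def test_em_loglik_trace_is_monotone(self):
        cfg = CohortConfig(n_subjects=120, seed=6, z_max=1.0)
        patients, _, _ = simulate.generate_cohort(cfg)
        zm = sustain.compute_zscores(patients, cfg.biomarker_sd_map, z_max=[1.0] * 12)
        model = sustain.fit_sustain(
            zm, 2, n_startpoints=3, mcmc_iterations=0, seed=1, n_split_tries=1
        )
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_subjects=80, seed=8, z_max=1.0)
        patients, _, _ = simulate.generate_cohort(cfg)
        zm = sustain.compute_zscores(patients, cfg.biomarker_sd_map, z_max=[1.0] * 12)
        m1 = sustain.fit_sustain(zm, 2, n_startpoints=2, mcmc_iterations=300, seed=11, n_split_tries=1)
        m2 = sustain.fit_sustain(zm, 2, n_startpoints=2, mcmc_iterations=300, seed=11, n_split_tries=1)
        assert all(np.array_equal(a, b) for a, b in zip(m1.orderings, m2.orderings))
        np.testing.assert_array_equal(m1.fractions, m2.fractions)
        assert m1.log_likelihood == m2.log_likelihood

    def test_pure_noise_prefers_one_subtype_in_cv(self, rng):
        z = np.abs(rng.normal(0, 1, (90, 4)))
        zm = tiny_zm(z, [[1], [1], [1], [1]])
        chosen, table = sustain.select_n_subtypes(
            zm, (1, 2), n_folds=3, seed=4, n_startpoints=3, mcmc_iterations=0,
            n_split_tries=1, em_max_iter=10,
        )
        assert chosen == 1

    def test_select_single_candidate(self, rng):
        zm = tiny_zm(np.abs(rng.normal(0, 1, (20, 2))), [[1], [1]])
        chosen, _ = sustain.select_n_subtypes(zm, [1], n_folds=2, seed=0)
        assert chosen == 1


class TestAssign:
    def test_posterior_rows_sum_to_one(self, small_cohort):
        cfg, patients, _, _ = small_cohort
        zm = sustain.compute_zscores(
            patients.head(60), cfg.biomarker_sd_map, z_max=[2.0] * 12
        )
        model = sustain.fit_sustain(zm, 2, n_startpoints=2, mcmc_iterations=0, seed=2, n_split_tries=1)
        asn = sustain.assign(model, zm)
        np.testing.assert_allclose(asn.posterior.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_noiseless_subject_gets_map_subtype_and_stage(self):
        grids = [[1, 2], [1], [1, 2]]
        zm0 = tiny_zm(np.zeros((1, 3)), grids)
        o1 = np.array([0, 2, 1, 3, 4])
        o2 = np.array([4, 3, 2, 0, 1])
        k = 3
        obs = sustain.trajectory_matrix(zm0, o1)[k]
        zm = tiny_zm(obs, grids)
        model = sustain.SubtypeModel(
            n_subtypes=2, orderings=[o1, o2], fractions=np.array([0.5, 0.5]),
            sigma=np.full(3, 0.05), biomarkers=zm.biomarkers,
            event_grids=zm.event_grids, z_max=zm.z_max, log_likelihood=0.0,
        )
        asn = sustain.assign(model, zm)
        assert asn.table["map_subtype"].iloc[0] == 0
        assert asn.table["map_stage"].iloc[0] == k

    def test_degenerate_mixture_assigns_everyone_to_first(self, rng):
        grids = [[1], [1, 2]]
        zm = tiny_zm(np.abs(rng.normal(0, 1, (15, 2))), grids)
        o1 = sustain.random_valid_ordering(zm, rng)
        o2 = sustain.random_valid_ordering(zm, rng)
        model = sustain.SubtypeModel(
            n_subtypes=2, orderings=[o1, o2], fractions=np.array([1.0, 0.0]),
            sigma=np.ones(2), biomarkers=zm.biomarkers,
            event_grids=zm.event_grids, z_max=zm.z_max, log_likelihood=0.0,
        )
        asn = sustain.assign(model, zm)
        assert (asn.table["map_subtype"] == 0).all()


class TestOrderingHelpers:
    def test_random_orderings_are_valid(self, rng):
        zm = tiny_zm(np.zeros((1, 3)), [[1, 2, 3], [1], [1, 2]])
        for _ in range(50):
            assert sustain.is_valid_ordering(zm, sustain.random_valid_ordering(zm, rng))

    def test_kendall_tau_self_and_reverse(self, rng):
        zm = tiny_zm(np.zeros((1, 4)), [[1], [1], [1], [1]])
        o = sustain.random_valid_ordering(zm, rng)
        assert sustain.ordering_kendall_tau(o, o) == pytest.approx(1.0)
        assert sustain.ordering_kendall_tau(o, o[::-1]) == pytest.approx(-1.0)

    def test_label_permutation_accuracy(self):
        true = np.array([0, 0, 1, 1])
        pred = np.array([1, 1, 0, 0])
        acc, perm = sustain.best_label_permutation_accuracy(true, pred, 2)
        assert acc == 1.0 and perm == (1, 0)
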