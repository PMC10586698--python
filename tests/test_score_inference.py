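import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vodscore.score_inference import (
    CohortAlignment,
    ScoreMcmcConfig,
    ScorePosterior,
    align_cohorts,
    case_prior_mean,
    classify_status,
    hpd_interval,
    learn_scores,
    load_benchmark_scores,
    status_thresholds,
)


def _grid_posterior_mean_2d(d, cfg, side_sd, grid):
    """Independent dense-grid oracle for the 3-patient unnormalised posterior."""
    S2, S3 = np.meshgrid(grid, grid, indexing="ij")

    def ln(x, mu, sd):
        return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)

    lt = ln(d[0, 1], np.abs(S2 - 1), cfg.likelihood_sd)
    lt += ln(d[0, 2], np.abs(S3 - 1), cfg.likelihood_sd)
    lt += ln(S2, case_prior_mean(S2, S3, d[0, 1], d[0, 2], d[1, 2]), cfg.prior_sd)
    lt += ln(S3, case_prior_mean(S3, S2, d[0, 2], d[0, 1], d[2, 1]), cfg.prior_sd)
    lt += ln(S2, 1 + d[0, 1], side_sd) + ln(S3, 1 + d[0, 2], side_sd)
    w = np.exp(lt - lt.max())
    w /= w.sum()
    return float((w * S2).sum()), float((w * S3).sum())


class TestHpdInterval:
    def test_contains_required_mass(self, rng):
        draws = rng.standard_normal(4000)
        lo, hi = hpd_interval(draws)
        frac = np.mean((draws >= lo) & (draws <= hi))
        assert frac >= 0.95
        # roughly the central normal interval
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)

    def test_shortest_for_skewed_sample(self, rng):
        draws = rng.exponential(size=4000)
        lo, hi = hpd_interval(draws)
        assert lo < 0.05  # mass concentrated at zero

    def test_mean_inside_hpd(self, rng):
        draws = rng.gamma(2.0, size=2000)
        lo, hi = hpd_interval(draws)
        assert lo <= draws.mean() <= hi


class TestCasePriorMean:
    def test_both_above_comparator_closer(self):
        # s_j, s_i >= 1 with delta_1i < delta_1j -> mean = s_i + delta_ij
        assert case_prior_mean(1.6, 1.2, 0.6, 0.2, 0.4) == pytest.approx(1.6)

    def test_both_below_comparator_farther(self):
        # s_j, s_i < 1 with delta_1i > delta_1j -> mean = s_i + delta_ij
        assert case_prior_mean(0.8, 0.5, 0.2, 0.5, 0.3) == pytest.approx(0.8)

    def test_both_above_comparator_farther(self):
        # s_j, s_i >= 1 with delta_1i > delta_1j -> mean = s_i - delta_ij
        assert case_prior_mean(1.2, 1.6, 0.2, 0.6, 0.4) == pytest.approx(1.2)

    def test_zero_distance_same_side_gives_comparator(self):
        for sj, si in [(1.4, 1.4), (0.6, 0.6)]:
            assert case_prior_mean(sj, si, 0.4, 0.4, 0.0) == pytest.approx(si)

    def test_mixed_side_algebra(self):
        # s_j >= 1 > s_i with delta_1j > delta_1i: s_j = 2 - s_i + delta_ij
        assert case_prior_mean(1.7, 0.9, 0.7, 0.1, 0.6) == pytest.approx(2 - 0.9 + 0.6)
        # mirrored: s_j < 1 <= s_i with delta_1j > delta_1i: s_j = 2 - s_i - delta_ij
        assert case_prior_mean(0.3, 1.1, 0.7, 0.1, 0.6) == pytest.approx(2 - 1.1 - 0.6)

    @settings(max_examples=60, deadline=None)
    @given(
        st.floats(0.0, 0.9),
        st.floats(0.0, 0.9),
        st.booleans(),
        st.booleans(),
    )
    def test_consistent_configurations_are_fixed_points(self, d1j, d1i, above_j, above_i):
        """A score vector exactly consistent with the distances satisfies
        s_j == case_prior_mean(...) in every side combination."""
        s_j = 1 + d1j if above_j else 1 - d1j
        s_i = 1 + d1i if above_i else 1 - d1i
        if above_j == above_i:
            d_ij = abs(d1j - d1i)
        else:
            d_ij = abs(d1j - d1i)  # model: distance reflects |delta_1j - delta_1i|
        if abs(d1i - d1j) < 1e-9:
            return
        assert case_prior_mean(s_j, s_i, d1j, d1i, d_ij) == pytest.approx(s_j, abs=1e-9)


class TestLearnScores:
    def test_two_patients_zero_distance(self):
        d = np.zeros((2, 2))
        cfg = ScoreMcmcConfig(n_sweeps=6000, burn_in=1000, seed=0)
        post = learn_scores(d, reference=0, config=cfg)
        assert post.means[1] == pytest.approx(1.0, abs=0.05)

    def test_two_patients_half_distance_side_prior(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        cfg = ScoreMcmcConfig(n_sweeps=8000, burn_in=2000, seed=1, side_prior_sd=0.2)
        post = learn_scores(d, reference=0, config=cfg, side={1: +1})
        # grid oracle over the single free score
        grid = np.linspace(-2, 4, 4001)
        lt = (
            -0.5 * ((0.5 - np.abs(grid - 1)) / cfg.likelihood_sd) ** 2
            - 0.5 * ((grid - 1.5) / cfg.side_prior_sd) ** 2
        )
        w = np.exp(lt - lt.max())
        w /= w.sum()
        oracle = float((w * grid).sum())
        assert post.means[1] == pytest.approx(oracle, abs=0.05)
        assert post.means[1] == pytest.approx(1.5, abs=0.05)

    def test_three_patients_match_grid_oracle(self):
        d = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.3], [0.5, 0.3, 0.0]])
        cfg = ScoreMcmcConfig(n_sweeps=12000, burn_in=3000, seed=7, side_prior_sd=0.1)
        post = learn_scores(d, reference=0, config=cfg, side={1: +1, 2: +1}, init="above")
        m2, m3 = _grid_posterior_mean_2d(d, cfg, cfg.side_prior_sd, np.linspace(-1, 3, 801))
        assert post.means[1] == pytest.approx(m2, abs=0.05)
        assert post.means[2] == pytest.approx(m3, abs=0.05)
        assert post.means[1] == pytest.approx(1.2, abs=0.05)
        assert post.means[2] == pytest.approx(1.5, abs=0.05)

    def test_posterior_consistency_with_observed_distances(self):
        rng = np.random.default_rng(3)
        n = 6
        pos = np.sort(rng.uniform(0, 1.5, size=n))
        pos[0] = 0.0
        d = np.abs(pos[:, None] - pos[None, :])
        cfg = ScoreMcmcConfig(n_sweeps=6000, burn_in=2000, seed=5)
        post = learn_scores(d, reference=0, config=cfg, init="above")
        for j in range(1, n):
            draws = post.draws[:, j]
            se = draws.std() / np.sqrt(200)  # conservative ESS guess
            assert abs(np.abs(draws - 1).mean() - d[0, j]) < max(3 * se, 0.05)

    def test_reference_score_never_moves(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        post = learn_scores(d, reference=0, config=ScoreMcmcConfig(n_sweeps=500, burn_in=100, seed=0))
        np.testing.assert_array_equal(post.draws[:, 0], 1.0)
        assert post.means[0] == 1.0

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ScoreMcmcConfig(likelihood_sd=0.0)


def _single_patient_posterior(cohort, pid, mean, ref=True):
    return ScorePosterior(
        patient_ids=[pid],
        means=np.array([mean]),
        hpd_lower=np.array([np.nan]),
        hpd_upper=np.array([np.nan]),
        reference_index=0 if ref else -1,
    )


class TestAlignCohorts:
    def test_worked_example_cohort_one(self):
        posts = {
            "A": _single_patient_posterior("A", "refA", 1.0),
            "B": _single_patient_posterior("B", "refB", 1.0),
        }
        aligns = [
            CohortAlignment("B", "refB", 1.17, reference_more_severe=False),
        ]
        table, shifts = align_cohorts("A", aligns, posts)
        row = table[table["patient_id"] == "refB"].iloc[0]
        assert row["mean_score"] == pytest.approx(-0.17)
        assert shifts["B"] == pytest.approx(-1.17)

    def test_worked_example_cohort_three(self):
        posts = {
            "A": _single_patient_posterior("A", "refA", 1.0),
            "C": _single_patient_posterior("C", "refC", 1.0),
        }
        aligns = [CohortAlignment("C", "refC", 2.43, reference_more_severe=False)]
        table, shifts = align_cohorts("A", aligns, posts)
        row = table[table["patient_id"] == "refC"].iloc[0]
        assert row["mean_score"] == pytest.approx(-1.43)
        assert shifts["C"] == pytest.approx(-2.43)

    def test_zero_distance_is_identity(self):
        posts = {
            "A": _single_patient_posterior("A", "refA", 1.0),
            "B": _single_patient_posterior("B", "refB", 1.0),
        }
        table, shifts = align_cohorts(
            "A", [CohortAlignment("B", "refB", 0.0, True)], posts
        )
        assert shifts["B"] == 0.0
        assert table[table["patient_id"] == "refB"]["mean_score"].iloc[0] == 1.0

    def test_more_severe_shifts_up(self):
        posts = {
            "A": _single_patient_posterior("A", "refA", 1.0),
            "B": _single_patient_posterior("B", "refB", 1.0),
        }
        table, shifts = align_cohorts("A", [CohortAlignment("B", "refB", 0.8, True)], posts)
        assert shifts["B"] == pytest.approx(0.8)
        assert table[table["patient_id"] == "refB"]["mean_score"].iloc[0] == pytest.approx(1.8)

    def test_missing_ordering_is_an_error(self):
        posts = {
            "A": _single_patient_posterior("A", "refA", 1.0),
            "B": _single_patient_posterior("B", "refB", 1.0),
        }
        with pytest.raises(ValueError, match="severity ordering"):
            align_cohorts("A", [], posts)

    def test_shift_equivariance(self):
        post = ScorePosterior(
            patient_ids=["r", "p"],
            means=np.array([1.0, 1.6]),
            hpd_lower=np.array([np.nan, 1.4]),
            hpd_upper=np.array([np.nan, 1.8]),
            reference_index=0,
        )
        base = {"A": _single_patient_posterior("A", "refA", 1.0), "B": post}
        t1, _ = align_cohorts("A", [CohortAlignment("B", "r", 0.5, False)], base)
        shifted = ScorePosterior(
            patient_ids=["r", "p"],
            means=post.means + 0.3,
            hpd_lower=post.hpd_lower + 0.3,
            hpd_upper=post.hpd_upper + 0.3,
            reference_index=0,
        )
        t2, _ = align_cohorts(
            "A", [CohortAlignment("B", "r", 0.2, False)], {"A": base["A"], "B": shifted}
        )
        p1 = t1[t1["patient_id"] == "p"].iloc[0]["mean_score"]
        p2 = t2[t2["patient_id"] == "p"].iloc[0]["mean_score"]
        assert p2 == pytest.approx(p1 + 0.3 + 0.3)

    def test_reference_uncertainty_dropped(self):
        post = ScorePosterior(
            patient_ids=["r", "p"],
            means=np.array([1.0, 1.6]),
            hpd_lower=np.array([np.nan, 1.4]),
            hpd_upper=np.array([np.nan, 1.8]),
            reference_index=0,
        )
        table, _ = align_cohorts(
            "A",
            [CohortAlignment("B", "r", 0.5, False)],
            {"A": _single_patient_posterior("A", "refA", 1.0), "B": post},
        )
        ref_row = table[(table["cohort_id"] == "B") & table["is_reference"]].iloc[0]
        assert np.isnan(ref_row["hpd_lower"]) and np.isnan(ref_row["hpd_upper"])
        other = table[(table["cohort_id"] == "B") & ~table["is_reference"]].iloc[0]
        assert other["hpd_lower"] == pytest.approx(0.9)


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "mean,expected", [(0.11, "N"), (0.44, "Y"), (-2.32, "N"), (0.111, "Y")]
    )
    def test_mean_cutoff(self, mean, expected):
        assert classify_status(mean) == expected

    def test_uncertainty_mode(self):
        assert classify_status(0.11, upper_hpd=0.31, use_uncertainty=True) == "N"
        assert classify_status(0.11, upper_hpd=0.32, use_uncertainty=True) == "Y"
        assert classify_status(0.5, upper_hpd=None, use_uncertainty=True) == "Y"


class TestBenchmarkTable:
    def test_shape_and_status_counts(self):
        table = load_benchmark_scores()
        assert len(table) == 25
        assert set(table["status"]) == {"Y", "N"}
        assert table["hpd_upper"].isna().sum() == 3  # two cohort refs + universal ref

    def test_thresholds(self):
        mean_cut, upper_cut = status_thresholds(load_benchmark_scores())
        assert mean_cut == 0.11
        assert upper_cut == 0.31

    def test_thresholds_separate_statuses(self):
        table = load_benchmark_scores()
        mean_cut, _ = status_thresholds(table)
        predicted = [classify_status(m, mean_cutoff=mean_cut) for m in table["mean_score"]]
        assert list(table["status"]) == predicted
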