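"""Dictionary building, KS scoring, windowing and day inference."""

import numpy as np
import pytest

from vped.config import PORE_FEATURES
from vped.dating import (CycleDayDictionary, DayProbabilityProfile,
                         build_dictionary, day_confusion_matrix,
                         day_error_estimate, infer_day, score_sample,
                         tophat_convolve)
from vped.ensembles import build_empirical
from vped.synthetic import sample_features


@pytest.fixture(scope="module")
def dictionary():
    samples = {d: [sample_features(d, 2000, seed=300 + d)]
               for d in range(15, 29)}
    return build_dictionary(samples)


def sample_dists(day, n, seed):
    fs = sample_features(day, n, seed=seed)
    return {f: build_empirical(fs.loc[fs[f].notna(), f].to_numpy(), feature=f)
            for f in PORE_FEATURES}


class TestBuildDictionary:
    def test_single_day_cohort(self):
        d = build_dictionary({20: [sample_features(20, 100, seed=1)]})
        assert list(d.days) == [20]

    def test_missing_day_flagged(self):
        samples = {d: [sample_features(d, 60, seed=d)] for d in (15, 16, 18)}
        d = build_dictionary(samples)
        assert 17 in d.missing_days
        assert 17 not in d.days

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            build_dictionary({})

    def test_pooled_cpdf_matches_generator(self, dictionary, trajectories):
        """Pooled per-day cPDF stays inside the KS band of the generating
        Weibull cPDF."""
        from scipy import stats
        from vped.ensembles import weibull_cdf
        for day in (15, 21, 28):
            params = trajectories.params(day, "pore_area")
            vals = dictionary.distribution(day, "pore_area").values
            res = stats.kstest(vals, lambda v: weibull_cdf(v, params))
            assert res.pvalue > 0.01

    def test_json_round_trip(self, dictionary):
        again = CycleDayDictionary.from_json(dictionary.to_json())
        assert list(again.days) == list(dictionary.days)
        d0 = dictionary.distribution(20, "pore_area")
        d1 = again.distribution(20, "pore_area")
        np.testing.assert_allclose(d0.values, d1.values)


class TestScoreSample:
    def test_self_sample_scores_one(self, dictionary):
        sample = {f: dictionary.distribution(20, f) for f in PORE_FEATURES}
        prof = score_sample(sample, dictionary)
        assert prof.scores[list(dictionary.days).index(20)] == pytest.approx(1.0)

    def test_disjoint_sample_scores_near_zero(self, dictionary):
        sample = {f: build_empirical(np.linspace(1e6, 2e6, 50), feature=f)
                  for f in PORE_FEATURES}
        prof = score_sample(sample, dictionary)
        assert prof.scores.max() < 1e-6

    def test_missing_feature_raises(self, dictionary):
        with pytest.raises(ValueError, match="pore_tortuosity"):
            score_sample({"pore_area": build_empirical([1.0, 2.0])}, dictionary)

    def test_day_recovery_majority(self, dictionary):
        """Argmax of the raw profile lands within one day of the truth for
        most fresh synthetic samples."""
        hits = 0
        for trial in range(25):
            prof = score_sample(sample_dists(21, 300, 900 + trial), dictionary)
            hits += abs(prof.days[np.argmax(prof.scores)] - 21) <= 1
        assert hits >= 20


class TestTophat:
    def days(self):
        return np.arange(15, 29)

    def test_delta_becomes_plateau(self):
        scores = np.zeros(14)
        scores[5] = 1.0                        # day 20
        prof = DayProbabilityProfile(self.days(), scores)
        out = tophat_convolve(prof)
        inside = out.scores[3:8]
        assert np.allclose(inside, inside[0])
        assert np.allclose(out.scores[np.r_[0:3, 8:14]], 0.0)
        assert out.scores.sum() == pytest.approx(1.0)

    def test_uniform_fixed_point(self):
        prof = DayProbabilityProfile(self.days(), np.ones(14))
        out = tophat_convolve(prof)
        assert np.allclose(out.scores, 1 / 14)

    def test_edge_delta_renormalized(self):
        scores = np.zeros(14)
        scores[-1] = 1.0                       # day 28
        out = tophat_convolve(DayProbabilityProfile(self.days(), scores))
        # windows centred at 26, 27, 28 see the delta over 5, 4, 3 days
        expect = np.array([1 / 5, 1 / 4, 1 / 3])
        expect = expect / expect.sum()
        assert out.scores[-3:] == pytest.approx(expect)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            tophat_convolve(DayProbabilityProfile(self.days(), np.ones(14)),
                            width_days=4)

    def test_symmetric_peak_not_moved(self):
        scores = np.exp(-0.5 * ((np.arange(14) - 6.0) / 2.0) ** 2)
        out = tophat_convolve(DayProbabilityProfile(self.days(), scores))
        assert np.argmax(out.scores) == 6


class TestInferDay:
    def test_peak_selection(self):
        scores = np.zeros(14)
        scores[5] = 1.0
        est = infer_day(DayProbabilityProfile(np.arange(15, 29), scores))
        assert est.day == 20

    def test_tie_break_deterministic(self):
        scores = np.zeros(14)
        scores[5] = scores[6] = 1.0           # days 20 and 21
        est1 = infer_day(DayProbabilityProfile(np.arange(15, 29), scores))
        est2 = infer_day(DayProbabilityProfile(np.arange(15, 29), scores))
        assert est1.day == est2.day
        assert est1.day in (20, 21)

    def test_monotone_profile_picks_last_day(self):
        scores = np.linspace(0.1, 1.0, 14)
        est = infer_day(DayProbabilityProfile(np.arange(15, 29), scores))
        assert est.day == 28

    def test_all_zero_unclassifiable(self):
        with pytest.raises(ValueError, match="nclassifiable"):
            infer_day(DayProbabilityProfile(np.arange(15, 29), np.zeros(14)))


class TestConfusionMatrix:
    def test_unit_diagonal_and_symmetry_presmoothing(self, dictionary):
        M = day_confusion_matrix(dictionary, smooth=False)
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M, M.T)

    def test_off_diagonal_decay(self, dictionary):
        M = day_confusion_matrix(dictionary)
        n = M.shape[0]
        far = [M[i, j] for i in range(n) for j in range(n) if abs(i - j) >= 3]
        assert np.max(far) < 0.1 * 1.0         # rows normalised to max 1

    def test_error_estimate_shapes(self, dictionary):
        M = day_confusion_matrix(dictionary)
        for i in range(M.shape[0]):
            lo, hi = day_error_estimate(M, i)
            assert lo >= 0 and hi >= 0
            assert lo <= 1.0 and hi <= 1.0     # sharp synthetic dictionary

    def test_identity_matrix_zero_error(self):
        assert day_error_estimate(np.eye(5), 2) == (0.0, 0.0)

    def test_uniform_matrix_spans_range(self):
        lo, hi = day_error_estimate(np.ones((5, 5)), 2)
        assert (lo, hi) == (2.0, 2.0)


class TestSelfRetrieval:
    def test_every_day_retrieves_itself(self, dictionary):
        """A pooled dictionary sample is dated to its own day with raw score
        1.0 there, for every supported day."""
        for day in dictionary.days:
            sample = {f: dictionary.distribution(day, f)
                      for f in PORE_FEATURES}
            prof = score_sample(sample, dictionary)
            i = list(dictionary.days).index(day)
            assert prof.scores[i] == pytest.approx(1.0)
            assert np.argmax(prof.scores) == i
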