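"""Score binning, intersection-point thresholds, bin probabilities and
physicochemical / combined models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from bsepscreen.labels import (HIGHER_IS_INHIBITOR, INHIBITOR, LOWER_IS_INHIBITOR,
                               NON_INHIBITOR)
from bsepscreen.metrics import confusion, gmean
from bsepscreen.score_models import (CombinedScoreClassifier, DegenerateFeatureError,
                                     IntersectionClassifier, NoIntersectionError,
                                     ScoreTable, ThresholdClassifier, aggregate_poses,
                                     bin_probability_table, bin_scores,
                                     classify_by_threshold, combined_score,
                                     find_intersection, fit_property_threshold,
                                     physchem_rule)
from bsepscreen.synthetic import GeneratorConfig, bayes_optimal_metrics, generate


def two_gaussians(rng, n, m_inh, s_inh, m_non, s_non):
    scores = np.concatenate([rng.normal(m_inh, s_inh, n), rng.normal(m_non, s_non, n)])
    labels = np.array([INHIBITOR] * n + [NON_INHIBITOR] * n, dtype=object)
    return scores, labels


class TestBinning:
    def test_scores_in_one_bin(self):
        b = bin_scores([35.1, 37.2, 39.9], [INHIBITOR, INHIBITOR, NON_INHIBITOR],
                       bin_width=5, anchor=0)
        assert b.n_bins == 1
        assert (b.bin_edges[0], b.bin_edges[1]) == (35.0, 40.0)
        assert b.counts[INHIBITOR][0] == 2 and b.counts[NON_INHIBITOR][0] == 1

    def test_huge_width_single_bin(self, rng):
        scores, labels = two_gaussians(rng, 50, 40, 2, 25, 2)
        b = bin_scores(scores, labels, bin_width=1e6)
        assert b.n_bins == 1

    def test_counts_conserved_and_freqs_normalized(self, rng):
        scores, labels = two_gaussians(rng, 200, 5, 2, 0, 2)
        b = bin_scores(scores, labels, bin_width=0.5)
        assert b.counts[INHIBITOR].sum() == 200
        assert b.counts[NON_INHIBITOR].sum() == 200
        assert b.rel_freq[INHIBITOR].sum() == pytest.approx(1.0, abs=1e-12)
        assert b.rel_freq[NON_INHIBITOR].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_class_named_in_error(self):
        with pytest.raises(ValueError, match="non-inhibitor"):
            bin_scores([1.0, 2.0], [INHIBITOR, INHIBITOR], bin_width=1)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            bin_scores([1.0], [INHIBITOR], bin_width=0)


class TestIntersection:
    def test_equal_variance_gaussians_recover_midpoint(self, rng):
        scores, labels = two_gaussians(rng, 20000, 2.0, 1.0, 0.0, 1.0)
        clf = find_intersection(bin_scores(scores, labels, 0.25), scores, labels)
        assert clf.threshold == pytest.approx(1.0, abs=0.1)
        assert clf.provenance == "intersection_point"

    def test_translation_equivariance(self, rng):
        scores, labels = two_gaussians(rng, 2000, 2.0, 1.0, 0.0, 1.0)
        t0 = find_intersection(bin_scores(scores, labels, 0.25), scores, labels).threshold
        shift = 13.7
        t1 = find_intersection(bin_scores(scores + shift, labels, 0.25),
                               scores + shift, labels).threshold
        assert t1 - t0 == pytest.approx(shift, abs=0.25)

    def test_identical_distributions_error_carries_curves(self):
        scores = np.array([1.0, 2.0, 3.0] * 2)
        labels = [INHIBITOR] * 3 + [NON_INHIBITOR] * 3
        with pytest.raises(NoIntersectionError) as exc:
            find_intersection(bin_scores(scores, labels, 1.0), scores, labels)
        assert exc.value.freq_inhibitor is not None

    def test_perfectly_separated_error(self):
        scores = np.array([10.0, 11.0, 0.0, 1.0])
        labels = [INHIBITOR, INHIBITOR, NON_INHIBITOR, NON_INHIBITOR]
        with pytest.raises(NoIntersectionError):
            find_intersection(bin_scores(scores, labels, 1.0), scores, labels)

    def test_orientation_coherence(self, rng):
        """Negating scores and flipping orientation yields identical labels."""
        scores, labels = two_gaussians(rng, 3000, 2.0, 1.0, 0.0, 1.2)
        hi = IntersectionClassifier(bin_width=0.25).fit(scores, labels)
        lo = IntersectionClassifier(bin_width=0.25,
                                    orientation=LOWER_IS_INHIBITOR).fit(-scores, labels)
        assert np.array_equal(hi.predict(scores), lo.predict(-scores))
        assert lo.threshold_ == pytest.approx(-hi.threshold_, abs=1e-9)


class TestThresholdClassification:
    def test_chemscore_style_threshold(self):
        clf = ThresholdClassifier(29.50, HIGHER_IS_INHIBITOR, "fixed", "ChemScore")
        assert classify_by_threshold([35.0], clf)[0] == INHIBITOR
        assert classify_by_threshold([20.0], clf)[0] == NON_INHIBITOR

    def test_glide_style_threshold(self):
        clf = ThresholdClassifier(-6.80, LOWER_IS_INHIBITOR, "fixed", "GlideXP")
        assert classify_by_threshold([-9.0], clf)[0] == INHIBITOR
        assert classify_by_threshold([-5.0], clf)[0] == NON_INHIBITOR

    def test_boundary_score_is_inhibitor(self):
        clf = ThresholdClassifier(29.50, HIGHER_IS_INHIBITOR)
        assert classify_by_threshold([29.50], clf)[0] == INHIBITOR

    def test_missing_scores_become_unpredicted(self):
        clf = ThresholdClassifier(0.0)
        out = classify_by_threshold([1.0, np.nan], clf)
        assert list(out) == [INHIBITOR, "unpredicted"]

    def test_json_round_trip(self, tmp_path):
        clf = ThresholdClassifier(6.15, HIGHER_IS_INHIBITOR, "intersection_point", "XScore")
        p = tmp_path / "model.json"
        clf.to_json(p)
        assert ThresholdClassifier.from_json(p) == clf


class TestBinProbability:
    def test_simple_probability(self):
        scores = [1.0] * 10 + [5.0] * 10
        labels = ([INHIBITOR] * 9 + [NON_INHIBITOR]) + ([INHIBITOR] + [NON_INHIBITOR] * 9)
        table = bin_probability_table(bin_scores(scores, labels, 2.0))
        assert table.loc[0, "p_inhibitor"] == pytest.approx(0.9)

    def test_chi_square_against_scipy_oracle(self):
        # 2x2 table [[20,5],[10,25]]: chi2 = 60*450^2/(25*35*30*30) = 15.4286
        scores = [1.0] * 25 + [5.0] * 35
        labels = ([INHIBITOR] * 20 + [NON_INHIBITOR] * 5
                  + [INHIBITOR] * 10 + [NON_INHIBITOR] * 25)
        table = bin_probability_table(bin_scores(scores, labels, 2.0))
        expected_chi2, expected_p, _, _ = chi2_contingency(
            [[20, 5], [10, 25]], correction=False)
        assert table.loc[0, "chi2"] == pytest.approx(expected_chi2)
        assert table.loc[0, "chi2"] == pytest.approx(15.428571, abs=1e-5)
        assert table.loc[0, "p_value"] == pytest.approx(expected_p)

    def test_single_bin_gives_prior_and_p_one(self):
        scores = [1.0, 1.2, 1.4, 1.6]
        labels = [INHIBITOR, INHIBITOR, INHIBITOR, NON_INHIBITOR]
        table = bin_probability_table(bin_scores(scores, labels, 10.0))
        assert len(table) == 1
        assert table.loc[0, "p_inhibitor"] == pytest.approx(0.75)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_bin_missing_probability(self):
        scores = [0.5, 4.5, 0.6, 4.6]
        labels = [INHIBITOR, INHIBITOR, NON_INHIBITOR, NON_INHIBITOR]
        table = bin_probability_table(bin_scores(scores, labels, 1.0))
        middle = table[(table["n_inhibitor"] == 0) & (table["n_non_inhibitor"] == 0)]
        assert len(middle) > 0
        assert middle["p_inhibitor"].isna().all()
        assert (middle["p_value"] == 1.0).all()

    def test_most_significant_bin_on_separated_data(self, rng):
        scores, labels = two_gaussians(rng, 500, 8.0, 1.0, 0.0, 1.0)
        table = bin_probability_table(bin_scores(scores, labels, 1.0))
        prior = 0.5
        best = table.loc[table["p_value"].idxmin()]
        occupied = table.dropna(subset=["p_inhibitor"])
        max_contrast = (occupied["p_inhibitor"] - prior).abs().max()
        assert abs(best["p_inhibitor"] - prior) == pytest.approx(max_contrast, abs=0.2)


class TestPhyschemRule:
    @pytest.mark.parametrize("mw, logp, expected", [
        (450.70, 9.05, INHIBITOR),       # phytomenadione
        (274.0, 2.74, NON_INHIBITOR),    # ebselen
        (333.38, 1.74, NON_INHIBITOR),   # benzylpenicillin
        (390.0, 0.0, INHIBITOR),         # inclusive MW boundary
        (100.0, 3.6, INHIBITOR),         # inclusive logP boundary
        (389.99, 3.59, NON_INHIBITOR),
    ])
    def test_or_rule(self, mw, logp, expected):
        assert physchem_rule(mw, logp) == expected

    def test_vectorized(self):
        out = physchem_rule([400.0, 100.0], [0.0, 0.0])
        assert list(out) == [INHIBITOR, NON_INHIBITOR]


class TestPropertyThreshold:
    def test_mw_like_recovery(self, rng):
        values = np.concatenate([rng.normal(480, 80, 5000), rng.normal(300, 80, 5000)])
        labels = np.array([INHIBITOR] * 5000 + [NON_INHIBITOR] * 5000, dtype=object)
        clf = fit_property_threshold(values, labels)
        assert clf.threshold == pytest.approx(390, abs=15)

    def test_constant_values_error(self):
        with pytest.raises(NoIntersectionError):
            fit_property_threshold([5.0] * 10,
                                   [INHIBITOR] * 5 + [NON_INHIBITOR] * 5)

    def test_gmean_near_analytic_optimum(self, rng):
        cfg = GeneratorConfig(
            n_inhibitors=5000, n_non_inhibitors=5000, seed=3,
            score_params={"ChemScore": {INHIBITOR: (480.0, 80.0),
                                        NON_INHIBITOR: (300.0, 80.0)}})
        oracle = bayes_optimal_metrics(cfg, "ChemScore")
        values = np.concatenate([rng.normal(480, 80, 5000), rng.normal(300, 80, 5000)])
        labels = np.array([INHIBITOR] * 5000 + [NON_INHIBITOR] * 5000, dtype=object)
        clf = fit_property_threshold(values, labels)
        cm = confusion(clf.classify(values), labels)
        assert gmean(cm) >= oracle["gmean"] - 0.02


class TestCombinedModel:
    RANGES = {"score": (0.0, 10.0), "mw": (100.0, 600.0), "logp": (-2.0, 8.0)}

    def test_extremes_map_to_zero_and_one(self):
        assert combined_score(0.0, 100.0, -2.0, self.RANGES) == pytest.approx(0.0)
        assert combined_score(10.0, 600.0, 8.0, self.RANGES) == pytest.approx(1.0)

    def test_degenerate_range_error(self):
        bad = dict(self.RANGES, mw=(300.0, 300.0))
        with pytest.raises(DegenerateFeatureError):
            combined_score(5.0, 300.0, 2.0, bad)

    def test_combining_weak_features_not_materially_worse(self, rng):
        # three independent features, each separating classes at d' = 1
        n = 4000
        labels = np.array([INHIBITOR] * n + [NON_INHIBITOR] * n, dtype=object)
        feats = [np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
                 for _ in range(3)]
        X = np.column_stack(feats)
        combined = CombinedScoreClassifier(bin_width=0.02).fit(X, labels)
        g_combined = gmean(confusion(combined.predict(X), labels))
        for i in range(3):
            single = IntersectionClassifier(bin_width=0.1).fit(X[:, i], labels)
            g_single = gmean(confusion(single.predict(X[:, i]), labels))
            assert g_combined >= g_single - 0.02

    def test_lower_orientation_score_handled(self, rng):
        n = 2000
        labels = np.array([INHIBITOR] * n + [NON_INHIBITOR] * n, dtype=object)
        score = np.concatenate([rng.normal(-8.5, 1.5, n), rng.normal(-5.5, 1.5, n)])
        mw = np.concatenate([rng.normal(480, 80, n), rng.normal(300, 80, n)])
        logp = np.concatenate([rng.normal(4.6, 1.5, n), rng.normal(2.6, 1.5, n)])
        X = np.column_stack([score, mw, logp])
        clf = CombinedScoreClassifier(orientation=LOWER_IS_INHIBITOR).fit(X, labels)
        cm = confusion(clf.predict(X), labels)
        assert gmean(cm) > 0.75


class TestPoseAggregation:
    def make_table(self, rows, orientations):
        return ScoreTable(pd.DataFrame(rows, columns=["compound_id",
                                                      "scoring_function", "score"]),
                          orientations)

    def test_best_of_higher(self):
        t = self.make_table([("s1", "ChemScore", 30.0), ("s2", "ChemScore", 35.0)],
                            {"ChemScore": HIGHER_IS_INHIBITOR})
        out = aggregate_poses(t, {"s1": "parent", "s2": "parent"})
        assert out.scores_for("ChemScore")["parent"] == 35.0

    def test_best_of_lower(self):
        t = self.make_table([("s1", "GlideXP", -5.0), ("s2", "GlideXP", -8.0)],
                            {"GlideXP": LOWER_IS_INHIBITOR})
        out = aggregate_poses(t, {"s1": "p", "s2": "p"})
        assert out.scores_for("GlideXP")["p"] == -8.0

    def test_identity_for_single_structures(self):
        t = self.make_table([("a", "ChemScore", 1.0), ("b", "ChemScore", 2.0)],
                            {"ChemScore": HIGHER_IS_INHIBITOR})
        out = aggregate_poses(t, {"a": "a", "b": "b"})
        assert dict(out.scores_for("ChemScore")) == {"a": 1.0, "b": 2.0}

    def test_orphan_structure_raises(self):
        t = self.make_table([("a", "ChemScore", 1.0)], {"ChemScore": HIGHER_IS_INHIBITOR})
        with pytest.raises(KeyError):
            aggregate_poses(t, {})


def test_score_table_requires_orientations():
    frame = pd.DataFrame({"compound_id": ["a"], "scoring_function": ["Mystery"],
                          "score": [1.0]})
    with pytest.raises(ValueError, match="orientation"):
        ScoreTable(frame, {})
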