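import numpy as np
import pytest
from scipy import special, stats

from helixcov.annotations import HelixAnnotation, Segment
from helixcov.detector import (
    PatternTemplate, StrengthDistributions, build_pattern_template,
    predict_all_pairs, raw_window_probability, scan_helix_pair,
)
from helixcov.synth import PlantedInteraction, PlantedTopology, gen_coupling_matrix


class TestPatternTemplate:
    def test_default_cell_count(self):
        tpl = build_pattern_template()
        assert tpl.size == 17
        assert tpl.n_cells == 289

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            build_pattern_template(size=16)

    def test_antiparallel_is_row_reversed_parallel(self):
        tpl = build_pattern_template(size=11)
        np.testing.assert_array_equal(
            tpl.weights_antiparallel, tpl.weights_parallel[::-1]
        )

    def test_ridge_recurrence_spacing(self):
        # maxima along the centre row recur every 3 or 4 cells (period 3.5)
        tpl = build_pattern_template()
        row = tpl.weights_parallel[tpl.size // 2]
        # local maxima with plateau runs merged (the half-integer period
        # makes neighbouring cells tie exactly)
        peaks = []
        j = 1
        while j < tpl.size - 1:
            if row[j] > 0 and row[j] >= row[j - 1]:
                k = j
                while k + 1 < tpl.size and row[k + 1] == row[j]:
                    k += 1
                if k + 1 >= tpl.size or row[j] >= row[k + 1]:
                    peaks.append(j)
                j = k + 1
            else:
                j += 1
        spacings = np.diff(peaks)
        assert len(spacings) > 0
        assert set(spacings) <= {3, 4}

    def test_weights_normalised(self):
        tpl = build_pattern_template()
        assert np.abs(tpl.weights_parallel).sum() == pytest.approx(1.0)

    def test_inconsistent_grids_rejected(self):
        w = np.ones((5, 5)) / 25
        bad = w.copy()
        bad[0, 0] = 0.5
        with pytest.raises(ValueError):
            PatternTemplate(5, 3.5, w, bad)


class TestRawWindowProbability:
    def test_identical_distributions_return_prior(self):
        tpl = build_pattern_template(size=5)
        dists = StrengthDistributions(2.0, 0.1, 2.0, 0.1, prior=0.37)
        window = np.random.default_rng(0).gamma(2.0, 0.1, size=(5, 5))
        assert raw_window_probability(window, tpl, dists, "parallel") == \
            pytest.approx(0.37, abs=1e-12)

    def test_longhand_bayes_oracle_3x3(self):
        """Hand-picked 3x3 weights: output equals an independent longhand
        Bayes computation to 1e-12."""
        w = np.array([[0.2, -0.1, 0.05], [0.0, 0.4, -0.05], [0.1, 0.0, 0.3]])
        tpl = PatternTemplate(3, 3.5, w, w[::-1].copy())
        dists = StrengthDistributions(4.0, 0.1, 1.0, 0.05, prior=0.25)
        window = np.array([[0.40, 0.06, 0.11], [0.05, 0.52, 0.08],
                           [0.30, 0.07, 0.44]])
        got = raw_window_probability(window, tpl, dists, "parallel")
        # longhand: per-cell log-likelihood ratios via scipy gamma densities
        fg = stats.gamma(4.0, scale=0.1)
        bg = stats.gamma(1.0, scale=0.05)
        logit = np.log(0.25 / 0.75)
        for i in range(3):
            for j in range(3):
                s = window[i, j]
                logit += w[i, j] * (fg.logpdf(s) - bg.logpdf(s))
        expected = 1.0 / (1.0 + np.exp(-logit))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_saturated_foreground_window(self):
        # all cells at the fg mode of well-separated densities
        tpl = build_pattern_template(size=5)
        dists = StrengthDistributions(6.0, 0.2, 1.0, 0.05, prior=0.3)
        mode = (6.0 - 1.0) * 0.2
        window = np.full((5, 5), mode)
        assert raw_window_probability(window, tpl, dists, "parallel") > 0.99

    def test_nonfinite_window_rejected(self):
        tpl = build_pattern_template(size=5)
        dists = StrengthDistributions(4.0, 0.1, 1.0, 0.05, prior=0.3)
        window = np.full((5, 5), np.nan)
        with pytest.raises(ValueError):
            raw_window_probability(window, tpl, dists, "parallel")

    def test_wrong_shape_rejected(self):
        tpl = build_pattern_template(size=5)
        dists = StrengthDistributions(4.0, 0.1, 1.0, 0.05, prior=0.3)
        with pytest.raises(ValueError):
            raw_window_probability(np.zeros((3, 3)), tpl, dists, "parallel")


def two_helix_case(orientation, register, seed=3, signal=3.0):
    segments = [
        Segment("A", 1, 20, "TM", "membrane", "cytoplasmic"),
        Segment("B", 26, 45, "TM", "membrane", "periplasmic"),
    ]
    pt = PlantedTopology(
        segments=segments,
        interactions=[PlantedInteraction("A", "B", orientation, register)],
        signal=signal, seed=seed,
    )
    return pt, gen_coupling_matrix(pt)


class TestScanHelixPair:
    def test_planted_antidiagonal_stripe_detected(
        self, default_template, default_dists
    ):
        register = 2
        pt, cm = two_helix_case("antiparallel", register)
        pred = scan_helix_pair(cm, pt.annotation, ("A", "B"),
                               default_template, default_dists)
        assert pred.orientation == "antiparallel"
        # best offset lies on the planted stripe: j_rel = n_b - 1 - reg - i_rel
        i_rel = pred.best_offset[0] - 1
        j_rel = pred.best_offset[1] - 26
        assert abs(j_rel - (20 - 1 - register - i_rel)) <= 1

    def test_planted_parallel_stripe_detected(
        self, default_template, default_dists
    ):
        pt, cm = two_helix_case("parallel", 1)
        pred = scan_helix_pair(cm, pt.annotation, ("A", "B"),
                               default_template, default_dists)
        assert pred.orientation == "parallel"

    def test_all_zero_matrix_scores_at_most_prior(
        self, default_template, default_dists
    ):
        segments = [
            Segment("A", 1, 20, "TM", "membrane", "cytoplasmic"),
            Segment("B", 26, 45, "TM", "membrane", "periplasmic"),
        ]
        ha = HelixAnnotation(segments)
        from helixcov.couplings import CouplingMatrix
        cm = CouplingMatrix(np.zeros((45, 45)), ref_map=np.arange(1, 46))
        pred = scan_helix_pair(cm, ha, ("A", "B"),
                               default_template, default_dists)
        assert pred.raw_score <= default_dists.prior

    def test_locality_unrelated_regions_ignored(
        self, default_template, default_dists
    ):
        pt, cm = two_helix_case("parallel", 0)
        pred1 = scan_helix_pair(cm, pt.annotation, ("A", "B"),
                                default_template, default_dists)
        # perturb couplings outside both helices (loop region 21..25)
        m = cm.strengths.copy()
        m[20:25, 20:25] = 0.9
        m[np.diag_indices(45)] = 0.0
        m = (m + m.T) / 2
        from helixcov.couplings import CouplingMatrix
        pred2 = scan_helix_pair(CouplingMatrix(m, ref_map=cm.ref_map),
                                pt.annotation, ("A", "B"),
                                default_template, default_dists)
        assert pred2.raw_score == pred1.raw_score

    def test_identical_helices_rejected(self, default_template, default_dists):
        pt, cm = two_helix_case("parallel", 0)
        with pytest.raises(ValueError):
            scan_helix_pair(cm, pt.annotation, ("A", "A"),
                            default_template, default_dists)

    def test_raw_score_monotone_in_positive_weight_cell(
        self, default_template, default_dists
    ):
        """Increasing a coupling under a positive-weight cell at the best
        offset never decreases the raw score."""
        pt, cm = two_helix_case("parallel", 0)
        pred = scan_helix_pair(cm, pt.annotation, ("A", "B"),
                               default_template, default_dists)
        i, j = pred.best_offset  # centre cell has the ridge maximum
        m = cm.strengths.copy()
        ii, jj = i - 1, j - 1  # ref numbering starts at 1
        m[ii, jj] = m[jj, ii] = m[ii, jj] + 0.5
        from helixcov.couplings import CouplingMatrix
        pred2 = scan_helix_pair(CouplingMatrix(m, ref_map=cm.ref_map),
                                pt.annotation, ("A", "B"),
                                default_template, default_dists)
        assert pred2.raw_score >= pred.raw_score


class TestPredictAllPairs:
    def test_seven_helices_give_21_pairs(
        self, seven_helix_case, default_template, default_dists
    ):
        pt, cm = seven_helix_case
        preds = predict_all_pairs(cm, pt.annotation, default_template,
                                  default_dists)
        assert len(preds) == 21
        assert all(0.0 <= p.posterior <= 1.0 for p in preds)
        posteriors = [p.posterior for p in preds]
        assert posteriors == sorted(posteriors, reverse=True)

    def test_planted_pairs_occupy_top_ranks(
        self, seven_helix_case, default_template, default_dists
    ):
        pt, cm = seven_helix_case
        preds = predict_all_pairs(cm, pt.annotation, default_template,
                                  default_dists)
        planted = {tuple(sorted((i.helix_a, i.helix_b)))
                   for i in pt.interactions}
        top7 = {tuple(sorted((p.helix_a, p.helix_b))) for p in preds[:7]}
        assert top7 == planted

    def test_relabelling_permutes_but_preserves_scores(
        self, seven_helix_case, default_template, default_dists
    ):
        pt, cm = seven_helix_case
        preds = predict_all_pairs(cm, pt.annotation, default_template,
                                  default_dists)
        renamed = HelixAnnotation([
            Segment("X" + s.name, s.start, s.end, s.kind, s.side, s.n_side)
            for s in pt.annotation.segments
        ])
        preds2 = predict_all_pairs(cm, renamed, default_template,
                                   default_dists)
        scores1 = {tuple(sorted((p.helix_a, p.helix_b))): p.raw_score
                   for p in preds}
        scores2 = {tuple(sorted((p.helix_a[1:], p.helix_b[1:]))): p.raw_score
                   for p in preds2}
        assert scores1 == scores2

    def test_logsumexp_aggregation_is_softer(
        self, seven_helix_case, default_template, default_dists
    ):
        pt, cm = seven_helix_case
        hard = predict_all_pairs(cm, pt.annotation, default_template,
                                 default_dists, aggregation="max")
        soft = predict_all_pairs(cm, pt.annotation, default_template,
                                 default_dists, aggregation="logsumexp")
        h = {tuple(sorted((p.helix_a, p.helix_b))): p.raw_score for p in hard}
        s = {tuple(sorted((p.helix_a, p.helix_b))): p.raw_score for p in soft}
        assert all(s[k] <= h[k] for k in h)
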