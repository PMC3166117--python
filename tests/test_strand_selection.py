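import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sisterstrand import annotation as am
from sisterstrand import strand_selection as ss
from sisterstrand.datasets import ExpressionMatrix, expression_threshold
from conftest import make_hairpin, make_mature


def pair_matrix(samples, x5, x3, extra=None):
    rows = {"m-5p": x5, "m-3p": x3}
    if extra:
        rows.update(extra)
    data = pd.DataFrame(rows, index=samples).T
    return ExpressionMatrix(data.astype(float))


PAIR = ss.SisterPair("m-5p|m-3p", "h", "m-5p", "m-3p")


def annotation_with_pairs(specs):
    """specs: list of (hairpin_id, mature5_id, mature3_id)."""
    ann = am.AnnotationSet()
    pos = 100
    for hid, m5, m3 in specs:
        ann.hairpins[hid] = make_hairpin(hid, pos, pos + 80, "+", [m5, m3])
        ann.matures[m5] = make_mature(m5, hid, pos + 4, pos + 26, "+", "5p")
        ann.matures[m3] = make_mature(m3, hid, pos + 54, pos + 76, "+", "3p")
        pos += 200
    return ann


class TestEnumeratePairs:
    def test_pair_requires_both_arms_measured(self):
        ann = annotation_with_pairs([("h1", "a-5p", "a-3p"), ("h2", "b-5p", "b-3p")])
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 2)), index=["a-5p", "a-3p", "b-5p"], columns=["s1", "s2"])
        )
        pairs = ss.enumerate_sister_pairs(ann, m)
        assert [(p.mature5_id, p.mature3_id) for p in pairs] == [("a-5p", "a-3p")]

    def test_identical_pairs_from_two_loci_collapse(self):
        ann = annotation_with_pairs([("h1", "a-5p", "a-3p"), ("h2", "a-5p", "a-3p")])
        # second locus: same mature ids at another position
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 2)), index=["a-5p", "a-3p"], columns=["s1", "s2"])
        )
        assert len(ss.enumerate_sister_pairs(ann, m)) == 1


class TestLogRatios:
    def test_raw_ratio_values(self):
        m = pair_matrix(["s1", "s2"], [8.0, 4.0], [2.0, 4.0])
        lrm = ss.raw_log_ratio(m, [PAIR])
        np.testing.assert_allclose(lrm.values.loc[PAIR.pair_id], [2.0, 0.0])

    def test_raw_ratio_rejects_nonpositive(self):
        m = pair_matrix(["s1"], [8.0], [0.0])
        with pytest.raises(ValueError, match="thresholded"):
            ss.raw_log_ratio(m, [PAIR])

    @given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=6))
    def test_swapping_arms_negates_ratios(self, xs):
        samples = [f"s{i}" for i in range(len(xs))]
        x3 = [v * 1.7 + 0.1 for v in xs]
        m = pair_matrix(samples, xs, x3)
        swapped = ss.SisterPair(PAIR.pair_id, "h", "m-3p", "m-5p")
        a = ss.raw_log_ratio(m, [PAIR]).values.to_numpy()
        b = ss.raw_log_ratio(m, [swapped]).values.to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_sentinels_and_missing_cells(self):
        # finite ratios span [-3, 2.5]; then one-arm and neither-arm samples
        m = pair_matrix(
            ["s1", "s2", "s3", "s4"],
            [48.0, 10.0, 30.0, 1.0],
            [8.48528, 80.0, 2.0, 1.5],
        )
        # threshold 5: s1 both (log2 ratio ~2.5), s2 both (-3), s3 only5, s4 neither
        lrm = ss.thresholded_log_ratio(m, [PAIR], 5.0)
        row = lrm.values.loc[PAIR.pair_id]
        assert lrm.sentinel_hi == pytest.approx(2.6, abs=1e-3)
        assert lrm.sentinel_lo == pytest.approx(-3.1, abs=1e-3)
        assert row["s3"] == lrm.sentinel_hi
        assert np.isnan(row["s4"])
        assert lrm.status.loc[PAIR.pair_id].tolist() == ["B", "B", "5", "N"]

    def test_only3_gets_low_sentinel(self):
        m = pair_matrix(["s1", "s2"], [48.0, 1.0], [8.0, 80.0])
        lrm = ss.thresholded_log_ratio(m, [PAIR], 5.0)
        assert lrm.values.loc[PAIR.pair_id, "s2"] == lrm.sentinel_lo

    def test_no_concurrent_sample_anywhere_is_error(self):
        m = pair_matrix(["s1"], [48.0], [1.0])
        with pytest.raises(ValueError, match="sentinel"):
            ss.thresholded_log_ratio(m, [PAIR], 5.0)


class TestStandardize:
    def test_zscore_row(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=["a", "b", "c"])
        lrm = ss.LogRatioMatrix(vals, pd.DataFrame("B", index=["p"], columns=["a", "b", "c"]))
        out = ss.standardize_rows(lrm)
        np.testing.assert_allclose(out.values.loc["p"], [-1.0, 0.0, 1.0])

    def test_masked_cells_excluded_and_rows_standardized(self):
        vals = pd.DataFrame([[1.0, np.nan, 3.0, 5.0]], index=["p"],
                            columns=list("abcd"))
        lrm = ss.LogRatioMatrix(vals, pd.DataFrame([["B", "N", "B", "B"]], index=["p"],
                                                   columns=list("abcd")))
        out = ss.standardize_rows(lrm)
        row = out.values.loc["p"]
        assert np.isnan(row["b"])
        obs = row[["a", "c", "d"]].to_numpy()
        assert obs.mean() == pytest.approx(0, abs=1e-12)
        assert obs.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_zero_spread_row_dropped(self):
        vals = pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], index=["p", "q"], columns=["a", "b"])
        lrm = ss.LogRatioMatrix(vals, pd.DataFrame("B", index=["p", "q"], columns=["a", "b"]))
        assert ss.standardize_rows(lrm).pair_ids == ["q"]


class TestClassification:
    @pytest.mark.parametrize(
        "x5, x3, label",
        [
            ([6, 7], [2, 1], "A"),
            ([6, 6], [7, 2], "AC"),
            ([6, 8], [7, 9], "C"),
            ([1, 3], [2, 4], "NOT_EXPRESSED"),
        ],
    )
    def test_definition_cases(self, x5, x3, label):
        samples = ["s1", "s2"]
        m = pair_matrix(samples, x5, x3)
        classes = ss.classify_pairs(m, [PAIR], 5.0)
        assert classes.loc[PAIR.pair_id, "label"] == label

    def test_counts_sum_to_pairs_and_labels_unique(self, default_study):
        study = default_study
        thr = expression_threshold(study.mirna)
        pairs = ss.enumerate_sister_pairs(study.annotation, study.mirna)
        classes = ss.classify_pairs(study.mirna, pairs, thr)
        assert len(classes) == len(pairs)
        assert classes["label"].isin(ss.LABELS).all()
        assert classes["label"].value_counts().sum() == len(pairs)

    def test_arm_swap_preserves_labels(self):
        m = pair_matrix(["s1", "s2", "s3"], [6, 6, 1], [7, 2, 2])
        swapped = ss.SisterPair(PAIR.pair_id, "h", "m-3p", "m-5p")
        a = ss.classify_pairs(m, [PAIR], 5.0)
        b = ss.classify_pairs(m, [swapped], 5.0)
        assert a.loc[PAIR.pair_id, "label"] == b.loc[PAIR.pair_id, "label"]


class TestComparable:
    def test_within_twofold_true(self):
        m = pair_matrix(["s1", "s2"], [6.0, 11.0], [7.0, 6.0])
        assert ss.comparable_flag(m, PAIR, 5.0) is True

    def test_exact_twofold_is_comparable(self):
        m = pair_matrix(["s1"], [6.0], [12.0])
        assert ss.comparable_flag(m, PAIR, 5.0) is True  # |log2| == 1, "not exceeds"

    def test_beyond_twofold_false(self):
        m = pair_matrix(["s1"], [6.0], [25.0])
        assert ss.comparable_flag(m, PAIR, 5.0) is False  # |log2(6/25)| ~ 2.06

    def test_no_concurrent_sample_returns_none(self):
        m = pair_matrix(["s1"], [6.0], [1.0])
        assert ss.comparable_flag(m, PAIR, 5.0) is None

    def test_aggregation_rules(self):
        # concurrent |log2 ratios| ~ (0.2, 0.9, 1.5): median 0.9, max 1.5, min 0.2
        m = pair_matrix(["s1", "s2", "s3"], [100.0, 100.0, 100.0],
                        [100 / 2**0.2, 100 / 2**0.9, 100 / 2**1.5])
        assert ss.comparable_flag(m, PAIR, 5.0, rule="median") is True
        assert ss.comparable_flag(m, PAIR, 5.0, rule="all") is False
        assert ss.comparable_flag(m, PAIR, 5.0, rule="any") is True
        assert ss.comparable_flag(m, PAIR, 5.0, rule="mean") is True


class TestSummaries:
    def test_single_dataset_percentages(self):
        table, cross = ss.summarize_class_counts(
            {"D": {"A": 1, "AC": 1, "C": 2, "NOT_EXPRESSED": 0}}
        )
        row = table.loc["D"]
        assert (row["pct_A"], row["pct_AC"], row["pct_C"], row["pct_NOT_EXPRESSED"]) == (
            25.0, 25.0, 50.0, 0.0)

    def test_cross_dataset_mean_sd_of_percentages(self):
        # five datasets whose AC percentages are 78.9, 83.1, 18.9, 59.4, 60.8
        pcts = [78.9, 83.1, 18.9, 59.4, 60.8]
        counts = {f"D{i}": {"AC": round(p * 10), "A": round((100 - p) * 10)}
                  for i, p in enumerate(pcts)}
        _, cross = ss.summarize_class_counts(counts)
        assert cross.loc["AC", "mean_pct"] == pytest.approx(60.2, abs=0.05)
        assert cross.loc["AC", "sd_pct"] == pytest.approx(25.4, abs=0.1)

    def test_identical_datasets_sd_zero(self):
        counts = {"D1": {"A": 3, "C": 1}, "D2": {"A": 3, "C": 1}}
        _, cross = ss.summarize_class_counts(counts)
        assert cross["sd_pct"].fillna(0).max() == 0.0


def upgma_oracle(D):
    """Naive UPGMA: merge heights as means of *original* pairwise distances."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights)


class TestClustering:
    def _lrm(self, X, ids=None, samples=None):
        ids = ids or [f"p{i}" for i in range(X.shape[0])]
        samples = samples or [f"s{j}" for j in range(X.shape[1])]
        vals = pd.DataFrame(X, index=ids, columns=samples)
        status = pd.DataFrame("B", index=ids, columns=samples).where(~vals.isna(), "N")
        return ss.LogRatioMatrix(vals, status)

    def test_identical_items_merge_at_zero(self):
        lrm = self._lrm(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]]))
        dend = ss.hierarchical_cluster(lrm, axis="pairs")
        assert dend.heights[0] == 0.0

    def test_hand_oracle_one_dimensional(self):
        lrm = self._lrm(np.array([[0.0], [1.0], [10.0]]))
        dend = ss.hierarchical_cluster(lrm, axis="pairs")
        np.testing.assert_allclose(dend.heights, [1.0, 9.5])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle_random(self, trial):
        rng = np.random.default_rng(trial)
        n, p = rng.integers(3, 8), rng.integers(2, 6)
        X = rng.normal(size=(n, p))
        lrm = self._lrm(X)
        dend = ss.hierarchical_cluster(lrm, axis="pairs")
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(dend.heights, upgma_oracle(D), atol=1e-12)

    def test_missing_cells_rescaled_distance(self):
        X = np.array([[1.0, np.nan, 3.0], [2.0, 5.0, 5.0]])
        lrm = self._lrm(X)
        dend = ss.hierarchical_cluster(lrm, axis="pairs")
        # shared dims {0, 2}: d^2 = (1 + 4) * 3/2 = 7.5
        assert dend.heights[0] == pytest.approx(np.sqrt(7.5))

    def test_disjoint_observations_error(self):
        X = np.array([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="share no observed cell"):
            ss.hierarchical_cluster(self._lrm(X), axis="pairs")

    def test_newick_and_cut(self):
        lrm = self._lrm(np.array([[0.0], [1.0], [10.0]]), ids=["a", "b", "c"])
        dend = ss.hierarchical_cluster(lrm, axis="pairs")
        cut = dend.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]
        nwk = dend.to_newick()
        assert nwk.endswith(";") and {"a", "b", "c"} <= set(nwk.replace("(", " ").replace(")", " ").replace(",", " ").split())
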