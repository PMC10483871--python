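import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from becabench.core_io import ValidationError
from becabench.metrics import (
    ConfusionCounts,
    ari,
    confusion,
    jaccard,
    mcc,
    pca_scores,
    rc,
    snr,
    total_score,
)
from conftest import toy_matrix


# -- independent oracles ------------------------------------------------------


def brute_force_snr(points: dict[str, np.ndarray], w: np.ndarray) -> float:
    """Direct enumeration of all between/within pairs from the defining formula."""
    donors = sorted(points)
    m = len(donors)
    n = {d: len(points[d]) for d in donors}
    between, nb = 0.0, 0
    for x, y in itertools.combinations(donors, 2):
        for i in range(n[x]):
            for j in range(n[y]):
                between += sum(
                    w[p] * (points[x][i][p] - points[y][j][p]) ** 2 for p in range(2)
                )
                nb += 1
    within, nw = 0.0, 0
    for x in donors:
        for i, j in itertools.combinations(range(n[x]), 2):
            within += sum(w[p] * (points[x][i][p] - points[x][j][p]) ** 2 for p in range(2))
            nw += 1
    return 10 * math.log10((between / nb) / (within / nw))


def brute_force_mcc(c: ConfusionCounts) -> float:
    num = c.tp * c.tn - c.fp * c.fn
    den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return 0.0 if den == 0 else num / den


def brute_force_ari(a: list, b: list) -> float:
    """Pair-counting ARI from first principles over all element pairs."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    same_a = {(i, j): a[i] == a[j] for i, j in pairs}
    same_b = {(i, j): b[i] == b[j] for i, j in pairs}
    n11 = sum(1 for p in pairs if same_a[p] and same_b[p])
    n00 = sum(1 for p in pairs if not same_a[p] and not same_b[p])
    n10 = sum(1 for p in pairs if same_a[p] and not same_b[p])
    n01 = sum(1 for p in pairs if not same_a[p] and same_b[p])
    total = len(pairs)
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total if total else 0.0
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:
        return 0.0 if (n10 or n01) else 1.0
    _ = n00
    return (index - expected) / (maximum - expected)


# -- PCA ----------------------------------------------------------------------


class TestPcaScores:
    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 1))
        vals = np.hstack([base, base, rng.normal(size=(20, 2))])
        m = toy_matrix(vals, scale="log2")
        scores, _ = pca_scores(m)
        np.testing.assert_allclose(scores.loc["s0"], scores.loc["s1"], atol=1e-9)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = toy_matrix(rng.normal(size=(30, 6)), scale="log2")
        _, var = pca_scores(m)
        assert var.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_gram_eigendecomposition(self):
        """Scores agree (up to sign) with a direct eigensolve of the Gram
        matrix of the centered, unit-variance-scaled data."""
        rng = np.random.default_rng(2)
        m = toy_matrix(rng.normal(size=(4, 5)), scale="log2")
        scores, var = pca_scores(m)
        x = m.values.to_numpy().T
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        lam, vec = np.linalg.eigh(x @ x.T)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        expected = vec * np.sqrt(np.clip(lam, 0, None))
        for k in range(min(3, scores.shape[1])):
            got = scores.iloc[:, k].to_numpy()
            assert np.allclose(got, expected[:, k], atol=1e-8) or np.allclose(
                got, -expected[:, k], atol=1e-8
            )

    def test_too_few_samples_rejected(self):
        m = toy_matrix(np.ones((5, 2)), scale="log2")
        with pytest.raises(ValidationError, match="samples"):
            pca_scores(m)


# -- SNR ----------------------------------------------------------------------


def _scores_df(points: dict[str, np.ndarray]):
    rows, idx, donors = [], [], []
    for d, pts in points.items():
        for i, p in enumerate(pts):
            rows.append(p)
            idx.append(f"{d}_{i}")
            donors.append(d)
    scores = pd.DataFrame(rows, index=idx, columns=["PC1", "PC2"])
    return scores, pd.Series(donors, index=idx)


class TestSnr:
    def test_hand_enumerated_example(self):
        """m=2, n=2, W=(1,1): 4 between-pair distances sum 408, 2 within sum 8
        → 10·log10(0.5·408/8) ≈ 14.07 dB."""
        points = {
            "A": np.array([[0.0, 0.0], [0.0, 2.0]]),
            "B": np.array([[10.0, 0.0], [10.0, 2.0]]),
        }
        scores, donors = _scores_df(points)
        w = np.array([1.0, 1.0])
        value = snr(scores, w, donors)
        assert value == pytest.approx(10 * math.log10(102 / 4), abs=1e-9)
        assert value == pytest.approx(14.07, abs=0.01)

    def test_equal_between_and_within_is_zero_db(self):
        # layout solved so mean squared between-distance = mean squared within
        h = math.sqrt(2) - 1  # root of h² + 2h − 1 = 0
        points = {
            "A": np.array([[0.0, 0.0], [2.0, 0.0]]),
            "B": np.array([[1.0, h], [1.0, h + 2.0]]),
        }
        scores, donors = _scores_df(points)
        assert snr(scores, np.array([1.0, 1.0]), donors) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(2, 5)
            n = rng.integers(2, 5)
            points = {f"d{i}": rng.normal(size=(n, 2)) for i in range(m)}
            w = rng.uniform(0.1, 1.0, size=2)
            scores, donors = _scores_df(points)
            assert snr(scores, w, donors) == pytest.approx(
                brute_force_snr(points, w), abs=1e-9
            )

    def test_label_permutation_lowers_snr(self):
        """On donor-separated scores, random label permutations essentially
        never beat the true labelling."""
        rng = np.random.default_rng(6)
        points = {
            d: rng.normal(loc=center, scale=0.3, size=(3, 2))
            for d, center in [("A", (0, 0)), ("B", (5, 0)), ("C", (0, 5))]
        }
        scores, donors = _scores_df(points)
        w = np.array([0.6, 0.4])
        true_snr = snr(scores, w, donors)
        worse = 0
        for _ in range(100):
            perm = pd.Series(
                rng.permutation(donors.to_numpy()), index=donors.index
            )
            if snr(scores, w, perm) < true_snr:
                worse += 1
        assert worse >= 99

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        points = {d: rng.normal(size=(3, 2)) for d in "AB"}
        scores, donors = _scores_df(points)
        w = np.array([0.7, 0.3])
        shifted = scores + np.array([123.0, -45.0])
        assert snr(shifted, w, donors) == pytest.approx(snr(scores, w, donors), abs=1e-9)

    def test_rotation_invariance_with_equal_weights(self):
        rng = np.random.default_rng(8)
        points = {d: rng.normal(size=(4, 2)) for d in "ABC"}
        scores, donors = _scores_df(points)
        w = np.array([0.5, 0.5])
        theta = 0.73
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        rotated = pd.DataFrame(
            scores.to_numpy() @ rot.T, index=scores.index, columns=scores.columns
        )
        assert snr(rotated, w, donors) == pytest.approx(snr(scores, w, donors), abs=1e-9)

    def test_zero_within_spread_is_infinite(self):
        points = {
            "A": np.array([[0.0, 0.0], [0.0, 0.0]]),
            "B": np.array([[1.0, 0.0], [1.0, 0.0]]),
        }
        scores, donors = _scores_df(points)
        with pytest.warns(RuntimeWarning, match="within"):
            assert snr(scores, np.array([1.0, 1.0]), donors) == math.inf

    def test_single_replicate_rejected(self):
        points = {"A": np.array([[0.0, 0.0]]), "B": np.array([[1.0, 1.0], [2.0, 2.0]])}
        scores, donors = _scores_df(points)
        with pytest.raises(ValidationError, match="replicates"):
            snr(scores, np.array([1.0, 1.0]), donors)


# -- RC -----------------------------------------------------------------------


class TestRc:
    def test_identity_and_negation(self):
        f = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        assert rc(f, f) == pytest.approx(1.0)
        assert rc(-f, f) == pytest.approx(-1.0)

    def test_noise_attenuation_closed_form(self):
        """test = reference + N(0, 0.1²) with unit-variance reference gives
        r ≈ 1/√1.01 (averaged over 50 seeds, 1000 features)."""
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ref = pd.Series(rng.normal(0, 1, 1000), index=[f"g{i}" for i in range(1000)])
            test = ref + rng.normal(0, 0.1, 1000)
            rs.append(rc(test, ref))
        assert np.mean(rs) == pytest.approx(1 / math.sqrt(1.01), abs=0.002)

    def test_intersection_and_errors(self):
        a = pd.Series([1.0, 2.0], index=["g1", "g2"])
        b = pd.Series([1.0, 2.0, 3.0], index=["g2", "g3", "g4"])
        with pytest.raises(ValidationError, match="overlapping"):
            rc(a, b)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        idx = [f"g{i}" for i in range(100)]
        a = pd.Series(rng.normal(size=100), index=idx)
        b = pd.Series(rng.normal(size=100), index=idx)
        assert rc(3 * a + 2, b) == pytest.approx(rc(a, b), abs=1e-12)


# -- confusion / MCC ----------------------------------------------------------


def _labels(seq):
    return pd.Series(list(seq), index=[f"g{i}" for i in range(len(seq))])


class TestConfusion:
    def test_identical_labellings(self):
        lab = _labels(["up", "down", "non", "up"])
        c = confusion(lab, lab)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp == 3 and c.tn == 1

    def test_all_non_test_gives_fn(self):
        ref = _labels(["up", "down", "non", "up"])
        test = _labels(["non"] * 4)
        c = confusion(test, ref)
        assert c.fn == 3 and c.fp == 0 and c.tn == 1

    def test_wrong_direction_counts_as_fp(self):
        c = confusion(_labels(["down"]), _labels(["up"]))
        assert c.fp == 1 and c.tp == 0

    def test_counts_partition_features(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = rng.integers(1, 30)
            test = _labels(rng.choice(["up", "down", "non"], size=n))
            ref = _labels(rng.choice(["up", "down", "non"], size=n))
            c = confusion(test, ref)
            assert c.total == n

    def test_disjoint_features_rejected(self):
        a = pd.Series(["up"], index=["g1"])
        b = pd.Series(["up"], index=["g2"])
        with pytest.raises(ValidationError, match="disjoint"):
            confusion(a, b)


class TestMcc:
    def test_worked_example(self):
        assert mcc(ConfusionCounts(tp=8, tn=5, fp=2, fn=1)) == pytest.approx(
            38 / math.sqrt(3780)
        )

    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(10, 10, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 5, 5)) == -1.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 10, 0, 0)) == 0.0

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            c = ConfusionCounts(
                tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            )
            ours = mcc(c)
            assert ours == pytest.approx(brute_force_mcc(c), abs=1e-12)
            sk = matthews_corrcoef(y_true, y_pred)
            if sk != 0 or ours == 0:  # sklearn shares the 0-denominator convention
                assert ours == pytest.approx(sk, abs=1e-9)


class TestJaccard:
    def test_half_overlap(self):
        assert jaccard({"g1", "g2", "g3"}, {"g2", "g3", "g4"}) == 0.5

    def test_identical_and_disjoint(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set(), set()) == 1.0


# -- ARI ----------------------------------------------------------------------


class TestAri:
    def _parts(self, a, b):
        idx = [f"e{i}" for i in range(len(a))]
        return pd.Series(a, index=idx), pd.Series(b, index=idx)

    def test_identical_partitions(self):
        pa, pb = self._parts([0, 0, 1, 1], [5, 5, 9, 9])
        assert ari(pa, pb) == pytest.approx(1.0)

    def test_hand_case_is_zero(self):
        pa, pb = self._parts([0, 0, 1, 1], [0, 0, 0, 1])
        assert ari(pa, pb) == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_is_zero(self):
        rng = np.random.default_rng(12)
        pa, pb = self._parts([0] * 10, rng.integers(0, 3, 10))
        assert ari(pa, pb) == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_elements_rejected(self):
        pa = pd.Series([0, 1], index=["a", "b"])
        pb = pd.Series([0, 1], index=["a", "c"])
        with pytest.raises(ValidationError, match="element"):
            ari(pa, pb)

    def test_index_alignment_not_positional(self):
        pa = pd.Series([0, 0, 1, 1], index=["a", "b", "c", "d"])
        pb = pd.Series([1, 1, 0, 0], index=["d", "c", "b", "a"])
        assert ari(pa, pb) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            a = list(rng.integers(0, 3, n))
            b = list(rng.integers(0, 3, n))
            pa, pb = self._parts(a, b)
            assert ari(pa, pb) == pytest.approx(brute_force_ari(a, b), abs=1e-9)


# -- total score --------------------------------------------------------------


class TestTotalScore:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["snr", "mcc_defs", "mcc_prediction", "ari"]
        ).set_axis([f"m{i}" for i in range(len(rows))], axis=0)

    def test_dominating_method_scores_one(self):
        t = self._table([[10, 0.9, 0.9, 1.0], [1, 0.1, 0.2, 0.0], [5, 0.5, 0.5, 0.5]])
        out = total_score(t)
        assert out.loc["m0", "total_score"] == pytest.approx(1.0)
        assert out.loc["m0", "rank"] == 1

    def test_mean_of_scaled_values(self):
        t = self._table([[1, 1, 1, 1], [0, 0, 0, 0], [1, 0.5, 0.75, 0.75]])
        out = total_score(t)
        assert out.loc["m2", "total_score"] == pytest.approx((1 + 0.5 + 0.75 + 0.75) / 4)

    def test_constant_column_scales_to_half(self):
        t = self._table([[1, 0.5, 1, 1], [0, 0.5, 0, 0]])
        out = total_score(t)
        assert (out["mcc_defs"] == 0.5).all()

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        st.floats(0.1, 10, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_ranking_invariant_to_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(14)
        t = self._table(rng.normal(size=(4, 4)))
        base = total_score(t)["rank"]
        t2 = t.copy()
        t2["snr"] = t2["snr"] * scale + shift
        assert total_score(t2)["rank"].equals(base)
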