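"""Composition matrices, Bray-Curtis, PCoA, PERMANOVA and ANOVA/Tukey."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from pksurvey.composition import (
    DistanceMatrix,
    anova_tukey,
    bray_curtis,
    ks_per_gbp,
    pcoa,
    permanova,
    rarefied_composition,
)


def _dm(points, ids=None):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids=ids, values=d)


class TestKsPerGbp:
    def test_direct_division(self):
        assert ks_per_gbp([10, 0, 4], 2.0).tolist() == [5.0, 0.0, 2.0]

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            ks_per_gbp([1], 0.0)

    def test_random_matches_manual(self, rng):
        counts = rng.integers(0, 50, size=11)
        size = float(rng.uniform(0.5, 5))
        assert np.allclose(ks_per_gbp(counts, size), counts / size)


class _FakeCall:
    def __init__(self, leaf):
        self.leaf_label = leaf


class TestRarefiedComposition:
    def test_exact_depth_equals_empirical_counts(self):
        calls = {"m1": [_FakeCall("PUFA")] * 7 + [_FakeCall("enediyne")] * 3}
        out = rarefied_composition(calls, depth=10, permutations=50, seed=0)
        assert out.loc["m1", "PUFA"] == 7
        assert out.loc["m1", "enediyne"] == 3

    def test_hypergeometric_expectation(self):
        """50/50 pool of 1,000, depth 100: means within 3 sigma of 50."""
        calls = {"m": [_FakeCall("PUFA")] * 500 + [_FakeCall("trans-AT")] * 500}
        out = rarefied_composition(calls, depth=100, permutations=1000, seed=1)
        # variance of one hypergeometric draw, shrunk by 1,000 permutations
        var = 100 * 0.5 * 0.5 * (1000 - 100) / (1000 - 1) / 1000
        for leaf in ("PUFA", "trans-AT"):
            assert abs(out.loc["m", leaf] - 50) < 3 * np.sqrt(var)

    def test_shallow_metagenome_excluded(self):
        calls = {"deep": [_FakeCall("PUFA")] * 30, "shallow": [_FakeCall("PUFA")] * 3}
        with pytest.warns(UserWarning, match="shallow"):
            out = rarefied_composition(calls, depth=10, permutations=10, seed=0)
        assert list(out.index) == ["deep"]

    def test_seeded_determinism(self):
        calls = {"m": [_FakeCall("PUFA")] * 60 + [_FakeCall("FAS")] * 60}
        a = rarefied_composition(calls, depth=50, permutations=100, seed=9)
        b = rarefied_composition(calls, depth=50, permutations=100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[3, 1], [3, 1]], index=["a", "b"])
        assert bray_curtis(m).values[0, 1] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert bray_curtis(m).values[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        m = pd.DataFrame([[2, 1], [1, 3]], index=["a", "b"])
        assert bray_curtis(m).values[0, 1] == pytest.approx(3 / 7)

    def test_bounds_symmetry_zero_diagonal(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, size=(8, 5)) + 0.01)
        dm = bray_curtis(m)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        assert ((dm.values >= 0) & (dm.values <= 1)).all()

    def test_all_zero_row_rejected(self):
        m = pd.DataFrame([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            bray_curtis(m)


class TestPcoa:
    def test_recovers_planar_configuration(self, rng):
        """PCoA of Euclidean distances reproduces the points up to rotation
        (Procrustes residual ~ 0)."""
        from scipy.spatial import procrustes

        pts = rng.normal(size=(5, 2))
        res = pcoa(_dm(pts))
        assert res.coordinates.shape[1] >= 2
        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-8

    def test_euclidean_input_nonnegative_eigenvalues(self, rng):
        pts = rng.normal(size=(10, 4))
        res = pcoa(_dm(pts))
        assert (res.eigenvalues > -1e-9 * abs(res.eigenvalues[0])).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_equilateral_three_points(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(ids=list("abc"), values=d))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_two_points(self):
        d = np.array([[0, 2], [2, 0]], dtype=float)
        res = pcoa(DistanceMatrix(ids=["a", "b"], values=d))
        assert sorted(res.coordinates[:, 0].tolist()) == pytest.approx([-1.0, 1.0])

    def test_matches_reference_implementation(self, rng):
        """Cross-check coordinates against scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(7, 3))
        dm = _dm(pts)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), method="eigh"
        )
        n_pos = ours.coordinates.shape[1]
        ref = theirs.samples.to_numpy()[:, :n_pos]
        for k in range(n_pos):
            assert np.allclose(np.abs(ours.coordinates[:, k]), np.abs(ref[:, k]), atol=1e-8)


class TestPermanova:
    def test_duplicated_points_full_separation(self):
        pts = [[0, 0]] * 4 + [[5, 5]] * 4
        res = permanova(_dm(pts), ["a"] * 4 + ["b"] * 4, permutations=99, seed=0)
        assert res.R2 == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_matches_exhaustive_permutation_oracle(self):
        """6-sample example: p from 999 draws ~ exact enumeration p."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        labels = ["a", "a", "a", "b", "b", "b"]
        dm = _dm(pts)
        res = permanova(dm, labels, permutations=9999, seed=0)
        # exhaustive enumeration over all 20 label assignments
        from pksurvey.composition import _permanova_stats

        d2 = dm.values ** 2
        uniq, groups = np.unique(labels, return_inverse=True)
        f_obs, _ = _permanova_stats(d2, groups, np.arange(2))
        fs = []
        for comb in itertools.combinations(range(6), 3):
            g = np.array([0 if i in comb else 1 for i in range(6)])
            fs.append(_permanova_stats(d2, g, np.arange(2))[0])
        exact_p = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.pseudo_F == pytest.approx(f_obs)
        assert abs(res.p_value - exact_p) < 0.05

    def test_matches_reference_implementation(self, rng):
        """Pseudo-F agrees with scikit-bio's PERMANOVA statistic."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        pts = rng.normal(size=(12, 3))
        labels = ["a"] * 6 + ["b"] * 6
        dm = _dm(pts)
        ours = permanova(dm, labels, permutations=99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(dm.values, ids=dm.ids), labels,
                              permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_rejects_tiny_groups(self):
        pts = [[0, 0], [1, 1], [2, 2]]
        with pytest.raises(ValueError):
            permanova(_dm(pts), ["a", "a", "b"], permutations=9, seed=0)

    def test_p_value_bounds(self, rng):
        pts = rng.normal(size=(8, 2))
        res = permanova(_dm(pts), ["a"] * 4 + ["b"] * 4, permutations=99, seed=3)
        assert 1 / 100 <= res.p_value <= 1.0


class TestAnovaTukey:
    def test_textbook_three_group_anova(self):
        """F matches the hand-computed one-way ANOVA."""
        groups = {"g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        res = anova_tukey(groups)
        allv = np.concatenate([groups[g] for g in sorted(groups)])
        grand = allv.mean()
        ss_b = sum(6 * (np.mean(groups[g]) - grand) ** 2 for g in groups)
        ss_w = sum(((np.array(groups[g]) - np.mean(groups[g])) ** 2).sum() for g in groups)
        f_hand = (ss_b / 2) / (ss_w / 15)
        assert res.f_statistic == pytest.approx(f_hand, abs=1e-10)

    def test_no_flags_when_means_equal(self):
        rng = np.random.default_rng(0)
        groups = {g: (5 + 0.01 * rng.normal(size=6)).tolist() for g in "abc"}
        res = anova_tukey(groups)
        assert not any(p.significant for p in res.pairs)

    def test_two_group_tukey_equals_t_relation(self):
        """With 2 groups, the Tukey q relates to the pooled t as q = |t| * sqrt(2)."""
        from scipy import stats

        a = [1.0, 2.0, 3.0, 4.0]
        b = [3.0, 5.0, 4.0, 6.0]
        res = anova_tukey({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        q = abs(t) * np.sqrt(2)
        p_from_q = stats.studentized_range.sf(q, 2, 6)
        assert res.pairs[0].p_value == pytest.approx(p_from_q, abs=1e-9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [2.0, 2.0], "b": [2.0, 2.0]})
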