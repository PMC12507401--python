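import itertools
import math

import numpy as np
import pandas as pd
import pytest

from guildaging.diversity import (
    alpha_diversity,
    bray_curtis,
    pcoa_with_age_arrow,
    permanova,
    permanova_terms,
    rarefy,
    uniqueness,
)
from guildaging.io import ValidationError


def _df(rows, prefix="s"):
    rows = np.asarray(rows)
    return pd.DataFrame(
        rows,
        index=[f"{prefix}{i}" for i in range(rows.shape[0])],
        columns=[f"t{j}" for j in range(rows.shape[1])],
    )


class TestRarefy:
    def test_totals_equal_depth_and_determinism(self):
        rng = np.random.default_rng(0)
        counts = _df(rng.integers(0, 50, size=(10, 8)))
        counts.iloc[:, 0] += 100  # guarantee depth
        r1 = rarefy(counts, 120, seed=42)
        r2 = rarefy(counts, 120, seed=42)
        assert (r1.sum(axis=1) == 120).all()
        assert r1.equals(r2)
        assert (r1 <= counts).all().all()

    def test_sample_at_depth_returned_unchanged(self):
        counts = _df([[5, 5], [7, 3]])
        out = rarefy(counts, 10, seed=0)
        assert out.equals(counts)

    def test_underdepth_samples_listed_in_error(self):
        counts = _df([[5, 5], [1, 1]])
        with pytest.raises(ValidationError, match="s1"):
            rarefy(counts, 10)


class TestAlphaDiversity:
    def test_uniform_sample_is_maximally_even(self):
        prof = alpha_diversity(_df([[5, 5, 5, 5]]))
        assert prof["pielou"].iloc[0] == pytest.approx(1.0)
        assert prof["shannon"].iloc[0] == pytest.approx(math.log(4))

    def test_hand_values_1_1_2(self):
        prof = alpha_diversity(_df([[1, 1, 2]]))
        assert prof["shannon"].iloc[0] == pytest.approx(1.0397, abs=1e-4)
        assert prof["pielou"].iloc[0] == pytest.approx(0.9464, abs=1e-4)

    def test_bias_corrected_chao1(self):
        # S = 5, F1 = 2, F2 = 1 -> 5 + 2*1/(2*2) = 5.5
        prof = alpha_diversity(_df([[1, 1, 2, 3, 4]]))
        assert prof["chao1"].iloc[0] == pytest.approx(5.5)

    def test_chao1_defined_without_doubletons(self):
        prof = alpha_diversity(_df([[1, 1, 3]]))
        assert prof["chao1"].iloc[0] == pytest.approx(3 + 2 * 1 / 2)

    def test_single_taxon_pielou_convention(self):
        prof = alpha_diversity(_df([[9, 0, 0]]))
        assert prof["pielou"].iloc[0] == 1.0
        assert prof["chao1"].iloc[0] >= 1.0

    def test_matches_reference_implementation(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=(5, 12))
        counts[:, 0] += 1
        prof = alpha_diversity(_df(counts))
        for i in range(5):
            assert prof["chao1"].iloc[i] == pytest.approx(
                float(skbio_alpha.chao1(counts[i], bias_corrected=True))
            )
            assert prof["shannon"].iloc[i] == pytest.approx(
                float(skbio_alpha.shannon(counts[i], base=math.e))
            )

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = _df(rng.integers(1, 20, size=(4, 6)))
        shuffled = counts[rng.permutation(counts.columns)]
        np.testing.assert_allclose(
            alpha_diversity(counts).to_numpy(),
            alpha_diversity(shuffled).to_numpy(),
        )

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            alpha_diversity(_df([[0, 0]]))


class TestBrayCurtis:
    def test_hand_values(self):
        D = bray_curtis(_df([[1, 2, 3], [3, 2, 1]]))
        assert D.iloc[0, 1] == pytest.approx(1.0 / 3.0)

    def test_identical_and_disjoint(self):
        D = bray_curtis(_df([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]]))
        assert D.iloc[0, 1] == pytest.approx(0.0)
        assert D.iloc[0, 2] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal_unit_range(self):
        rng = np.random.default_rng(5)
        counts = _df(rng.integers(0, 40, size=(8, 10)))
        counts.iloc[:, 0] += 1
        D = bray_curtis(counts)
        A = D.to_numpy()
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.diag(A).max() == 0.0
        assert A.min() >= 0.0 and A.max() <= 1.0


class TestUniqueness:
    def test_row_minima(self):
        D = pd.DataFrame(
            [[0.0, 0.2, 0.5], [0.2, 0.0, 0.4], [0.5, 0.4, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        np.testing.assert_allclose(uniqueness(D).to_numpy(), [0.2, 0.2, 0.4])

    def test_duplicate_sample_has_zero_uniqueness(self):
        counts = _df([[1, 2], [1, 2], [9, 1]])
        u = uniqueness(bray_curtis(counts))
        assert u.iloc[0] == 0.0 and u.iloc[1] == 0.0

    def test_adding_samples_never_increases_uniqueness(self):
        rng = np.random.default_rng(2)
        counts = _df(rng.integers(1, 30, size=(8, 6)))
        u_small = uniqueness(bray_curtis(counts.iloc[:5]))
        u_big = uniqueness(bray_curtis(counts)).iloc[:5]
        assert (u_big.to_numpy() <= u_small.to_numpy() + 1e-12).all()

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            uniqueness(pd.DataFrame([[0.0]]))


def _brute_force_permanova_p(D, labels):
    """Independent enumeration oracle: direct SS computation per assignment."""
    D = np.asarray(D, dtype=float)
    n = len(labels)

    def f_of(lab):
        lab = np.asarray(lab)
        sst = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            ssw += sum(
                D[i, j] ** 2 for i in idx for j in idx if i < j
            ) / len(idx)
        k = len(set(lab))
        return ((sst - ssw) / (k - 1)) / (ssw / (n - k))

    f_obs = f_of(labels)
    group1 = [i for i, l in enumerate(labels) if l == labels[0]]
    count = total = 0
    for combo in itertools.combinations(range(n), len(group1)):
        lab = ["b"] * n
        for i in combo:
            lab[i] = "a"
        total += 1
        if f_of(lab) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / total


class TestPermanova:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(D, labels, exhaustive=True)
        f_oracle, p_oracle = _brute_force_permanova_p(D, labels)
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 20

    def test_duplicated_groups_show_no_effect(self):
        rng = np.random.default_rng(4)
        counts = _df(rng.integers(1, 40, size=(4, 6)))
        doubled = pd.concat([counts, counts.set_axis([f"d{i}" for i in range(4)])])
        D = bray_curtis(doubled)
        labels = ["a"] * 4 + ["b"] * 4  # group 2 is an exact copy of group 1
        res = permanova(D, labels, n_permutations=199, seed=0)
        assert res.R2 < 0.05
        assert res.p > 0.5

    def test_matches_reference_implementation_statistic(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 3))
        pts[:6, 0] += 1.0
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(D, labels, n_permutations=99, seed=0)
        ref = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(D), grouping=labels, permutations=99
        )
        assert res.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_constant_grouping_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValidationError):
            permanova(D, ["a"] * 4)

    def test_sequential_terms_detect_true_covariate(self):
        rng = np.random.default_rng(9)
        n = 40
        age = rng.uniform(50, 90, n)
        pts = np.column_stack([age / 10 + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        cov = pd.DataFrame({"age": age, "noise": rng.normal(size=n)})
        tab = permanova_terms(D, cov, ["age", "noise"], n_permutations=99, seed=0)
        assert tab.loc[tab["term"] == "age", "p"].iloc[0] < 0.05
        assert tab.loc[tab["term"] == "noise", "p"].iloc[0] > 0.05


class TestPcoa:
    def test_euclidean_distances_preserved(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(15, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa_with_age_arrow(pd.DataFrame(D), ages=rng.uniform(50, 90, 15))
        C = res.coordinates.to_numpy()
        D_hat = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        np.testing.assert_allclose(D_hat, D, atol=1e-9)

    def test_variance_explained_ordered_and_bounded(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(20, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa_with_age_arrow(pd.DataFrame(D), ages=rng.uniform(50, 90, 20),
                                  top_axes=4)
        ve = res.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert ve.sum() <= 1.0 + 1e-12
        assert (ve >= 0).all()

    def test_age_slopes_match_ols(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(25, 2))
        ages = rng.uniform(50, 90, 25)
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa_with_age_arrow(pd.DataFrame(D), ages=ages)
        for k in range(res.coordinates.shape[1]):
            slope = np.polyfit(ages, res.coordinates.iloc[:, k], 1)[0]
            assert res.age_slopes[k] == pytest.approx(slope, rel=1e-8, abs=1e-12)
        # arrow length is 0.8 of the maximum coordinate radius
        assert np.linalg.norm(res.age_arrow) == pytest.approx(
            0.8 * np.abs(res.coordinates.to_numpy()).max()
        )
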