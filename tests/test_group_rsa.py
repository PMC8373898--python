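"""Condition betas, Mann-Whitney group comparison, and RSMs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anxmvpa.group_rsa import (
    build_rsm,
    compare_groups_mwu,
    estimate_betas,
    mann_whitney_u,
)
from anxmvpa.synthetic_data import CohortSpec, generate_cohort
from anxmvpa.volume_io import TimePointDataset


def _toy_dataset(features, labels, groups=None):
    n, t, v = features.shape
    return TimePointDataset(
        features=features,
        stimulus_labels=np.asarray(labels),
        group_labels=np.asarray(groups if groups is not None
                                else ["anxious"] * (n // 2) + ["non_anxious"] * (n - n // 2)),
        subject_ids=[f"s{i}" for i in range(n)],
        region_index={1: slice(0, v)},
    )


class TestEstimateBetas:
    def test_noiseless_indicator_data_recovers_exact_betas(self):
        labels = np.array(["fear"] * 4 + ["anger"] * 3)
        fear = (labels == "fear").astype(float)
        y = 2.0 * fear + 5.0 * (1 - fear)
        feats = np.tile(y[None, :, None], (2, 1, 3))
        ds = _toy_dataset(feats, labels)
        b = estimate_betas(ds, 1)
        np.testing.assert_allclose(b.betas[:, 0, :], 2.0)  # fear beta
        np.testing.assert_allclose(b.betas[:, 1, :], 5.0)  # anger beta

    def test_pure_noise_betas_within_three_standard_errors(self, rng):
        labels = np.array(["fear"] * 18 + ["anger"] * 17)
        feats = rng.standard_normal((4, 35, 50))
        ds = _toy_dataset(feats, labels)
        b = estimate_betas(ds, 1)
        # SE of a condition mean of unit noise
        for ci, n_c in enumerate([18, 17]):
            z = b.betas[:, ci, :] / (1.0 / np.sqrt(n_c))
            assert (np.abs(z) < 3).mean() > 0.95

    def test_linearity_in_the_data(self, tiny_ds):
        b1 = estimate_betas(tiny_ds, 2)
        doubled = TimePointDataset(
            features=2.0 * tiny_ds.features,
            stimulus_labels=tiny_ds.stimulus_labels,
            group_labels=tiny_ds.group_labels,
            subject_ids=list(tiny_ds.subject_ids),
            region_index=tiny_ds.region_index,
        )
        b2 = estimate_betas(doubled, 2)
        np.testing.assert_allclose(b2.betas, 2.0 * b1.betas, atol=1e-12)

    def test_rank_deficient_design_rejected(self):
        labels = np.array(["fear"] * 5)  # single condition
        ds = _toy_dataset(np.zeros((2, 5, 3)), labels)
        with pytest.raises(ValueError, match="rank-deficient"):
            estimate_betas(ds, 1)


class TestMannWhitneyU:
    def test_frozen_example_no_overlap(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == 0.0

    def test_identical_multisets_give_half_product(self):
        x = [1.0, 2.0, 2.0, 5.0]
        assert mann_whitney_u(x, x) == len(x) ** 2 / 2

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 31, size=2)
            # integer draws force ties
            x = rng.integers(0, 10, n1).astype(float)
            y = rng.integers(0, 10, n2).astype(float)
            brute = sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y
            )
            assert mann_whitney_u(x, y) == brute

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=12),
        st.lists(st.integers(0, 5), min_size=1, max_size=12),
    )
    def test_orientation_symmetry_with_ties(self, x, y):
        assert mann_whitney_u(x, y) + mann_whitney_u(y, x) == len(x) * len(y)

    def test_exact_p_matches_full_enumeration_at_small_n(self, rng):
        from itertools import combinations

        from scipy import stats

        for _ in range(8):
            n1, n2 = rng.integers(3, 8, size=2)
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2)
            u_obs = mann_whitney_u(x, y)
            pooled = np.concatenate([x, y])
            n = n1 + n2
            # exact two-sided p by enumerating all C(n, n1) label assignments
            mid = n1 * n2 / 2
            count = total = 0
            for pick in combinations(range(n), n1):
                mask = np.zeros(n, bool)
                mask[list(pick)] = True
                u = mann_whitney_u(pooled[mask], pooled[~mask])
                total += 1
                if abs(u - mid) >= abs(u_obs - mid) - 1e-9:
                    count += 1
            p_enum = count / total
            p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            assert p_exact == pytest.approx(p_enum, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n_12(self, rng):
        """At 12 samples per group the tie-corrected normal approximation
        agrees with the exact null distribution to within 0.01 (the
        approximation degrades for much smaller groups)."""
        from scipy import stats

        for _ in range(100):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            p_norm = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.01


class TestCompareGroups:
    def test_frozen_exact_p(self):
        labels = np.array(["fear", "anger"])
        feats = np.zeros((2, 2, 3))
        feats[0] = [[1, 2, 3], [1, 2, 3]]  # anxious subject
        feats[1] = [[4, 5, 6], [4, 5, 6]]  # control subject
        ds = _toy_dataset(feats, labels, groups=["anxious", "non_anxious"])
        comp = compare_groups_mwu(estimate_betas(ds, 1))
        assert comp.U == 0.0
        assert comp.p_two_sided == pytest.approx(0.1)
        assert comp.method == "exact"

    def test_planted_group_shift_detected(self):
        cohort = generate_cohort(
            CohortSpec(seed=9, n_anxious=10, n_control=10, atlas_shape=(8, 8, 8),
                       n_regions=4, voxels_per_region=30, signal_region_id=3,
                       group_effect=2.0, stim_effect=0.0)
        )
        ds = cohort.to_dataset()
        comp = compare_groups_mwu(estimate_betas(ds, 3))
        assert comp.n1 == comp.n2 == 30
        assert comp.U > comp.n1 * comp.n2 / 2  # anxious betas shifted up
        assert comp.p_two_sided < 0.005

    def test_all_tied_warns_p_one(self):
        labels = np.array(["fear", "anger"])
        ds = _toy_dataset(np.zeros((2, 2, 4)), labels)
        with pytest.warns(UserWarning, match="tied"):
            comp = compare_groups_mwu(estimate_betas(ds, 1))
        assert comp.p_two_sided == 1.0

    def test_empty_group_rejected(self):
        labels = np.array(["fear", "anger"])
        ds = _toy_dataset(np.zeros((2, 2, 4)), labels,
                          groups=["anxious", "anxious"])
        with pytest.raises(ValueError, match="empty"):
            compare_groups_mwu(estimate_betas(ds, 1))


class TestBuildRSM:
    def test_identical_patterns_zero_dissimilarity(self, rng):
        labels = np.array(["fear"] * 3 + ["anger"] * 3)
        pattern = rng.standard_normal(6)
        feats = np.tile(pattern[None, None, :], (4, 6, 1))
        ds = _toy_dataset(feats, labels)
        for mat in build_rsm(estimate_betas(ds, 1)).values():
            assert mat.loc["fear", "anger"] == pytest.approx(0.0, abs=1e-12)
            assert mat.loc["fear", "fear"] == 0.0

    def test_anticorrelated_patterns_dissimilarity_two(self, rng):
        labels = np.array(["fear"] * 3 + ["anger"] * 3)
        pattern = rng.standard_normal(6)
        feats = np.where((labels == "fear")[None, :, None],
                         pattern[None, None, :], -pattern[None, None, :])
        feats = np.broadcast_to(feats, (4, 6, 6)).copy()
        ds = _toy_dataset(feats, labels)
        for mat in build_rsm(estimate_betas(ds, 1)).values():
            assert mat.loc["fear", "anger"] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_pattern_flagged(self):
        labels = np.array(["fear", "anger"])
        ds = _toy_dataset(np.zeros((2, 2, 4)), labels)
        with pytest.warns(UserWarning, match="zero-variance"):
            mats = build_rsm(estimate_betas(ds, 1))
        assert all(np.isnan(m.loc["fear", "anger"]) for m in mats.values())

    def test_planted_group_difference_recovered(self, rng):
        # anxious: opposed fear/anger condition patterns (dissimilarity -> 2);
        # control: a common pattern for both conditions (dissimilarity -> 0)
        labels = np.array((["fear"] * 4 + ["anger"] * 4) * 2)
        v = 10
        p1, p2 = rng.standard_normal(v), rng.standard_normal(v)
        feats = np.empty((6, len(labels), v))
        for i in range(6):
            anxious = i < 3
            for t, lab in enumerate(labels):
                base = (p1 if lab == "fear" else -p1) if anxious else p2
                feats[i, t] = base + 0.05 * rng.standard_normal(v)
        ds = _toy_dataset(feats, labels,
                          groups=["anxious"] * 3 + ["non_anxious"] * 3)
        rsms = build_rsm(estimate_betas(ds, 1))
        assert rsms["anxious"].loc["fear", "anger"] > 1.5
        assert rsms["non_anxious"].loc["fear", "anger"] < 0.5
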