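"""Weighted multi-rater kappa: oracles, variance, CIs, p-values, bands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emeskappa as ek
from emeskappa.agreement import DegenerateAgreementError
from emeskappa.scales import ALL_SCALES

from .conftest import random_count_matrix
from .oracles import (
    jackknife_se,
    pairwise_weighted_kappa,
    two_rater_contingency_kappa,
)

MAYO = ALL_SCALES["mayo"]


def cm(counts, scale=MAYO):
    return ek.CountMatrix.from_counts(np.asarray(counts), scale)


@st.composite
def rating_assignments(draw, n_subjects=(3, 8), n_raters=(2, 6), K=4):
    """Per-subject rating lists with a common rater count."""
    n = draw(st.integers(*n_subjects))
    r = draw(st.integers(*n_raters))
    rows = draw(
        st.lists(
            st.lists(st.integers(0, K - 1), min_size=r, max_size=r),
            min_size=n,
            max_size=n,
        )
    )
    return np.asarray(rows)


def counts_from_assignments(assign, K=4):
    n = assign.shape[0]
    c = np.zeros((n, K), dtype=np.int64)
    for i, row in enumerate(assign):
        c[i] = np.bincount(row, minlength=K)
    return c


class TestWeights:
    @pytest.mark.parametrize("scheme", ek.WEIGHT_SCHEMES)
    @pytest.mark.parametrize("K", [2, 3, 4, 12, 56])
    def test_invariants(self, scheme, K):
        w = ek.make_weights(scheme, K).w
        assert np.allclose(w, w.T)
        assert np.allclose(np.diag(w), 1.0)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_closed_forms(self):
        lin = ek.make_weights("linear", 4).w
        assert lin[0, 3] == 0.0
        assert lin[0, 2] == pytest.approx(1 / 3)
        assert lin[0, 1] == pytest.approx(2 / 3)
        quad = ek.make_weights("quadratic", 3).w
        assert quad[0, 2] == 0.0
        assert quad[0, 1] == pytest.approx(0.75)
        ident = ek.make_weights("identity", 3).w
        assert np.array_equal(ident, np.eye(3))

    def test_K_below_2_rejected(self):
        with pytest.raises(ValueError):
            ek.make_weights("linear", 1)


class TestBuildCountMatrix:
    def test_direct_tabulation(self):
        recs = []
        for rater, v in zip("ABC", (0, 1, 1)):
            recs.append(ek.RatingRecord(rater, "S_A", "rectum", "erythema", v))
        for rater, v in zip("ABC", (3, 3, 2)):
            recs.append(ek.RatingRecord(rater, "S_B", "rectum", "erythema", v))
        t = ek.RatingsTable.from_records(recs)
        counts = ek.build_count_matrix(t, "erythema", "rectum")
        expected = {"S_A": [1, 2, 0, 0], "S_B": [0, 0, 1, 2]}
        for sid, row in zip(counts.subject_ids, counts.counts):
            assert list(row) == expected[sid]

    def test_all_zero_grades(self):
        recs = [
            ek.RatingRecord(r, s, "sigmoid", "ulcers", 0)
            for r in "ABC"
            for s in ("S1", "S2")
        ]
        t = ek.RatingsTable.from_records(recs)
        counts = ek.build_count_matrix(t, "ulcers", "sigmoid")
        assert counts.counts.tolist() == [[3, 0, 0, 0], [3, 0, 0, 0]]

    def test_derived_global_scale_spans_full_range(self):
        recs = []
        for rater, grade in (("RA", 0), ("RB", 3)):
            vp = 2 if grade else 0
            for seg in ek.SEGMENTS:
                for item in ek.EMES_ITEMS:
                    v = vp if item == "vascular_pattern" else grade
                    recs.append(ek.RatingRecord(rater, "S1", seg.value, item, v))
        t = ek.RatingsTable.from_records(recs)
        counts = ek.build_count_matrix(t, "global_emes")
        assert counts.K == 56
        row = counts.counts[0]
        assert row[0] == 1 and row[55] == 1 and row.sum() == 2

    def test_unknown_item_and_empty_selection(self, zero_noise_table):
        with pytest.raises(ValueError, match="unknown item"):
            ek.build_count_matrix(zero_noise_table, "bleeding", "rectum")
        recs = [ek.RatingRecord("R", "S", "rectum", "erythema", 1),
                ek.RatingRecord("Q", "S", "rectum", "erythema", 1)]
        t = ek.RatingsTable.from_records(recs)
        with pytest.raises(ValueError, match="empty selection"):
            ek.build_count_matrix(t, "erythema", "sigmoid")

    def test_single_rater_subjects_dropped(self):
        c = np.array([[1, 0, 0, 0], [2, 1, 0, 0]])
        m = ek.CountMatrix.from_counts(c, MAYO)
        assert m.n_subjects == 1 and m.n_dropped == 1


class TestWeightedFleissKappa:
    @pytest.mark.parametrize("scheme", ek.WEIGHT_SCHEMES)
    def test_perfect_agreement_is_1(self, scheme):
        counts = cm([[13, 0, 0, 0], [0, 0, 13, 0], [0, 0, 0, 13]])
        w = ek.make_weights(scheme, 4)
        kappa, pa, pe = ek.weighted_fleiss_kappa(counts, w)
        assert kappa == pytest.approx(1.0, abs=1e-12)
        assert pa == pytest.approx(1.0)

    def test_frozen_linear_example(self):
        # brute-force pairwise value frozen from tests/oracles.py
        counts = cm([[3, 0, 0], [0, 2, 1], [1, 1, 1]],
                    scale=ALL_SCALES["vascular_pattern"])
        w = ek.make_weights("linear", 3)
        kappa, _, _ = ek.weighted_fleiss_kappa(counts, w)
        assert kappa == pytest.approx(0.20588235294117654, abs=1e-12)
        ident, _, _ = ek.weighted_fleiss_kappa(
            counts, ek.make_weights("identity", 3)
        )
        assert ident == pytest.approx(0.1346153846153846, abs=1e-12)

    @given(rating_assignments())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_pairwise_oracle_all_schemes(self, assign):
        counts = counts_from_assignments(assign)
        if (counts.sum(axis=0) > 0).sum() < 2:
            return  # degenerate: single category used
        m = cm(counts)
        for scheme in ek.WEIGHT_SCHEMES:
            w = ek.make_weights(scheme, 4)
            kappa, _, _ = ek.weighted_fleiss_kappa(m, w)
            assert kappa == pytest.approx(
                pairwise_weighted_kappa(counts, w.w), abs=1e-12
            )

    def test_two_raters_match_contingency_table_oracle(self, rng):
        for _ in range(25):
            x1 = rng.integers(0, 4, size=16)
            x2 = rng.integers(0, 4, size=16)
            counts = np.zeros((16, 4), dtype=np.int64)
            for i in range(16):
                counts[i, x1[i]] += 1
                counts[i, x2[i]] += 1
            if (counts.sum(axis=0) > 0).sum() < 2:
                continue
            for scheme in ek.WEIGHT_SCHEMES:
                w = ek.make_weights(scheme, 4)
                kappa, _, _ = ek.weighted_fleiss_kappa(cm(counts), w)
                assert kappa == pytest.approx(
                    two_rater_contingency_kappa(x1, x2, w.w, 4), abs=1e-12
                )

    def test_kappa_depends_on_counts_only(self, rng):
        """Permuting rater labels or subject order leaves kappa unchanged."""
        assign = rng.integers(0, 4, size=(10, 5))
        counts = counts_from_assignments(assign)
        w = ek.make_weights("linear", 4)
        base, _, _ = ek.weighted_fleiss_kappa(cm(counts), w)
        # rater-label permutation: shuffle each subject's rating list
        shuffled = np.apply_along_axis(rng.permutation, 1, assign)
        k2, _, _ = ek.weighted_fleiss_kappa(
            cm(counts_from_assignments(shuffled)), w
        )
        assert k2 == pytest.approx(base, abs=1e-15)
        # subject permutation
        k3, _, _ = ek.weighted_fleiss_kappa(
            cm(counts[rng.permutation(10)]), w
        )
        assert k3 == pytest.approx(base, abs=1e-15)

    def test_kappa_never_exceeds_1(self, rng):
        w = ek.make_weights("quadratic", 4)
        for _ in range(50):
            counts = random_count_matrix(rng)
            if (counts.sum(axis=0) > 0).sum() < 2:
                continue
            kappa, pa, pe = ek.weighted_fleiss_kappa(cm(counts), w)
            assert kappa <= 1.0 + 1e-12
            assert (kappa == pytest.approx(1.0)) == (pa == pytest.approx(1.0))

    def test_all_one_category_is_degenerate(self):
        counts = cm([[5, 0, 0, 0], [5, 0, 0, 0]])
        with pytest.raises(DegenerateAgreementError):
            ek.weighted_fleiss_kappa(counts, ek.make_weights("linear", 4))


class TestStandardError:
    def test_identical_subjects_give_zero_se(self):
        counts = cm([[6, 4, 0, 0]] * 5)
        se = ek.kappa_se_asymptotic(counts, ek.make_weights("linear", 4))
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_close_to_jackknife_on_study_like_instances(self, rng):
        w = ek.make_weights("linear", 4)
        for _ in range(20):
            truth = ek.sample_cohort(
                ek.CohortConfig(seed=int(rng.integers(2**31)))
            )
            table = ek.simulate_ratings(
                truth, ek.RaterProfile(), 13, int(rng.integers(2**31))
            )
            counts = ek.build_count_matrix(table, "mayo")
            se_a = ek.kappa_se_asymptotic(counts, w)
            se_j = ek.kappa_se_jackknife(counts, w)
            assert se_a == pytest.approx(se_j, rel=0.10)

    def test_package_jackknife_matches_bruteforce(self, rng):
        counts = random_count_matrix(rng)
        w = ek.make_weights("linear", 4)
        assert ek.kappa_se_jackknife(cm(counts), w) == pytest.approx(
            jackknife_se(counts, w.w), abs=1e-10
        )

    def test_se_scales_as_inverse_sqrt_n(self, rng):
        counts = random_count_matrix(rng)
        w = ek.make_weights("linear", 4)
        se1 = ek.kappa_se_asymptotic(cm(counts), w)
        se2 = ek.kappa_se_asymptotic(cm(np.vstack([counts, counts])), w)
        assert se2 / se1 == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            ek.kappa_se_asymptotic(
                cm([[3, 2, 0, 0]]), ek.make_weights("linear", 4)
            )


class TestBootstrapCI:
    def test_perfect_agreement_ci_is_1_1(self):
        counts = cm([[13, 0, 0, 0], [0, 13, 0, 0], [0, 0, 0, 13]])
        lo, hi, _ = ek.kappa_ci_bootstrap(
            counts, ek.make_weights("linear", 4), B=500, seed=0
        )
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_given_seed(self, rng):
        counts = cm(random_count_matrix(rng))
        w = ek.make_weights("linear", 4)
        a = ek.kappa_ci_bootstrap(counts, w, B=300, seed=11)
        b = ek.kappa_ci_bootstrap(counts, w, B=300, seed=11)
        assert a == b

    def test_independent_raters_ci_covers_zero(self, rng):
        n = 150
        assign = rng.integers(0, 4, size=(n, 13))
        counts = counts_from_assignments(assign)
        lo, hi, _ = ek.kappa_ci_bootstrap(
            cm(counts), ek.make_weights("linear", 4), B=400, seed=2
        )
        assert lo < 0.0 < hi

    def test_small_B_rejected(self, rng):
        counts = cm(random_count_matrix(rng))
        with pytest.raises(ValueError, match="B"):
            ek.kappa_ci_bootstrap(counts, ek.make_weights("linear", 4), B=50)


class TestPValueAndBands:
    def test_null_kappa_gives_p_1(self):
        assert ek.kappa_pvalue(0.0, 0.1) == pytest.approx(1.0)

    def test_normal_quantiles(self):
        assert ek.kappa_pvalue(0.196, 0.1) == pytest.approx(0.05, abs=5e-4)
        assert ek.kappa_pvalue(0.329, 0.1) == pytest.approx(0.001, abs=5e-5)

    def test_zero_se_nonzero_kappa_floors(self):
        p = ek.kappa_pvalue(0.8, 0.0)
        assert 0 < p < 1e-300

    @pytest.mark.parametrize(
        "kappa, band",
        [
            (-0.01, "poor"),
            (0.0, "slight"),
            (0.10, "slight"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.56, "moderate"),
            (0.60, "moderate"),
            (0.74, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
            (-1.0, "poor"),
        ],
    )
    def test_agreement_bands(self, kappa, band):
        assert ek.label_agreement(kappa) == band

    def test_out_of_range_kappa_rejected(self):
        with pytest.raises(ValueError):
            ek.label_agreement(1.5)


class TestKappaAnalysis:
    def test_result_invariants(self, rng):
        counts = cm(random_count_matrix(rng))
        res = ek.kappa_analysis(counts, ek.make_weights("linear", 4))
        assert res.ci_low <= res.kappa <= res.ci_high
        assert res.kappa == pytest.approx(
            (res.pa - res.pe) / (1 - res.pe), abs=1e-12
        )
        assert res.label == ek.label_agreement(res.kappa)
        assert res.n_subjects == 16
        assert res.n_raters_min == res.n_raters_max == 13

    def test_degenerate_input_flagged_not_silent(self):
        counts = cm([[5, 0, 0, 0], [5, 0, 0, 0]])
        res = ek.kappa_analysis(counts, ek.make_weights("linear", 4))
        assert res.flag == "degenerate"
        assert np.isnan(res.kappa)

    def test_bootstrap_ci_method(self, rng):
        counts = cm(random_count_matrix(rng))
        res = ek.kappa_analysis(
            counts, ek.make_weights("linear", 4),
            ci_method="bootstrap", B=300, seed=5,
        )
        assert res.ci_low <= res.kappa <= res.ci_high
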