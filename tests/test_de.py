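"""Differential-expression branch: size factors, NB Wald, moderated t, BH,
fold-change arithmetic and threshold screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from keloidcerna.de import (
    DERecord,
    DEThresholds,
    bh_adjust,
    log2fc_of_means,
    moderated_t_test,
    nb_wald_test,
    screen_de,
    size_factors,
)
from keloidcerna.reference import load_keloid_lncrna_reference, screened_reference

from conftest import make_sheet, make_matrix, two_condition_matrix


def brute_force_bh(pvalues):
    """Step-up definition evaluated literally: padj_i = min over j with
    p_(j) >= p_(i) of m * p_(j) / j, capped at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [None] * m
    for rank_i, i in enumerate(order, start=1):
        candidates = [
            m * p[j] / rank_j
            for rank_j, j in enumerate(order, start=1)
            if rank_j >= rank_i
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = two_condition_matrix([[5, 5, 5, 5], [10, 10, 10, 10]])
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_hand_evaluation(self):
        """3-gene, 2-sample matrix with column2 = 2 × column1: factors are
        proportional to (1, 2); median-of-ratios pins them at (1/√2, √2)."""
        counts = two_condition_matrix(np.array([[4, 8], [10, 20], [50, 100]]))
        factors = size_factors(counts)
        assert factors["S1"] / factors["S0"] == pytest.approx(2.0)
        assert factors["S0"] == pytest.approx(1 / math.sqrt(2))

    def test_all_zero_gene_excluded_from_median(self):
        base = np.array([[4, 8], [10, 20], [50, 100]])
        with_zero = np.vstack([base, [0, 0]])
        f1 = size_factors(two_condition_matrix(base))
        f2 = size_factors(two_condition_matrix(with_zero))
        np.testing.assert_allclose(f1.values, f2.values)

    def test_no_always_positive_gene_is_an_error(self):
        counts = two_condition_matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="positive"):
            size_factors(counts)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.01]), [0.01])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_output_at_least_input(self, pvalues):
        adjusted = bh_adjust(pvalues)
        assert np.all(adjusted >= np.asarray(pvalues) - 1e-15)
        assert np.all(adjusted <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_definition_by_enumeration(self):
        """All p-vectors of length <= 6 over a coarse grid agree with a
        literal evaluation of the step-up definition."""
        import itertools

        grid = [0.0, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for m in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, m):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), brute_force_bh(combo), atol=1e-12
                )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=15))
    def test_matches_statsmodels(self, pvalues):
        expected = multipletests(pvalues, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(pvalues), expected, atol=1e-12)


class TestLog2fcOfMeans:
    @pytest.mark.parametrize(
        "mean1,mean2,expected",
        [(306.79, 641.38, 1.06), (1350.45, 552.62, -1.29), (66.42, 119.35, 0.85)],
    )
    def test_published_mean_pairs(self, mean1, mean2, expected):
        assert round(log2fc_of_means(mean1, mean2), 2) == expected

    def test_reference_table_reproduced_to_two_decimals(self):
        """All 12 published log2FC values (6 lncRNAs × 2 groups) equal
        log2 of the ratio of the published means after rounding."""
        ref = load_keloid_lncrna_reference()
        for _, row in ref.iterrows():
            for grp in ("keloid", "control"):
                lfc = log2fc_of_means(row[f"{grp}_day0"], row[f"{grp}_day42"])
                assert round(lfc, 2) == row[f"{grp}_log2fc"]

    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_equal_means_give_zero(self, x):
        assert log2fc_of_means(x, x) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            log2fc_of_means(0.0, 5.0)


class TestNbWald:
    def test_identical_conditions_are_null(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, size=(50, 1))
        counts = two_condition_matrix(np.tile(col, (1, 8)))
        for r in nb_wald_test(counts):
            assert abs(r.log2fc) < 1e-9
            assert r.pvalue > 0.99

    def test_all_zero_gene_gets_null_result(self):
        values = np.vstack([[0, 0, 0, 0], np.full(4, 50), np.full(4, 200)])
        records = nb_wald_test(two_condition_matrix(values))
        zero = records[0]
        assert zero.log2fc == 0.0 and zero.pvalue == 1.0

    def test_planted_fourfold_change_recovered(self):
        """200 genes planted at 4-fold among 1800 nulls: the median
        estimated log2FC of the planted genes lands near 2."""
        rng = np.random.default_rng(3)
        n_genes, n = 2000, 8
        means = 2.0 ** rng.uniform(3, 10, n_genes)
        mu = np.tile(means[:, None], (1, 2 * n))
        mu[:200, n:] *= 4.0
        r_nb = 1 / 0.05
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        records = nb_wald_test(two_condition_matrix(counts))
        planted_lfc = [r.log2fc for r in records[:200]]
        assert abs(np.median(planted_lfc) - 2.0) < 0.3

    def test_null_type_one_error_calibrated(self):
        """Raw p < 0.05 fraction on 2000 null NB genes stays in [0.03, 0.07]."""
        rng = np.random.default_rng(1)
        means = 2.0 ** rng.uniform(3, 10, 2000)
        mu = np.tile(means[:, None], (1, 16))
        r_nb = 1 / 0.05
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        records = nb_wald_test(two_condition_matrix(counts))
        frac = np.mean([r.pvalue < 0.05 for r in records])
        assert 0.03 <= frac <= 0.07

    def test_label_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(30, 8))
        forward = nb_wald_test(two_condition_matrix(counts))
        swapped = nb_wald_test(
            two_condition_matrix(counts), condition_pair=("day42", "day0")
        )
        for f, s in zip(forward, swapped):
            assert f.log2fc == pytest.approx(-s.log2fc, abs=1e-12)
            assert f.pvalue == pytest.approx(s.pvalue, abs=1e-12)

    def test_single_sample_condition_rejected(self):
        rows = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "individual_id": ["a", "b", "c"],
             "group": "keloid", "timepoint": ["day0", "day0", "day42"]}
        )
        from keloidcerna.containers import validate_sample_sheet
        sheet = validate_sample_sheet(rows)
        counts = make_matrix(np.ones((2, 3), dtype=int), ["g0", "g1"], sheet, "counts")
        with pytest.raises(ValueError, match="day42"):
            nb_wald_test(counts)


class TestModeratedT:
    def _array(self, seed, n_probes=500, n_planted=20, n=8, sd=0.25, fc=2.0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(6, 12, n_probes)
        vals = np.tile(base[:, None], (1, 2 * n)) + rng.normal(0, sd, (n_probes, 2 * n))
        vals[:n_planted, n:] += np.log2(fc)
        return two_condition_matrix(vals, unit="log2-intensity")

    def test_identical_groups_are_null(self):
        vals = np.tile(np.arange(10, 20, dtype=float)[:, None], (1, 8))
        records = moderated_t_test(two_condition_matrix(vals, unit="log2-intensity"))
        assert all(r.pvalue > 0.99 for r in records)

    def test_planted_probes_flagged(self):
        """Linear FC 2 on 20 of 500 probes at sd 0.25: >= 16 recovered
        under the |FC| > 1.5, p < 0.05 screen."""
        records = screen_de(moderated_t_test(self._array(1)), DEThresholds(), scale="linear")
        flagged = {r.feature_id for r in records if r.significant}
        true_positives = flagged & {f"g{i}" for i in range(20)}
        assert len(true_positives) >= 16

    def test_fold_change_exactly_at_threshold_not_flagged(self):
        record = DERecord("p1", 10.0, 10.0 + math.log2(1.5), math.log2(1.5), 1e-9, 1e-9)
        screened = screen_de([record], DEThresholds(), scale="linear")
        assert not screened[0].significant

    def test_wrong_unit_rejected(self):
        counts = two_condition_matrix(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="log2-intensity"):
            moderated_t_test(counts)

    def test_paired_branch_gains_power_on_blocked_data(self):
        """With a strong per-individual baseline shift, pairing by individual
        recovers a signal the unpaired test dilutes."""
        rng = np.random.default_rng(4)
        n = 8
        individual_effect = rng.normal(0, 3.0, n)
        vals = np.tile(individual_effect, 2)[None, :] + rng.normal(0, 0.2, (1, 2 * n))
        vals[0, n:] += 1.0  # day42 shift
        em = two_condition_matrix(vals, unit="log2-intensity")
        paired = moderated_t_test(em, paired=True)[0]
        unpaired = moderated_t_test(em, paired=False)[0]
        assert paired.pvalue < unpaired.pvalue
        assert paired.pvalue < 0.01


class TestScreen:
    def test_reference_keloid_rows_all_significant(self):
        keloid, control = screened_reference()
        assert all(r.significant for r in keloid)
        assert sum(r.significant for r in control) == 0

    def test_small_p_alone_is_not_enough(self):
        """A |log2FC| of 0.85 fails the screen despite adjusted p 7.08e-3."""
        record = DERecord("AP000317.2", 66.42, 119.35, 0.85, 7.08e-3, 7.08e-3)
        assert not screen_de([record])[0].significant

    def test_raw_p_switch(self):
        record = DERecord("g", 1.0, 4.0, 2.0, 0.01, 0.5)
        assert not screen_de([record])[0].significant
        assert screen_de([record], DEThresholds(use_adjusted_p=False))[0].significant

    def test_strict_inequalities_at_both_thresholds(self):
        at_lfc = DERecord("g1", 100.0, 200.0, 1.0, 1e-9, 1e-9)
        at_alpha = DERecord("g2", 100.0, 500.0, math.log2(5), 0.05, 0.05)
        screened = screen_de([at_lfc, at_alpha])
        assert not screened[0].significant
        assert not screened[1].significant
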