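"""Generator contracts: determinism, ground-truth consistency, planted signal."""

import numpy as np
import pytest

from keloidcerna.coexpression import pearson_cc
from keloidcerna.de import DEThresholds, nb_wald_test, screen_de
from keloidcerna.quantify import compute_fpkm, log2_fpkm
from keloidcerna.simulate import (
    SimulationConfig,
    emit_target_table,
    simulate_counts,
    simulate_mirna_array,
)
from keloidcerna.specificity import keloid_specific_features


def test_deterministic_under_fixed_seed(small_config):
    c1, s1, _, l1, t1 = simulate_counts(small_config)
    c2, s2, _, l2, t2 = simulate_counts(small_config)
    assert c1.values.equals(c2.values)
    assert l1 == l2
    assert t1.planted_triads == t2.planted_triads
    assert t1.de_keloid_only == t2.de_keloid_only
    m1 = simulate_mirna_array(small_config, t1)
    m2 = simulate_mirna_array(small_config, t2)
    assert m1.values.equals(m2.values)


def test_design_matches_study_layout(small_bundle):
    sheet = small_bundle["sheet"]
    assert (sheet["group"] == "keloid").sum() == 16  # 8 individuals × 2 timepoints
    assert (sheet["group"] == "control").sum() == 12
    per_ind = sheet.groupby("individual_id")["timepoint"].nunique()
    assert (per_ind == 2).all()


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="triads"):
        SimulationConfig(n_mrna=50, n_lncrna=2, n_mirna=2, n_planted_triads=5,
                         n_de_keloid_only=0, n_de_shared=0).validate()
    with pytest.raises(ValueError, match="budget"):
        SimulationConfig(n_mrna=10, n_lncrna=10, n_de_keloid_only=50).validate()


def test_ground_truth_consistent_with_biotypes(small_bundle):
    biotypes = small_bundle["biotypes"]
    for lnc, mir, gene in small_bundle["truth"].planted_triads:
        assert biotypes.biotype(lnc) == "lncRNA"
        assert biotypes.biotype(gene) == "mRNA"
        assert mir in small_bundle["truth"].de_mirna
        # triad gene members are keloid-only DE by construction
        assert lnc in small_bundle["truth"].de_keloid_only
        assert gene in small_bundle["truth"].de_keloid_only


class TestTargetTable:
    def test_planted_pairs_always_present(self, small_bundle):
        truth = small_bundle["truth"]
        table = small_bundle["targets"]
        for lnc, mir, gene in truth.planted_triads:
            assert (mir, lnc) in table
            assert (mir, gene) in table

    def test_zero_decoys_gives_exactly_planted(self, small_bundle):
        truth = small_bundle["truth"]
        table = emit_target_table(truth, decoy_fraction=0.0)
        assert len(table) == 2 * len(truth.planted_triads)

    def test_decoys_never_touch_planted_features(self, small_bundle):
        truth = small_bundle["truth"]
        table = small_bundle["targets"]
        planted_mirnas = {t[1] for t in truth.planted_triads}
        planted_genes = {t[0] for t in truth.planted_triads} | {
            t[2] for t in truth.planted_triads
        }
        planted_pairs = {(m, g) for _, m, _ in truth.planted_triads for g in ()}
        for mir, gene in table.pairs:
            if mir in planted_mirnas or gene in planted_genes:
                # must be one of the planted interactions, never a decoy
                assert any(
                    (mir, gene) in {(m, l), (m, g2)}
                    for l, m, g2 in truth.planted_triads
                )


def test_realized_triad_correlations_near_target(small_bundle):
    """Generator self-check: realized pairwise PCCs on the log2 scale sit
    within ±0.05 of the configured triad_pcc over the keloid samples."""
    cfg = small_bundle["config"]
    expr = log2_fpkm(
        compute_fpkm(small_bundle["counts"], small_bundle["lengths"])
    ).select(group="keloid")
    mirna = small_bundle["mirna"].select(group="keloid")
    for lnc, mir, gene in small_bundle["truth"].planted_triads:
        r_lg = pearson_cc(expr.values.loc[lnc], expr.values.loc[gene])
        r_lm = pearson_cc(expr.values.loc[lnc], mirna.values.loc[mir])
        r_gm = pearson_cc(expr.values.loc[gene], mirna.values.loc[mir])
        assert abs(r_lg - cfg.triad_pcc) < 0.05
        assert abs(abs(r_lm) - cfg.triad_pcc) < 0.05 and r_lm < 0
        assert abs(abs(r_gm) - cfg.triad_pcc) < 0.05 and r_gm < 0


def test_nontriad_mirna_uncorrelated_with_random_gene(small_bundle):
    truth = small_bundle["truth"]
    expr = log2_fpkm(
        compute_fpkm(small_bundle["counts"], small_bundle["lengths"])
    ).select(group="keloid")
    mirna = small_bundle["mirna"].select(group="keloid")
    planted_mirnas = {t[1] for t in truth.planted_triads}
    planted_genes = set(truth.de_keloid_only) | set(truth.de_shared)
    rng = np.random.default_rng(3)
    free_mirnas = [m for m in mirna.feature_ids
                   if m not in planted_mirnas and m not in truth.de_mirna]
    free_genes = [g for g in expr.feature_ids if g not in planted_genes]
    hits = 0
    n_checks = 100
    for _ in range(n_checks):
        m = free_mirnas[rng.integers(len(free_mirnas))]
        g = free_genes[rng.integers(len(free_genes))]
        if abs(pearson_cc(mirna.values.loc[m], expr.values.loc[g])) >= 0.5:
            hits += 1
    # null |PCC| at n=16 exceeds 0.5 with probability ~0.05 per pair
    assert hits <= 10


def test_mirna_factor_correlation_matches_calibration(small_config):
    """Loadings are calibrated to the noise level, so a triad miRNA's
    correlation with its latent factor is sqrt(triad_pcc) regardless of the
    absolute noise scale."""
    import dataclasses
    import math

    for sd in (1e-4, 0.25):
        cfg = dataclasses.replace(small_config, array_noise_sd=sd)
        _, _, _, _, truth = simulate_counts(cfg)
        mirna = simulate_mirna_array(cfg, truth).select(group="keloid")
        lnc, mir, gene = truth.planted_triads[0]
        factor = truth.latent_factors.loc[mir, mirna.sample_ids]
        r = pearson_cc(mirna.values.loc[mir], factor)
        assert abs(r) == pytest.approx(math.sqrt(cfg.triad_pcc), abs=0.02)


def test_keloid_only_de_power_at_moderate_effect():
    """Six keloid-only DE genes at |log2FC| ~ 1.3: the screen plus
    subtraction recovers at least five."""
    cfg = SimulationConfig(
        n_mrna=600, n_lncrna=120, n_mirna=60, n_de_keloid_only=6,
        n_de_shared=0, n_planted_triads=0, de_log2fc_magnitude=1.3, seed=17,
    )
    counts, sheet, biotypes, lengths, truth = simulate_counts(cfg)
    thr = DEThresholds()
    keloid = screen_de(nb_wald_test(counts.select(group="keloid")), thr)
    control = screen_de(nb_wald_test(counts.select(group="control")), thr)
    recovered = keloid_specific_features(keloid, control).keloid_specific
    assert len(set(truth.de_keloid_only) & recovered) >= 5


def test_shared_de_genes_are_subtracted(small_bundle):
    truth = small_bundle["truth"]
    counts = small_bundle["counts"]
    thr = DEThresholds()
    keloid = screen_de(nb_wald_test(counts.select(group="keloid")), thr)
    control = screen_de(nb_wald_test(counts.select(group="control")), thr)
    result = keloid_specific_features(keloid, control)
    assert not set(truth.de_shared) & result.keloid_specific
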