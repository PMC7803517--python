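"""Seeded generator for every input the pipeline consumes, with ground truth.

The generator emulates the study design the pipeline targets: 8 keloid-prone
and 6 control individuals, each sampled before injury (day0) and six weeks
after (day42); RNA-seq counts for mRNAs and lncRNAs; log2 miRNA array
intensities on the same samples; an miRNA → target interaction table; gene
biotypes and lengths.

Counts follow a negative binomial with variance mu + dispersion * mu**2.
Keloid-only DE genes get a multiplicative 2**(±de_log2fc_magnitude) shift at
day42 in keloid individuals only; shared DE genes shift in both groups.

Planted competitive triads use one latent factor per triad, shared between
the count and array simulations: the lncRNA and mRNA load positively, the
miRNA negatively, with loadings calibrated in closed form so the realised
pairwise Pearson correlation on the log2 scale is close to ``triad_pcc``.
The factor's mean shifts at day42 in keloid individuals only, so triad
members are simultaneously keloid-specific DE and strongly correlated —
their differential expression is carried by the factor itself rather than a
separate shift.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BiotypeMap, ExpressionMatrix, TargetTable, validate_sample_sheet

_LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    The 8/6 individual split and the paired day0/day42 sampling mirror the
    study design; feature budgets are kept small (2000 mRNA, 300 lncRNA,
    300 miRNA) so the full pipeline runs in seconds.
    """

    n_keloid_individuals: int = 8
    n_control_individuals: int = 6
    n_mrna: int = 2000
    n_lncrna: int = 300
    n_mirna: int = 300
    nb_dispersion: float = 0.05
    baseline_mean_log2_range: tuple[float, float] = (3.0, 10.0)
    n_de_keloid_only: int = 30
    n_de_shared: int = 20
    de_log2fc_magnitude: float = 2.0
    n_planted_triads: int = 3
    triad_pcc: float = 0.99
    triad_factor_shift: float = 5.0  # latent-factor mean shift at keloid day42
    triad_baseline_log2: float = 11.0  # high baseline keeps the factor's low swing count-rich
    n_de_mirna: int = 20
    mirna_linear_fc: float = 2.0
    array_noise_sd: float = 0.25
    array_baseline_log2_range: tuple[float, float] = (6.0, 12.0)
    library_size_sd: float = 0.15  # log2 sd of per-sample depth factors
    gene_length_range: tuple[int, int] = (200, 10000)
    seed: int = 0

    def validate(self) -> None:
        n_genes = self.n_mrna + self.n_lncrna
        needed = 2 * self.n_planted_triads + self.n_de_keloid_only + self.n_de_shared
        if needed > n_genes:
            raise ValueError(
                f"infeasible config: {needed} planted genes exceed the "
                f"{n_genes}-gene feature budget"
            )
        if self.n_planted_triads > min(self.n_lncrna, self.n_mrna, self.n_mirna):
            raise ValueError("more planted triads than available features")
        if self.n_planted_triads + self.n_de_mirna > self.n_mirna:
            raise ValueError("planted miRNAs exceed the miRNA budget")
        if not 0 < self.triad_pcc < 1:
            raise ValueError("triad_pcc must lie strictly between 0 and 1")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    de_keloid_only: dict[str, str]  # feature -> up/down (keloid day42 vs day0)
    de_shared: dict[str, str]
    de_mirna: dict[str, str]
    planted_triads: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    latent_factors: pd.DataFrame = field(default_factory=pd.DataFrame)  # triads × samples


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for group, prefix, n in (
        ("keloid", "K", config.n_keloid_individuals),
        ("control", "N", config.n_control_individuals),
    ):
        for i in range(1, n + 1):
            for timepoint in ("day0", "day42"):
                rows.append(
                    {
                        "sample_id": f"{prefix}{i}_{timepoint}",
                        "individual_id": f"{prefix}{i}",
                        "group": group,
                        "timepoint": timepoint,
                    }
                )
    return validate_sample_sheet(pd.DataFrame(rows))


def _loading(noise_sd: float, rho: float, factor_var: float) -> float:
    """Closed-form loading giving Pearson ~ rho against a same-loading partner."""
    return noise_sd * math.sqrt(rho / (1.0 - rho)) / math.sqrt(factor_var)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, BiotypeMap, dict[str, int], GroundTruth]:
    """Generate the RNA-seq count matrix and all gene-side metadata."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config)
    sample_ids = list(sheet.index)
    n_samples = len(sample_ids)
    keloid_day42 = np.array(
        [(sheet.loc[s, "group"] == "keloid") and (sheet.loc[s, "timepoint"] == "day42")
         for s in sample_ids]
    )
    any_day42 = np.array([sheet.loc[s, "timepoint"] == "day42" for s in sample_ids])

    mrna_ids = [f"GENE{i:04d}" for i in range(1, config.n_mrna + 1)]
    lnc_ids = [f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)]
    mirna_ids = [f"sim-miR-{i:04d}" for i in range(1, config.n_mirna + 1)]
    gene_ids = mrna_ids + lnc_ids
    n_genes = len(gene_ids)
    biotypes = BiotypeMap(
        {**{g: "mRNA" for g in mrna_ids}, **{g: "lncRNA" for g in lnc_ids}}
    )
    lo, hi = config.gene_length_range
    lengths = {g: int(n) for g, n in zip(gene_ids, rng.integers(lo, hi + 1, n_genes))}

    # feature assignment: triad members first, then keloid-only and shared DE
    lnc_pool = [str(g) for g in rng.permutation(lnc_ids)]
    mrna_pool = [str(g) for g in rng.permutation(mrna_ids)]
    mirna_pool = [str(g) for g in rng.permutation(mirna_ids)]
    triad_lnc = [lnc_pool.pop() for _ in range(config.n_planted_triads)]
    triad_mrna = [mrna_pool.pop() for _ in range(config.n_planted_triads)]
    triad_mirna = [mirna_pool.pop() for _ in range(config.n_planted_triads)]
    gene_pool = [str(g) for g in rng.permutation(lnc_pool + mrna_pool)]
    de_keloid = [gene_pool.pop() for _ in range(config.n_de_keloid_only)]
    de_shared = [gene_pool.pop() for _ in range(config.n_de_shared)]
    de_mirna_extra = [mirna_pool.pop() for _ in range(config.n_de_mirna)]

    b_lo, b_hi = config.baseline_mean_log2_range
    base_log2 = rng.uniform(b_lo, b_hi, n_genes)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    log2_mean = np.tile(base_log2[:, None], (1, n_samples)).astype(float)

    truth_keloid: dict[str, str] = {}
    truth_shared: dict[str, str] = {}
    for g in de_keloid:
        sign = rng.choice([-1.0, 1.0])
        log2_mean[gene_index[g], keloid_day42] += sign * config.de_log2fc_magnitude
        truth_keloid[g] = "up" if sign > 0 else "down"
    for g in de_shared:
        sign = rng.choice([-1.0, 1.0])
        log2_mean[gene_index[g], any_day42] += sign * config.de_log2fc_magnitude
        truth_shared[g] = "up" if sign > 0 else "down"

    # latent triad factors: unit-variance noise around a keloid-day42 shift
    m = config.triad_factor_shift
    factor_var = 1.0 + m * m / 4.0  # pooled variance over the keloid samples
    factors = np.empty((config.n_planted_triads, n_samples))
    triad_signs = rng.choice([-1.0, 1.0], size=config.n_planted_triads)
    gene_noise_sd = (
        math.sqrt(2.0 ** -config.triad_baseline_log2 + config.nb_dispersion) / _LN2
    )
    b_gene = _loading(gene_noise_sd, config.triad_pcc, factor_var)
    truth_mirna: dict[str, str] = {}
    triads: list[tuple[str, str, str]] = []
    keloid_mask = np.array([sheet.loc[s, "group"] == "keloid" for s in sample_ids])
    for k in range(config.n_planted_triads):
        factors[k] = rng.normal(0.0, 1.0, n_samples) + m * keloid_day42
        sign = triad_signs[k]
        for g in (triad_lnc[k], triad_mrna[k]):
            idx = gene_index[g]
            # the planted circuit operates in keloid-prone individuals only:
            # control samples stay at baseline so the control contrast is a
            # clean null for triad members
            log2_mean[idx, :] = config.triad_baseline_log2
            log2_mean[idx, keloid_mask] += sign * b_gene * factors[k, keloid_mask]
            truth_keloid[g] = "up" if sign > 0 else "down"
        truth_mirna[triad_mirna[k]] = "down" if sign > 0 else "up"
        triads.append((triad_lnc[k], triad_mirna[k], triad_mrna[k]))
    for mir in de_mirna_extra:
        truth_mirna[mir] = "up" if rng.choice([-1.0, 1.0]) > 0 else "down"

    depth = 2.0 ** rng.normal(0.0, config.library_size_sd, n_samples)
    mu = (2.0 ** log2_mean) * depth[None, :]
    r = 1.0 / max(config.nb_dispersion, 1e-8)
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), sheet, "counts"
    )
    truth = GroundTruth(
        de_keloid_only=truth_keloid,
        de_shared=truth_shared,
        de_mirna=truth_mirna,
        planted_triads=sorted(triads),
        latent_factors=pd.DataFrame(
            factors, index=[t[1] for t in triads], columns=sample_ids
        ),
    )
    return matrix, sheet, biotypes, lengths, truth


def simulate_mirna_array(config: SimulationConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Log2 miRNA array intensities on the same samples as the count matrix.

    Triad miRNAs load negatively on their triad's latent factor (so they are
    anti-correlated with the triad's lncRNA and mRNA and shifted at keloid
    day42); other planted DEmiRNAs shift by log2 of the configured linear
    fold change at keloid day42; everything gets Gaussian noise of sd
    ``array_noise_sd``.
    """
    rng = np.random.default_rng(config.seed + 1)
    sheet = _sample_sheet(config)
    sample_ids = list(sheet.index)
    n_samples = len(sample_ids)
    keloid_day42 = np.array(
        [(sheet.loc[s, "group"] == "keloid") and (sheet.loc[s, "timepoint"] == "day42")
         for s in sample_ids]
    )
    mirna_ids = [f"sim-miR-{i:04d}" for i in range(1, config.n_mirna + 1)]
    a_lo, a_hi = config.array_baseline_log2_range
    base = rng.uniform(a_lo, a_hi, config.n_mirna)
    values = np.tile(base[:, None], (1, n_samples)).astype(float)

    m = config.triad_factor_shift
    factor_var = 1.0 + m * m / 4.0
    b_mir = _loading(config.array_noise_sd, config.triad_pcc, factor_var)
    mir_index = {mir: i for i, mir in enumerate(mirna_ids)}
    triad_mirnas = {t[1] for t in truth.planted_triads}
    keloid_mask = np.array([sheet.loc[s, "group"] == "keloid" for s in sample_ids])
    for lnc, mir, gene in truth.planted_triads:
        # miRNA direction in the truth is opposite the gene direction; like
        # the gene members, the factor loads on keloid samples only
        sign = -1.0 if truth.de_keloid_only[lnc] == "up" else 1.0
        factor = truth.latent_factors.loc[mir].to_numpy()
        values[mir_index[mir], keloid_mask] += sign * b_mir * factor[keloid_mask]
    shift = math.log2(config.mirna_linear_fc)
    for mir, direction in truth.de_mirna.items():
        if mir in triad_mirnas:
            continue
        values[mir_index[mir], keloid_day42] += shift if direction == "up" else -shift
    values += rng.normal(0.0, config.array_noise_sd, values.shape)
    return ExpressionMatrix(
        pd.DataFrame(values, index=mirna_ids, columns=sample_ids), sheet, "log2-intensity"
    )


def emit_target_table(
    truth: GroundTruth,
    decoy_fraction: float = 10.0,
    seed: int = 0,
    mirna_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> TargetTable:
    """Planted (miRNA, lncRNA) and (miRNA, mRNA) pairs plus random decoys.

    Decoys number ``round(decoy_fraction × planted pairs)`` and are drawn
    among non-planted miRNAs and non-planted genes only — they are noise
    interactions in the background, so they can never complete a spurious
    triad with planted features.  ``decoy_fraction=0`` returns exactly the
    planted pairs.
    """
    planted = set()
    for lnc, mir, gene in truth.planted_triads:
        planted.add((mir, lnc))
        planted.add((mir, gene))
    n_decoys = int(round(decoy_fraction * len(planted)))
    if n_decoys and (mirna_ids is None or gene_ids is None):
        raise ValueError("decoys need mirna_ids and gene_ids to draw from")
    pairs = set(planted)
    if n_decoys:
        rng = np.random.default_rng(seed + 2)
        triad_mirnas = {t[1] for t in truth.planted_triads}
        triad_genes = {t[0] for t in truth.planted_triads} | {
            t[2] for t in truth.planted_triads
        }
        free_mirnas = sorted(set(mirna_ids) - triad_mirnas)
        free_genes = sorted(set(gene_ids) - triad_genes)
        while len(pairs) < len(planted) + n_decoys:
            mir = free_mirnas[rng.integers(len(free_mirnas))]
            gene = free_genes[rng.integers(len(free_genes))]
            pairs.add((mir, gene))
    return TargetTable(frozenset(pairs))


def emit_gene_sets(
    truth: GroundTruth,
    universe: list[str],
    n_sets: int = 10,
    set_size: int = 30,
    seed: int = 0,
):
    """Random gene sets plus one set concentrated in keloid-only DE genes.

    A convenience for exercising the enrichment stage end to end: the set
    named ``planted_de_set`` holds the keloid-only DE genes padded with
    random universe members, so it should rank first in the enrichment
    output.
    """
    from .containers import GeneSetCollection

    rng = np.random.default_rng(seed + 3)
    universe = sorted(universe)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(1, n_sets + 1):
        name = f"random_set_{i:02d}"
        sets[name] = set(rng.choice(universe, size=min(set_size, len(universe)), replace=False))
        descriptions[name] = "random background set"
    de_in_universe = [g for g in sorted(truth.de_keloid_only) if g in set(universe)]
    planted = set(de_in_universe[:set_size])
    pad = [g for g in universe if g not in planted]
    while len(planted) < min(set_size, len(universe)):
        planted.add(pad[rng.integers(len(pad))])
    sets["planted_de_set"] = planted
    descriptions["planted_de_set"] = "set concentrated in keloid-only DE genes"
    return GeneSetCollection(sets, descriptions, set(universe))
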