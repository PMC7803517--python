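"""End-to-end orchestration: DE screen → group subtraction → co-expression →
competitive triads → ceRNA network (→ optional enrichment).

The stages run in the fixed order above.  All thresholds live in
:class:`PipelineConfig`; unknown config keys are rejected.  Outputs are
deterministic: identical config and inputs reproduce identical CSV files, and
every output directory carries a sidecar metadata file with the config hash
and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as kio
from .coexpression import (
    CorrelationPair,
    coexpression_pairs,
    negative_mirna_correlations,
)
from .containers import BiotypeMap, ExpressionMatrix, GeneSetCollection, TargetTable
from .de import (
    DERecord,
    DEThresholds,
    moderated_t_test,
    nb_wald_test,
    screen_de,
)
from .enrichment import EnrichmentRecord, fisher_enrichment
from .network import (
    CeRNANetwork,
    CompetitiveTriad,
    annotate_directions,
    assemble_network,
    build_triads,
    triads_to_frame,
)
from .quantify import compute_fpkm, log2_fpkm
from .specificity import GroupSpecificResult, keloid_specific_features

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Union of all stage thresholds plus the seed.

    Defaults reproduce the published screening rules: |log2FC| > 1 and
    FDR < 0.05 for RNA-seq, linear |FC| > 1.5 with p (adjusted) < 0.05 for
    the miRNA array, PCC > 0.95 for co-expression pairs, negative
    correlation below 0 for the miRNA side, and an enrichment alpha of 0.05.
    """

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    mirna_fc_threshold: float = 1.5
    mirna_alpha: float = 0.05
    use_adjusted_p: bool = True
    paired: bool = False
    pcc_threshold: float = 0.95
    neg_threshold: float = 0.0
    correlation_scale: str = "log2"  # log2 | fpkm
    require_de_mirna: bool = True
    mirna_keloid_specific: bool = True
    enrichment_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineInputs:
    """In-memory bundle of everything the pipeline consumes."""

    counts: ExpressionMatrix
    biotypes: BiotypeMap
    lengths: dict[str, int]
    mirna: ExpressionMatrix | None = None
    targets: TargetTable | None = None
    gene_sets: GeneSetCollection | None = None


@dataclass
class PipelineResult:
    de_keloid: list[DERecord]
    de_control: list[DERecord]
    specific_mrna: GroupSpecificResult
    specific_lncrna: GroupSpecificResult
    de_mirna_keloid: list[DERecord] = field(default_factory=list)
    specific_mirna: GroupSpecificResult | None = None
    pairs: list[CorrelationPair] = field(default_factory=list)
    neg_corrs: list[CorrelationPair] = field(default_factory=list)
    triads: list[CompetitiveTriad] = field(default_factory=list)
    network: CeRNANetwork | None = None
    enrichment: list[EnrichmentRecord] = field(default_factory=list)

    @property
    def directions(self) -> dict[str, str]:
        return {**self.specific_mrna.directions, **self.specific_lncrna.directions}


def _rna_thresholds(config: PipelineConfig) -> DEThresholds:
    return DEThresholds(
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
        use_adjusted_p=config.use_adjusted_p,
    )


def _mirna_thresholds(config: PipelineConfig) -> DEThresholds:
    return DEThresholds(
        lfc_threshold=config.lfc_threshold,
        alpha=config.mirna_alpha,
        fc_threshold_linear=config.mirna_fc_threshold,
        use_adjusted_p=config.use_adjusted_p,
    )


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs and return the full result bundle.

    Correlation screening uses log2(FPKM + 1) on the pooled keloid samples
    (both timepoints) unless ``correlation_scale='fpkm'``.  The triad stage
    runs only when a target table is supplied; enrichment only when gene sets
    are supplied.
    """
    config = config or PipelineConfig()
    thr = _rna_thresholds(config)
    log.info("thresholds: |log2FC|>%g, alpha=%g (adjusted=%s); miRNA |FC|>%g, alpha=%g; "
             "PCC>%g, negative<%g",
             config.lfc_threshold, config.alpha, config.use_adjusted_p,
             config.mirna_fc_threshold, config.mirna_alpha,
             config.pcc_threshold, config.neg_threshold)

    # stage 1: DE screen per group, day0 vs day42
    keloid_counts = inputs.counts.select(group="keloid")
    control_counts = inputs.counts.select(group="control")
    de_keloid = screen_de(nb_wald_test(keloid_counts, paired=config.paired), thr)
    de_control = screen_de(nb_wald_test(control_counts, paired=config.paired), thr)

    # stage 2: keloid-specific subtraction, per biotype
    gene_ids = inputs.counts.feature_ids
    mrna_ids = set(inputs.biotypes.genes_of("mRNA", gene_ids))
    lnc_ids = set(inputs.biotypes.genes_of("lncRNA", gene_ids))
    specific_mrna = keloid_specific_features(
        [r for r in de_keloid if r.feature_id in mrna_ids],
        [r for r in de_control if r.feature_id in mrna_ids],
    )
    specific_lnc = keloid_specific_features(
        [r for r in de_keloid if r.feature_id in lnc_ids],
        [r for r in de_control if r.feature_id in lnc_ids],
    )
    result = PipelineResult(de_keloid, de_control, specific_mrna, specific_lnc)
    log.info("keloid-specific: %d mRNAs, %d lncRNAs",
             len(specific_mrna.keloid_specific), len(specific_lnc.keloid_specific))

    # stage 3: miRNA array screen (linear FC criterion)
    de_mirnas: set[str] | None = None
    mirna_directions: dict[str, str] = {}
    if inputs.mirna is not None:
        mthr = _mirna_thresholds(config)
        mir_keloid = screen_de(
            moderated_t_test(inputs.mirna.select(group="keloid"), paired=config.paired),
            mthr, scale="linear",
        )
        result.de_mirna_keloid = mir_keloid
        if config.mirna_keloid_specific:
            mir_control = screen_de(
                moderated_t_test(inputs.mirna.select(group="control"), paired=config.paired),
                mthr, scale="linear",
            )
            result.specific_mirna = keloid_specific_features(mir_keloid, mir_control)
            de_mirnas = result.specific_mirna.keloid_specific
        else:
            de_mirnas = {r.feature_id for r in mir_keloid if r.significant}
        mirna_directions = {r.feature_id: r.direction for r in mir_keloid if r.significant}

    # stage 4: co-expression screen on pooled keloid samples
    fpkm = compute_fpkm(inputs.counts, inputs.lengths)
    expr = log2_fpkm(fpkm) if config.correlation_scale == "log2" else fpkm
    keloid_expr = expr.select(group="keloid")
    lnc_expr = keloid_expr.subset_features(sorted(specific_lnc.keloid_specific))
    mrna_expr = keloid_expr.subset_features(sorted(specific_mrna.keloid_specific))
    if lnc_expr.feature_ids and mrna_expr.feature_ids:
        result.pairs = coexpression_pairs(lnc_expr, mrna_expr, config.pcc_threshold)
    if not result.pairs:
        log.warning("no lncRNA-mRNA pair passed PCC > %g", config.pcc_threshold)

    # stage 5: negative miRNA correlations and triads
    if inputs.mirna is not None and result.pairs and inputs.targets is not None:
        pair_features = sorted(
            {p.feature_a for p in result.pairs} | {p.feature_b for p in result.pairs}
        )
        result.neg_corrs = negative_mirna_correlations(
            pair_features, keloid_expr, inputs.mirna.select(group="keloid"),
            config.neg_threshold,
        )
        result.triads = build_triads(
            result.pairs, result.neg_corrs, inputs.targets,
            de_mirnas=de_mirnas if config.require_de_mirna else None,
        )
        result.triads = annotate_directions(result.triads, result.directions)
        if result.triads:
            result.network = assemble_network(
                result.triads, result.directions, mirna_directions
            )
        else:
            log.warning("no competitive triad found")

    # stage 6: enrichment of keloid-specific mRNAs
    if inputs.gene_sets is not None and specific_mrna.keloid_specific:
        universe = mrna_ids
        result.enrichment = fisher_enrichment(
            specific_mrna.keloid_specific, universe, inputs.gene_sets,
            config.enrichment_alpha,
        )
    return result


def _specific_frame(res: GroupSpecificResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature_id": f, "direction": res.directions[f]}
         for f in sorted(res.keloid_specific)],
        columns=["feature_id", "direction"],
    )


def write_results(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    """Write every result table plus a metadata sidecar to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kio.write_de_table(result.de_keloid, outdir / "de_keloid.csv")
    kio.write_de_table(result.de_control, outdir / "de_control.csv")
    _specific_frame(result.specific_mrna).to_csv(outdir / "keloid_specific_mrna.csv", index=False)
    _specific_frame(result.specific_lncrna).to_csv(outdir / "keloid_specific_lncrna.csv", index=False)
    if result.de_mirna_keloid:
        kio.write_de_table(result.de_mirna_keloid, outdir / "de_mirna_keloid.csv")
    pd.DataFrame(
        [dataclasses.asdict(p) for p in result.pairs],
        columns=["feature_a", "feature_b", "pcc", "n_samples"],
    ).to_csv(outdir / "coexpression_pairs.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        [dataclasses.asdict(p) for p in result.neg_corrs],
        columns=["feature_a", "feature_b", "pcc", "n_samples"],
    ).to_csv(outdir / "negative_mirna_correlations.csv", index=False, float_format="%.6g")
    triads_to_frame(result.triads).to_csv(
        outdir / "triads.csv", index=False, float_format="%.6g"
    )
    if result.network is not None:
        kio.write_network(result.network.nodes, result.network.edges,
                          outdir / "cerna_network.sif", "SIF")
        kio.write_network(result.network.nodes, result.network.edges,
                          outdir / "cerna_network.graphml", "GraphML")
    if result.enrichment:
        pd.DataFrame(
            [dataclasses.asdict(r) for r in result.enrichment]
        ).to_csv(outdir / "enrichment.csv", index=False, float_format="%.6g")
    meta = {"config": config.to_dict(), "config_hash": config.digest(), "seed": config.seed}
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
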