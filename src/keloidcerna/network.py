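"""Competitive-triad assembly and ceRNA network construction.

A competitive triad is an (lncRNA, miRNA, mRNA) triple in which the
lncRNA–mRNA pair passed the positive co-expression screen, both members are
negatively correlated with the miRNA, and both are annotated targets of that
miRNA.  The network wires each triad as two edges — lncRNA–miRNA and
miRNA–mRNA — with no direct lncRNA–mRNA edge: the competition is mediated by
the shared miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .coexpression import CorrelationPair
from .containers import TargetTable
from .specificity import GroupSpecificResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompetitiveTriad:
    lncrna: str
    mirna: str
    mrna: str
    pcc_lnc_mrna: float
    pcc_lnc_mirna: float
    pcc_mrna_mirna: float
    lnc_direction: str = ""
    mrna_direction: str = ""

    @property
    def concordant(self) -> bool:
        """True when lncRNA and mRNA move together — the expected ceRNA pattern."""
        return bool(self.lnc_direction) and self.lnc_direction == self.mrna_direction


@dataclass
class CeRNANetwork:
    """Node/edge tables ready for export; every node belongs to >= 1 triad."""

    nodes: pd.DataFrame  # columns: id, node_class, direction
    edges: pd.DataFrame  # columns: source, target, kind

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_triads(
    pairs: list[CorrelationPair],
    neg_corrs: list[CorrelationPair],
    targets: TargetTable,
    de_mirnas: set[str] | None = None,
) -> list[CompetitiveTriad]:
    """Enumerate competitive triads from the three evidence sources.

    For every retained (lncRNA, mRNA) pair and every miRNA, a triad is
    emitted iff both members are negatively correlated with that miRNA and
    both are annotated targets of it.  When ``de_mirnas`` is given, the miRNA
    must additionally belong to that set (the differentially-expressed-miRNA
    filter, on by default in the pipeline).  Output order is lexicographic by
    (lncrna, mirna, mrna) and independent of input row order.
    """
    neg_by_feature: dict[str, dict[str, float]] = {}
    for c in neg_corrs:
        neg_by_feature.setdefault(c.feature_a, {})[c.feature_b] = c.pcc
    triads: list[CompetitiveTriad] = []
    for pair in pairs:
        lnc, gene = pair.feature_a, pair.feature_b
        lnc_neg = neg_by_feature.get(lnc, {})
        gene_neg = neg_by_feature.get(gene, {})
        for mirna in sorted(set(lnc_neg) & set(gene_neg)):
            if de_mirnas is not None and mirna not in de_mirnas:
                continue
            if (mirna, lnc) not in targets or (mirna, gene) not in targets:
                continue
            triads.append(
                CompetitiveTriad(
                    lnc, mirna, gene, pair.pcc, lnc_neg[mirna], gene_neg[mirna]
                )
            )
    triads.sort(key=lambda t: (t.lncrna, t.mirna, t.mrna))
    return triads


def annotate_directions(
    triads: list[CompetitiveTriad], directions: dict[str, str]
) -> list[CompetitiveTriad]:
    """Attach up/down labels from the keloid-group screen to each triad."""
    out = []
    for t in triads:
        try:
            out.append(
                CompetitiveTriad(
                    t.lncrna, t.mirna, t.mrna,
                    t.pcc_lnc_mrna, t.pcc_lnc_mirna, t.pcc_mrna_mirna,
                    directions[t.lncrna], directions[t.mrna],
                )
            )
        except KeyError as exc:
            raise KeyError(f"no direction recorded for triad member {exc.args[0]!r}") from exc
    return out


def assemble_network(
    triads: list[CompetitiveTriad],
    directions: GroupSpecificResult | dict[str, str],
    mirna_directions: dict[str, str] | None = None,
) -> CeRNANetwork:
    """Union the triads into a deduplicated node/edge network.

    Each triad contributes its lncRNA–miRNA and miRNA–mRNA edge; nodes carry
    molecule class and regulation direction.  Every triad member must have a
    direction (miRNA direction defaults to the opposite of its lncRNA partner
    when no miRNA screen result is supplied, matching the ceRNA expectation).
    """
    if isinstance(directions, GroupSpecificResult):
        directions = directions.directions
    mirna_directions = mirna_directions or {}
    node_rows: dict[str, tuple[str, str]] = {}
    edge_rows: set[tuple[str, str, str]] = set()
    for t in triads:
        for feat, cls in ((t.lncrna, "lncRNA"), (t.mrna, "mRNA")):
            if feat not in directions:
                raise KeyError(f"no direction recorded for triad member {feat!r}")
            node_rows[feat] = (cls, directions[feat])
        mir_dir = mirna_directions.get(
            t.mirna, "down" if directions[t.lncrna] == "up" else "up"
        )
        node_rows[t.mirna] = ("miRNA", mir_dir)
        edge_rows.add((t.lncrna, t.mirna, "lncRNA-miRNA"))
        edge_rows.add((t.mirna, t.mrna, "miRNA-mRNA"))
    nodes = pd.DataFrame(
        [(n, cls, d) for n, (cls, d) in sorted(node_rows.items())],
        columns=["id", "node_class", "direction"],
    )
    edges = pd.DataFrame(sorted(edge_rows), columns=["source", "target", "kind"])
    log.info("ceRNA network: %d nodes, %d edges from %d triads",
             len(nodes), len(edges), len(triads))
    return CeRNANetwork(nodes, edges)


def triads_to_frame(triads: list[CompetitiveTriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncRNA": t.lncrna,
                "miRNA": t.mirna,
                "mRNA": t.mrna,
                "pcc_lnc_mrna": t.pcc_lnc_mrna,
                "pcc_lnc_mirna": t.pcc_lnc_mirna,
                "pcc_mrna_mirna": t.pcc_mrna_mirna,
                "lnc_direction": t.lnc_direction,
                "mrna_direction": t.mrna_direction,
                "concordant": t.concordant,
            }
            for t in triads
        ],
        columns=[
            "lncRNA", "miRNA", "mRNA", "pcc_lnc_mrna", "pcc_lnc_mirna",
            "pcc_mrna_mirna", "lnc_direction", "mrna_direction", "concordant",
        ],
    )
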