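"""Fisher's-exact over-representation analysis against user-supplied gene sets.

One-sided (enrichment-direction) test on the 2×2 table
(in-term / not-in-term) × (DE / not-DE), which equals the hypergeometric
upper-tail probability; BH adjustment across the tested terms; terms with
adjusted p < alpha are flagged.  The gene-set databases themselves are not
bundled — any GMT works.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .containers import GeneSetCollection
from .de import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    term_id: str
    term_description: str
    count: int  # DE genes in the term (the "Ct." column)
    pvalue: float
    padj: float = float("nan")
    significant: bool = False


def fisher_enrichment(
    de_genes,
    universe,
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Per-term one-sided Fisher's exact p, BH-adjusted across tested terms.

    DE genes outside the universe are dropped with a warning; set members
    outside the universe do not count toward the table.  Output is sorted by
    adjusted p then term id.
    """
    universe = set(universe)
    de_genes = set(de_genes)
    if not universe:
        raise ValueError("empty universe")
    if not de_genes:
        raise ValueError("empty DE gene list")
    outside = de_genes - universe
    if outside:
        log.warning("dropping %d DE gene(s) outside the universe", len(outside))
        de_genes &= universe
        if not de_genes:
            raise ValueError("no DE genes left inside the universe")
    n_universe = len(universe)
    n_de = len(de_genes)
    records = []
    for term_id in sorted(sets.sets):
        members = sets.sets[term_id] & universe
        if not members:
            continue
        k = len(members & de_genes)
        # hypergeometric upper tail: P(X >= k) drawing n_de from n_universe
        # with len(members) successes
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members), n_de))
        records.append(
            EnrichmentRecord(term_id, sets.descriptions.get(term_id, ""), k, min(p, 1.0))
        )
    padj = bh_adjust([r.pvalue for r in records])
    for r, q in zip(records, padj):
        r.padj = float(q)
        r.significant = q < alpha
    records.sort(key=lambda r: (r.padj, r.term_id))
    return records
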