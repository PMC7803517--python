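"""Pearson co-expression screening.

The screen works on log2(FPKM + 1) by default, pooling the keloid-prone
samples from both timepoints, because the ceRNA network is keloid-specific by
construction.  lncRNA–mRNA pairs are retained at PCC > 0.95 (strict);
feature–miRNA pairs at PCC < neg_threshold (default 0, with a stringent
−0.95 mode mirroring the positive screen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

PCC_THRESHOLD = 0.95
NEG_THRESHOLD = 0.0


class ZeroVarianceError(ValueError):
    """A correlation is undefined because one vector is constant."""


@dataclass(frozen=True)
class CorrelationPair:
    feature_a: str
    feature_b: str
    pcc: float
    n_samples: int


def pearson_cc(x, y) -> float:
    """Pearson correlation coefficient, clamped to [-1, 1].

    Both vectors must have equal length >= 3 and non-zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ZeroVarianceError("correlation undefined: zero variance input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson between two feature × sample blocks; constant rows -> nan."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ac @ bc.T) / np.outer(sa, sb)
    corr[np.outer(sa == 0, np.ones(len(sb), dtype=bool))] = np.nan
    corr[np.outer(np.ones(len(sa), dtype=bool), sb == 0)] = np.nan
    return np.clip(corr, -1.0, 1.0)


def coexpression_pairs(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    threshold: float = PCC_THRESHOLD,
) -> list[CorrelationPair]:
    """All (lncRNA, mRNA) pairs with PCC strictly above ``threshold``.

    Enumeration is exhaustive over the two matrices' feature sets; the
    matrices must share identical sample columns.  Pairs with an undefined
    correlation (constant feature) are skipped with a log line.
    """
    if lnc_expr.sample_ids != mrna_expr.sample_ids:
        raise ValueError("lncRNA and mRNA matrices must share identical sample columns")
    n = len(lnc_expr.sample_ids)
    corr = _corr_matrix(
        lnc_expr.values.to_numpy(dtype=float), mrna_expr.values.to_numpy(dtype=float)
    )
    pairs: list[CorrelationPair] = []
    for i, lnc in enumerate(lnc_expr.feature_ids):
        for j, gene in enumerate(mrna_expr.feature_ids):
            c = corr[i, j]
            if np.isnan(c):
                log.info("skipping pair (%s, %s): zero-variance feature", lnc, gene)
                continue
            if c > threshold:
                pairs.append(CorrelationPair(lnc, gene, float(c), n))
    pairs.sort(key=lambda p: (p.feature_a, p.feature_b))
    return pairs


def negative_mirna_correlations(
    pair_features,
    rna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    neg_threshold: float = NEG_THRESHOLD,
) -> list[CorrelationPair]:
    """(feature, miRNA) pairs with PCC strictly below ``neg_threshold``.

    RNA and miRNA matrices are matched on shared sample ids (exact string
    equality); no shared samples is an error.
    """
    shared = [s for s in rna_expr.sample_ids if s in set(mirna_expr.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between RNA and miRNA matrices")
    features = [f for f in pair_features if f in rna_expr.values.index]
    features = sorted(set(features))
    if not features:
        return []
    rna = rna_expr.subset_samples(shared).subset_features(features)
    mirna = mirna_expr.subset_samples(shared)
    corr = _corr_matrix(
        rna.values.to_numpy(dtype=float), mirna.values.to_numpy(dtype=float)
    )
    out: list[CorrelationPair] = []
    for i, feat in enumerate(rna.feature_ids):
        for j, mir in enumerate(mirna.feature_ids):
            c = corr[i, j]
            if np.isnan(c):
                log.info("skipping pair (%s, %s): zero-variance feature", feat, mir)
                continue
            if c < neg_threshold:
                out.append(CorrelationPair(feat, mir, float(c), len(shared)))
    out.sort(key=lambda p: (p.feature_a, p.feature_b))
    return out
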