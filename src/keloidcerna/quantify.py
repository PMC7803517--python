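"""Raw counts to FPKM (fragments per kilobase per million mapped fragments).

FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * library_size[s]), where the
library size is the column sum of the supplied count matrix.  FPKM is the
expression unit the downstream correlation screen consumes (after a log2
transform chosen there).
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix


def compute_fpkm(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Convert an integer count matrix to FPKM.

    Every gene must have a length; every sample must have a positive library
    size.  A zero count maps to FPKM 0 exactly.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
    missing = [g for g in counts.feature_ids if g not in lengths]
    if missing:
        raise KeyError(f"no length for gene {missing[0]!r}")
    library = counts.values.sum(axis=0)
    zero = library[library <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    length_vec = np.array([lengths[g] for g in counts.feature_ids], dtype=float)
    fpkm = counts.values.astype(float).mul(1e9) \
        .div(length_vec, axis=0).div(library.astype(float), axis=1)
    return ExpressionMatrix(fpkm, counts.samples, "fpkm")


def log2_fpkm(fpkm: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount); the default scale for the co-expression screen."""
    if fpkm.unit != "fpkm":
        raise ValueError(f"expected an FPKM matrix, got unit {fpkm.unit!r}")
    values = np.log2(fpkm.values + pseudocount)
    return ExpressionMatrix(values, fpkm.samples, "log2-intensity")
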