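"""Published reference values for the six keloid-specific lncRNAs.

The bundled table carries the reported per-condition mean expression
(KDay0/KDay42 and NDay0/NDay42), log2 fold changes, and adjusted p-values for
the six lncRNAs found differentially expressed only in keloid-prone
individuals after injury (DLEU2, AP000317.2, ADIRF-AS1, AC006333.2,
AL137127.1, LINC01725).  It is the fixture the screening and subtraction
stages are validated against: the printed log2FC values equal log2 of the
ratio of the printed means to two decimals, and the |log2FC| > 1, FDR < 0.05
screen plus control subtraction recovers exactly these six, two up and four
down.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .de import DERecord, DEThresholds, screen_de


def load_keloid_lncrna_reference() -> pd.DataFrame:
    """The six-lncRNA reference table as a DataFrame."""
    path = resources.files("keloidcerna").joinpath("data/keloid_lncrna_reference.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def reference_de_records(group: str = "keloid") -> list[DERecord]:
    """DERecord list for one group's columns, log2FC recomputed from the means."""
    table = load_keloid_lncrna_reference()
    prefix = {"keloid": "keloid", "control": "control"}[group]
    from .de import log2fc_of_means

    return [
        DERecord(
            feature_id=row["gene_name"],
            mean_cond1=row[f"{prefix}_day0"],
            mean_cond2=row[f"{prefix}_day42"],
            log2fc=log2fc_of_means(row[f"{prefix}_day0"], row[f"{prefix}_day42"]),
            pvalue=row[f"{prefix}_padj"],
            padj=row[f"{prefix}_padj"],
        )
        for _, row in table.iterrows()
    ]


def screened_reference(
    thresholds: DEThresholds | None = None,
) -> tuple[list[DERecord], list[DERecord]]:
    """Both groups' reference records with significance flags set."""
    thresholds = thresholds or DEThresholds()
    return (
        screen_de(reference_de_records("keloid"), thresholds),
        screen_de(reference_de_records("control"), thresholds),
    )
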