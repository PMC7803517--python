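"""Core in-memory containers shared by every pipeline stage.

Expression data travels as an :class:`ExpressionMatrix` — a features × samples
``pandas.DataFrame`` plus the sample sheet rows for its columns and a unit tag
(``counts``, ``fpkm`` or ``log2-intensity``).  Stages check the unit tag rather
than guessing the scale of their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Recognised expression unit tags.
UNITS = ("counts", "fpkm", "log2-intensity")

#: Sample sheet columns required by the two-group / two-timepoint design.
SAMPLE_SHEET_COLUMNS = ("sample_id", "individual_id", "group", "timepoint")

GROUPS = ("keloid", "control")
TIMEPOINTS = ("day0", "day42")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check sample-sheet invariants and return the sheet indexed by sample_id.

    Invariants: the four required columns are present, sample ids are unique,
    group/timepoint values come from the fixed vocabularies, and no individual
    appears twice at the same timepoint.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s): {', '.join(missing)}")
    sheet = sheet.copy()
    for col in SAMPLE_SHEET_COLUMNS:
        sheet[col] = sheet[col].astype(str)
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample_id in sample sheet: {dup.iloc[0]}")
    bad_group = set(sheet["group"]) - set(GROUPS)
    if bad_group:
        raise FormatError(f"unknown group label(s): {sorted(bad_group)}")
    bad_tp = set(sheet["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"unknown timepoint label(s): {sorted(bad_tp)}")
    pair_counts = sheet.groupby(["individual_id", "timepoint"]).size()
    clashes = pair_counts[pair_counts > 1]
    if len(clashes):
        ind, tp = clashes.index[0]
        raise FormatError(
            f"individual {ind!r} has {clashes.iloc[0]} samples at timepoint {tp!r}"
        )
    return sheet.set_index("sample_id", drop=False)


@dataclass
class ExpressionMatrix:
    """Numeric features × samples matrix with sample metadata and a unit tag."""

    values: pd.DataFrame
    samples: pd.DataFrame  # indexed by sample_id, aligned to values.columns
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata index does not match matrix columns")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return ExpressionMatrix(
            self.values[sample_ids], self.samples.loc[sample_ids], self.unit
        )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        feature_ids = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[feature_ids], self.samples, self.unit)

    def select(self, group: str | None = None, timepoint: str | None = None) -> "ExpressionMatrix":
        """Samples restricted by group and/or timepoint label."""
        mask = pd.Series(True, index=self.samples.index)
        if group is not None:
            mask &= self.samples["group"] == group
        if timepoint is not None:
            mask &= self.samples["timepoint"] == timepoint
        return self.subset_samples(self.samples.index[mask])


@dataclass
class BiotypeMap:
    """Total map gene_id -> biotype; genes absent from the table are 'other'."""

    mapping: dict[str, str] = field(default_factory=dict)

    VALID = ("mRNA", "lncRNA", "other")

    def __post_init__(self) -> None:
        bad = {b for b in self.mapping.values() if b not in self.VALID}
        if bad:
            raise FormatError(f"unknown biotype value(s): {sorted(bad)}")

    def biotype(self, gene_id: str) -> str:
        return self.mapping.get(gene_id, "other")

    def genes_of(self, biotype: str, candidates=None) -> list[str]:
        """Genes with the given biotype, optionally restricted to ``candidates``."""
        if candidates is None:
            return [g for g, b in self.mapping.items() if b == biotype]
        return [g for g in candidates if self.biotype(g) == biotype]


@dataclass(frozen=True)
class TargetTable:
    """Deduplicated set of (miRNA id, target gene id) interaction pairs."""

    pairs: frozenset[tuple[str, str]]

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}

    def targets_of(self, mirna: str) -> set[str]:
        return {t for m, t in self.pairs if m == mirna}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)
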