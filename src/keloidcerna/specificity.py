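"""Keloid-specific feature selection by group subtraction.

A feature is keloid-specific when it passes the DE screen in the keloid-prone
group's day0-vs-day42 contrast but not in the control group's same contrast.
"Expressed in the control group" is read as "significantly differentially
expressed there": keloid-specific transcripts typically still show non-zero
control expression, so literal presence cannot be the exclusion rule.
Direction concordance is not required for exclusion — a feature DE in both
groups is excluded regardless of sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .de import DERecord


@dataclass
class GroupSpecificResult:
    """Set algebra of the two groups' significant features."""

    keloid_de: set[str]
    control_de: set[str]
    keloid_specific: set[str]
    shared: set[str]
    directions: dict[str, str] = field(default_factory=dict)

    def direction(self, feature_id: str) -> str:
        return self.directions[feature_id]


def keloid_specific_features(
    de_keloid: list[DERecord], de_control: list[DERecord]
) -> GroupSpecificResult:
    """Subtract the control group's DE set from the keloid group's.

    Both record lists must have been screened with identical thresholds.
    Directions (up/down) are taken from the keloid-group records.
    """
    keloid_set = {r.feature_id for r in de_keloid if r.significant}
    control_set = {r.feature_id for r in de_control if r.significant}
    specific = keloid_set - control_set
    shared = keloid_set & control_set
    directions = {r.feature_id: r.direction for r in de_keloid if r.significant}
    return GroupSpecificResult(keloid_set, control_set, specific, shared, directions)
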