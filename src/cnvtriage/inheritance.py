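"""Inheritance labelling of proband CNVs from family-member call lists.

A proband CNV is matched against same-type calls from the mother, father
and siblings at a reciprocal-overlap threshold (default 0.5, the
conventional "same variant" criterion for CNV concordance).  With a
complete trio and no parental match the call is de novo; a single-parent
match gives maternal/paternal; matches in both parents are reported as
inherited with the side unresolved; without both parents sequenced no de
novo claim is made.

Size-discordant parental calls (reciprocal overlap below threshold but
high mutual containment) are flagged rather than silently ignored:
under-called parental variants would otherwise masquerade as de novo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotations import CohortEntry
from .core import CnvCall, containment_fraction, reciprocal_overlap

__all__ = ["InheritanceCall", "match_family_cnvs", "infer_inheritance", "label_inheritance"]

DEFAULT_MIN_RECIPROCAL = 0.5
PARENT_RELATIONS = ("mother", "father")


@dataclass(frozen=True)
class FamilyMatch:
    relation: str
    call: CnvCall
    reciprocal: float
    size_discordant: bool = False


@dataclass
class InheritanceCall:
    label: str  # de_novo | maternal | paternal | inherited_unspecified | unknown
    matching_calls: list[FamilyMatch] = field(default_factory=list)
    trio_complete: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.label == "de_novo" and not self.trio_complete:
            raise ValueError("de novo may only be asserted on a complete trio")


def match_family_cnvs(
    cnv: CnvCall,
    internal_cohort: Sequence[CohortEntry],
    family_id: str,
    min_reciprocal: float = DEFAULT_MIN_RECIPROCAL,
) -> list[FamilyMatch]:
    """Same-type family-member calls at reciprocal overlap >= threshold,
    sorted by overlap descending.

    Overlapping-but-size-discordant parental calls (reciprocal below
    threshold, containment of the smaller interval >= 0.9) are returned
    flagged ``size_discordant`` — they do not count as matches for
    labelling but warn against a de novo reading.
    """
    family = [e for e in internal_cohort if e.family_id == family_id and e.relation != "proband"]
    matches: list[FamilyMatch] = []
    for entry in family:
        if entry.call.cnv_type is not cnv.cnv_type:
            continue
        ro = reciprocal_overlap(cnv.interval, entry.call.interval)
        if ro >= min_reciprocal:
            matches.append(FamilyMatch(entry.relation, entry.call, ro))
        elif ro > 0 and entry.relation in PARENT_RELATIONS:
            cont = max(
                containment_fraction(cnv.interval, entry.call.interval),
                containment_fraction(entry.call.interval, cnv.interval),
            )
            if cont >= 0.9:
                matches.append(FamilyMatch(entry.relation, entry.call, ro, size_discordant=True))
    matches.sort(key=lambda m: -m.reciprocal)
    return matches


def infer_inheritance(matches: Sequence[FamilyMatch], trio_complete: bool) -> InheritanceCall:
    """Label from parental matches; siblings are informational only."""
    proper = [m for m in matches if not m.size_discordant]
    parents = {m.relation for m in proper if m.relation in PARENT_RELATIONS}
    flags = []
    if any(m.size_discordant for m in matches):
        flags.append("possible inherited, size-discordant")
    if parents == {"mother"}:
        label = "maternal"
    elif parents == {"father"}:
        label = "paternal"
    elif parents == {"mother", "father"}:
        label = "inherited_unspecified"
    elif trio_complete and not flags:
        label = "de_novo"
    else:
        label = "unknown"
    return InheritanceCall(label, list(matches), trio_complete, flags)


def label_inheritance(
    cnv: CnvCall,
    internal_cohort: Sequence[CohortEntry],
    family_id: str,
    min_reciprocal: float = DEFAULT_MIN_RECIPROCAL,
) -> InheritanceCall:
    """Convenience wrapper: match then infer; trio completeness is read
    from the cohort table (both parents present for the family)."""
    relations = {e.relation for e in internal_cohort if e.family_id == family_id}
    trio_complete = set(PARENT_RELATIONS) <= relations
    matches = match_family_cnvs(cnv, internal_cohort, family_id, min_reciprocal)
    return infer_inheritance(matches, trio_complete)
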