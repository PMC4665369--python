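"""Disruptive-power categories and the decision rule that assigns them.

Heterologous inferential analysis (HIA) grades each rRNA variant by the
strength of evidence available from ribosomes of other organisms and, where
it exists, direct mitochondrial biochemistry:

* ``P`` (proven) — direct biochemical evidence of disruption in the
  mitochondrial system itself (e.g. cybrid studies).
* ``und`` (undetermined) — the site cannot be placed on the high-resolution
  structure, or no heterologous data exist to extrapolate from.
* ``E`` (expectedly disruptive) / ``N`` (certainly not disruptive) —
  direct heterologous mutagenesis data at the residue or its base-pairing
  partner support disruption / tolerance.
* ``L`` (likely disruptive) / ``U`` (unlikely disruptive) — only indirect
  heterologous data, supporting disruption / tolerance.
* ``NEE`` (not enough evidence) — placeable and evaluable, but no evidence
  argues either way.

Direct mitochondrial biochemistry dominates every other flag; lack of
structural placement or of heterologous data comes next; direct heterologous
evidence outranks indirect.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import InputError


class Support(str, Enum):
    """Direction of a body of heterologous evidence."""

    NONE = "none"
    DISRUPTION = "disruption"
    TOLERANCE = "tolerance"


class Category(str, Enum):
    """The seven disruptive-potential categories."""

    NOT_DISRUPTIVE = "N"
    UNLIKELY = "U"
    NOT_ENOUGH_EVIDENCE = "NEE"
    LIKELY = "L"
    EXPECTEDLY = "E"
    UNDETERMINED = "und"
    PROVEN = "P"


#: Grouping order used in the published classification table.
CATEGORY_ORDER = (
    Category.NOT_ENOUGH_EVIDENCE,
    Category.UNLIKELY,
    Category.UNDETERMINED,
    Category.LIKELY,
    Category.EXPECTEDLY,
    Category.PROVEN,
    Category.NOT_DISRUPTIVE,
)


@dataclass(frozen=True)
class EvidenceProfile:
    """Evidence flags feeding the category decision for one variant.

    ``direct_heterologous`` refers to mutagenesis at the residue itself or
    its base-pairing partner in a heterologous ribosome;
    ``indirect_heterologous`` to neighbourhood or conservation-based
    arguments.  A non-``NONE`` direct call implies heterologous data exist.
    """

    placeable_on_structure: bool
    heterologous_data_exists: bool
    direct_heterologous: Support = Support.NONE
    indirect_heterologous: Support = Support.NONE
    direct_mito_biochemical: bool = False

    def __post_init__(self) -> None:
        if (self.direct_heterologous is not Support.NONE
                and not self.heterologous_data_exists):
            raise InputError(
                "direct heterologous evidence recorded while "
                "heterologous_data_exists is false"
            )


def classify(profile: EvidenceProfile) -> Category:
    """Assign the single category implied by an evidence profile."""
    if profile.direct_mito_biochemical:
        return Category.PROVEN
    if not profile.placeable_on_structure or not profile.heterologous_data_exists:
        return Category.UNDETERMINED
    if profile.direct_heterologous is Support.DISRUPTION:
        return Category.EXPECTEDLY
    if profile.direct_heterologous is Support.TOLERANCE:
        return Category.NOT_DISRUPTIVE
    if profile.indirect_heterologous is Support.DISRUPTION:
        return Category.LIKELY
    if profile.indirect_heterologous is Support.TOLERANCE:
        return Category.UNLIKELY
    return Category.NOT_ENOUGH_EVIDENCE


def classify_all(
    profiles: Iterable[EvidenceProfile],
) -> tuple[list[Category], Counter]:
    """Classify a batch of profiles; returns categories plus a histogram.

    The histogram carries a bin for every category (zero where empty) and
    its counts always sum to the number of inputs.
    """
    categories = [classify(p) for p in profiles]
    histogram = Counter({c: 0 for c in Category})
    histogram.update(categories)
    return categories, histogram
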