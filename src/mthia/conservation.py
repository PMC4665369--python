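"""Conservation index (Cv) of rRNA alignment columns on a 0-2 scale.

The index is information-based: for a column with non-gap base frequencies
``f`` and gap fraction ``g``,

    Cv = (2 - H) * (1 - g),   H = -sum f_i log2 f_i

so a gap-free, single-base column scores exactly 2.000 (universal
conservation), a uniform four-base column scores 0, and gaps penalize the
score multiplicatively.  A fully gapped column scores 0.  The definition is
pluggable: :func:`conservation_index` accepts an alternative entropy-to-score
function should a different published index be preferred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import InputError

BASES = ("A", "C", "G", "U")
GAP = "-"


@dataclass(frozen=True)
class AlignmentColumn:
    """One multiple-alignment column over {A, C, G, U, '-'}."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise InputError("alignment column must contain at least one symbol")
        bad = set(self.symbols) - set(BASES) - {GAP}
        if bad:
            raise InputError(f"unknown alignment symbols: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ConservationScore:
    cv: float
    gap_fraction: float


def column_frequencies(
    column: AlignmentColumn,
) -> tuple[dict[str, float], float]:
    """Non-gap base frequencies (summing to 1, or all zero if fully gapped)
    and the gap fraction."""
    counts = Counter(column.symbols)
    n_gap = counts.get(GAP, 0)
    n_base = column.n - n_gap
    gap_fraction = n_gap / column.n
    if n_base == 0:
        return {b: 0.0 for b in BASES}, gap_fraction
    return {b: counts.get(b, 0) / n_base for b in BASES}, gap_fraction


def conservation_index(
    column: AlignmentColumn,
    score_fn: Callable[[float, float], float] | None = None,
) -> ConservationScore:
    """Compute the conservation index of a column.

    ``score_fn(entropy_bits, gap_fraction)`` may replace the default
    ``(2 - H) * (1 - g)`` mapping.
    """
    freqs, gap_fraction = column_frequencies(column)
    probs = np.array([f for f in freqs.values() if f > 0.0])
    entropy = float(-(probs * np.log2(probs)).sum()) if probs.size else 2.0
    if score_fn is None:
        cv = (2.0 - entropy) * (1.0 - gap_fraction)
    else:
        cv = score_fn(entropy, gap_fraction)
    return ConservationScore(cv=cv, gap_fraction=gap_fraction)
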