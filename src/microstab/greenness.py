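"""Twelve-principle green-analytical-chemistry (AGREE-style) scoring.

Each of the twelve greenness principles receives a sub-score in [0, 1]
and a positive integer weight; the overall eco-scale value is the
weighted arithmetic mean

    overall = sum(score_i * weight_i) / sum(weight_i)

which is invariant under uniform weight scaling, monotone in every
sub-score, and bounded by the extreme sub-scores.  The overall value is
banded (default: >= 0.75 is "high greenness") and each sub-score maps to
a colour band for a tabular rendering of the usual clock pictogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import InputError

__all__ = [
    "GreennessPrinciple",
    "GreennessAssessment",
    "aggregate_greenness",
    "score_color",
    "DEFAULT_BAND_EDGES",
    "DEFAULT_COLOR_EDGES",
]

N_PRINCIPLES = 12

#: (lower edge, band label), scanned from the top.
DEFAULT_BAND_EDGES: tuple[tuple[float, str], ...] = (
    (0.75, "high greenness"),
    (0.50, "moderate greenness"),
    (0.00, "low greenness"),
)

#: (lower edge, colour) for per-principle rendering.
DEFAULT_COLOR_EDGES: tuple[tuple[float, str], ...] = (
    (0.85, "dark green"),
    (0.65, "green"),
    (0.45, "yellow"),
    (0.25, "orange"),
    (0.00, "red"),
)


@dataclass(frozen=True)
class GreennessPrinciple:
    """One greenness principle: id 1-12, sub-score in [0, 1], integer weight."""

    principle_id: int
    score: float
    weight: int = 1

    def __post_init__(self):
        if not 1 <= int(self.principle_id) <= N_PRINCIPLES:
            raise InputError(f"principle_id must be 1..12, got {self.principle_id}")
        if not 0.0 <= self.score <= 1.0:
            raise InputError(f"score must lie in [0, 1], got {self.score}")
        if int(self.weight) != self.weight or self.weight < 1:
            raise InputError(f"weight must be a positive integer, got {self.weight}")


@dataclass(frozen=True)
class GreennessAssessment:
    principles: tuple[GreennessPrinciple, ...]
    overall: float
    band: str


def score_color(
    score: float, edges: Sequence[tuple[float, str]] = DEFAULT_COLOR_EDGES
) -> str:
    """Colour band for one sub-score (tabular stand-in for the pictogram)."""
    for lower, color in edges:
        if score >= lower:
            return color
    return edges[-1][1]


def aggregate_greenness(
    principles: Iterable[GreennessPrinciple],
    band_edges: Sequence[tuple[float, str]] = DEFAULT_BAND_EDGES,
) -> GreennessAssessment:
    """Weighted-mean eco-scale value over exactly twelve principles."""
    ps = tuple(principles)
    if len(ps) != N_PRINCIPLES:
        raise InputError(f"expected exactly {N_PRINCIPLES} principles, got {len(ps)}")
    ids = [p.principle_id for p in ps]
    if len(set(ids)) != N_PRINCIPLES:
        raise InputError(f"principle ids must be unique 1..12, got {sorted(ids)}")
    total_weight = sum(p.weight for p in ps)
    overall = sum(p.score * p.weight for p in ps) / total_weight
    band = band_edges[-1][1]
    for lower, label in band_edges:
        if overall >= lower:
            band = label
            break
    return GreennessAssessment(principles=ps, overall=overall, band=band)
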