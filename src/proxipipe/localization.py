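"""Localization inference by comparing prey profiles with marker baits.

A bait's high-confidence prey set is compared against a compendium of
compartment-marker baits (emulating large organellar BioID maps) using the
Jaccard distance, 1 - |A n B| / |A u B|.  The compartment whose marker has
the smallest distance to the query profile is the most plausible residence
of the bait.  An optional exclusion list removes preys with no curated
function or localization from both sides before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, ValidationError


@dataclass(frozen=True)
class Marker:
    marker_bait: str
    compartment: str
    prey_set: frozenset[str]


@dataclass(frozen=True)
class ReferenceCompendium:
    markers: tuple[Marker, ...]

    def __post_init__(self):
        if not self.markers:
            raise ValidationError("compendium has no markers")
        for m in self.markers:
            if not m.prey_set:
                raise ValidationError(f"marker {m.marker_bait!r} has empty prey set")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, Iterable[str]]]):
        markers = tuple(
            Marker(bait, comp, frozenset(str(p).upper() for p in preys))
            for bait, comp, preys in records
        )
        return cls(markers)


def read_compendium(path) -> ReferenceCompendium:
    """Read a long-form TSV (marker_bait, compartment, prey) with header."""
    path = Path(path)
    sets: dict[tuple[str, str], set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError("expected 3 columns", path=path, line=lineno)
            sets.setdefault((parts[0], parts[1]), set()).add(parts[2].upper())
    return ReferenceCompendium.from_records(
        (bait, comp, preys) for (bait, comp), preys in sorted(sets.items())
    )


def jaccard_distance(set_a: set[str], set_b: set[str]) -> float:
    """1 - intersection/union; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValidationError("Jaccard distance undefined for two empty sets")
    return 1.0 - len(a & b) / len(union)


def weighted_jaccard_distance(
    weights_a: Mapping[str, float], weights_b: Mapping[str, float]
) -> float:
    """Quantitative variant: 1 - sum(min w) / sum(max w) over the key union."""
    keys = set(weights_a) | set(weights_b)
    if not keys:
        raise ValidationError("weighted Jaccard undefined for two empty profiles")
    num = sum(min(weights_a.get(k, 0.0), weights_b.get(k, 0.0)) for k in keys)
    den = sum(max(weights_a.get(k, 0.0), weights_b.get(k, 0.0)) for k in keys)
    if den == 0:
        raise ValidationError("weighted Jaccard undefined for all-zero profiles")
    return 1.0 - num / den


def rank_compartments(
    query_preys: set[str],
    compendium: ReferenceCompendium,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Rank compendium markers by Jaccard distance to the query prey set.

    Excluded genes are removed from both the query and every marker before
    the distance is taken.  The result is sorted by ascending distance with
    lexicographic tie-break on the marker name.
    """
    exclude = {g.upper() for g in (exclude or set())}
    query = {g.upper() for g in query_preys} - exclude
    if not query:
        raise ValidationError("query prey set empty after exclusion")
    rows = []
    for m in compendium.markers:
        marker_set = set(m.prey_set) - exclude
        # a marker emptied by exclusion shares nothing with the query
        dist = 1.0 if not marker_set else jaccard_distance(query, marker_set)
        rows.append((m.marker_bait, m.compartment, dist))
    frame = pd.DataFrame(rows, columns=["marker_bait", "compartment", "jaccard_distance"])
    return frame.sort_values(
        ["jaccard_distance", "marker_bait"], kind="mergesort"
    ).reset_index(drop=True)
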