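"""Known-interactor annotation and dot-plot / network-edge exports.

Dot plots follow the ProHits-viz encoding: cell colour is the
control-subtracted spectral count capped at 20, cell size is the count
relative to the prey's maximum across bait-conditions, and the border tier
encodes the BFDR (black <= 0.01, blue <= 0.05, light blue above).  Network
exports are plain edge tables (bait, prey, avg_count, bfdr, is_known) for
downstream renderers; no graphics are produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .scoring import ScoredInteraction

DOTPLOT_CAP = 20.0


@dataclass(frozen=True)
class KnownInteractorList:
    """A set of previously reported interactor gene symbols (uppercased)."""

    source: str
    genes: frozenset[str]

    @classmethod
    def from_genes(cls, genes, source: str = "user") -> "KnownInteractorList":
        genes = frozenset(str(g).upper() for g in genes)
        if not genes:
            raise ValidationError("known-interactor list is empty")
        return cls(source=source, genes=genes)


def read_known_list(path, source: str | None = None) -> KnownInteractorList:
    """Read a known-interactor list from a two-column (source, gene) or
    one-column (gene) TSV with a header row."""
    path = Path(path)
    genes = []
    src = source
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        if ncol not in (1, 2):
            raise ParseError("known list must have 1 or 2 columns", path=path, line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ParseError("inconsistent column count", path=path, line=lineno)
            if ncol == 2:
                src = src or parts[0]
                genes.append(parts[1])
            else:
                genes.append(parts[0])
    return KnownInteractorList.from_genes(genes, source=src or "user")


def annotate_known(
    scored: Sequence[ScoredInteraction], known: KnownInteractorList
) -> tuple[list[ScoredInteraction], int]:
    """Flag each scored prey found in *known* (case-insensitive).

    Returns the annotated list (same objects, ``is_known`` set) and the
    number of distinct flagged preys.
    """
    if not known.genes:
        raise ValidationError("known-interactor list is empty")
    flagged = set()
    for s in scored:
        s.is_known = s.prey.upper() in known.genes
        if s.is_known:
            flagged.add(s.prey.upper())
    return list(scored), len(flagged)


@dataclass(frozen=True)
class DotPlotCell:
    prey: str
    bait_condition: str
    color_value: float  # control-subtracted count, capped at 20
    relative_size: float  # vs the prey's max across bait-conditions
    border_tier: str  # black | blue | lightblue


def bfdr_border_tier(bfdr: float) -> str:
    """Border tier from BFDR; boundary values fall in the stricter tier."""
    if bfdr <= 0.01:
        return "black"
    if bfdr <= 0.05:
        return "blue"
    return "lightblue"


def control_subtracted(avg_count: float, control_counts: Sequence[int]) -> float:
    mean_ctrl = sum(control_counts) / len(control_counts) if control_counts else 0.0
    return max(0.0, avg_count - mean_ctrl)


def export_dotplot_matrix(
    scored_by_condition: Mapping[str, Sequence[ScoredInteraction]],
    prey_subset: set[str] | None = None,
    path=None,
) -> list[DotPlotCell]:
    """Build dot-plot cells for the given preys across bait-conditions.

    One cell is emitted per (prey, bait-condition) in which the prey was
    scored.  Preys whose control-subtracted count is zero in every condition
    carry no size information and are dropped with a warning, as are preys
    absent from every condition.
    """
    by_prey: dict[str, dict[str, ScoredInteraction]] = {}
    for cond, scored in scored_by_condition.items():
        for s in scored:
            if prey_subset is not None and s.prey not in prey_subset:
                continue
            by_prey.setdefault(s.prey, {})[cond] = s
    if prey_subset is not None:
        for prey in sorted(prey_subset - set(by_prey)):
            warnings.warn(f"prey {prey!r} absent from every condition; dropped")
    cells: list[DotPlotCell] = []
    for prey in sorted(by_prey):
        subs = {
            cond: control_subtracted(s.avg_count, s.control_counts)
            for cond, s in by_prey[prey].items()
        }
        max_sub = max(subs.values())
        if max_sub == 0:
            warnings.warn(
                f"prey {prey!r} has zero control-subtracted counts everywhere; dropped"
            )
            continue
        for cond, s in by_prey[prey].items():
            cells.append(
                DotPlotCell(
                    prey=prey,
                    bait_condition=cond,
                    color_value=min(subs[cond], DOTPLOT_CAP),
                    relative_size=subs[cond] / max_sub,
                    border_tier=bfdr_border_tier(s.bfdr),
                )
            )
    if path is not None:
        frame = pd.DataFrame(
            [
                (c.prey, c.bait_condition, c.color_value, c.relative_size, c.border_tier)
                for c in cells
            ],
            columns=["prey", "bait_condition", "color_value", "relative_size", "border_tier"],
        )
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return cells


def export_network_edges(
    scored: Sequence[ScoredInteraction],
    bfdr_max: float,
    known: KnownInteractorList | None = None,
    path=None,
) -> int:
    """Write bait-prey edges at BFDR <= bfdr_max; returns the row count."""
    if not (0 < bfdr_max <= 1):
        raise ValidationError("bfdr_max must lie in (0, 1]")
    rows = []
    for s in scored:
        if s.bfdr <= bfdr_max:
            is_known = (
                s.prey.upper() in known.genes if known is not None else bool(s.is_known)
            )
            rows.append((s.bait_condition, s.prey, s.avg_count, s.bfdr, is_known))
    if path is not None:
        frame = pd.DataFrame(
            rows, columns=["bait", "prey", "avg_count", "bfdr", "is_known"]
        )
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return len(rows)


# -- scored-interaction tables on disk ------------------------------------

_SCORED_COLUMNS = [
    "bait_condition",
    "prey",
    "avg_count",
    "control_counts",
    "prob",
    "bfdr",
    "is_known",
]


def write_scored_table(scored: Sequence[ScoredInteraction], path) -> None:
    rows = [
        (
            s.bait_condition,
            s.prey,
            s.avg_count,
            ",".join(str(c) for c in s.control_counts),
            s.prob,
            s.bfdr,
            "" if s.is_known is None else str(bool(s.is_known)),
        )
        for s in scored
    ]
    pd.DataFrame(rows, columns=_SCORED_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_scored_table(path) -> list[ScoredInteraction]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SCORED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"scored table missing columns {missing}", path=path, line=1)
    out = []
    for _, r in frame.iterrows():
        ctrl = [int(c) for c in r["control_counts"].split(",")] if r["control_counts"] else []
        out.append(
            ScoredInteraction(
                bait_condition=r["bait_condition"],
                prey=r["prey"],
                avg_count=float(r["avg_count"]),
                control_counts=ctrl,
                prob=float(r["prob"]),
                bfdr=float(r["bfdr"]) if r["bfdr"] else float("nan"),
                is_known=None if r["is_known"] == "" else r["is_known"] == "True",
            )
        )
    return out
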