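"""Run-level spectral-count tables and their on-disk dialects.

The central container is :class:`SpectralCountTable`, a long-form table with
one row per (run, prey) pair carrying the bait, experimental condition and
replicate index of the run.  Control runs (cells expressing the free
biotin-ligase tag alone) are identified by the reserved condition label
``"control"``.

Two dialects are supported on disk:

``long_tsv``
    A single tab-delimited file with a header row and the columns
    ``run_id, bait, condition, replicate, prey, count``.  This is the native
    format of the pipeline.

``saint_triplet``
    The three co-located files consumed by SAINT-style scorers — an
    interaction file (run, bait label, prey, count), a bait file (run, bait
    label, T/C flag) and a prey file.  Bait label cells encode
    ``bait|condition|replicate`` so that a table round-trips losslessly.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ParseError, ValidationError

CONTROL_CONDITION = "control"

COLUMNS = ("run_id", "bait", "condition", "replicate", "prey", "count")

_TRIPLET_NAMES = {
    "interaction": "interactions.txt",
    "bait": "baits.txt",
    "prey": "preys.txt",
}


@dataclass(frozen=True)
class SpectralCountTable:
    """Long-form spectral counts with run metadata.

    Use :meth:`from_frame` rather than the raw constructor so the structural
    invariants (no duplicate (run, prey) pairs, non-negative integer counts,
    every non-control run labelled with a bait) are enforced.
    """

    frame: pd.DataFrame

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectralCountTable":
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"count table missing columns: {missing}")
        df = frame.loc[:, list(COLUMNS)].copy()
        for col in ("run_id", "bait", "condition", "prey"):
            df[col] = df[col].astype(str)
        try:
            df["replicate"] = df["replicate"].astype(int)
            df["count"] = df["count"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer replicate or count: {exc}") from None
        if (df["count"] < 0).any():
            raise ValidationError("negative spectral counts")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        dup = df.duplicated(subset=["run_id", "prey"])
        if dup.any():
            first = df.loc[dup, ["run_id", "prey"]].iloc[0]
            raise ValidationError(
                f"duplicate (run_id, prey) pair: ({first['run_id']}, {first['prey']})"
            )
        noncontrol = df[df["condition"] != CONTROL_CONDITION]
        if (noncontrol["bait"].str.strip() == "").any():
            raise ValidationError("non-control run with empty bait")
        # one (bait, condition, replicate) combination per run
        meta = df.groupby("run_id")[["bait", "condition", "replicate"]].nunique()
        if (meta > 1).any().any():
            raise ValidationError("inconsistent run metadata within a run_id")
        return cls(df.reset_index(drop=True))

    # -- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def runs(self) -> pd.DataFrame:
        """One row of metadata per run."""
        return (
            self.frame.groupby("run_id", sort=True)[["bait", "condition", "replicate"]]
            .first()
            .reset_index()
        )

    def is_control_run(self, run_id: str) -> bool:
        cond = self.frame.loc[self.frame["run_id"] == run_id, "condition"]
        return bool((cond == CONTROL_CONDITION).all()) and len(cond) > 0

    def run_ids(self, condition: str | None = None) -> list[str]:
        runs = self.runs
        if condition is not None:
            runs = runs[runs["condition"] == condition]
        return list(runs["run_id"])

    def control_run_ids(self) -> list[str]:
        return self.run_ids(CONTROL_CONDITION)

    def count_matrix(self, run_ids: Iterable[str]) -> pd.DataFrame:
        """Prey x run matrix of counts for the given runs; absent preys are 0."""
        run_ids = list(run_ids)
        sub = self.frame[self.frame["run_id"].isin(run_ids)]
        mat = sub.pivot_table(
            index="prey", columns="run_id", values="count", fill_value=0, aggfunc="sum"
        )
        return mat.reindex(columns=run_ids, fill_value=0).astype(float)

    def equals(self, other: "SpectralCountTable") -> bool:
        key = ["run_id", "prey"]
        a = self.frame.sort_values(key).reset_index(drop=True)
        b = other.frame.sort_values(key).reset_index(drop=True)
        return a.equals(b)


# -- long_tsv dialect ------------------------------------------------------


def _read_long_tsv(path: Path) -> SpectralCountTable:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != list(COLUMNS):
            raise ParseError(
                f"expected header {list(COLUMNS)}, got {header}", path=path, line=1
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(COLUMNS):
                raise ParseError(
                    f"expected {len(COLUMNS)} fields, got {len(parts)}",
                    path=path,
                    line=lineno,
                )
            run_id, bait, condition, replicate, prey, count = parts
            try:
                replicate = int(replicate)
                count = int(count)
            except ValueError:
                raise ParseError(
                    "replicate and count must be integers", path=path, line=lineno
                ) from None
            rows.append((run_id, bait, condition, replicate, prey, count))
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return SpectralCountTable.from_frame(frame)


def _write_long_tsv(table: SpectralCountTable, path: Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# -- saint_triplet dialect -------------------------------------------------


def _encode_bait_label(bait: str, condition: str, replicate: int) -> str:
    for field in (bait, condition):
        if "|" in field:
            raise ValidationError(
                f"'|' not allowed in bait/condition names for saint_triplet: {field!r}"
            )
    return f"{bait}|{condition}|{replicate}"


def _decode_bait_label(label: str, path, lineno: int) -> tuple[str, str, int]:
    parts = label.split("|")
    if len(parts) != 3:
        raise ParseError(f"malformed bait label {label!r}", path=path, line=lineno)
    try:
        rep = int(parts[2])
    except ValueError:
        raise ParseError(
            f"non-integer replicate in bait label {label!r}", path=path, line=lineno
        ) from None
    return parts[0], parts[1], rep


def _write_saint_triplet(table: SpectralCountTable, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    runs = table.runs
    with open(path / _TRIPLET_NAMES["bait"], "w", encoding="utf-8") as fh:
        for _, r in runs.iterrows():
            flag = "C" if r["condition"] == CONTROL_CONDITION else "T"
            label = _encode_bait_label(r["bait"], r["condition"], int(r["replicate"]))
            fh.write(f"{r['run_id']}\t{label}\t{flag}\n")
    labels = {
        r["run_id"]: _encode_bait_label(r["bait"], r["condition"], int(r["replicate"]))
        for _, r in runs.iterrows()
    }
    with open(path / _TRIPLET_NAMES["interaction"], "w", encoding="utf-8") as fh:
        for _, r in table.frame.iterrows():
            fh.write(f"{r['run_id']}\t{labels[r['run_id']]}\t{r['prey']}\t{r['count']}\n")
    preys = sorted(table.frame["prey"].unique())
    with open(path / _TRIPLET_NAMES["prey"], "w", encoding="utf-8") as fh:
        for prey in preys:
            fh.write(f"{prey}\t{prey}\n")


def _read_saint_triplet(path: Path) -> SpectralCountTable:
    for name in _TRIPLET_NAMES.values():
        if not (path / name).exists():
            raise ParseError(f"missing triplet file {name}", path=path)
    meta: dict[str, tuple[str, str, int]] = {}
    with open(path / _TRIPLET_NAMES["bait"], "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError("bait file needs 3 fields", path=path, line=lineno)
            run_id, label, flag = parts
            bait, condition, rep = _decode_bait_label(label, path, lineno)
            if flag == "C" and condition != CONTROL_CONDITION:
                raise ParseError(
                    f"control-flagged run {run_id} with condition {condition!r}",
                    path=path,
                    line=lineno,
                )
            meta[run_id] = (bait, condition, rep)
    rows = []
    with open(path / _TRIPLET_NAMES["interaction"], "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(
                    "interaction file needs 4 fields", path=path, line=lineno
                )
            run_id, _label, prey, count = parts
            if run_id not in meta:
                raise ParseError(f"run {run_id} absent from bait file",
                                 path=path, line=lineno)
            try:
                count = int(count)
            except ValueError:
                raise ParseError("non-integer count", path=path, line=lineno) from None
            bait, condition, rep = meta[run_id]
            rows.append((run_id, bait, condition, rep, prey, count))
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return SpectralCountTable.from_frame(frame)


# -- public API ------------------------------------------------------------


def read_count_table(path, dialect: str = "long_tsv") -> SpectralCountTable:
    """Read a spectral-count table from *path* in the given dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_tsv":
        return _read_long_tsv(path)
    if dialect == "saint_triplet":
        return _read_saint_triplet(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_table(table: SpectralCountTable, path, dialect: str = "long_tsv") -> None:
    """Write *table* so that :func:`read_count_table` round-trips it exactly."""
    path = Path(path)
    if dialect == "long_tsv":
        _write_long_tsv(table, path)
    elif dialect == "saint_triplet":
        _write_saint_triplet(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
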