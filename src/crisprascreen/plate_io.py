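"""Reading, validation and structuring of plate fluorescence tables.

A screening plate carries one sgRNA condition per well group: each well
holds a dual-channel readout — the promoter-driven TdTomato reporter and
the constitutive TagBFP2 transfection control. Tables arrive either as
bulk per-well sums (one row per well) or as per-cell sums from a
high-content reader (one row per segmented TagBFP2-positive cell), and
either "wide" (two channel columns) or "long" (channel + intensity
columns). This module parses both, normalises well identifiers, and
assembles a :class:`ScreenDataset` keyed by condition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PlateTableError",
    "SchemaError",
    "RowValidationError",
    "WellRecord",
    "PerCellRecord",
    "ScreenDataset",
    "normalize_well_id",
    "parse_condition_guides",
    "read_plate_table",
    "read_per_cell_table",
    "aggregate_per_cell",
    "build_screen_dataset",
    "write_plate_table",
]


class PlateTableError(ValueError):
    """Base class for plate-table parsing and validation failures."""


class SchemaError(PlateTableError):
    """The table is missing a required column or has an unrecognisable layout."""


class RowValidationError(PlateTableError):
    """One or more data rows failed parsing or validation.

    Rows are never silently dropped: every rejected row is listed with its
    0-based data-row index and the reason.
    """

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems)
        super().__init__(f"{len(self.problems)} rejected row(s): {lines}")


_WELL_RE = re.compile(r"^([A-Pa-p])0*([0-9]{1,2})$")


def normalize_well_id(well: str) -> str:
    """Normalise a well label to row letter + zero-padded two-digit column.

    ``"A1"`` and ``"a01"`` both become ``"A01"``. Raises ``ValueError`` for
    labels that are not a row letter followed by a column number.
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"unrecognised well id {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col == 0:
        raise ValueError(f"well column must be >= 1 in {well!r}")
    return f"{row}{col:02d}"


def parse_condition_guides(condition: str, control_condition: str | None = None) -> frozenset[str]:
    """Extract the set of sgRNA identifiers named by a condition label.

    Dual conditions are written ``"1+5"`` / ``"sgRNA 1+5"``; the scramble
    control maps to the empty set.
    """
    label = condition.strip()
    if control_condition is not None and label == control_condition:
        return frozenset()
    if label.lower() in {"scr", "scramble", "scrambled"}:
        return frozenset()
    parts = [p.strip() for p in label.split("+")]
    guides = frozenset(p for p in parts if p)
    return guides


@dataclass(frozen=True)
class WellRecord:
    """Channel sums for one well of a screening plate."""

    plate_id: str
    well_id: str
    condition: str
    tdtomato_au: float
    tagbfp_au: float

    def __post_init__(self) -> None:
        if self.tdtomato_au < 0:
            raise ValueError(
                f"tdtomato_au must be >= 0, got {self.tdtomato_au} "
                f"({self.plate_id}/{self.well_id})"
            )
        if self.tagbfp_au <= 0:
            raise ValueError(
                f"tagbfp_au must be > 0, got {self.tagbfp_au} "
                f"({self.plate_id}/{self.well_id})"
            )


@dataclass(frozen=True)
class PerCellRecord:
    """Channel sums for one segmented transfection-control-positive cell.

    ``condition`` is optional (high-content exports often omit it); it can
    be attached later through a well→condition map.
    """

    plate_id: str
    well_id: str
    cell_id: int
    tdtomato_au: float
    tagbfp_au: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.tagbfp_au <= 0:
            raise ValueError("per-cell records require tagbfp_au > 0")


@dataclass
class ScreenDataset:
    """A validated screening dataset keyed by condition."""

    wells: list[WellRecord]
    control_condition: str
    mode: str = "bulk"
    replicate_map: dict[str, list[WellRecord]] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.replicate_map)


# ---------------------------------------------------------------------------
# CSV readers

_CHANNEL_ALIASES = {
    "tdtomato": "tdtomato_au",
    "tdtomato_au": "tdtomato_au",
    "tagbfp": "tagbfp_au",
    "tagbfp2": "tagbfp_au",
    "tagbfp_au": "tagbfp_au",
    "bfp": "tagbfp_au",
}
_WELL_ALIASES = {"well", "well_id"}


def _canonical_columns(df: pd.DataFrame) -> dict[str, str]:
    """Map canonical names onto the actual (lowercased) header names."""
    out: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _CHANNEL_ALIASES:
            out[_CHANNEL_ALIASES[key]] = col
        elif key in _WELL_ALIASES:
            out["well_id"] = col
        elif key in {"plate", "plate_id"}:
            out["plate_id"] = col
        elif key in {"condition", "channel", "intensity", "cell_id", "cell"}:
            out[{"cell": "cell_id"}.get(key, key)] = col
    return out


def _require(cols: Mapping[str, str], names: Iterable[str]) -> None:
    missing = [n for n in names if n not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _parse_float(value, row: int, label: str, problems: list[tuple[int, str]]):
    try:
        x = float(value)
    except (TypeError, ValueError):
        problems.append((row, f"non-numeric {label} value {value!r}"))
        return None
    if x != x:  # NaN
        problems.append((row, f"missing {label} value"))
        return None
    return x


def read_plate_table(path: str | Path) -> list[WellRecord]:
    """Read a bulk plate CSV (wide or long layout, auto-detected by header).

    Wide: ``plate_id, well, condition, tdtomato, tagbfp``.
    Long: ``plate_id, well, condition, channel, intensity`` with one row per
    well × channel.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True, comment="#")
    cols = _canonical_columns(df)
    if "channel" in cols and "intensity" in cols:
        return _records_from_long(df, cols)
    _require(cols, ["plate_id", "well_id", "condition", "tdtomato_au", "tagbfp_au"])
    return _records_from_wide(df, cols)


def _records_from_wide(df: pd.DataFrame, cols: Mapping[str, str]) -> list[WellRecord]:
    problems: list[tuple[int, str]] = []
    records: list[WellRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        td = _parse_float(r[cols["tdtomato_au"]], i, "tdtomato", problems)
        bfp = _parse_float(r[cols["tagbfp_au"]], i, "tagbfp", problems)
        if td is None or bfp is None:
            continue
        try:
            well = normalize_well_id(r[cols["well_id"]])
        except ValueError as exc:
            problems.append((i, str(exc)))
            continue
        if td < 0:
            problems.append((i, f"tdtomato must be >= 0, got {td}"))
            continue
        if bfp <= 0:
            problems.append((i, f"tagbfp must be > 0, got {bfp}"))
            continue
        key = (str(r[cols["plate_id"]]), well)
        if key in seen:
            problems.append((i, f"duplicate well {key[0]}/{key[1]}"))
            continue
        seen.add(key)
        records.append(
            WellRecord(
                plate_id=str(r[cols["plate_id"]]),
                well_id=well,
                condition=str(r[cols["condition"]]).strip(),
                tdtomato_au=td,
                tagbfp_au=bfp,
            )
        )
    if problems:
        raise RowValidationError(problems)
    return records


def _records_from_long(df: pd.DataFrame, cols: Mapping[str, str]) -> list[WellRecord]:
    _require(cols, ["plate_id", "well_id", "condition", "channel", "intensity"])
    problems: list[tuple[int, str]] = []
    # (plate, well) -> {channel: value, condition: label}
    acc: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        value = _parse_float(r[cols["intensity"]], i, "intensity", problems)
        if value is None:
            continue
        try:
            well = normalize_well_id(r[cols["well_id"]])
        except ValueError as exc:
            problems.append((i, str(exc)))
            continue
        channel = str(r[cols["channel"]]).strip().lower()
        if channel not in _CHANNEL_ALIASES:
            problems.append((i, f"unknown channel {r[cols['channel']]!r}"))
            continue
        key = (str(r[cols["plate_id"]]), well)
        slot = acc.setdefault(key, {"condition": str(r[cols["condition"]]).strip()})
        slot[_CHANNEL_ALIASES[channel]] = value
    records: list[WellRecord] = []
    for (plate, well), slot in acc.items():
        if "tdtomato_au" not in slot or "tagbfp_au" not in slot:
            raise SchemaError(f"well {plate}/{well} lacks one of the two channels")
        try:
            records.append(
                WellRecord(plate, well, slot["condition"], slot["tdtomato_au"], slot["tagbfp_au"])
            )
        except ValueError as exc:
            problems.append((-1, f"{plate}/{well}: {exc}"))
    if problems:
        raise RowValidationError(problems)
    return records


def read_per_cell_table(path: str | Path) -> list[PerCellRecord]:
    """Read a per-cell CSV: ``plate_id, well, cell_id, tdtomato, tagbfp``
    (+ optional ``condition``)."""
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True, comment="#")
    cols = _canonical_columns(df)
    _require(cols, ["plate_id", "well_id", "cell_id", "tdtomato_au", "tagbfp_au"])
    problems: list[tuple[int, str]] = []
    records: list[PerCellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        td = _parse_float(r[cols["tdtomato_au"]], i, "tdtomato", problems)
        bfp = _parse_float(r[cols["tagbfp_au"]], i, "tagbfp", problems)
        if td is None or bfp is None:
            continue
        if bfp <= 0:
            problems.append((i, f"tagbfp must be > 0, got {bfp}"))
            continue
        try:
            well = normalize_well_id(r[cols["well_id"]])
            cell = int(r[cols["cell_id"]])
        except ValueError as exc:
            problems.append((i, str(exc)))
            continue
        condition = str(r[cols["condition"]]).strip() if "condition" in cols else ""
        records.append(PerCellRecord(str(r[cols["plate_id"]]), well, cell, td, bfp, condition))
    if problems:
        raise RowValidationError(problems)
    return records


# ---------------------------------------------------------------------------
# Per-cell aggregation

def aggregate_per_cell(
    records: Iterable[PerCellRecord],
    conditions: Mapping[tuple[str, str], str] | None = None,
) -> list[WellRecord]:
    """Collapse per-cell sums to per-well channel means.

    Each well's TdTomato (resp. TagBFP2) value becomes the mean of the
    per-cell sums, so the downstream well ratio equals
    (mean TdTomato per cell) / (mean TagBFP2 per cell) — the high-content
    reader convention. Condition labels come from the records themselves or
    from ``conditions`` keyed by ``(plate_id, well_id)``.
    """
    by_well: dict[tuple[str, str], list[PerCellRecord]] = {}
    for rec in records:
        by_well.setdefault((rec.plate_id, rec.well_id), []).append(rec)
    out: list[WellRecord] = []
    for (plate, well), cells in sorted(by_well.items()):
        n = len(cells)
        td = sum(c.tdtomato_au for c in cells) / n
        bfp = sum(c.tagbfp_au for c in cells) / n
        cond = ""
        if conditions is not None and (plate, well) in conditions:
            cond = conditions[(plate, well)]
        else:
            labels = {c.condition for c in cells if c.condition}
            if len(labels) > 1:
                raise PlateTableError(
                    f"conflicting condition labels in {plate}/{well}: {sorted(labels)}"
                )
            if labels:
                cond = labels.pop()
        out.append(WellRecord(plate, well, cond, td, bfp))
    return out


# ---------------------------------------------------------------------------
# Dataset assembly

def build_screen_dataset(
    wells: Sequence[WellRecord],
    control_condition: str,
    mode: str = "bulk",
    min_replicates: int = 2,
) -> ScreenDataset:
    """Group wells by condition and enforce the screening invariants.

    Every condition (control included) needs at least ``min_replicates``
    replicate wells, and condition labels may reference at most two distinct
    sgRNA identifiers.
    """
    if not wells:
        raise PlateTableError("no wells supplied")
    if mode not in {"bulk", "per_cell"}:
        raise ValueError(f"mode must be 'bulk' or 'per_cell', got {mode!r}")
    replicate_map: dict[str, list[WellRecord]] = {}
    seen: set[tuple[str, str]] = set()
    for w in wells:
        key = (w.plate_id, w.well_id)
        if key in seen:
            raise PlateTableError(f"duplicate well {w.plate_id}/{w.well_id}")
        seen.add(key)
        replicate_map.setdefault(w.condition, []).append(w)
    if control_condition not in replicate_map:
        raise PlateTableError(f"control condition {control_condition!r} absent from dataset")
    thin = sorted(c for c, ws in replicate_map.items() if len(ws) < min_replicates)
    if thin:
        raise PlateTableError(
            f"condition(s) with fewer than {min_replicates} replicate wells: {', '.join(thin)}"
        )
    for cond in replicate_map:
        guides = parse_condition_guides(cond, control_condition)
        if len(guides) > 2:
            raise PlateTableError(
                f"condition {cond!r} references {len(guides)} sgRNA identifiers (max 2)"
            )
    return ScreenDataset(list(wells), control_condition, mode, replicate_map)


def write_plate_table(wells: Iterable[WellRecord], path: str | Path) -> None:
    """Write wells back to the wide CSV schema (round-trips with
    :func:`read_plate_table`)."""
    df = pd.DataFrame(
        [
            {
                "plate_id": w.plate_id,
                "well": w.well_id,
                "condition": w.condition,
                "tdtomato": w.tdtomato_au,
                "tagbfp": w.tagbfp_au,
            }
            for w in wells
        ]
    )
    df.to_csv(path, index=False)
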