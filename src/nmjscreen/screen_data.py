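"""Data model and delimited-text I/O for the behavioral screen.

A screen is a collection of per-larva locomotion records: each fish sits in
a well of a 96-well plate, belongs to a control group or a drug treatment,
and carries the total distance it traveled during the one-hour assay.
Control wells are identified by their group label, never by their column;
the conventional column-1/12 placement is checked by :func:`validate_layout`
but not assumed anywhere else.
"""

from __future__ import annotations

import csv
import enum
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Group",
    "WellAddress",
    "DrugRecord",
    "FishObservation",
    "ScreenTable",
    "ScreenFormatError",
    "ScreenValidationError",
    "read_screen_table",
    "write_screen_table",
    "validate_layout",
]

ROWS = "ABCDEFGH"
N_COLUMNS = 12

#: Column order of the interchange CSV.
CSV_COLUMNS = (
    "plate",
    "row",
    "column",
    "fish_index",
    "group",
    "drug_id",
    "alive",
    "distance_m",
    "excluded",
)


class ScreenFormatError(ValueError):
    """A file does not conform to the screen-table CSV dialect."""


class ScreenValidationError(ValueError):
    """Record contents violate a screen-table invariant."""


class Group(enum.Enum):
    WT_CONTROL = "WT_CONTROL"
    MO_CONTROL = "MO_CONTROL"
    TREATED = "TREATED"


@dataclass(frozen=True, order=True)
class WellAddress:
    """Plate/row/column coordinate of a well (plate and column are 1-based)."""

    plate_index: int
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.plate_index < 1:
            raise ScreenValidationError(f"plate_index must be >= 1, got {self.plate_index}")
        if self.row not in ROWS:
            raise ScreenValidationError(f"row must be one of {ROWS}, got {self.row!r}")
        if not 1 <= self.column <= N_COLUMNS:
            raise ScreenValidationError(
                f"column must be in 1..{N_COLUMNS}, got {self.column}"
            )

    def label(self) -> str:
        return f"P{self.plate_index}:{self.row}{self.column:02d}"


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str = ""
    library_plate: WellAddress | None = None
    therapeutic_class: str | None = None


@dataclass(frozen=True)
class FishObservation:
    """One larva's assay record.

    ``distance_m`` is the total distance traveled in one hour, in meters.
    Dead fish carry ``distance_m == 0`` and ``alive == False``; the zero is a
    toxicity signal, not a motility measurement, and scoring consults
    ``alive`` before using the distance.  ``excluded`` is a manual flag for
    wells judged unusable by the observer (no automatic criterion is applied).
    """

    address: WellAddress
    fish_index: int
    group: Group
    drug_id: str | None
    alive: bool
    distance_m: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ScreenValidationError(f"distance_m must be >= 0, got {self.distance_m}")
        if (self.group is Group.TREATED) != (self.drug_id is not None):
            raise ScreenValidationError(
                "drug_id must be present iff group is TREATED "
                f"(group={self.group.value}, drug_id={self.drug_id!r})"
            )
        if not self.alive and self.distance_m != 0:
            raise ScreenValidationError(
                f"dead fish must carry distance_m = 0, got {self.distance_m}"
            )
        if self.fish_index < 1:
            raise ScreenValidationError(f"fish_index must be >= 1, got {self.fish_index}")


@dataclass
class ScreenTable:
    """All observations of one screen plus the drug annotations."""

    observations: list[FishObservation]
    drugs: list[DrugRecord] = field(default_factory=list)
    replicate_count: int = 4
    #: Unknown CSV columns are preserved here, keyed by column name, one value
    #: per observation row (in file order).
    metadata: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {d.drug_id for d in self.drugs}
        for obs in self.observations:
            if obs.drug_id is not None and obs.drug_id not in known:
                raise ScreenValidationError(
                    f"TREATED observation references unknown drug {obs.drug_id!r}"
                )

    # -- convenience accessors used throughout scoring ---------------------

    def plates(self) -> list[int]:
        return sorted({o.address.plate_index for o in self.observations})

    def on_plate(self, plate_index: int) -> list[FishObservation]:
        return [o for o in self.observations if o.address.plate_index == plate_index]

    def by_drug(self) -> dict[str, list[FishObservation]]:
        out: dict[str, list[FishObservation]] = defaultdict(list)
        for o in self.observations:
            if o.drug_id is not None:
                out[o.drug_id].append(o)
        return dict(out)

    def controls(self, group: Group, plate_index: int | None = None) -> list[FishObservation]:
        return [
            o
            for o in self.observations
            if o.group is group
            and (plate_index is None or o.address.plate_index == plate_index)
        ]


def _parse_bool(text: str, row_num: int, column: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no"}:
        return False
    raise ScreenFormatError(f"row {row_num}: cannot parse {column}={text!r} as boolean")


def read_screen_table(path: str | Path, replicate_count: int = 4) -> ScreenTable:
    """Read a screen table from the interchange CSV.

    Unknown columns are preserved in ``table.metadata``; column order in the
    file is irrelevant.  Raises :class:`ScreenFormatError` for missing
    columns and :class:`ScreenValidationError` (with the offending row
    number) for invariant violations.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ScreenFormatError(f"{path}: empty file, header row required")
        required = set(CSV_COLUMNS) - {"excluded"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ScreenFormatError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        extra_cols = [c for c in reader.fieldnames if c not in CSV_COLUMNS]
        metadata: dict[str, list[str]] = {c: [] for c in extra_cols}

        observations: list[FishObservation] = []
        drug_ids: dict[str, None] = {}
        for row_num, row in enumerate(reader, start=2):
            try:
                group = Group(row["group"].strip())
                drug_id = row["drug_id"].strip() or None
                distance = float(row["distance_m"])
                obs = FishObservation(
                    address=WellAddress(
                        plate_index=int(row["plate"]),
                        row=row["row"].strip(),
                        column=int(row["column"]),
                    ),
                    fish_index=int(row["fish_index"]),
                    group=group,
                    drug_id=drug_id,
                    alive=_parse_bool(row["alive"], row_num, "alive"),
                    distance_m=distance,
                    excluded=_parse_bool(row.get("excluded") or "false", row_num, "excluded"),
                )
            except ScreenValidationError as exc:
                raise ScreenValidationError(f"{path} row {row_num}: {exc}") from None
            except (KeyError, ValueError) as exc:
                raise ScreenFormatError(f"{path} row {row_num}: {exc}") from None
            observations.append(obs)
            if drug_id is not None:
                drug_ids.setdefault(drug_id, None)
            for c in extra_cols:
                metadata[c].append(row.get(c, ""))

    drugs = [DrugRecord(drug_id=d) for d in drug_ids]
    return ScreenTable(
        observations=observations,
        drugs=drugs,
        replicate_count=replicate_count,
        metadata=metadata,
    )


def write_screen_table(table: ScreenTable, path: str | Path) -> Path:
    """Write ``table`` to the interchange CSV; inverse of :func:`read_screen_table`."""
    path = Path(path)
    extra_cols = sorted(table.metadata)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(CSV_COLUMNS) + extra_cols)
        for i, o in enumerate(table.observations):
            row = [
                o.address.plate_index,
                o.address.row,
                o.address.column,
                o.fish_index,
                o.group.value,
                o.drug_id or "",
                "true" if o.alive else "false",
                repr(o.distance_m),
                "true" if o.excluded else "false",
            ]
            row += [table.metadata[c][i] for c in extra_cols]
            writer.writerow(row)
    return path


def validate_layout(table: ScreenTable) -> dict:
    """Report layout anomalies without mutating the table.

    The report lists, per plate, control counts (and whether either control
    group is absent), wells whose fish count differs from
    ``table.replicate_count`` for a single drug, and duplicate
    (address, fish_index) records.  A fully conforming table yields empty
    anomaly lists.
    """
    report: dict = {"plates": {}, "bad_wells": [], "duplicates": [], "off_layout_controls": []}

    seen: Counter = Counter((o.address, o.fish_index) for o in table.observations)
    for (addr, fi), n in sorted(seen.items()):
        if n > 1:
            report["duplicates"].append({"address": addr.label(), "fish_index": fi, "count": n})

    per_well_drug: dict[tuple[WellAddress, str], int] = Counter()
    for o in table.observations:
        if o.drug_id is not None:
            per_well_drug[(o.address, o.drug_id)] += 1
    for (addr, drug), n in sorted(per_well_drug.items()):
        if n != table.replicate_count:
            report["bad_wells"].append(
                {"address": addr.label(), "drug_id": drug, "n_fish": n}
            )

    for plate in table.plates():
        wt = table.controls(Group.WT_CONTROL, plate)
        mo = table.controls(Group.MO_CONTROL, plate)
        entry = {
            "n_wt_controls": len(wt),
            "n_mo_controls": len(mo),
            "missing_wt": len(wt) == 0,
            "missing_mo": len(mo) == 0,
        }
        report["plates"][str(plate)] = entry
        # column-1/12 placement is convention, not an invariant: report only
        for o in wt + mo:
            if o.address.column not in (1, N_COLUMNS):
                report["off_layout_controls"].append(
                    {"address": o.address.label(), "group": o.group.value}
                )

    report["ok"] = (
        not report["bad_wells"]
        and not report["duplicates"]
        and not report["off_layout_controls"]
        and all(
            not (p["missing_wt"] or p["missing_mo"]) for p in report["plates"].values()
        )
    )
    return report


def write_validation_report(report: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
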