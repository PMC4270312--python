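"""Shared data model: plate layouts, acquisition schedules, result I/O.

Concentrations are stored in molar throughout the package; plate-map CSVs
use a ``concentration_uM`` column and conversion happens only at the file
boundary.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "WellSpec",
    "PlateLayout",
    "AcquisitionSchedule",
    "CompoundRecord",
    "R1Class",
    "R2Class",
    "PlateMapError",
    "load_plate_map",
    "save_plate_map",
    "default_schedule",
    "write_results",
    "read_results",
    "parse_address",
]

#: grid dimensions per plate format
_FORMATS = {96: (8, 12), 384: (16, 24)}


class PlateMapError(ValueError):
    """Raised when a plate map violates layout invariants."""


class WellRole(str, enum.Enum):
    TEST = "test"
    VEHICLE = "vehicle"
    POSITIVE_CONTROL = "positive_control"
    UNTREATED = "untreated"


class R1Class(str, enum.Enum):
    NITRO = "nitro"
    HALOGEN = "halogen"
    TRIFLUOROMETHYL = "trifluoromethyl"
    CYANO = "cyano"
    HYDROGEN = "hydrogen"
    OTHER = "other"


class R2Class(str, enum.Enum):
    ALIPHATIC = "aliphatic"
    BENZYLPIPERIDINYL = "benzylpiperidinyl"
    PHENETHYLPIPERIDINYL = "phenethylpiperidinyl"
    OTHER = "other"


def parse_address(address: str) -> tuple[int, int]:
    """Parse a well address like ``"A1"`` into 0-based (row, column).

    Row letters run A.. (single letter); columns are 1-based in the address.
    """
    address = address.strip()
    if len(address) < 2 or address[0].upper() not in string.ascii_uppercase:
        raise PlateMapError(f"malformed well address: {address!r}")
    row = string.ascii_uppercase.index(address[0].upper())
    try:
        col = int(address[1:])
    except ValueError as exc:
        raise PlateMapError(f"malformed well address: {address!r}") from exc
    if col < 1:
        raise PlateMapError(f"column must be >= 1 in address {address!r}")
    return row, col - 1


@dataclass(frozen=True)
class WellSpec:
    """One well of a plate map."""

    address: str
    role: WellRole
    compound_id: str | None = None
    concentration: float | None = None  # molar
    replicate_group: str = ""

    def __post_init__(self) -> None:
        parse_address(self.address)
        if self.role is WellRole.VEHICLE and self.compound_id:
            raise PlateMapError(
                f"vehicle well {self.address} must not carry a compound"
            )
        if self.role is WellRole.TEST:
            if not self.compound_id:
                raise PlateMapError(f"test well {self.address} lacks compound_id")
            if self.concentration is None or self.concentration <= 0:
                raise PlateMapError(
                    f"test well {self.address} needs concentration > 0"
                )


@dataclass(frozen=True)
class PlateLayout:
    """A validated plate map."""

    plate_id: str
    format: int
    wells: tuple[WellSpec, ...]

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise PlateMapError(f"unsupported plate format: {self.format}")
        if not self.wells:
            raise PlateMapError("no wells")
        seen: set[str] = set()
        n_rows, n_cols = _FORMATS[self.format]
        for w in self.wells:
            if w.address in seen:
                raise PlateMapError(f"duplicate address: {w.address}")
            seen.add(w.address)
            r, c = parse_address(w.address)
            if r >= n_rows or c >= n_cols:
                raise PlateMapError(
                    f"address {w.address} outside {self.format}-well grid"
                )

    def wells_with_role(self, role: WellRole) -> list[WellSpec]:
        return [w for w in self.wells if w.role is role]

    def compounds(self) -> list[str]:
        out: list[str] = []
        for w in self.wells:
            if w.role is WellRole.TEST and w.compound_id not in out:
                out.append(w.compound_id)  # type: ignore[arg-type]
        return out

    def replicate_wells(self, compound_id: str) -> list[WellSpec]:
        return [
            w
            for w in self.wells
            if w.role is WellRole.TEST and w.compound_id == compound_id
        ]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame timestamps (seconds) plus the index of the first post-stimulus
    frame."""

    timestamps: tuple[float, ...]
    dispense_index: int

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.size < 2:
            raise ValueError("schedule needs at least two frames")
        if ts[0] != 0.0:
            raise ValueError("first timestamp must be 0")
        if not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not 1 <= self.dispense_index < ts.size:
            raise ValueError("dispense_index out of range")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def total_duration(self) -> float:
        return self.timestamps[-1] - self.timestamps[0]

    @property
    def pre_indices(self) -> slice:
        return slice(0, self.dispense_index)

    @property
    def post_indices(self) -> slice:
        return slice(self.dispense_index, None)

    def to_dict(self) -> dict[str, Any]:
        return {
            "timestamps": list(self.timestamps),
            "dispense_index": self.dispense_index,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AcquisitionSchedule":
        return cls(tuple(float(t) for t in d["timestamps"]), int(d["dispense_index"]))


@dataclass(frozen=True)
class CompoundRecord:
    """Substituent annotation for one compound."""

    compound_id: str
    r1_class: R1Class = R1Class.OTHER
    r2_class: R2Class = R2Class.OTHER
    source: str = "library"  # library | commercial | synthesized


def default_schedule() -> AcquisitionSchedule:
    """The default 13-frame time-lapse schedule.

    Three pre-stimulus frames at 2.5 s spacing, five post-stimulus frames at
    1 s spacing, then five more at 2.5 s spacing; the stimulus is dispensed
    between frames 2 and 3.
    """
    pre = [0.0, 2.5, 5.0]
    fast = [6.0, 7.0, 8.0, 9.0, 10.0]
    slow = [12.5, 15.0, 17.5, 20.0, 22.5]
    return AcquisitionSchedule(tuple(pre + fast + slow), dispense_index=3)


def load_plate_map(path: str | Path, plate_id: str | None = None) -> PlateLayout:
    """Load and validate a plate map CSV.

    Expected columns: ``address,role,compound_id,concentration_uM,
    replicate_group``.  The plate format (96 vs 384) is inferred as the
    smallest grid containing every address.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"address": str, "compound_id": str})
    except pd.errors.EmptyDataError as exc:
        raise PlateMapError("no wells") from exc
    if df.empty:
        raise PlateMapError("no wells")
    required = {"address", "role", "compound_id", "concentration_uM", "replicate_group"}
    missing = required - set(df.columns)
    if missing:
        raise PlateMapError(f"plate map missing columns: {sorted(missing)}")

    wells: list[WellSpec] = []
    for row in df.itertuples(index=False):
        try:
            role = WellRole(str(row.role).strip())
        except ValueError as exc:
            raise PlateMapError(f"unknown role: {row.role!r}") from exc
        compound = None if pd.isna(row.compound_id) or row.compound_id == "" else str(row.compound_id)
        conc_um = row.concentration_uM
        if pd.isna(conc_um) or conc_um == "":
            conc = None
        else:
            try:
                conc = float(conc_um) * 1e-6
            except (TypeError, ValueError) as exc:
                raise PlateMapError(
                    f"malformed concentration {conc_um!r} in well {row.address}"
                ) from exc
        group = "" if pd.isna(row.replicate_group) else str(row.replicate_group)
        wells.append(
            WellSpec(
                address=str(row.address),
                role=role,
                compound_id=compound,
                concentration=conc,
                replicate_group=group,
            )
        )

    max_row = max(parse_address(w.address)[0] for w in wells)
    max_col = max(parse_address(w.address)[1] for w in wells)
    fmt = 96 if (max_row < 8 and max_col < 12 and len(wells) <= 96) else 384
    return PlateLayout(plate_id=plate_id or path.stem, format=fmt, wells=tuple(wells))


def save_plate_map(layout: PlateLayout, path: str | Path) -> None:
    """Write a layout back to the CSV interchange format."""
    rows = []
    for w in layout.wells:
        rows.append(
            {
                "address": w.address,
                "role": w.role.value,
                "compound_id": w.compound_id or "",
                "concentration_uM": ""
                if w.concentration is None
                else repr(w.concentration * 1e6),
                "replicate_group": w.replicate_group,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(records: Any, path: str | Path) -> None:
    """Serialize a result table (CSV) or nested structure (JSON).

    DataFrames go to CSV with full float precision so a load-back is equal
    to 1e-9 relative; anything else is written as JSON.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("refusing to write an empty result table")
        records.to_csv(path, index=False, float_format="%.17g")
        return
    if records is None or (hasattr(records, "__len__") and len(records) == 0):
        raise ValueError("refusing to write empty results")
    with open(path, "w") as fh:
        json.dump(_jsonable(records), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: str | Path) -> Any:
    """Read back a file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return json.load(fh)
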