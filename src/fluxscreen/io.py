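"""Data model and delimited-text I/O for reporter screens.

The interchange unit is the per-well median reporter fluorescence: one row
per (compound, medium condition, biological replicate).  Raw per-event flow
cytometry files are deliberately not parsed; the screen statistic operates
on well medians, so medians are what travels between tools.

Vehicle (mock-treated) wells carry a sentinel compound identifier, ``DMSO``
by default, and are the normalization anchor for every condition.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from os import PathLike
from typing import Any, Mapping, Sequence

import pandas as pd

__all__ = [
    "Condition",
    "Dialect",
    "CompoundRecord",
    "WellMeasurement",
    "ScreenTable",
    "ScreenFormatError",
    "ScreenValidationError",
    "read_screen_table",
    "write_screen_table",
    "read_codemap",
    "write_codemap",
    "blind",
    "unblind",
    "write_results_table",
]

DEFAULT_VEHICLE_ID = "DMSO"

#: significant digits preserved by every writer
_SIGNIFICANT_DIGITS = 9


class ScreenFormatError(ValueError):
    """A file does not have the expected tabular structure."""


class ScreenValidationError(ValueError):
    """A table violates a screen-data invariant."""


class Condition(str, enum.Enum):
    """Growth-medium condition of a well.

    ``FULL`` is serum-supplied medium with amino acids (basal autophagy);
    ``STARVATION`` is serum- and amino-acid-free medium (induced flux).
    """

    FULL = "full"
    STARVATION = "starvation"

    @classmethod
    def parse(cls, value: "str | Condition") -> "Condition":
        if isinstance(value, Condition):
            return value
        key = str(value).strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "full": cls.FULL,
            "full_medium": cls.FULL,
            "fed": cls.FULL,
            "basal": cls.FULL,
            "starvation": cls.STARVATION,
            "starvation_medium": cls.STARVATION,
            "starved": cls.STARVATION,
            "starv": cls.STARVATION,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ScreenValidationError(
                f"unknown condition {value!r}; expected one of "
                f"{sorted(set(aliases))}"
            ) from None


@dataclass(frozen=True)
class Dialect:
    """Column naming and formatting conventions of a screen table file."""

    delimiter: str = ","
    compound_column: str = "compound_id"
    condition_column: str = "condition"
    replicate_column: str = "replicate"
    fluorescence_column: str = "median_fluorescence"
    event_count_column: str = "event_count"
    vehicle_id: str = DEFAULT_VEHICLE_ID

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (
            self.compound_column,
            self.condition_column,
            self.replicate_column,
            self.fluorescence_column,
        )


@dataclass(frozen=True)
class CompoundRecord:
    """A library member: plate-well identifier plus optional blinding code
    and human-readable name (e.g. ``P05E07`` / ``Arzanol``)."""

    compound_id: str
    blinded_code: str | None = None
    display_name: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ScreenValidationError("compound_id must be non-empty")


@dataclass(frozen=True)
class WellMeasurement:
    """One biological replicate's median reporter fluorescence."""

    compound_id: str
    condition: Condition
    replicate: int
    median_fluorescence: float
    event_count: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition.parse(self.condition))
        if not self.compound_id:
            raise ScreenValidationError("compound_id must be non-empty")
        if self.replicate < 1:
            raise ScreenValidationError(
                f"replicate must be a positive integer, got {self.replicate}"
            )
        if not self.median_fluorescence > 0:
            raise ScreenValidationError(
                "median_fluorescence must be > 0, got "
                f"{self.median_fluorescence} for compound "
                f"{self.compound_id!r}"
            )
        if self.event_count is not None and self.event_count < 1:
            raise ScreenValidationError("event_count must be positive")


@dataclass
class ScreenTable:
    """A full screen: compound catalogue, well measurements, metadata."""

    compounds: list[CompoundRecord] = field(default_factory=list)
    wells: list[WellMeasurement] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)
    vehicle_id: str = DEFAULT_VEHICLE_ID

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.compound_id for c in self.compounds]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ScreenValidationError(f"duplicate compound_ids: {dupes}")
        codes = [c.blinded_code for c in self.compounds if c.blinded_code]
        if len(codes) != len(set(codes)):
            raise ScreenValidationError("blinded codes are not unique")
        known = set(ids)
        seen: set[tuple[str, Condition, int]] = set()
        for i, w in enumerate(self.wells):
            key = (w.compound_id, w.condition, w.replicate)
            if key in seen:
                raise ScreenValidationError(
                    f"duplicate (compound, condition, replicate) at row {i}: {key}"
                )
            seen.add(key)
            if w.compound_id != self.vehicle_id and w.compound_id not in known:
                raise ScreenValidationError(
                    f"well row {i} references unknown compound "
                    f"{w.compound_id!r}"
                )

    # -- convenience views ------------------------------------------------
    def conditions(self) -> list[Condition]:
        seen: dict[Condition, None] = {}
        for w in self.wells:
            seen.setdefault(w.condition, None)
        return list(seen)

    def vehicle_wells(self, condition: Condition | str) -> list[WellMeasurement]:
        cond = Condition.parse(condition)
        return [
            w
            for w in self.wells
            if w.condition is cond and w.compound_id == self.vehicle_id
        ]

    def compound_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.compound_id != self.vehicle_id:
                seen.setdefault(w.compound_id, None)
        return list(seen)

    def to_frame(self, dialect: Dialect | None = None) -> pd.DataFrame:
        d = dialect or Dialect(vehicle_id=self.vehicle_id)
        rows = [
            {
                d.compound_column: w.compound_id,
                d.condition_column: w.condition.value,
                d.replicate_column: w.replicate,
                d.fluorescence_column: w.median_fluorescence,
                d.event_count_column: w.event_count,
            }
            for w in self.wells
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                d.compound_column,
                d.condition_column,
                d.replicate_column,
                d.fluorescence_column,
                d.event_count_column,
            ],
        )
        return frame


def _fmt(value: Any) -> str:
    # repr of a float is its shortest round-trippable decimal form
    if isinstance(value, float):
        return repr(value)
    if value is None:
        return ""
    return str(value)


def read_screen_table(
    path: str | PathLike[str], dialect: Dialect | None = None
) -> ScreenTable:
    """Read a delimited screen table into a validated :class:`ScreenTable`.

    Row order is preserved; condition strings are mapped to
    :class:`Condition` case-insensitively.  Raises
    :class:`ScreenFormatError` when a required column is absent and
    :class:`ScreenValidationError` (with the offending row index) on
    invariant violations.
    """
    d = dialect or Dialect()
    frame = pd.read_csv(
        path,
        sep=d.delimiter,
        dtype={d.compound_column: str},
        float_precision="round_trip",
    )
    missing = [c for c in d.required_columns if c not in frame.columns]
    if missing:
        raise ScreenFormatError(
            f"missing required column(s) {missing} in {path}; "
            f"found {list(frame.columns)}"
        )
    has_events = d.event_count_column in frame.columns
    wells: list[WellMeasurement] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rec = row._asdict()
        count = rec.get(d.event_count_column) if has_events else None
        if count is not None and pd.isna(count):
            count = None
        try:
            wells.append(
                WellMeasurement(
                    compound_id=str(rec[d.compound_column]),
                    condition=Condition.parse(rec[d.condition_column]),
                    replicate=int(rec[d.replicate_column]),
                    median_fluorescence=float(rec[d.fluorescence_column]),
                    event_count=int(count) if count is not None else None,
                )
            )
        except ScreenValidationError as exc:
            raise ScreenValidationError(f"row {i}: {exc}") from None
    compounds = [
        CompoundRecord(cid)
        for cid in dict.fromkeys(
            w.compound_id for w in wells if w.compound_id != d.vehicle_id
        )
    ]
    return ScreenTable(
        compounds=compounds, wells=wells, vehicle_id=d.vehicle_id
    )


def write_screen_table(
    table: ScreenTable, path: str | PathLike[str], dialect: Dialect | None = None
) -> None:
    """Write a screen table as delimited text with ≥ 6 significant digits."""
    d = dialect or Dialect(vehicle_id=table.vehicle_id)
    with open(path, "w", newline="") as fh:
        header = [
            d.compound_column,
            d.condition_column,
            d.replicate_column,
            d.fluorescence_column,
            d.event_count_column,
        ]
        fh.write(d.delimiter.join(header) + "\n")
        for w in table.wells:
            fh.write(
                d.delimiter.join(
                    [
                        w.compound_id,
                        w.condition.value,
                        str(w.replicate),
                        _fmt(w.median_fluorescence),
                        _fmt(w.event_count),
                    ]
                )
                + "\n"
            )


def read_codemap(
    path: str | PathLike[str], delimiter: str = ","
) -> dict[str, str]:
    """Read a two-column blinding map (blinded_code, compound_id)."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if frame.shape[1] < 2:
        raise ScreenFormatError(
            f"blinding map {path} needs two columns (blinded_code, compound_id)"
        )
    codes = frame.iloc[:, 0].tolist()
    targets = frame.iloc[:, 1].tolist()
    mapping = dict(zip(codes, targets))
    if len(mapping) != len(codes):
        raise ScreenValidationError("duplicate blinded codes in map")
    if len(set(targets)) != len(targets):
        raise ScreenValidationError("blinding map is not a bijection")
    return mapping


def write_codemap(
    codemap: Mapping[str, str], path: str | PathLike[str], delimiter: str = ","
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(delimiter.join(["blinded_code", "compound_id"]) + "\n")
        for code, cid in codemap.items():
            fh.write(delimiter.join([code, cid]) + "\n")


def _substitute(table: ScreenTable, mapping: Mapping[str, str]) -> ScreenTable:
    wells = [
        dataclasses.replace(w, compound_id=mapping.get(w.compound_id, w.compound_id))
        if w.compound_id != table.vehicle_id
        else w
        for w in table.wells
    ]
    compounds = [
        dataclasses.replace(c, compound_id=mapping.get(c.compound_id, c.compound_id))
        for c in table.compounds
    ]
    return ScreenTable(
        compounds=compounds,
        wells=wells,
        metadata=dict(table.metadata),
        vehicle_id=table.vehicle_id,
    )


def blind(table: ScreenTable, codemap: Mapping[str, str]) -> ScreenTable:
    """Replace compound identities by blinded codes (inverse of codemap).

    ``codemap`` maps blinded_code -> compound_id, as stored on disk; this
    applies the inverse so that ``unblind(blind(t, m), m) == t``.
    """
    inverse = {cid: code for code, cid in codemap.items()}
    if len(inverse) != len(codemap):
        raise ScreenValidationError("codemap is not a bijection")
    missing = [c for c in _nonvehicle_ids(table) if c not in inverse]
    if missing:
        raise ScreenValidationError(
            f"no blinded code for compound(s): {sorted(missing)}"
        )
    return _substitute(table, inverse)


def unblind(table: ScreenTable, codemap: Mapping[str, str]) -> ScreenTable:
    """Restore true compound identities from a blinded table.

    Vehicle wells are untouched.  Codes present in the table but absent
    from ``codemap`` raise, listing every missing code.
    """
    if not codemap:
        return _substitute(table, {})
    present = _nonvehicle_ids(table)
    known_targets = set(codemap.values())
    missing = [
        c for c in present if c not in codemap and c not in known_targets
    ]
    if missing:
        raise ScreenValidationError(
            f"blinded code(s) not in map: {sorted(missing)}"
        )
    return _substitute(table, dict(codemap))


def _nonvehicle_ids(table: ScreenTable) -> list[str]:
    seen: dict[str, None] = {}
    for w in table.wells:
        if w.compound_id != table.vehicle_id:
            seen.setdefault(w.compound_id, None)
    for c in table.compounds:
        seen.setdefault(c.compound_id, None)
    return list(seen)


def write_results_table(
    results: "pd.DataFrame | Sequence[Any]",
    path: str | PathLike[str],
    delimiter: str = ",",
) -> None:
    """Write any result collection as delimited text with a header row.

    Accepts a DataFrame, a sequence of dataclasses, or a sequence of
    mappings.  Floats keep ≥ 6 significant digits.  An empty sequence of
    dataclasses cannot infer a header, so it requires a DataFrame instead.
    """
    if results is None:
        raise ValueError("results must not be None")
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        rows: list[dict[str, Any]] = []
        for r in results:
            if dataclasses.is_dataclass(r) and not isinstance(r, type):
                rows.append(dataclasses.asdict(r))
            elif isinstance(r, Mapping):
                rows.append(dict(r))
            else:
                raise TypeError(f"cannot tabulate {type(r).__name__}")
        frame = pd.DataFrame(rows)
    frame.to_csv(
        path,
        sep=delimiter,
        index=False,
        float_format=f"%.{_SIGNIFICANT_DIGITS}g",
    )
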