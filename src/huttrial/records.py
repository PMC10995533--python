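"""Data model and CSV I/O for hut-night mosquito collection records.

The unit of observation is one hut on one night for one species group.
Each mosquito found in the hut (or its window traps) in the morning is
scored into exactly one of four fates:

* ``trapped`` — caught in the net's trap compartment;
* ``dead_untrapped`` — found dead in the room or window traps;
* ``alive_delayed_dead`` — collected alive but dead after the 24-36 h
  holding period;
* ``alive_survived`` — collected alive and still alive after holding.

CSV schema (UTF-8, header row)::

    night,hut,sleeper,arm,species_group,trapped,dead_untrapped,alive_delayed_dead,alive_survived
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SPECIES_GROUPS = ("an_gambiae", "other")

CSV_COLUMNS = [
    "night",
    "hut",
    "sleeper",
    "arm",
    "species_group",
    "trapped",
    "dead_untrapped",
    "alive_delayed_dead",
    "alive_survived",
]

_COUNT_COLUMNS = CSV_COLUMNS[5:]


class RecordValidationError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FateCounts:
    trapped: int
    dead_untrapped: int
    alive_delayed_dead: int
    alive_survived: int

    def __post_init__(self) -> None:
        for name in _COUNT_COLUMNS:
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise RecordValidationError(
                    f"count {name}={value!r} must be a non-negative integer"
                )

    @property
    def total_entry(self) -> int:
        return (
            self.trapped
            + self.dead_untrapped
            + self.alive_delayed_dead
            + self.alive_survived
        )


@dataclass(frozen=True)
class HutNightRecord:
    night: int
    hut: int
    sleeper: int
    arm: str
    species_group: str
    counts: FateCounts

    def __post_init__(self) -> None:
        if self.night < 1:
            raise RecordValidationError("night index must be >= 1")
        if self.species_group not in SPECIES_GROUPS:
            raise RecordValidationError(
                f"species_group {self.species_group!r} not in "
                f"{SPECIES_GROUPS}"
            )


def records_to_frame(records: list[HutNightRecord]) -> pd.DataFrame:
    rows = [
        {
            "night": r.night,
            "hut": r.hut,
            "sleeper": r.sleeper,
            "arm": r.arm,
            "species_group": r.species_group,
            "trapped": r.counts.trapped,
            "dead_untrapped": r.counts.dead_untrapped,
            "alive_delayed_dead": r.counts.alive_delayed_dead,
            "alive_survived": r.counts.alive_survived,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[HutNightRecord]:
    """Convert a schema-conforming frame to records, citing bad rows.

    Row numbers in error messages are 1-based data rows (header is
    row 1, first data row is row 2) to match what a user sees in the
    file.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    records = []
    seen: set[tuple] = set()
    for pos, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            counts = FateCounts(
                trapped=int(row["trapped"]),
                dead_untrapped=int(row["dead_untrapped"]),
                alive_delayed_dead=int(row["alive_delayed_dead"]),
                alive_survived=int(row["alive_survived"]),
            )
            rec = HutNightRecord(
                night=int(row["night"]),
                hut=int(row["hut"]),
                sleeper=int(row["sleeper"]),
                arm=str(row["arm"]),
                species_group=str(row["species_group"]),
                counts=counts,
            )
        except (RecordValidationError, ValueError) as exc:
            raise RecordValidationError(f"row {pos}: {exc}") from exc
        key = (rec.night, rec.hut, rec.species_group)
        if key in seen:
            raise RecordValidationError(
                f"row {pos}: duplicate observation for night={rec.night}, "
                f"hut={rec.hut}, species_group={rec.species_group}"
            )
        seen.add(key)
        records.append(rec)
    return records


def read_records(path) -> list[HutNightRecord]:
    """Read and validate a records CSV."""
    df = pd.read_csv(path)
    return frame_to_records(df)


def write_records(records: list[HutNightRecord], path) -> None:
    """Write records in canonical order (night, hut, species_group).

    Canonical ordering makes the output a pure function of the record
    *set*: two permutations of the same records produce byte-identical
    files.
    """
    df = records_to_frame(records)
    df = df.sort_values(["night", "hut", "species_group"], kind="mergesort")
    df.to_csv(path, index=False)


def filter_records(
    records: list[HutNightRecord],
    species_group: str | None = None,
    arm: str | None = None,
    night_range: tuple[int, int] | None = None,
) -> list[HutNightRecord]:
    """Subset records, preserving input order; filters compose (AND).

    ``night_range`` is inclusive on both ends. Filtering on an arm name
    absent from the data raises ``KeyError`` to catch typos early.
    """
    if arm is not None:
        known = {r.arm for r in records}
        if arm not in known:
            raise KeyError(f"arm {arm!r} not present (have {sorted(known)})")
    if species_group is not None and species_group not in SPECIES_GROUPS:
        raise KeyError(f"species_group {species_group!r} not in {SPECIES_GROUPS}")
    out = []
    for r in records:
        if species_group is not None and r.species_group != species_group:
            continue
        if arm is not None and r.arm != arm:
            continue
        if night_range is not None and not (
            night_range[0] <= r.night <= night_range[1]
        ):
            continue
        out.append(r)
    return out
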