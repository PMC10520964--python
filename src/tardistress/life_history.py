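"""Life-history records for individually reared females.

Each female is followed from birth to death: lifespan, molts and an
ordered series of clutches (egg-laying events). From these the module
derives the traits used downstream: fecundity, fertility per clutch,
inter-oviposition interval, age at first oviposition, hatching time and
hatching percentage. Days are integers with day 0 = birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Generation = Literal["P", "F1", "F2"]

VALID_GENERATIONS = ("P", "F1", "F2")


@dataclass(frozen=True)
class ClutchRecord:
    """One egg-laying event of a female.

    Parameters
    ----------
    clutch_index
        1-based ordinal of the clutch in the female's life.
    oviposition_day
        Day of laying, counted from the female's birth (day 0).
    eggs_laid
        Number of eggs in the clutch (the clutch's fertility).
    eggs_hatched
        How many of those eggs eventually hatched.
    hatching_times
        Days from oviposition to hatching, one entry per hatched egg.
    """

    clutch_index: int
    oviposition_day: int
    eggs_laid: int
    eggs_hatched: int
    hatching_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "hatching_times", tuple(self.hatching_times))

    def violations(self) -> list[str]:
        out = []
        if self.clutch_index < 1:
            out.append(f"clutch_index {self.clutch_index} < 1")
        if self.oviposition_day <= 0:
            out.append(f"oviposition_day {self.oviposition_day} <= 0")
        if self.eggs_laid < 0:
            out.append(f"eggs_laid {self.eggs_laid} < 0")
        if self.eggs_hatched < 0 or self.eggs_hatched > self.eggs_laid:
            out.append(
                f"eggs_hatched {self.eggs_hatched} outside [0, eggs_laid={self.eggs_laid}]"
            )
        if len(self.hatching_times) != self.eggs_hatched:
            out.append(
                f"{len(self.hatching_times)} hatching times for "
                f"{self.eggs_hatched} hatched eggs"
            )
        if any(t <= 0 for t in self.hatching_times):
            out.append("non-positive hatching time")
        return out


@dataclass(frozen=True)
class FemaleRecord:
    """One female's complete life history."""

    female_id: str
    generation: Generation
    rearing_temperature_C: int
    lifespan_days: int
    n_molts: int
    clutches: tuple[ClutchRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "clutches", tuple(self.clutches))

    def violations(self) -> list[str]:
        out = []
        if self.generation not in VALID_GENERATIONS:
            out.append(f"unknown generation {self.generation!r}")
        if self.lifespan_days <= 0:
            out.append(f"lifespan_days {self.lifespan_days} <= 0")
        if self.n_molts < 0:
            out.append(f"n_molts {self.n_molts} < 0")
        for c in self.clutches:
            out.extend(f"clutch {c.clutch_index}: {v}" for v in c.violations())
        days = [c.oviposition_day for c in self.clutches]
        if any(b <= a for a, b in zip(days, days[1:])):
            out.append("oviposition days not strictly increasing")
        if days and days[-1] > self.lifespan_days:
            out.append(
                f"last oviposition day {days[-1]} after death at {self.lifespan_days}"
            )
        return out


#: Traits whose values are durations or counts per female; used by callers
#: that iterate over the derived table.
TRAIT_COLUMNS = (
    "fecundity",
    "n_ovipositions",
    "mean_interoviposition_days",
    "age_at_first_oviposition_days",
    "mean_hatching_time_days",
    "total_hatched_eggs",
    "hatching_percentage",
)


def derive_traits(
    cohort: Sequence[FemaleRecord], interval_aggregator: str = "mean"
) -> pd.DataFrame:
    """Derive per-female life-history traits.

    Returns one row per female. Traits that are undefined for a female
    (age at first oviposition when she never laid; hatching time when no
    egg hatched; hatching percentage when fecundity is zero) are NaN,
    never imputed.

    Parameters
    ----------
    cohort
        Female records; clutches are sorted by oviposition day before any
        interval is computed, so input clutch order is irrelevant.
    interval_aggregator
        "mean" (default) or "median" of successive oviposition-day
        differences.
    """
    if interval_aggregator not in ("mean", "median"):
        raise ValueError(f"unknown interval aggregator {interval_aggregator!r}")
    agg = np.mean if interval_aggregator == "mean" else np.median
    rows = []
    for f in cohort:
        clutches = sorted(f.clutches, key=lambda c: c.oviposition_day)
        fecundity = sum(c.eggs_laid for c in clutches)
        hatched = sum(c.eggs_hatched for c in clutches)
        days = [c.oviposition_day for c in clutches]
        hatch_times = [t for c in clutches for t in c.hatching_times]
        rows.append(
            {
                "female_id": f.female_id,
                "generation": f.generation,
                "rearing_temperature_C": f.rearing_temperature_C,
                "lifespan_days": f.lifespan_days,
                "n_molts": f.n_molts,
                "fecundity": fecundity,
                "n_ovipositions": len(clutches),
                "mean_interoviposition_days": (
                    float(agg(np.diff(days))) if len(days) >= 2 else np.nan
                ),
                "age_at_first_oviposition_days": (
                    float(days[0]) if days else np.nan
                ),
                "mean_hatching_time_days": (
                    float(np.mean(hatch_times)) if hatch_times else np.nan
                ),
                "total_hatched_eggs": hatched,
                "hatching_percentage": (
                    100.0 * hatched / fecundity if fecundity > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "female_id",
            "generation",
            "rearing_temperature_C",
            "lifespan_days",
            "n_molts",
            *TRAIT_COLUMNS,
        ],
    )


def clutch_table(cohort: Sequence[FemaleRecord]) -> pd.DataFrame:
    """One row per clutch, for clutch-level models (fertility vs
    oviposition order, hatch time/percentage vs clutch size)."""
    rows = []
    for f in cohort:
        for c in sorted(f.clutches, key=lambda c: c.oviposition_day):
            rows.append(
                {
                    "female_id": f.female_id,
                    "generation": f.generation,
                    "rearing_temperature_C": f.rearing_temperature_C,
                    "clutch_index": c.clutch_index,
                    "oviposition_day": c.oviposition_day,
                    "eggs_laid": c.eggs_laid,
                    "eggs_hatched": c.eggs_hatched,
                    "mean_hatching_time_days": (
                        float(np.mean(c.hatching_times))
                        if c.hatching_times
                        else np.nan
                    ),
                    "hatching_percentage": (
                        100.0 * c.eggs_hatched / c.eggs_laid
                        if c.eggs_laid > 0
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def validate_cohort(cohort: Sequence[FemaleRecord]) -> list[str]:
    """Return a list of human-readable invariant violations; empty iff the
    cohort is valid. Duplicated female ids are reported once per extra."""
    out = []
    seen: set[str] = set()
    for f in cohort:
        if f.female_id in seen:
            out.append(f"{f.female_id}: duplicate female_id")
        seen.add(f.female_id)
        out.extend(f"{f.female_id}: {v}" for v in f.violations())
    return out


class CohortFormatError(ValueError):
    """Raised when a cohort CSV row cannot be parsed or violates a
    record invariant."""


def _parse_hatching_times(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    s = str(cell).strip()
    if not s:
        return ()
    return tuple(float(x) for x in s.split(";") if x.strip())


_REQUIRED_COLUMNS = (
    "female_id",
    "generation",
    "rearing_temperature_C",
    "lifespan_days",
    "n_molts",
    "clutch_index",
    "oviposition_day",
    "eggs_laid",
    "eggs_hatched",
    "hatching_times",
)


def load_cohort(path) -> list[FemaleRecord]:
    """Load a cohort from long-format CSV, one row per clutch.

    Female-level columns repeat on every row; a female with no clutches
    appears as a single row with the clutch fields empty. Raises
    :class:`CohortFormatError` naming the offending row or female on
    malformed input or violated invariants.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing columns: {', '.join(missing)}")
    females: dict[str, dict] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            fid = str(row["female_id"])
            if fid not in females:
                females[fid] = {
                    "female_id": fid,
                    "generation": str(row["generation"]),
                    "rearing_temperature_C": int(row["rearing_temperature_C"]),
                    "lifespan_days": int(row["lifespan_days"]),
                    "n_molts": int(row["n_molts"]),
                    "clutches": [],
                }
                order.append(fid)
            if not pd.isna(row["clutch_index"]):
                females[fid]["clutches"].append(
                    ClutchRecord(
                        clutch_index=int(row["clutch_index"]),
                        oviposition_day=int(row["oviposition_day"]),
                        eggs_laid=int(row["eggs_laid"]),
                        eggs_hatched=int(row["eggs_hatched"]),
                        hatching_times=_parse_hatching_times(
                            row["hatching_times"]
                        ),
                    )
                )
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(f"row {rowno}: {exc}") from exc
    cohort = [
        FemaleRecord(
            female_id=d["female_id"],
            generation=d["generation"],
            rearing_temperature_C=d["rearing_temperature_C"],
            lifespan_days=d["lifespan_days"],
            n_molts=d["n_molts"],
            clutches=tuple(
                sorted(d["clutches"], key=lambda c: c.oviposition_day)
            ),
        )
        for d in (females[fid] for fid in order)
    ]
    problems = validate_cohort(cohort)
    if problems:
        raise CohortFormatError("; ".join(problems))
    return cohort


def write_cohort(cohort: Iterable[FemaleRecord], path) -> None:
    """Write a cohort to the long-format CSV read by :func:`load_cohort`."""
    rows = []
    for f in cohort:
        base = {
            "female_id": f.female_id,
            "generation": f.generation,
            "rearing_temperature_C": f.rearing_temperature_C,
            "lifespan_days": f.lifespan_days,
            "n_molts": f.n_molts,
        }
        if not f.clutches:
            rows.append(
                {**base, "clutch_index": "", "oviposition_day": "",
                 "eggs_laid": "", "eggs_hatched": "", "hatching_times": ""}
            )
        for c in f.clutches:
            rows.append(
                {
                    **base,
                    "clutch_index": c.clutch_index,
                    "oviposition_day": c.oviposition_day,
                    "eggs_laid": c.eggs_laid,
                    "eggs_hatched": c.eggs_hatched,
                    "hatching_times": ";".join(
                        f"{t:g}" for t in c.hatching_times
                    ),
                }
            )
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(path, index=False)
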