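"""Weighbridge quality control: from raw crossing logs to clean daily masses.

An automated weighbridge logs, for every transit of a PIT-tagged bird, the
PIT identifier, a timestamp and up to six mass recordings (the balance reads
to the nearest gram, but recordings are easily corrupted by movement or by a
second bird on the scale). The QC cascade turns that raw log into at most one
trustworthy mass per bird per calendar day, assigned to a morning (leaving)
or evening (returning) window:

1. parse rows (malformed rows are reported with line numbers, never silently
   dropped);
2. reject crossings whose PIT is not in the registry or whose date is not in
   the season calendar;
3. assign the clock time to the morning window (01:20–09:59), the evening
   window (10:00–23:40, both inclusive) or reject it as outside both;
4. reject male crossings during the guard stage — males do not forage while
   guarding the chick and no plausibility band is defined for them;
5. the mass rules, in order: (i) at least two recordings, (ii) within-
   crossing spread strictly below 200 g, (iii) mean mass inside the sex- and
   stage-specific plausibility band — 1700–3500 g for females (guard and
   crèche), 2000–3900 g for males (crèche), bounds inclusive;
6. when a bird still has more than one accepted crossing on a day, keep
   exactly one chosen uniformly at random under an explicit seed.

A rejected crossing is tallied under the *first* failing rule, so the report
categories are disjoint and counts reconcile exactly:
``read = accepted + sum(rejected) + removed by deduplication``.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FEMALE_BOUNDS_G",
    "MALE_CRECHE_BOUNDS_G",
    "MAX_SPREAD_G",
    "MIN_RECORDINGS",
    "MAX_RECORDINGS",
    "Crossing",
    "CleanMass",
    "Rejection",
    "RowError",
    "QcReport",
    "parse_crossings",
    "assign_window",
    "filter_crossing",
    "deduplicate",
    "run_qc",
]

#: Plausibility band for female body mass (g), guard and crèche, inclusive.
FEMALE_BOUNDS_G = (1700.0, 3500.0)
#: Plausibility band for male body mass (g), crèche only, inclusive.
MALE_CRECHE_BOUNDS_G = (2000.0, 3900.0)
#: Recordings within one crossing must differ by strictly less than this.
MAX_SPREAD_G = 200.0
MIN_RECORDINGS = 2
MAX_RECORDINGS = 6

# Window boundaries, inclusive at both ends. Anything in (23:40, 01:20) is
# outside both windows and rejected; the evening window closing before
# midnight also means no crossing ever spans into the next calendar day.
_MORNING = (dt.time(1, 20), dt.time(9, 59, 59))
_EVENING = (dt.time(10, 0), dt.time(23, 40, 59))

RULES = (
    "unknown-pit",
    "unknown-date",
    "outside-window",
    "male-during-guard",
    "too-few-recordings",
    "spread",
    "out-of-bounds",
)


@dataclass(frozen=True)
class Crossing:
    """One transit of one bird over the scale."""

    pit_id: str
    timestamp: dt.datetime
    recordings: tuple[float, ...]
    line_no: int | None = None

    def __post_init__(self):
        if not (1 <= len(self.recordings) <= MAX_RECORDINGS):
            raise ValueError(
                f"a crossing carries 1..{MAX_RECORDINGS} recordings, "
                f"got {len(self.recordings)}"
            )
        if any(m <= 0 for m in self.recordings):
            raise ValueError("mass recordings must be positive")


@dataclass(frozen=True)
class CleanMass:
    """A QC-accepted per-crossing mass, assigned to a day and window."""

    pit_id: str
    date: dt.date
    window: str  # morning | evening
    mass_g: float
    sex: str
    season: str
    stage: str


@dataclass(frozen=True)
class Rejection:
    crossing: Crossing
    rule: str


@dataclass(frozen=True)
class RowError:
    line_no: int
    message: str


@dataclass
class QcReport:
    """Disjoint tallies of every crossing's fate."""

    read: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})
    dedup_removed: int = 0
    accepted: int = 0
    accepted_morning: int = 0
    accepted_evening: int = 0
    malformed_rows: int = 0

    def balances(self) -> bool:
        return self.read == self.accepted + sum(self.rejected.values()) + self.dedup_removed

    def to_dict(self) -> dict:
        return {
            "read": self.read,
            "malformed_rows": self.malformed_rows,
            "rejected": dict(self.rejected),
            "dedup_removed": self.dedup_removed,
            "accepted": self.accepted,
            "accepted_morning": self.accepted_morning,
            "accepted_evening": self.accepted_evening,
            "balances": self.balances(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


# --------------------------------------------------------------------------
# parsing

_LOG_COLUMNS = ["pit_id", "timestamp"] + [f"mass_{i}" for i in range(1, 7)]


def parse_crossings(source) -> tuple[list[Crossing], list[RowError]]:
    """Parse a crossing-log CSV into :class:`Crossing` records.

    ``source`` may be a path, an open text handle, or a DataFrame with the
    log schema. Malformed rows (bad timestamp, non-numeric or non-positive
    mass, no recordings at all) are collected as line-numbered
    :class:`RowError` diagnostics. A file whose header does not contain the
    required columns is a hard error.
    """
    if isinstance(source, pd.DataFrame):
        buf = io.StringIO()
        source.to_csv(buf, index=False)
        buf.seek(0)
        return parse_crossings(buf)
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return parse_crossings(fh)

    reader = csv.DictReader(source)
    header = reader.fieldnames or []
    missing = [c for c in _LOG_COLUMNS[:2] if c not in header]
    mass_cols = [c for c in header if c.startswith("mass_")]
    if missing or not mass_cols:
        raise ValueError(
            f"crossing log header {header} lacks required columns "
            f"(need pit_id, timestamp, mass_1..)"
        )
    crossings: list[Crossing] = []
    errors: list[RowError] = []
    for i, row in enumerate(reader, start=2):  # line 1 is the header
        pit = (row.get("pit_id") or "").strip()
        ts_raw = (row.get("timestamp") or "").strip()
        if not pit:
            errors.append(RowError(i, "missing pit_id"))
            continue
        try:
            ts = dt.datetime.fromisoformat(ts_raw)
        except ValueError:
            errors.append(RowError(i, f"unparseable timestamp {ts_raw!r}"))
            continue
        masses: list[float] = []
        bad = None
        for c in mass_cols:
            raw = (row.get(c) or "").strip()
            if raw == "":
                continue
            try:
                m = float(raw)
            except ValueError:
                bad = f"non-numeric mass {raw!r} in {c}"
                break
            if not np.isfinite(m) or m <= 0:
                bad = f"non-positive mass {m!r} in {c}"
                break
            masses.append(m)
        if bad is not None:
            errors.append(RowError(i, bad))
            continue
        if not masses:
            errors.append(RowError(i, "no mass recordings"))
            continue
        if len(masses) > MAX_RECORDINGS:
            errors.append(RowError(i, f"more than {MAX_RECORDINGS} recordings"))
            continue
        crossings.append(Crossing(pit, ts, tuple(masses), line_no=i))
    return crossings, errors


# --------------------------------------------------------------------------
# the filter cascade


def assign_window(timestamp: dt.datetime | dt.time) -> str:
    """Map a clock time to ``morning``, ``evening`` or ``outside``."""
    t = timestamp.time() if isinstance(timestamp, dt.datetime) else timestamp
    if _MORNING[0] <= t <= _MORNING[1]:
        return "morning"
    if _EVENING[0] <= t <= _EVENING[1]:
        return "evening"
    return "outside"


def filter_crossing(
    crossing: Crossing, sex: str, stage: str, season: str = ""
) -> CleanMass | Rejection:
    """Apply the mass rules to one crossing with known sex and stage.

    Rules in order: male-during-guard (no plausibility band exists for
    guarding males), then (i) ≥ 2 recordings, (ii) spread < 200 g strictly,
    (iii) mean inside the inclusive sex/stage band. Returns the accepted
    :class:`CleanMass` (mass = arithmetic mean of the recordings) or a
    :class:`Rejection` carrying the first failing rule.
    """
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    if stage not in ("guard", "creche"):
        raise ValueError(f"stage must be 'guard' or 'creche', got {stage!r}")
    if sex == "M" and stage == "guard":
        return Rejection(crossing, "male-during-guard")
    rec = crossing.recordings
    if len(rec) < MIN_RECORDINGS:
        return Rejection(crossing, "too-few-recordings")
    if max(rec) - min(rec) >= MAX_SPREAD_G:
        return Rejection(crossing, "spread")
    lo, hi = FEMALE_BOUNDS_G if sex == "F" else MALE_CRECHE_BOUNDS_G
    mass = float(np.mean(rec))
    if not (lo <= mass <= hi):
        return Rejection(crossing, "out-of-bounds")
    window = assign_window(crossing.timestamp)
    return CleanMass(
        pit_id=crossing.pit_id,
        date=crossing.timestamp.date(),
        window=window,
        mass_g=mass,
        sex=sex,
        season=season,
        stage=stage,
    )


def deduplicate(
    clean: list[CleanMass], seed: int | None
) -> tuple[list[CleanMass], int]:
    """Keep exactly one accepted mass per (bird, day).

    When a bird has several accepted crossings on one day (e.g. both a
    morning and an evening mass), one is chosen uniformly at random under
    ``seed``. Output preserves the input order of the kept records; inputs
    with no duplicates pass through unchanged. Returns the kept list and the
    number of removed records.
    """
    if seed is None:
        raise ValueError("deduplicate requires an explicit seed")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, dt.date], list[int]] = {}
    for i, cm in enumerate(clean):
        groups.setdefault((cm.pit_id, cm.date), []).append(i)
    keep: set[int] = set()
    # Iterate in first-occurrence order so the rng stream is reproducible
    # regardless of dict/hash details.
    for key in groups:
        idxs = groups[key]
        if len(idxs) == 1:
            keep.add(idxs[0])
        else:
            keep.add(idxs[int(rng.integers(len(idxs)))])
    kept = [cm for i, cm in enumerate(clean) if i in keep]
    return kept, len(clean) - len(kept)


# --------------------------------------------------------------------------
# orchestration


def _load_table(source, parse_date: str | None = None) -> pd.DataFrame:
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if parse_date and parse_date in df.columns:
        df[parse_date] = pd.to_datetime(df[parse_date]).dt.date
    return df


@dataclass
class QcResult:
    clean: list[CleanMass]
    report: QcReport
    parse_errors: list[RowError]
    rejections: list[Rejection]

    def clean_frame(self) -> pd.DataFrame:
        """Clean masses as the documented CSV schema."""
        return pd.DataFrame(
            [
                {
                    "pit_id": c.pit_id,
                    "date": c.date.isoformat(),
                    "window": c.window,
                    "mass_g": c.mass_g,
                    "sex": c.sex,
                    "season": c.season,
                    "stage": c.stage,
                }
                for c in self.clean
            ],
            columns=["pit_id", "date", "window", "mass_g", "sex", "season", "stage"],
        )


def run_qc(log, registry, calendar, seed: int | None) -> QcResult:
    """Run the full cascade: parse → registry/calendar → window → filter → dedup.

    Parameters
    ----------
    log, registry, calendar
        Paths, handles or DataFrames with the documented CSV schemas.
    seed
        Seed for the random deduplication choice (required).
    """
    if seed is None:
        raise ValueError("run_qc requires an explicit seed for deduplication")
    crossings, parse_errors = parse_crossings(log)
    reg = _load_table(registry)
    cal = _load_table(calendar, parse_date="date")
    sex_of = dict(zip(reg["pit_id"].astype(str), reg["sex"].astype(str)))
    cal_of = {
        d: (str(s), str(g))
        for d, s, g in zip(cal["date"], cal["season"], cal["stage"])
    }

    report = QcReport(read=len(crossings), malformed_rows=len(parse_errors))
    accepted: list[CleanMass] = []
    rejections: list[Rejection] = []

    def reject(c: Crossing, rule: str):
        report.rejected[rule] += 1
        rejections.append(Rejection(c, rule))

    for c in crossings:
        sex = sex_of.get(c.pit_id)
        if sex is None:
            reject(c, "unknown-pit")
            continue
        cal_entry = cal_of.get(c.timestamp.date())
        if cal_entry is None:
            reject(c, "unknown-date")
            continue
        season, stage = cal_entry
        if assign_window(c.timestamp) == "outside":
            reject(c, "outside-window")
            continue
        res = filter_crossing(c, sex, stage, season)
        if isinstance(res, Rejection):
            report.rejected[res.rule] += 1
            rejections.append(res)
        else:
            accepted.append(res)

    kept, removed = deduplicate(accepted, seed)
    report.dedup_removed = removed
    report.accepted = len(kept)
    report.accepted_morning = sum(1 for c in kept if c.window == "morning")
    report.accepted_evening = sum(1 for c in kept if c.window == "evening")
    return QcResult(clean=kept, report=report, parse_errors=parse_errors, rejections=rejections)
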