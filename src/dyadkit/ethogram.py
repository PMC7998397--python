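"""Code inventory, session data model and annotation-stream I/O.

The ethogram is the formal inventory of behavior codes used to micro-code a
dyadic child-therapist play session: who emits the code (child, therapist, or
the dyad as a unit), whether it is a point event or a duration state, its
interactive function, and which codes by the other partner count as a valid
answer to it.  The default inventory models 15 codes: 13 point events, one
dyadic duration state (SA, the shared activity), and a numeric engagement
attribute (ENG, levels 1-3) attached to shared activities.

Annotation streams are read and written in a BORIS-style tabular dialect:
one row per point event, two rows (START/STOP) per state event, with columns
Time, Subject, Behavior, Modifiers, Behavior type.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "EthogramCode",
    "Ethogram",
    "DEFAULT_ETHOGRAM",
    "AnnotatedEvent",
    "SessionRecord",
    "OutcomeRecord",
    "ValidationError",
    "read_events",
    "write_events",
    "compute_outcome_indices",
    "DAYS_PER_MONTH",
]

#: conversion used when ages are supplied in days instead of months
DAYS_PER_MONTH = 30.44


class ValidationError(ValueError):
    """Raised when an annotation file or record violates the data model."""


@dataclass(frozen=True)
class EthogramCode:
    """One behavior code of the inventory.

    Parameters
    ----------
    code_id:
        Short label (e.g. ``"TP"`` for *therapist proposes*).
    actor:
        ``"child"``, ``"therapist"`` or ``"dyad"``.
    event_class:
        ``"point"`` or ``"state"`` (state codes span a duration).
    function:
        One of ``initiation``, ``response``, ``termination``, ``affect``,
        ``activity_state``, ``engagement_attribute``.
    valid_responses:
        Codes by the *opposite* actor that answer this code.
    description:
        Human-readable gloss.
    """

    code_id: str
    actor: str
    event_class: str
    function: str
    valid_responses: frozenset[str] = frozenset()
    description: str = ""


class Ethogram:
    """An immutable collection of :class:`EthogramCode` indexed by code id."""

    def __init__(self, codes: Iterable[EthogramCode]):
        self._codes: dict[str, EthogramCode] = {}
        for c in codes:
            if c.code_id in self._codes:
                raise ValidationError(f"duplicate code id {c.code_id!r}")
            self._codes[c.code_id] = c
        self._validate()

    def _validate(self) -> None:
        for c in self._codes.values():
            for r in c.valid_responses:
                if r not in self._codes:
                    raise ValidationError(
                        f"{c.code_id}: unknown response code {r!r}"
                    )
                if self._codes[r].actor == c.actor:
                    raise ValidationError(
                        f"{c.code_id}: response {r} must belong to the "
                        "opposite actor"
                    )

    def __contains__(self, code_id: str) -> bool:
        return code_id in self._codes

    def __getitem__(self, code_id: str) -> EthogramCode:
        return self._codes[code_id]

    def __iter__(self):
        return iter(self._codes.values())

    def __len__(self) -> int:
        return len(self._codes)

    @property
    def code_ids(self) -> list[str]:
        return list(self._codes)

    def codes_with_function(self, function: str) -> list[EthogramCode]:
        return [c for c in self._codes.values() if c.function == function]

    # ------------------------------------------------------------------ io
    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "code": c.code_id,
                "actor": c.actor,
                "class": c.event_class,
                "function": c.function,
                "valid_responses": sorted(c.valid_responses),
                "description": c.description,
            }
            for c in self._codes.values()
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Ethogram":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            EthogramCode(
                code_id=d["code"],
                actor=d["actor"],
                event_class=d.get("class", "point"),
                function=d["function"],
                valid_responses=frozenset(d.get("valid_responses", [])),
                description=d.get("description", ""),
            )
            for d in data
        )


def _default_codes() -> list[EthogramCode]:
    T, C, D = "therapist", "child", "dyad"
    return [
        EthogramCode("TP", T, "point", "initiation", frozenset({"CA", "CR"}),
                     "Therapist proposes"),
        EthogramCode("TW", T, "point", "initiation", frozenset({"CA", "CR"}),
                     "Therapist widens"),
        EthogramCode("CA", C, "point", "response", frozenset(),
                     "Child accepts"),
        EthogramCode("CR", C, "point", "response", frozenset(),
                     "Child refuses"),
        EthogramCode("CI", C, "point", "initiation", frozenset({"TI"}),
                     "Child's signal of intentionality"),
        EthogramCode("TI", T, "point", "response", frozenset(),
                     "Therapist recognizes intentionality"),
        EthogramCode("CP", C, "point", "initiation", frozenset({"TA"}),
                     "Child proposes"),
        EthogramCode("TA", T, "point", "response", frozenset(),
                     "Therapist shares"),
        EthogramCode("SA", D, "state", "activity_state", frozenset(),
                     "Shared activity"),
        EthogramCode("CX", C, "point", "termination", frozenset(),
                     "Child's withdrawal to interrupt the sharing"),
        EthogramCode("TE", T, "point", "termination", frozenset(),
                     "Therapist ends activity"),
        EthogramCode("CE", C, "point", "termination", frozenset(),
                     "Child ends the activity"),
        EthogramCode("CD", C, "point", "affect", frozenset({"TR"}),
                     "Child's signals of dysregulation"),
        EthogramCode("TR", T, "point", "affect", frozenset(),
                     "Therapist recognizes child's emotional state"),
        EthogramCode("ENG", C, "point", "engagement_attribute", frozenset(),
                     "Child engagement level (1 low, 2 medium, 3 high)"),
    ]


#: the default 15-code inventory
DEFAULT_ETHOGRAM = Ethogram(_default_codes())

#: ENG levels allowed as modifiers
ENG_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class AnnotatedEvent:
    """One timestamped behavior code.

    Point events have ``stop_s is None``; state events span
    ``[time_s, stop_s]``.  ``modifier`` is the ENG level and is present iff
    the code is the engagement attribute.
    """

    time_s: float
    code_id: str
    stop_s: float | None = None
    modifier: int | None = None
    coder_id: str = ""

    @property
    def is_state(self) -> bool:
        return self.stop_s is not None

    @property
    def duration_s(self) -> float | None:
        return None if self.stop_s is None else self.stop_s - self.time_s


@dataclass
class SessionRecord:
    """A coded session: a time-ordered event stream plus metadata."""

    session_id: str
    events: list[AnnotatedEvent] = field(default_factory=list)
    dyad_id: str = ""
    timepoint: str = "T0"
    window_len_s: float = 1200.0
    coder_id: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time_s)
        self.validate()

    def validate(self, ethogram: Ethogram = DEFAULT_ETHOGRAM) -> None:
        if self.window_len_s <= 0:
            raise ValidationError("window_len_s must be positive")
        prev = -1.0
        for ev in self.events:
            if ev.code_id not in ethogram:
                raise ValidationError(f"unknown code {ev.code_id!r}")
            if ev.time_s < 0:
                raise ValidationError(f"negative time {ev.time_s} for {ev.code_id}")
            if ev.time_s < prev:
                raise ValidationError("events not sorted by time")
            prev = ev.time_s
            code = ethogram[ev.code_id]
            if code.event_class == "state":
                if ev.stop_s is None or ev.stop_s < ev.time_s:
                    raise ValidationError(
                        f"state event {ev.code_id}@{ev.time_s} needs stop >= start"
                    )
            elif ev.stop_s is not None:
                raise ValidationError(
                    f"point event {ev.code_id}@{ev.time_s} cannot span a duration"
                )
            if code.function == "engagement_attribute":
                if ev.modifier not in ENG_LEVELS:
                    raise ValidationError(
                        f"ENG@{ev.time_s}: modifier must be one of {ENG_LEVELS}"
                    )
            elif ev.modifier is not None:
                raise ValidationError(
                    f"{ev.code_id}@{ev.time_s}: modifier only allowed on ENG"
                )

    def point_events(self) -> list[AnnotatedEvent]:
        return [e for e in self.events if not e.is_state]

    def state_events(self, code_id: str = "SA") -> list[AnnotatedEvent]:
        return [e for e in self.events if e.is_state and e.code_id == code_id]


# --------------------------------------------------------------------------
# annotation file dialect
# --------------------------------------------------------------------------

_COLUMNS = ["Time", "Subject", "Behavior", "Modifiers", "Behavior type"]


def _sniff_delimiter(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_events(
    path: str | Path,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    *,
    session_id: str | None = None,
    dyad_id: str = "",
    timepoint: str = "T0",
    window_len_s: float = 1200.0,
    coder_id: str = "",
) -> SessionRecord:
    """Parse a tabular annotation export into a validated session record.

    START/STOP row pairs are merged into single state events, matching by
    (behavior, subject) to the nearest following STOP.  Unknown codes,
    negative times, unmatched STARTs and stray STOPs raise
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    reader = csv.reader(_io.StringIO(text), delimiter=delim)
    rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: empty file")
    header = [h.strip().lower() for h in rows[0]]

    def col(name: str) -> int:
        name = name.lower()
        for i, h in enumerate(header):
            if h == name:
                return i
        raise ValidationError(f"{path}: missing column {name!r}")

    i_time, i_subj, i_beh = col("time"), col("subject"), col("behavior")
    i_mod, i_type = col("modifiers"), col("behavior type")

    events: list[AnnotatedEvent] = []
    open_states: dict[tuple[str, str], tuple[int, float]] = {}
    n_parsed = 0
    for rownum, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        beh = row[i_beh].strip()
        if beh not in ethogram:
            raise ValidationError(f"{path} row {rownum}: unknown code {beh!r}")
        try:
            t = float(row[i_time])
        except ValueError as exc:
            raise ValidationError(f"{path} row {rownum}: bad time {row[i_time]!r}") from exc
        if t < 0:
            raise ValidationError(f"{path} row {rownum}: negative time {t}")
        subj = row[i_subj].strip()
        mod_raw = row[i_mod].strip() if i_mod < len(row) else ""
        modifier = int(float(mod_raw)) if mod_raw else None
        etype = row[i_type].strip().upper()
        if etype == "POINT":
            events.append(AnnotatedEvent(t, beh, modifier=modifier, coder_id=coder_id))
            n_parsed += 1
        elif etype == "START":
            key = (beh, subj)
            if key in open_states:
                raise ValidationError(
                    f"{path} row {rownum}: {beh} START while a previous "
                    f"START (row {open_states[key][0]}) is still open"
                )
            open_states[key] = (rownum, t)
        elif etype == "STOP":
            key = (beh, subj)
            if key not in open_states:
                raise ValidationError(f"{path} row {rownum}: {beh} STOP without START")
            _, t0 = open_states.pop(key)
            if t < t0:
                raise ValidationError(f"{path} row {rownum}: STOP before START for {beh}")
            events.append(AnnotatedEvent(t0, beh, stop_s=t, coder_id=coder_id))
            n_parsed += 1
        else:
            raise ValidationError(
                f"{path} row {rownum}: behavior type must be POINT/START/STOP, "
                f"got {etype!r}"
            )
    if open_states:
        missing = ", ".join(
            f"{code} (row {rownum})" for (code, _), (rownum, _) in open_states.items()
        )
        raise ValidationError(f"{path}: START without matching STOP: {missing}")

    return SessionRecord(
        session_id=session_id or path.stem,
        events=events,
        dyad_id=dyad_id,
        timepoint=timepoint,
        window_len_s=window_len_s,
        coder_id=coder_id,
    )


def write_events(
    session: SessionRecord,
    path: str | Path,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    *,
    delimiter: str = ",",
) -> None:
    """Write a session back to the tabular dialect consumed by
    :func:`read_events` (lossless round trip); times formatted to ms."""
    session.validate(ethogram)
    rows: list[tuple[float, int, list[str]]] = []  # (time, seq, row)
    for seq, ev in enumerate(session.events):
        subject = ethogram[ev.code_id].actor
        mod = "" if ev.modifier is None else str(ev.modifier)
        if ev.is_state:
            rows.append((ev.time_s, seq, [f"{ev.time_s:.3f}", subject, ev.code_id, mod, "START"]))
            rows.append((ev.stop_s, seq, [f"{ev.stop_s:.3f}", subject, ev.code_id, mod, "STOP"]))
        else:
            rows.append((ev.time_s, seq, [f"{ev.time_s:.3f}", subject, ev.code_id, mod, "POINT"]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for _, _, row in rows:
            writer.writerow(row)


# --------------------------------------------------------------------------
# outcome indices
# --------------------------------------------------------------------------


@dataclass
class OutcomeRecord:
    """Per-child, per-timepoint outcome measures.

    ``rMC`` is the mental/chronological age ratio at the timepoint; ``LR``
    (learning rate) is the mental-age gain divided by elapsed time between
    the two assessments, so LR = 1 marks a typical developmental pace.
    """

    child_id: str
    timepoint: str
    chron_age_months: float
    mental_age_months: float
    rMC: float = 0.0
    LR: float | None = None
    ados_sa: float | None = None
    ados_rrb: float | None = None
    language_q: float | None = None
    eas_involvement: float | None = None
    eas_responsiveness: float | None = None


def compute_outcome_indices(
    records: pd.DataFrame,
    *,
    age_unit: str = "months",
) -> pd.DataFrame:
    """Derive rMC per timepoint and LR between T0 and T1.

    ``records`` needs columns ``child_id``, ``timepoint``,
    ``chron_age_months``, ``mental_age_months`` (any extra outcome columns
    are passed through).  If ``age_unit == "days"`` ages are converted at
    30.44 days/month.  LR is attached to the T1 row of each child with both
    timepoints; requesting LR implicitly needs a T0 row and a nonzero
    elapsed time.
    """
    df = records.copy()
    if age_unit == "days":
        df["chron_age_months"] = df["chron_age_months"] / DAYS_PER_MONTH
        df["mental_age_months"] = df["mental_age_months"] / DAYS_PER_MONTH
    elif age_unit != "months":
        raise ValueError("age_unit must be 'months' or 'days'")
    if (df["chron_age_months"] <= 0).any():
        raise ValidationError("chronological age must be positive")
    df["rMC"] = df["mental_age_months"] / df["chron_age_months"]
    df["LR"] = float("nan")
    for child, grp in df.groupby("child_id"):
        tps = dict(zip(grp["timepoint"], grp.index))
        if "T0" in tps and "T1" in tps:
            i0, i1 = tps["T0"], tps["T1"]
            elapsed = df.loc[i1, "chron_age_months"] - df.loc[i0, "chron_age_months"]
            if elapsed == 0:
                raise ValidationError(f"child {child}: zero elapsed time between T0 and T1")
            gain = df.loc[i1, "mental_age_months"] - df.loc[i0, "mental_age_months"]
            df.loc[i1, "LR"] = gain / elapsed
    return df
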