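"""Structural segmentation of an annotation stream.

Turns the flat time-event stream of a session into the structural model of
the interaction: paired initiation-response exchanges, interaction units
(successful pairings outside a shared activity that may launch one), and
shared-activity episodes with their interior codes, engagement levels and a
termination label.

Pairing rule: a response answers the most recent unanswered initiation by
the other partner whose valid-response set contains it.  An initiation is
marked *ignored* as soon as a new (non-affect) initiation by either partner
occurs, the shared-activity state changes, or the coding window ends --
whichever comes first.  Affect codes (CD/TR) are paired on a separate
channel so that inserting them never perturbs interaction pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ethogram import (
    DEFAULT_ETHOGRAM,
    AnnotatedEvent,
    Ethogram,
    SessionRecord,
)

__all__ = [
    "PairedExchange",
    "InteractionUnit",
    "SharedActivity",
    "SequencerDiagnostics",
    "pair_exchanges",
    "interaction_units",
    "segment_shared_activities",
    "count_synchrony",
    "screen_sparse_codes",
]

#: pair types counted as interaction units when successful outside an SA
IU_PAIR_TYPES = ("TP-CA", "CI-TI", "CP-TA")

#: codes that terminate a shared activity
TERMINATOR_CODES = ("CX", "CE", "TE")


@dataclass
class PairedExchange:
    """One initiation and its (possibly missing) answer."""

    start_event: AnnotatedEvent
    response_event: AnnotatedEvent | None
    outcome: str  # answered | refused | ignored
    context: str  # outside_sa | inside_sa

    @property
    def pair_type(self) -> str:
        if self.response_event is None:
            return self.start_event.code_id
        return f"{self.start_event.code_id}-{self.response_event.code_id}"

    @property
    def latency_s(self) -> float | None:
        if self.response_event is None:
            return None
        return self.response_event.time_s - self.start_event.time_s


@dataclass
class InteractionUnit:
    """A successful outside-SA exchange that may launch a shared activity."""

    exchange: PairedExchange
    initiated_sa: bool = False
    sa_latency_s: float | None = None

    @property
    def pair_type(self) -> str:
        return self.exchange.pair_type


@dataclass
class SharedActivity:
    """A segmented shared-activity episode."""

    start_s: float
    end_s: float
    initiating_iu: InteractionUnit | None = None
    mid_events: list[AnnotatedEvent] = field(default_factory=list)
    termination: str = "window_end"  # CX | CE | TE | window_end
    eng_levels: list[int] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SequencerDiagnostics:
    """Row-level oddities collected (never raised) during sequencing."""

    orphan_responses: list[AnnotatedEvent] = field(default_factory=list)
    ignored_initiations: list[AnnotatedEvent] = field(default_factory=list)
    eng_outside_sa: list[AnnotatedEvent] = field(default_factory=list)
    tw_outside_sa: list[AnnotatedEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _fmt(evs):
            return [{"time_s": e.time_s, "code": e.code_id} for e in evs]

        return {
            "orphan_responses": _fmt(self.orphan_responses),
            "ignored_initiations": _fmt(self.ignored_initiations),
            "eng_outside_sa": _fmt(self.eng_outside_sa),
            "tw_outside_sa": _fmt(self.tw_outside_sa),
        }


def _sa_spans(session: SessionRecord) -> list[tuple[float, float]]:
    spans = sorted(
        (e.time_s, e.stop_s) for e in session.state_events("SA")
    )
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError(
                f"overlapping SA states: [{s0}, {e0}] and starting {s1}"
            )
    return spans


def _context(t: float, spans: list[tuple[float, float]]) -> str:
    for s, e in spans:
        if s <= t < e:
            return "inside_sa"
    return "outside_sa"


def pair_exchanges(
    session: SessionRecord,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    *,
    max_latency_s: float | None = None,
    diagnostics: SequencerDiagnostics | None = None,
) -> list[PairedExchange]:
    """Assign every initiation exactly one outcome.

    Returns exchanges ordered by initiation time.  Orphan responses (answers
    that match no open initiation) are recorded in ``diagnostics``, never
    raised.  ``max_latency_s`` optionally expires an open initiation once the
    candidate response arrives later than the cap.
    """
    diag = diagnostics if diagnostics is not None else SequencerDiagnostics()
    spans = _sa_spans(session)

    # boundary markers where the SA state changes expire open initiations
    boundaries = sorted({t for span in spans for t in span})

    interaction_inits = {"TP", "TW", "CI", "CP"}
    affect_inits = {"CD"}
    responses = {"CA", "CR", "TI", "TA", "TR"}

    exchanges: list[PairedExchange] = []
    pending: dict[str, tuple[AnnotatedEvent, int] | None] = {
        "interaction": None,
        "affect": None,
    }
    b_idx = 0

    def _close(channel: str) -> None:
        slot = pending[channel]
        if slot is not None:
            ev, _ = slot
            exchanges.append(
                PairedExchange(ev, None, "ignored", _context(ev.time_s, spans))
            )
            diag.ignored_initiations.append(ev)
            pending[channel] = None

    events = [e for e in session.events if not e.is_state]
    for row, ev in enumerate(events):
        # expire open initiations at any SA boundary crossed before this event
        while b_idx < len(boundaries) and boundaries[b_idx] < ev.time_s:
            _close("interaction")
            _close("affect")
            b_idx += 1
        code = ev.code_id
        fn = ethogram[code].function if code in ethogram else ""
        if code in interaction_inits or fn == "initiation":
            _close("interaction")
            pending["interaction"] = (ev, row)
            if code == "TW" and _context(ev.time_s, spans) == "outside_sa":
                diag.tw_outside_sa.append(ev)
        elif code in affect_inits:
            _close("affect")
            pending["affect"] = (ev, row)
        elif code in responses:
            channel = "affect" if code == "TR" else "interaction"
            slot = pending[channel]
            matched = False
            if slot is not None:
                init_ev, _ = slot
                init_code = ethogram[init_ev.code_id]
                same_actor = ethogram[code].actor == init_code.actor
                in_valid = code in init_code.valid_responses
                within_cap = (
                    max_latency_s is None
                    or ev.time_s - init_ev.time_s <= max_latency_s
                )
                if in_valid and not same_actor and within_cap:
                    outcome = "refused" if code == "CR" else "answered"
                    exchanges.append(
                        PairedExchange(
                            init_ev, ev, outcome, _context(init_ev.time_s, spans)
                        )
                    )
                    pending[channel] = None
                    matched = True
            if not matched:
                diag.orphan_responses.append(ev)
        elif ev.code_id == "ENG":
            if _context(ev.time_s, spans) == "outside_sa":
                diag.eng_outside_sa.append(ev)
        # terminators and other codes pass through

    _close("interaction")
    _close("affect")
    exchanges.sort(key=lambda x: x.start_event.time_s)
    return exchanges


def interaction_units(
    exchanges: list[PairedExchange],
) -> list[InteractionUnit]:
    """Successful outside-SA exchanges of an IU pair type, in time order."""
    return [
        InteractionUnit(x)
        for x in exchanges
        if x.outcome == "answered"
        and x.context == "outside_sa"
        and x.pair_type in IU_PAIR_TYPES
    ]


def segment_shared_activities(
    session: SessionRecord,
    exchanges: list[PairedExchange],
    *,
    terminator_tolerance_s: float = 2.0,
    ius: list[InteractionUnit] | None = None,
) -> list[SharedActivity]:
    """Build one :class:`SharedActivity` per SA state event.

    The initiating IU is the latest successful interaction unit whose
    response precedes the SA start; a terminator code (CX/CE/TE) inside the
    span or within ``terminator_tolerance_s`` after its end labels the
    termination, else ``window_end``.  Mutates ``initiated_sa`` /
    ``sa_latency_s`` on the linked IUs.
    """
    spans = _sa_spans(session)
    if ius is None:
        ius = interaction_units(exchanges)
    points = [e for e in session.events if not e.is_state]

    activities: list[SharedActivity] = []
    for start, end in spans:
        sa = SharedActivity(start_s=start, end_s=end)
        # terminator: last CX/CE/TE with start < t <= end + tolerance
        terminator_ev = None
        for ev in points:
            if ev.code_id in TERMINATOR_CODES and start < ev.time_s <= end + terminator_tolerance_s:
                terminator_ev = ev
        if terminator_ev is not None:
            sa.termination = terminator_ev.code_id
        for ev in points:
            if ev is terminator_ev:
                continue
            if start < ev.time_s < end:
                if ev.code_id == "ENG":
                    sa.eng_levels.append(int(ev.modifier))
                else:
                    sa.mid_events.append(ev)
            elif ev.code_id == "ENG" and ev.time_s in (start, end):
                sa.eng_levels.append(int(ev.modifier))
        # link the latest successful IU completing before the SA start
        best = None
        for iu in ius:
            resp_t = iu.exchange.response_event.time_s
            if resp_t <= start and (
                best is None
                or resp_t > best.exchange.response_event.time_s
            ):
                best = iu
        if best is not None and not best.initiated_sa:
            best.initiated_sa = True
            best.sa_latency_s = start - best.exchange.response_event.time_s
            sa.initiating_iu = best
        activities.append(sa)
    return activities


def count_synchrony(
    exchanges: list[PairedExchange],
    *,
    include_refusals: bool = False,
    include_affect: bool = False,
) -> tuple[int, int]:
    """(n_sync, n_pairs) over initiation exchanges.

    ``n_pairs`` counts every initiation (all contexts); ``n_sync`` counts
    those answered by the appropriate complementary response.  Refusals are
    excluded by default (a refusal acknowledges but does not attune);
    affect pairs (CD-TR) are excluded from both counts by default.
    """
    affect_codes = {"CD"}
    n_pairs = 0
    n_sync = 0
    for x in exchanges:
        if not include_affect and x.start_event.code_id in affect_codes:
            continue
        n_pairs += 1
        if x.outcome == "answered" or (include_refusals and x.outcome == "refused"):
            n_sync += 1
    return n_sync, n_pairs


def screen_sparse_codes(
    sessions_or_props: "list[SessionRecord] | pd.DataFrame",
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Exclude codes whose per-session proportional frequency is too sparse.

    For each code, the proportional frequency (count over total coded
    events, engagement attribute excluded) is computed per session; a code
    is excluded when the group SD (ddof=1) exceeds the group mean.  Returns
    ``(kept, excluded, stats)`` where ``stats`` has one row per code with
    its mean and SD.
    """
    if isinstance(sessions_or_props, pd.DataFrame):
        props = sessions_or_props
    else:
        sessions = sessions_or_props
        codes = [
            c.code_id
            for c in ethogram
            if c.function != "engagement_attribute"
        ]
        rows = []
        for s in sessions:
            counts = {c: 0 for c in codes}
            for ev in s.events:
                if ev.code_id in counts:
                    counts[ev.code_id] += 1
            total = sum(counts.values())
            rows.append(
                {c: (counts[c] / total if total else 0.0) for c in codes}
            )
        props = pd.DataFrame(rows)
    if len(props) < 2:
        raise ValueError("sparsity screening needs at least 2 sessions")
    mean = props.mean(axis=0)
    sd = props.std(axis=0, ddof=1)
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    stats["excluded"] = stats["sd"] > stats["mean"]
    kept = list(stats.index[~stats["excluded"]])
    excluded = list(stats.index[stats["excluded"]])
    return kept, excluded, stats
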