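"""Session-level behavioral descriptors and group aggregation.

Every descriptor quantifies one facet of the coded interaction: event counts
and rates (how much happened), success rates (how often initiations were
answered), latencies and durations (how fast and how long), and engagement.
Denominators are documented per field; a descriptor whose denominator is
zero is ``None`` -- missing, never silently zero.

Conventions
-----------
* ``n_tot`` counts every coded event including shared-activity occurrences
  but not the engagement attribute (ENG annotates an SA, it is not a
  behavior of its own).
* ``cpm`` uses the actual coded window length, not a nominal value.
* ``eng`` is the unweighted mean of per-activity mean engagement levels
  (``eng_duration_weighted=True`` switches to duration weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ethogram import DEFAULT_ETHOGRAM, Ethogram, SessionRecord
from .sequencer import (
    IU_PAIR_TYPES,
    InteractionUnit,
    PairedExchange,
    SharedActivity,
    count_synchrony,
    interaction_units,
    pair_exchanges,
    segment_shared_activities,
)

__all__ = ["DescriptorSet", "compute_descriptors", "descriptor_table", "aggregate_group"]


def _mean(xs) -> float | None:
    xs = list(xs)
    return float(np.mean(xs)) if xs else None


def _ratio(num: float, den: float) -> float | None:
    return num / den if den else None


@dataclass
class DescriptorSet:
    """The full indicator vector for one session."""

    session_id: str
    dyad_id: str
    timepoint: str

    n_tot: int = 0
    n_sync: int = 0
    n_udi: int = 0
    p_ca: float | None = None
    p_cx: float | None = None
    p_sa: float | None = None
    r_tpca: float | None = None
    r_citi: float | None = None
    r_sync: float | None = None
    sr_tpca: float | None = None
    sr_citi: float | None = None
    r_sa: float | None = None
    r_sa_tpca: float | None = None
    latency_tpca: float | None = None
    latency_sa: float | None = None
    latency_twca: float | None = None
    duration_sa: float | None = None
    duration_sa_tpca: float | None = None
    r_cx: float | None = None
    srtwca_sa: float | None = None
    n_between_sa: float | None = None
    cpm: float | None = None
    sr_udi: float | None = None
    eng: float | None = None
    code_proportions: dict[str, float] = field(default_factory=dict)

    #: canonical column names, upper-case as used in reports
    _TABLE_FIELDS = (
        "n_tot n_sync n_udi p_ca p_cx p_sa r_tpca r_citi r_sync sr_tpca "
        "sr_citi r_sa r_sa_tpca latency_tpca latency_sa latency_twca "
        "duration_sa r_cx srtwca_sa n_between_sa cpm sr_udi eng"
    ).split()

    def to_dict(self, *, upper: bool = True) -> dict:
        out = {"session_id": self.session_id, "dyad_id": self.dyad_id,
               "timepoint": self.timepoint}
        for name in self._TABLE_FIELDS + ["duration_sa_tpca"]:
            key = name.upper() if upper else name
            out[key] = getattr(self, name)
        for code, p in sorted(self.code_proportions.items()):
            out[f"P_{code}" if upper else f"p_{code.lower()}"] = p
        return out


def compute_descriptors(
    session: SessionRecord,
    exchanges: list[PairedExchange] | None = None,
    activities: list[SharedActivity] | None = None,
    *,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    ius: list[InteractionUnit] | None = None,
    include_refusals_in_sync: bool = False,
    eng_duration_weighted: bool = False,
) -> DescriptorSet:
    """Compute every descriptor for one session.

    If ``exchanges``/``activities`` are omitted the sequencer is run with
    defaults.  Passing them in lets callers reuse sequencer output and
    non-default segmentation options.
    """
    if exchanges is None:
        exchanges = pair_exchanges(session, ethogram)
    if ius is None:
        ius = interaction_units(exchanges)
    if activities is None:
        activities = segment_shared_activities(session, exchanges, ius=ius)

    events = [
        e for e in session.events
        if ethogram[e.code_id].function != "engagement_attribute"
    ]
    n_tot = len(events)
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.code_id] = counts.get(ev.code_id, 0) + 1

    n_sync, n_pairs = count_synchrony(
        exchanges, include_refusals=include_refusals_in_sync
    )
    n_udi = len(ius)

    by_type = {pt: [iu for iu in ius if iu.pair_type == pt] for pt in IU_PAIR_TYPES}
    tp_exchanges = [x for x in exchanges if x.start_event.code_id == "TP"]
    ci_exchanges = [x for x in exchanges if x.start_event.code_id == "CI"]
    tw_in_sa = [
        x for x in exchanges
        if x.start_event.code_id == "TW" and x.context == "inside_sa"
    ]
    answered_tp = [x for x in tp_exchanges if x.outcome == "answered"]
    answered_ci = [x for x in ci_exchanges if x.outcome == "answered"]
    answered_tw_sa = [x for x in tw_in_sa if x.outcome == "answered"]

    tpca_ius = by_type["TP-CA"]
    sa_initiating = [iu for iu in ius if iu.initiated_sa]
    sa_initiating_tpca = [iu for iu in tpca_ius if iu.initiated_sa]

    sa_tpca = [
        a for a in activities
        if a.initiating_iu is not None and a.initiating_iu.pair_type == "TP-CA"
    ]

    if eng_duration_weighted:
        w = [(a.duration_s, float(np.mean(a.eng_levels)))
             for a in activities if a.eng_levels]
        eng = (sum(d * m for d, m in w) / sum(d for d, _ in w)) if w else None
    else:
        eng = _mean(float(np.mean(a.eng_levels)) for a in activities if a.eng_levels)

    return DescriptorSet(
        session_id=session.session_id,
        dyad_id=session.dyad_id,
        timepoint=session.timepoint,
        n_tot=n_tot,
        n_sync=n_sync,
        n_udi=n_udi,
        p_ca=_ratio(counts.get("CA", 0), n_tot),
        p_cx=_ratio(counts.get("CX", 0), n_tot),
        p_sa=_ratio(counts.get("SA", 0), n_tot),
        r_tpca=_ratio(len(tpca_ius), n_udi),
        r_citi=_ratio(len(by_type["CI-TI"]), n_udi),
        r_sync=_ratio(n_sync, n_pairs),
        sr_tpca=_ratio(len(answered_tp), len(tp_exchanges)),
        sr_citi=_ratio(len(answered_ci), len(ci_exchanges)),
        r_sa=_ratio(len(sa_initiating), n_udi),
        r_sa_tpca=_ratio(len(sa_initiating_tpca), len(tpca_ius)),
        latency_tpca=_mean(x.latency_s for x in answered_tp),
        latency_sa=_mean(
            a.start_s - a.initiating_iu.exchange.response_event.time_s
            for a in activities if a.initiating_iu is not None
        ),
        latency_twca=_mean(
            x.latency_s for x in exchanges
            if x.start_event.code_id == "TW" and x.outcome == "answered"
        ),
        duration_sa=_mean(a.duration_s for a in activities),
        duration_sa_tpca=_mean(a.duration_s for a in sa_tpca),
        r_cx=_ratio(sum(a.termination == "CX" for a in activities), len(activities)),
        srtwca_sa=_ratio(len(answered_tw_sa), len(tw_in_sa)),
        n_between_sa=_mean(len(a.mid_events) for a in activities),
        cpm=_ratio(n_tot, session.window_len_s / 60.0),
        sr_udi=_ratio(counts.get("CA", 0), counts.get("TP", 0) + counts.get("TW", 0)),
        eng=eng,
        code_proportions={
            c: _ratio(counts.get(c, 0), n_tot) or 0.0
            for c in ethogram.code_ids
            if ethogram[c].function != "engagement_attribute"
        },
    )


def descriptor_table(descriptor_sets: list[DescriptorSet]) -> pd.DataFrame:
    """One row per session, canonical upper-case column names."""
    return pd.DataFrame([d.to_dict() for d in descriptor_sets])


def aggregate_group(
    table: pd.DataFrame,
    *,
    by: str = "timepoint",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Group summary plus the paired (wide) table for downstream tests.

    Returns ``(summary, paired, incomplete)``:

    * ``summary``: mean, SD (ddof=1, ``NaN`` for singleton groups), min and
      max per descriptor per group level;
    * ``paired``: one row per dyad with complete T0/T1 coverage, columns
      ``<DESCRIPTOR>_<level>``;
    * ``incomplete``: dyad ids excluded for missing a timepoint.
    """
    meta = {"session_id", "dyad_id", "timepoint"}
    value_cols = [c for c in table.columns if c not in meta]
    grouped = table.groupby(by)[value_cols]
    summary = grouped.agg(["mean", "std", "min", "max"])

    levels = sorted(table[by].unique())
    counts = table.groupby("dyad_id")[by].nunique()
    complete = counts.index[counts == len(levels)]
    incomplete = sorted(set(table["dyad_id"]) - set(complete))
    wide = (
        table[table["dyad_id"].isin(complete)]
        .pivot_table(index="dyad_id", columns=by, values=value_cols, aggfunc="first")
    )
    wide.columns = [f"{c}_{lv}" for c, lv in wide.columns]
    return summary, wide, incomplete
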