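"""Shared fixtures: the hand-enumerated worked session and random streams."""

import numpy as np
import pytest

from dyadkit.ethogram import AnnotatedEvent as E
from dyadkit.ethogram import SessionRecord


@pytest.fixture
def toy_session() -> SessionRecord:
    """600-s worked example whose descriptors were enumerated by hand.

    TP@0 answered by CA@3; SA(5-100) containing TW@60/CA@63 and ended by
    CX@100; CI@120 answered by TI@122; SA(125-300) with ENG levels 1 and 2,
    ended by TE@300.
    """
    events = [
        E(0, "TP"), E(3, "CA"),
        E(5, "SA", stop_s=100), E(60, "TW"), E(63, "CA"), E(100, "CX"),
        E(120, "CI"), E(122, "TI"),
        E(125, "SA", stop_s=300),
        E(200, "ENG", modifier=1), E(250, "ENG", modifier=2),
        E(300, "TE"),
    ]
    return SessionRecord("toy", events, dyad_id="d1", window_len_s=600.0)


#: hand-enumerated descriptor values for the toy session
TOY_EXPECTED = {
    "n_tot": 10, "n_sync": 3, "n_udi": 2,
    "p_ca": 0.2, "p_cx": 0.1, "p_sa": 0.2,
    "r_tpca": 0.5, "r_citi": 0.5, "r_sync": 1.0,
    "sr_tpca": 1.0, "sr_citi": 1.0,
    "r_sa": 1.0, "r_sa_tpca": 1.0,
    "latency_tpca": 3.0, "latency_sa": 2.5, "latency_twca": 3.0,
    "duration_sa": 135.0, "duration_sa_tpca": 95.0,
    "r_cx": 0.5, "srtwca_sa": 1.0, "n_between_sa": 1.0,
    "cpm": 1.0, "sr_udi": 1.0, "eng": 1.5,
}


def random_stream(rng: np.random.Generator, max_events: int = 30) -> SessionRecord:
    """A random (not necessarily plausible) stream for oracle comparison."""
    window = 120.0
    n = int(rng.integers(0, max_events + 1))
    point_codes = ["TP", "TW", "CA", "CR", "CI", "TI", "CP", "TA",
                   "CD", "TR", "CX", "CE", "TE", "ENG"]
    events = []
    times = np.sort(rng.uniform(0, window, size=n))
    for t in times:
        code = point_codes[int(rng.integers(len(point_codes)))]
        mod = int(rng.integers(1, 4)) if code == "ENG" else None
        events.append(E(float(t), code, modifier=mod))
    # up to two non-overlapping SA spans
    n_sa = int(rng.integers(0, 3))
    cuts = np.sort(rng.uniform(0, window, size=2 * n_sa))
    for i in range(n_sa):
        s, e = float(cuts[2 * i]), float(cuts[2 * i + 1])
        if e > s:
            events.append(E(s, "SA", stop_s=e))
    return SessionRecord("rnd", events, window_len_s=window)


def oracle_pair(session: SessionRecord) -> list[tuple]:
    """Brute-force pairing oracle, structured independently of the
    production automaton.

    Enumerates every initiation's 'alive window' explicitly -- it ends at
    the next (same-channel) initiation, at any SA boundary, or at the
    window end -- then walks responses in time order, answering the most
    recent alive, unanswered, valid initiation by the opposite actor.
    Returns tuples (init_time, init_code, resp_time|None, outcome).
    """
    from dyadkit.ethogram import DEFAULT_ETHOGRAM as eth

    points = [e for e in session.events if not e.is_state]
    boundaries = sorted(
        {t for e in session.events if e.is_state for t in (e.time_s, e.stop_s)}
    )
    inter_init = [
        (i, e) for i, e in enumerate(points)
        if eth[e.code_id].function == "initiation"
    ]
    affect_init = [(i, e) for i, e in enumerate(points) if e.code_id == "CD"]
    resp_rows = [
        (i, e) for i, e in enumerate(points)
        if eth[e.code_id].function == "response" or e.code_id == "TR"
    ]

    def alive(init_row, init_ev, resp_row, resp_ev, channel_inits):
        if resp_row < init_row:
            return False
        # a newer same-channel initiation between them kills it
        for j, other in channel_inits:
            if init_row < j < resp_row:
                return False
        # an SA boundary in [t_init, t_resp) kills it
        for b in boundaries:
            if init_ev.time_s <= b < resp_ev.time_s:
                return False
        return True

    answered: dict[int, tuple] = {}
    used_resp: set[int] = set()
    for rrow, rev in resp_rows:
        channel = affect_init if rev.code_id == "TR" else inter_init
        candidates = [
            (irow, iev) for irow, iev in channel
            if irow not in answered
            and rev.code_id in eth[iev.code_id].valid_responses
            and eth[rev.code_id].actor != eth[iev.code_id].actor
            and alive(irow, iev, rrow, rev, channel)
        ]
        if candidates:
            irow, iev = max(candidates, key=lambda c: c[0])
            outcome = "refused" if rev.code_id == "CR" else "answered"
            answered[irow] = (iev.time_s, iev.code_id, rev.time_s, outcome)
            used_resp.add(rrow)
    out = []
    for irow, iev in sorted(inter_init + affect_init):
        if irow in answered:
            out.append(answered[irow])
        else:
            out.append((iev.time_s, iev.code_id, None, "ignored"))
    out.sort(key=lambda r: r[0])
    return out
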