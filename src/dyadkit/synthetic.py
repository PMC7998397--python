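"""Generative model of dyadic therapy sessions and longitudinal cohorts.

The simulator emulates the structure of a coded 20-minute play session as a
semi-Markov event process.  Outside a shared activity, initiations by the
two partners (therapist proposals TP, child intentionality CI, child
proposals CP, child dysregulation CD) arrive by competing exponential
clocks; each initiation is answered with a configurable probability after a
log-normal latency.  A successful interaction unit starts a shared activity
(SA) with some probability after an exponential delay; inside the SA the
therapist widens the play (TW) at its own exponential rate and each
widening may be accepted (CA).  SA durations are log-normal; the episode
ends with a termination code drawn from (CX, CE, TE) weights and carries an
engagement (ENG) level drawn from a three-point distribution.  Streams are
truncated at the window end.

Default parameter values are moment-matched to the baseline (T0) condition
of an early-intervention cohort of n = 24 dyads coded at diagnosis and
after roughly one year of therapy; the default T1 shift moves the same
parameters toward the post-intervention condition (higher acceptance and
engagement, longer and less frequently child-interrupted activities, lower
overall code rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any

import numpy as np
import pandas as pd

from .ethogram import AnnotatedEvent, SessionRecord

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "CohortResult",
    "DEFAULT_T1_SHIFT",
    "DEFAULT_PARAM_JITTER",
    "simulate_session",
    "simulate_cohort",
    "apply_shift",
    "expected_code_mix",
]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given moments."""
    var = sd * sd
    sigma2 = math.log(1.0 + var / (mean * mean))
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters for one session condition.

    Rates are events per minute; latencies and durations in seconds.
    Defaults describe the baseline (T0) condition.
    """

    window_len_s: float = 1200.0
    # outside-SA initiation clocks (per minute of outside-SA time)
    rate_tp: float = 3.2
    rate_ci: float = 1.85
    rate_cp: float = 0.28
    rate_cd: float = 0.55
    # response probabilities
    p_accept: float = 0.62          # TP -> CA
    p_refuse: float = 0.08          # TP -> CR (remainder ignored)
    p_recognize: float = 0.92       # CI -> TI
    p_share: float = 0.95           # CP -> TA
    p_tr: float = 0.55              # CD -> TR
    # interaction-unit -> shared-activity transition
    p_sa_after_iu: float = 0.49
    latency_response: tuple[float, float] = (2.75, 1.3)   # log-normal mean, sd
    latency_sa_mean: float = 12.5                         # exponential mean
    sa_duration: tuple[float, float] = (150.0, 100.0)     # log-normal mean, sd
    # inside-SA dynamics
    rate_tw_in_sa: float = 1.8
    p_tw_accept: float = 0.57
    termination_probs: tuple[float, float, float] = (0.87, 0.05, 0.08)  # CX, CE, TE
    eng_probs: tuple[float, float, float] = (0.89, 0.10, 0.01)          # levels 1..3

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("rate_") and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
            if f.name.startswith("p_") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1], got {v}")
        if self.p_accept + self.p_refuse > 1.0:
            raise ValueError("p_accept + p_refuse must not exceed 1")
        for name in ("termination_probs", "eng_probs"):
            probs = getattr(self, name)
            if any(q < 0 for q in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.window_len_s <= 0:
            raise ValueError("window_len_s must be positive")


#: per-parameter deltas moving the T0 condition to the T1 condition
DEFAULT_T1_SHIFT: dict[str, Any] = {
    "rate_tp": -0.8,
    "rate_ci": -0.70,
    "rate_cd": -0.15,
    "p_accept": +0.17,
    "p_refuse": -0.04,
    "p_tw_accept": +0.20,
    "rate_tw_in_sa": -0.40,
    "sa_duration": (+95.0, +45.0),
    "latency_response": (-0.6, -0.2),
    "latency_sa_mean": +2.0,
    "termination_probs": (-0.22, +0.07, +0.15),
    "eng_probs": (-0.49, +0.41, +0.08),
}

#: between-dyad SDs of the parameters that vary across dyads (drawn once
#: per dyad, shared by both timepoints so paired contrasts cancel them)
DEFAULT_PARAM_JITTER: dict[str, float] = {
    "rate_tp": 0.60,
    "rate_ci": 0.45,
    "p_accept": 0.07,
    "p_tw_accept": 0.10,
    "p_sa_after_iu": 0.10,
    "latency_sa_mean": 4.0,
}


def apply_shift(config: SimulationConfig, shift: dict[str, Any]) -> SimulationConfig:
    """Add per-parameter deltas to a config; tuple-valued parameters are
    shifted componentwise.  The shifted config is re-validated and errors
    name the offending parameter."""
    updates: dict[str, Any] = {}
    for name, delta in shift.items():
        cur = getattr(config, name)
        if isinstance(cur, tuple):
            updates[name] = tuple(c + d for c, d in zip(cur, delta))
        else:
            updates[name] = cur + delta
    out = replace(config, **updates)
    try:
        out.validate()
    except ValueError as exc:
        raise ValueError(f"invalid shifted parameter: {exc}") from exc
    return out


def _clipped_jitter(
    config: SimulationConfig,
    jitter: dict[str, float],
    rng: np.random.Generator,
    shift: dict[str, Any] | None = None,
) -> dict[str, float]:
    """Per-dyad parameter offsets, clipped so that both the jittered value
    and its later shifted (T1) value stay inside the valid range."""
    shift = shift or {}
    margin = 0.02
    offsets = {}
    for name, sd in jitter.items():
        base = getattr(config, name)
        delta = float(shift.get(name, 0.0))
        off = float(rng.normal(0.0, sd))
        if name.startswith("p_"):
            hi = 1.0 - margin - max(delta, 0.0)
            if name == "p_accept":
                refuse_max = max(
                    config.p_refuse,
                    config.p_refuse + float(shift.get("p_refuse", 0.0)),
                )
                hi -= refuse_max
            lo = margin - min(delta, 0.0)
            off = min(max(off, lo - base), hi - base)
        else:  # rates and mean latencies: keep above a small floor
            floor = 0.05
            lo = floor - min(delta, 0.0)
            off = max(off, lo - base)
        offsets[name] = off
    return offsets


def simulate_session(
    config: SimulationConfig,
    seed: "int | np.random.Generator" = 0,
    *,
    session_id: str = "sim",
    dyad_id: str = "",
    timepoint: str = "T0",
) -> SessionRecord:
    """Draw one session event stream from the generative model."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = config.window_len_s
    events: list[AnnotatedEvent] = []

    rates = np.array(
        [config.rate_tp, config.rate_ci, config.rate_cp, config.rate_cd]
    ) / 60.0
    total_rate = rates.sum()
    init_codes = ["TP", "CI", "CP", "CD"]
    resp_map = {"TP": "CA", "CI": "TI", "CP": "TA", "CD": "TR"}
    succ_prob = {
        "TP": config.p_accept,
        "CI": config.p_recognize,
        "CP": config.p_share,
        "CD": config.p_tr,
    }
    lat_mu, lat_sigma = _lognormal_params(*config.latency_response)
    dur_mu, dur_sigma = _lognormal_params(*config.sa_duration)

    def resp_latency() -> float:
        return float(rng.lognormal(lat_mu, lat_sigma))

    t = 0.0
    while t < W and total_rate > 0:
        gap = float(rng.exponential(1.0 / total_rate))
        t_init = t + gap
        if t_init >= W:
            break
        code = init_codes[int(rng.choice(4, p=rates / total_rate))]
        events.append(AnnotatedEvent(t_init, code))
        t = t_init
        u = rng.random()
        answered = False
        if code == "TP":
            if u < config.p_accept:
                answered = True
            elif u < config.p_accept + config.p_refuse:
                rt = t_init + resp_latency()
                if rt < W:
                    events.append(AnnotatedEvent(rt, "CR"))
                    t = rt
                continue
            else:
                continue
        else:
            answered = u < succ_prob[code]
            if not answered:
                continue
        rt = t_init + resp_latency()
        if rt >= W:
            break
        events.append(AnnotatedEvent(rt, resp_map[code]))
        t = rt
        if code == "CD":
            continue
        # successful interaction unit: maybe launch a shared activity
        if rng.random() >= config.p_sa_after_iu:
            continue
        sa_start = t + float(rng.exponential(config.latency_sa_mean))
        if sa_start >= W:
            break
        duration = float(rng.lognormal(dur_mu, dur_sigma))
        sa_end = sa_start + duration
        truncated = sa_end > W
        sa_end = min(sa_end, W)
        events.append(AnnotatedEvent(sa_start, "SA", stop_s=sa_end))
        # interior widenings
        tw_rate = config.rate_tw_in_sa / 60.0
        tt = sa_start
        while tw_rate > 0:
            tt = tt + float(rng.exponential(1.0 / tw_rate))
            if tt >= sa_end:
                break
            events.append(AnnotatedEvent(tt, "TW"))
            if rng.random() < config.p_tw_accept:
                rt2 = tt + resp_latency()
                if rt2 < sa_end:
                    events.append(AnnotatedEvent(rt2, "CA"))
                    tt = rt2
        # engagement annotation at mid-span
        level = 1 + int(rng.choice(3, p=np.asarray(config.eng_probs)))
        events.append(
            AnnotatedEvent((sa_start + sa_end) / 2.0, "ENG", modifier=level)
        )
        if not truncated:
            term = ["CX", "CE", "TE"][
                int(rng.choice(3, p=np.asarray(config.termination_probs)))
            ]
            events.append(AnnotatedEvent(sa_end, term))
        t = sa_end

    return SessionRecord(
        session_id=session_id,
        events=events,
        dyad_id=dyad_id,
        timepoint=timepoint,
        window_len_s=W,
    )


def expected_code_mix(config: SimulationConfig) -> dict[str, float]:
    """Analytic per-cycle expected event counts implied by the clocks and
    response probabilities, and the implied pooled P_CA.

    Exact for the event-type mixture when ``p_tw_accept == 0`` (interior
    widenings are then a Poisson process over the activity duration); with
    accepted widenings the interior count uses a renewal approximation.
    Window truncation is ignored, so expectations describe the long-window
    limit.
    """
    c = config
    w = np.array([c.rate_tp, c.rate_ci, c.rate_cp, c.rate_cd], dtype=float)
    if w.sum() == 0:
        return {"P_CA": float("nan"), "events_per_cycle": 0.0}
    w = w / w.sum()
    w_tp, w_ci, w_cp, w_cd = w
    resp = (
        w_tp * (c.p_accept + c.p_refuse)
        + w_ci * c.p_recognize
        + w_cp * c.p_share
        + w_cd * c.p_tr
    )
    p_sa = (
        w_tp * c.p_accept + w_ci * c.p_recognize + w_cp * c.p_share
    ) * c.p_sa_after_iu
    mean_d = c.sa_duration[0]
    lam_tw = c.rate_tw_in_sa / 60.0
    if c.p_tw_accept == 0:
        n_tw = lam_tw * mean_d
    else:  # renewal approximation: each accepted widening consumes a latency
        cycle = 1.0 / lam_tw + c.p_tw_accept * c.latency_response[0] if lam_tw > 0 else math.inf
        n_tw = mean_d / cycle if lam_tw > 0 else 0.0
    n_ca_sa = n_tw * c.p_tw_accept
    per_sa = 2.0 + n_tw + n_ca_sa  # SA event + terminator + interior
    e_ca = w_tp * c.p_accept + p_sa * n_ca_sa
    e_n = 1.0 + resp + p_sa * per_sa
    return {
        "P_CA": e_ca / e_n,
        "events_per_cycle": e_n,
        "sa_per_cycle": p_sa,
        "tw_per_sa": n_tw,
    }


@dataclass(frozen=True)
class OutcomeModel:
    """Linear map from a dyad's true generator parameters to outcomes.

    ``terms`` maps an outcome column to (intercept, {param: coef},
    noise_sd); parameters refer to scalar fields of the dyad's T0 config.
    """

    terms: dict[str, tuple[float, dict[str, float], float]] = field(
        default_factory=lambda: {
            "rMC": (0.18, {"p_accept": 0.55, "p_tw_accept": 0.35}, 0.10),
            "LR": (-0.10, {"p_accept": 0.90, "p_sa_after_iu": 0.60}, 0.18),
            "ados_sa": (19.5, {"p_accept": -8.0, "p_tw_accept": -3.5}, 1.8),
        }
    )

    def draw(self, config: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name, (b0, coefs, sd) in self.terms.items():
            mu = b0 + sum(b * getattr(config, p) for p, b in coefs.items())
            out[name] = float(mu + rng.normal(0.0, sd))
        return out


@dataclass(frozen=True)
class CohortConfig:
    n_dyads: int = 24
    t0_config: SimulationConfig = field(default_factory=SimulationConfig)
    t1_shift: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_T1_SHIFT))
    param_jitter: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_JITTER)
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)


@dataclass
class CohortResult:
    sessions: list[SessionRecord]          # 2 per dyad (T0 then T1)
    outcomes: pd.DataFrame                 # child/timepoint outcome table
    truth: dict[str, dict[str, Any]]       # per-dyad true parameters


def simulate_cohort(
    cohort: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> CohortResult:
    """Simulate paired T0/T1 sessions plus an outcome table for a cohort.

    Each dyad draws a persistent parameter offset (its interaction style),
    shared by both timepoints; the T1 condition additionally applies the
    cohort's parameter shift.  Outcomes are generated by the cohort's
    linear outcome model from the dyad's true T0 parameters.
    """
    rng = np.random.default_rng(seed)
    apply_shift(cohort.t0_config, cohort.t1_shift)  # fail fast on a bad shift
    sessions: list[SessionRecord] = []
    truth: dict[str, dict[str, Any]] = {}
    outcome_rows = []
    for d in range(cohort.n_dyads):
        dyad = f"dyad{d:03d}"
        offsets = _clipped_jitter(
            cohort.t0_config, cohort.param_jitter, rng, shift=cohort.t1_shift
        )
        cfg0 = apply_shift(cohort.t0_config, offsets)
        cfg1 = apply_shift(cfg0, cohort.t1_shift)
        truth[dyad] = {"offsets": offsets, "t0": cfg0, "t1": cfg1}
        for tp, cfg in (("T0", cfg0), ("T1", cfg1)):
            sessions.append(
                simulate_session(
                    cfg, rng, session_id=f"{dyad}_{tp}", dyad_id=dyad,
                    timepoint=tp,
                )
            )
        draws = cohort.outcome_model.draw(cfg0, rng)
        for tp in ("T0", "T1"):
            outcome_rows.append({"child_id": dyad, "timepoint": tp, **draws})
    return CohortResult(sessions, pd.DataFrame(outcome_rows), truth)
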