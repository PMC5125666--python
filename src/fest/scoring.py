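"""Scoring of FEST responses.

A FEST-S trial presents one five-sound sequence; the listener rates its
contextual coherence on a 0–1 slider, then picks the five sound names
from the closed 25-label set and arranges them in presentation order.
Three nested metrics score the same response with increasing stringency:

* **LC** (labels correct) — a slot is correct if its label occurs
  anywhere in the sequence, regardless of position;
* **OC** (order correct) — a slot is correct only if the right label
  sits at the right serial position;
* **SC** (sequence correct) — a per-trial binary: all five labels in the
  correct order.

Per listener and coherence condition there are 25 scored LC/OC responses
(five sounds × five sequences) and 5 SC trials, so SC% ≤ OC% ≤ LC%
always holds.  Proportions destined for ANOVA/regression are
variance-stabilised with an arcsine transform; response times are
log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .battery import Battery, SequenceSpec

__all__ = [
    "TrialResponse",
    "SessionResult",
    "TrialScore",
    "ScoreReport",
    "GROUPS",
    "score_trial",
    "score_session",
    "score_identification",
    "arcsine_transform",
    "serial_position_profile",
    "summarize_ratings",
    "log_rt",
    "session_scores_frame",
]

GROUPS = ("YNH", "MON", "MOI", "CIV", "CI", "other")
CONDITIONS = ("coherent", "incoherent")


@dataclass(frozen=True)
class TrialResponse:
    """One rated + ordered-identification response to a sequence."""

    sequence_name: str
    rating: float
    chosen: tuple[str, ...]
    rating_time: float = 0.0
    identification_time: float = 0.0

    def __post_init__(self):
        if len(self.chosen) != 5:
            raise ValueError(f"{self.sequence_name}: expected 5 chosen labels, got {len(self.chosen)}")
        if not 0.0 <= self.rating <= 1.0:
            raise ValueError(f"{self.sequence_name}: rating {self.rating} outside [0, 1]")
        if self.rating_time < 0 or self.identification_time < 0:
            raise ValueError(f"{self.sequence_name}: negative response time")


@dataclass
class SessionResult:
    """All ten trials of one listener, plus optional covariates."""

    listener_id: str
    group: str
    trials: list[TrialResponse]
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group {self.group!r} not one of {GROUPS}")

    def trial(self, sequence_name: str) -> TrialResponse:
        for t in self.trials:
            if t.sequence_name == sequence_name:
                return t
        raise KeyError(f"no trial for sequence {sequence_name!r}")


@dataclass(frozen=True)
class TrialScore:
    lc_count: int
    oc_count: int
    sc: int
    position_correct: tuple[bool, ...]  # OC basis, positions 1..5


@dataclass
class ScoreReport:
    """Per-condition percentages and transforms for one session."""

    listener_id: str
    group: str
    lc_pct: dict[str, float]
    oc_pct: dict[str, float]
    sc_pct: dict[str, float]
    lc_asin: dict[str, float]
    oc_asin: dict[str, float]
    sc_asin: dict[str, float]
    serial_position: dict[str, tuple[float, ...]]  # condition -> 5 accuracies
    mean_rating: dict[str, float]
    mean_log_rating_time: dict[str, float]
    mean_log_identification_time: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "listener_id": self.listener_id,
            "group": self.group,
            "lc_pct": self.lc_pct,
            "oc_pct": self.oc_pct,
            "sc_pct": self.sc_pct,
            "lc_asin": self.lc_asin,
            "oc_asin": self.oc_asin,
            "sc_asin": self.sc_asin,
            "serial_position": {k: list(v) for k, v in self.serial_position.items()},
            "mean_rating": self.mean_rating,
            "mean_log_rating_time": self.mean_log_rating_time,
            "mean_log_identification_time": self.mean_log_identification_time,
        }


def _check_chosen(chosen: Sequence[str], labels: Iterable[str], allow_duplicates: bool) -> None:
    unknown = [c for c in chosen if c not in set(labels)]
    if unknown:
        raise ValueError(f"chosen labels outside the closed set: {unknown}")
    if not allow_duplicates and len(set(chosen)) != len(chosen):
        raise ValueError(f"duplicate chosen labels: {list(chosen)}")


def score_trial(
    response: TrialResponse,
    truth: SequenceSpec,
    *,
    battery: Battery | None = None,
    allow_duplicates: bool = False,
) -> TrialScore:
    """Score one trial against its sequence.

    LC counts slots whose label belongs to the sequence (set membership,
    scored slot-by-slot so duplicates in lenient mode each count); OC
    counts exact positional matches; SC is 1 iff all five are positional
    matches.
    """
    if response.sequence_name != truth.name:
        raise ValueError(
            f"response is for {response.sequence_name!r}, truth is {truth.name!r}"
        )
    if battery is not None:
        _check_chosen(response.chosen, battery.labels, allow_duplicates)
    elif not allow_duplicates and len(set(response.chosen)) != 5:
        raise ValueError(f"duplicate chosen labels: {list(response.chosen)}")
    truth_set = set(truth.labels)
    lc = sum(1 for c in response.chosen if c in truth_set)
    pos = tuple(c == t for c, t in zip(response.chosen, truth.labels))
    oc = sum(pos)
    return TrialScore(lc_count=lc, oc_count=oc, sc=int(oc == 5), position_correct=pos)


def score_session(
    session: SessionResult,
    battery: Battery,
    *,
    allow_partial: bool = False,
    allow_duplicates: bool = False,
    arcsine_variant: str = "asin_sqrt",
) -> ScoreReport:
    """Score a full ten-trial session into per-condition percentages.

    LC/OC percentages are over 25 scored responses per condition (five
    sounds × five sequences); SC is over the 5 trials.  Missing trials
    raise unless ``allow_partial``, in which case absent sequences score
    zero in every slot.
    """
    have = {t.sequence_name for t in session.trials}
    missing = [q.name for q in battery.sequences if q.name not in have]
    if missing and not allow_partial:
        raise ValueError(f"session {session.listener_id!r} missing trials for: {missing}")

    lc_pct: dict[str, float] = {}
    oc_pct: dict[str, float] = {}
    sc_pct: dict[str, float] = {}
    serial: dict[str, tuple[float, ...]] = {}
    mean_rating: dict[str, float] = {}
    mean_lrt: dict[str, float] = {}
    mean_lit: dict[str, float] = {}

    for condition in CONDITIONS:
        seqs = battery.sequences_by_coherence(condition)
        lc = oc = sc = 0
        pos_hits = np.zeros(5)
        ratings, rts, its = [], [], []
        for q in seqs:
            if q.name in have:
                t = session.trial(q.name)
                s = score_trial(t, q, battery=battery, allow_duplicates=allow_duplicates)
                lc += s.lc_count
                oc += s.oc_count
                sc += s.sc
                pos_hits += np.array(s.position_correct, dtype=float)
                ratings.append(t.rating)
                if t.rating_time > 0:
                    rts.append(np.log(t.rating_time))
                if t.identification_time > 0:
                    its.append(np.log(t.identification_time))
        lc_pct[condition] = 100.0 * lc / 25.0
        oc_pct[condition] = 100.0 * oc / 25.0
        sc_pct[condition] = 100.0 * sc / 5.0
        serial[condition] = tuple(pos_hits / 5.0)
        mean_rating[condition] = float(np.mean(ratings)) if ratings else float("nan")
        mean_lrt[condition] = float(np.mean(rts)) if rts else float("nan")
        mean_lit[condition] = float(np.mean(its)) if its else float("nan")

    def asin(d: dict[str, float]) -> dict[str, float]:
        return {k: arcsine_transform(v / 100.0, variant=arcsine_variant) for k, v in d.items()}

    return ScoreReport(
        listener_id=session.listener_id,
        group=session.group,
        lc_pct=lc_pct,
        oc_pct=oc_pct,
        sc_pct=sc_pct,
        lc_asin=asin(lc_pct),
        oc_asin=asin(oc_pct),
        sc_asin=asin(sc_pct),
        serial_position=serial,
        mean_rating=mean_rating,
        mean_log_rating_time=mean_lrt,
        mean_log_identification_time=mean_lit,
    )


def score_identification(
    responses: Iterable[tuple[str, str]], *, labels: Iterable[str] | None = None
) -> float:
    """Percent correct for single-sound closed-set identification (FEST-I)."""
    responses = list(responses)
    if not responses:
        raise ValueError("no responses to score")
    if labels is not None:
        closed = set(labels)
        bad = [(t, c) for t, c in responses if t not in closed or c not in closed]
        if bad:
            raise ValueError(f"labels outside the closed set: {bad}")
    return 100.0 * sum(1 for t, c in responses if t == c) / len(responses)


def arcsine_transform(p: float, *, variant: str = "asin_sqrt") -> float:
    """Variance-stabilising arcsine transform of a proportion.

    ``asin_sqrt`` returns arcsin(√p) in radians; ``two_asin_sqrt``
    returns 2·arcsin(√p).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    val = float(np.arcsin(np.sqrt(p)))
    if variant == "asin_sqrt":
        return val
    if variant == "two_asin_sqrt":
        return 2.0 * val
    raise ValueError(f"unknown variant {variant!r}")


def serial_position_profile(
    sessions: Iterable[SessionResult],
    battery: Battery,
    *,
    basis: str = "oc",
) -> dict[str, pd.DataFrame]:
    """Mean per-position accuracy by group and coherence condition.

    Returns ``{group: DataFrame}`` with rows ``coherent``/``incoherent``
    and columns position 1–5.  The canonical basis is OC (correct label
    at the correct position); an LC basis (label credited wherever it
    appears) is available but non-canonical.
    """
    if basis not in ("oc", "lc"):
        raise ValueError("basis must be 'oc' or 'lc'")
    acc: dict[str, dict[str, list[np.ndarray]]] = {}
    for session in sessions:
        per_cond: dict[str, np.ndarray] = {}
        for condition in CONDITIONS:
            hits = np.zeros(5)
            seqs = battery.sequences_by_coherence(condition)
            for q in seqs:
                t = session.trial(q.name)
                if basis == "oc":
                    s = score_trial(t, q, battery=battery)
                    hits += np.array(s.position_correct, dtype=float)
                else:
                    truth_set = set(q.labels)
                    hits += np.array([c in truth_set for c in t.chosen], dtype=float)
            per_cond[condition] = hits / len(seqs)
        acc.setdefault(session.group, {c: [] for c in CONDITIONS})
        for condition in CONDITIONS:
            acc[session.group][condition].append(per_cond[condition])
    out: dict[str, pd.DataFrame] = {}
    for group, byc in acc.items():
        out[group] = pd.DataFrame(
            {c: np.mean(byc[c], axis=0) for c in CONDITIONS},
            index=pd.Index([1, 2, 3, 4, 5], name="position"),
        ).T
    return out


def summarize_ratings(sessions: Iterable[SessionResult], battery: Battery) -> pd.DataFrame:
    """Group means and standard errors of coherence ratings per condition.

    Layout: rows (condition, statistic), one column per group — the
    standard summary table for sequence-plausibility ratings.
    """
    rows = []
    for session in sessions:
        for condition in CONDITIONS:
            vals = [
                session.trial(q.name).rating
                for q in battery.sequences_by_coherence(condition)
                if q.name in {t.sequence_name for t in session.trials}
            ]
            rows.append(
                {"group": session.group, "condition": condition, "rating": float(np.mean(vals))}
            )
    df = pd.DataFrame(rows)
    out = df.groupby(["condition", "group"])["rating"].agg(
        mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    )
    return out.unstack("group")


def log_rt(times: np.ndarray | Sequence[float]) -> np.ndarray:
    """Natural-log transform of response times (seconds, strictly positive)."""
    arr = np.asarray(times, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("response times must be positive for the log transform")
    return np.log(arr)


def session_scores_frame(
    sessions: Iterable[SessionResult], battery: Battery, **kwargs
) -> pd.DataFrame:
    """Long-format score table: one row per listener × condition.

    Columns: listener_id, group, condition, lc_pct, oc_pct, sc_pct, the
    arcsine-transformed equivalents, mean rating and mean log times.
    This is the input layout for the mixed ANOVA and regression stages.
    """
    rows = []
    for session in sessions:
        rep = score_session(session, battery, **kwargs)
        for condition in CONDITIONS:
            rows.append(
                {
                    "listener_id": rep.listener_id,
                    "group": rep.group,
                    "condition": condition,
                    "lc_pct": rep.lc_pct[condition],
                    "oc_pct": rep.oc_pct[condition],
                    "sc_pct": rep.sc_pct[condition],
                    "lc_asin": rep.lc_asin[condition],
                    "oc_asin": rep.oc_asin[condition],
                    "sc_asin": rep.sc_asin[condition],
                    "mean_rating": rep.mean_rating[condition],
                    "mean_log_rating_time": rep.mean_log_rating_time[condition],
                    "mean_log_identification_time": rep.mean_log_identification_time[condition],
                }
            )
    return pd.DataFrame(rows)
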