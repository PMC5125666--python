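"""Session/covariate file formats and deterministic report serialization.

Session CSV schema (one row per trial):

    listener_id, group, sequence_name, rating,
    chosen_1..chosen_5, rating_time_s, identification_time_s

Covariates live in a separate CSV keyed by ``listener_id``.  All report
output is deterministic — sorted keys, fixed decimal places — so runs
can be compared byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .battery import Battery
from .scoring import GROUPS, ScoreReport, SessionResult, TrialResponse

__all__ = [
    "SessionFormatError",
    "read_sessions",
    "write_sessions",
    "read_covariates",
    "write_covariates",
    "write_report",
]

_SESSION_COLUMNS = [
    "listener_id",
    "group",
    "sequence_name",
    "rating",
    "chosen_1",
    "chosen_2",
    "chosen_3",
    "chosen_4",
    "chosen_5",
    "rating_time_s",
    "identification_time_s",
]


class SessionFormatError(ValueError):
    """A session file violates the documented schema; lists every bad row."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid session file:\n  " + "\n  ".join(self.problems))


def read_sessions(path: str | Path, battery: Battery | None = None) -> list[SessionResult]:
    """Read a session CSV into validated :class:`SessionResult` objects.

    Errors are collected across the whole file and reported with 1-based
    data row numbers.  If a battery is given, chosen labels and sequence
    names are checked against it.
    """
    df = pd.read_csv(path, dtype={"listener_id": str})
    missing = [c for c in _SESSION_COLUMNS if c not in df.columns]
    extra_chosen = [c for c in df.columns if c.startswith("chosen_") and c not in _SESSION_COLUMNS]
    problems = []
    if missing:
        problems.append(f"missing columns: {missing}")
    if extra_chosen:
        problems.append(f"unexpected chosen columns (exactly 5 labels per trial): {extra_chosen}")
    if problems:
        raise SessionFormatError(problems)

    labels = set(battery.labels) if battery is not None else None
    seq_names = {q.name for q in battery.sequences} if battery is not None else None

    sessions: dict[str, SessionResult] = {}
    for i, row in df.iterrows():
        rowno = int(i) + 1
        chosen = tuple(str(row[f"chosen_{j}"]) for j in range(1, 6))
        if not 0.0 <= float(row["rating"]) <= 1.0:
            problems.append(f"row {rowno}: rating {row['rating']} outside [0, 1]")
            continue
        if labels is not None:
            bad = [c for c in chosen if c not in labels]
            if bad:
                problems.append(f"row {rowno}: unknown labels {bad}")
                continue
        if seq_names is not None and row["sequence_name"] not in seq_names:
            problems.append(f"row {rowno}: unknown sequence {row['sequence_name']!r}")
            continue
        if row["group"] not in GROUPS:
            problems.append(f"row {rowno}: unknown group {row['group']!r}")
            continue
        try:
            trial = TrialResponse(
                sequence_name=str(row["sequence_name"]),
                rating=float(row["rating"]),
                chosen=chosen,
                rating_time=float(row["rating_time_s"]),
                identification_time=float(row["identification_time_s"]),
            )
        except ValueError as e:
            problems.append(f"row {rowno}: {e}")
            continue
        lid = str(row["listener_id"])
        if lid not in sessions:
            sessions[lid] = SessionResult(listener_id=lid, group=str(row["group"]), trials=[])
        sessions[lid].trials.append(trial)

    if problems:
        raise SessionFormatError(problems)
    return list(sessions.values())


def write_sessions(sessions: Iterable[SessionResult], path: str | Path) -> None:
    """Write sessions to the canonical CSV layout (deterministic order)."""
    rows = []
    for s in sorted(sessions, key=lambda s: s.listener_id):
        for t in s.trials:
            rows.append(
                {
                    "listener_id": s.listener_id,
                    "group": s.group,
                    "sequence_name": t.sequence_name,
                    "rating": round(t.rating, 6),
                    **{f"chosen_{j + 1}": t.chosen[j] for j in range(5)},
                    "rating_time_s": round(t.rating_time, 6),
                    "identification_time_s": round(t.identification_time, 6),
                }
            )
    pd.DataFrame(rows, columns=_SESSION_COLUMNS).to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate table keyed by listener_id."""
    df = pd.read_csv(path, dtype={"listener_id": str})
    if "listener_id" not in df.columns:
        raise SessionFormatError(["covariate file missing 'listener_id' column"])
    return df.set_index("listener_id")


def write_covariates(sessions: Iterable[SessionResult], path: str | Path) -> None:
    rows = [
        {"listener_id": s.listener_id, **{k: round(v, 6) for k, v in sorted(s.covariates.items())}}
        for s in sorted(sessions, key=lambda s: s.listener_id)
        if s.covariates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _round_floats(obj, places: int):
    if isinstance(obj, float):
        return round(obj, places)
    if isinstance(obj, dict):
        return {k: _round_floats(v, places) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, places) for v in obj]
    return obj


def write_report(
    report: ScoreReport | dict | list,
    path: str | Path,
    fmt: str = "json",
    *,
    decimals: int = 4,
) -> None:
    """Serialize a score report deterministically.

    ``json`` writes sorted keys with floats rounded to ``decimals``;
    ``csv`` flattens per-condition metrics to columns; ``text`` prints a
    small human-readable table of the three metrics × two conditions.
    """
    path = Path(path)
    data = report.as_dict() if isinstance(report, ScoreReport) else report
    data = _round_floats(data, decimals)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        reports = data if isinstance(data, list) else [data]
        rows = []
        for d in reports:
            row = {"listener_id": d["listener_id"], "group": d["group"]}
            for metric in ("lc_pct", "oc_pct", "sc_pct", "lc_asin", "oc_asin", "sc_asin"):
                for cond in ("coherent", "incoherent"):
                    row[f"{metric}_{cond}"] = d[metric][cond]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, float_format=f"%.{decimals}f")
    elif fmt == "text":
        reports = data if isinstance(data, list) else [data]
        lines = []
        for d in reports:
            lines.append(f"listener {d['listener_id']} ({d['group']})")
            lines.append(f"  {'metric':<6} {'coherent':>10} {'incoherent':>11}")
            for metric, key in (("LC", "lc_pct"), ("OC", "oc_pct"), ("SC", "sc_pct")):
                lines.append(
                    f"  {metric:<6} {d[key]['coherent']:>9.1f}% {d[key]['incoherent']:>10.1f}%"
                )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (json|csv|text)")
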