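"""Domain types and file I/O for team chat logs, score tables and team features.

The data model mirrors a common experimental design in small-group research:
teams of ≥2 members complete an ordered battery of tasks while communicating
over text chat.  Three kinds of records exist per team: a timestamped chat log,
a row of task scores (rescaled to [0, 1]), and a row of compositional baseline
features (gender share, Big-5 averages, social perceptiveness, communication
amount/distribution).  Everything is plain CSV/TSV on disk.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Message",
    "ChatLog",
    "ScoreTable",
    "BaselineFeatures",
    "ResponseAnnotation",
    "ChatLogParseError",
    "parse_timestamp",
    "read_chat_log",
    "write_chat_log",
    "read_score_table",
    "write_score_table",
    "normalize_scores",
    "read_annotations",
    "write_annotations",
    "BASELINE_FEATURE_NAMES",
]

BASELINE_FEATURE_NAMES = (
    "proportion_female",
    "big5_openness",
    "big5_conscientiousness",
    "big5_extraversion",
    "big5_agreeableness",
    "big5_neuroticism",
    "social_perceptiveness",
    "communication_amount",
    "communication_distribution",
)


class ChatLogParseError(ValueError):
    """Raised when a chat-log file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Message:
    """A single chat message: sender alias, time in seconds, text, sentiment.

    ``sentiment``, when present, is a real in [-1, 1] (negative to positive);
    ``None`` means the message carries no sentiment annotation.
    """

    sender: str
    time: float
    text: str = ""
    sentiment: float | None = None

    def __post_init__(self) -> None:
        if not self.sender:
            raise ValueError("message sender must be non-empty")
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"message time must be finite and >= 0, got {self.time}")
        if self.sentiment is not None and not -1.0 <= self.sentiment <= 1.0:
            raise ValueError(f"sentiment must lie in [-1, 1], got {self.sentiment}")


@dataclass(frozen=True)
class ChatLog:
    """An ordered chat transcript for one team.

    Messages are stored sorted by time (ties allowed); every sender belongs to
    ``members``, which may include silent members.
    """

    team_id: str
    members: frozenset[str]
    messages: tuple[Message, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a team needs at least 2 members")
        times = [m.time for m in self.messages]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("messages must be non-decreasing in time")
        senders = {m.sender for m in self.messages}
        if not senders <= self.members:
            raise ValueError(f"unknown senders: {sorted(senders - self.members)}")

    @classmethod
    def from_messages(
        cls,
        team_id: str,
        messages: Iterable[Message],
        members: Iterable[str] | None = None,
    ) -> "ChatLog":
        msgs = tuple(sorted(messages, key=lambda m: m.time))
        if members is None:
            members = {m.sender for m in msgs}
        return cls(team_id=team_id, members=frozenset(members), messages=msgs)

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)


@dataclass
class ScoreTable:
    """Teams × tasks matrix of scores in [0, 1] (NaN = missing).

    Task order is the battery order and is identical for every team.
    """

    team_ids: list[str]
    task_ids: list[str]
    scores: np.ndarray  # shape (n_teams, n_tasks), float, NaN for missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.team_ids), len(self.task_ids)):
            raise ValueError("score matrix shape does not match team/task ids")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("scores must lie in [0, 1] (or be missing)")

    @property
    def n_teams(self) -> int:
        return len(self.team_ids)

    @property
    def n_tasks(self) -> int:
        return len(self.task_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.team_ids, columns=self.task_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScoreTable":
        return cls(
            team_ids=[str(i) for i in frame.index],
            task_ids=[str(c) for c in frame.columns],
            scores=frame.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return (
            self.team_ids == other.team_ids
            and self.task_ids == other.task_ids
            and np.array_equal(self.scores, other.scores, equal_nan=True)
        )


@dataclass
class BaselineFeatures:
    """Per-team compositional and gross-communication features.

    Columns: proportion of female members, five Big-5 trait averages, social
    perceptiveness (e.g. Reading-the-Mind-in-the-Eyes score average), total
    communication amount, and the communication distribution (the standard
    deviation of per-member communication amounts).
    """

    table: pd.DataFrame  # index: team ids, columns: BASELINE_FEATURE_NAMES

    def __post_init__(self) -> None:
        missing = set(BASELINE_FEATURE_NAMES) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing baseline feature columns: {sorted(missing)}")
        pf = self.table["proportion_female"].dropna()
        if ((pf < 0) | (pf > 1)).any():
            raise ValueError("proportion_female must lie in [0, 1]")
        cd = self.table["communication_distribution"].dropna()
        if (cd < 0).any():
            raise ValueError("communication_distribution must be >= 0")

    @property
    def team_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]


@dataclass(frozen=True)
class ResponseAnnotation:
    """A labelled ordered message pair from one chat log.

    Indices refer to positions in ``ChatLog.messages``; ``is_response`` is the
    (human or generator) ground truth of whether the candidate message answers
    the antecedent.
    """

    antecedent: int
    candidate: int
    is_response: bool

    def __post_init__(self) -> None:
        if self.antecedent < 0 or self.candidate < 0:
            raise ValueError("annotation indices must be non-negative")


_TS_RE = re.compile(r"^(\d+):([0-5]?\d)(?::([0-5]?\d))?$")


def parse_timestamp(value: str | float | int) -> float:
    """Parse a chat timestamp into seconds from session start.

    Accepted forms: raw seconds (number or numeric string), ``MM:SS`` and
    ``HH:MM:SS``.  In ``MM:SS`` the minute field may exceed 59 — chat
    platforms often print a running minute counter for sessions about an hour
    long — so ``"75:10"`` parses to 4510 s.
    """
    if isinstance(value, (int, float)):
        out = float(value)
        if not math.isfinite(out) or out < 0:
            raise ValueError(f"timestamp must be finite and >= 0, got {value!r}")
        return out
    text = value.strip()
    m = _TS_RE.match(text)
    if m:
        a, b, c = m.group(1), m.group(2), m.group(3)
        if c is None:  # MM:SS, minutes unbounded
            return 60.0 * int(a) + int(b)
        if int(b) > 59:
            raise ValueError(f"minutes out of range in {value!r}")
        return 3600.0 * int(a) + 60.0 * int(b) + int(c)
    try:
        return parse_timestamp(float(text))
    except (TypeError, ValueError):
        raise ValueError(f"malformed timestamp {value!r}") from None


def _sniff_delimiter(sample: str, default: str = ",") -> str:
    # comma vs tab only; honest CSVs with quoted commas still win on count
    counts = {d: sample.count(d) for d in (",", "\t")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else default


def read_chat_log(
    path,
    *,
    team_id: str | None = None,
    members: Iterable[str] | None = None,
    delimiter: str | None = None,
) -> ChatLog:
    """Read a chat log from a delimited text file.

    Required columns: ``time``, ``sender``, ``message``; ``sentiment`` is
    optional (empty cells mean missing).  Timestamps may be raw seconds,
    ``MM:SS`` or ``HH:MM:SS``.  The returned log is sorted by time even when
    rows are out of order in the file.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        content = fh.read()
    if not content.strip():
        raise ChatLogParseError(f"chat log file {path} is empty")
    delim = delimiter or _sniff_delimiter(content.splitlines()[0])
    reader = csv.DictReader(_io.StringIO(content), delimiter=delim)
    required = {"time", "sender", "message"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ChatLogParseError(
            f"chat log {path} must have columns time, sender, message "
            f"(got {reader.fieldnames})"
        )
    messages = []
    for lineno, row in enumerate(reader, start=2):
        try:
            t = parse_timestamp(row["time"])
        except ValueError as exc:
            raise ChatLogParseError(f"{path}, line {lineno}: {exc}") from exc
        raw_sent = (row.get("sentiment") or "").strip()
        sentiment = float(raw_sent) if raw_sent else None
        messages.append(
            Message(
                sender=row["sender"].strip(),
                time=t,
                text=row["message"],
                sentiment=sentiment,
            )
        )
    if not messages:
        raise ChatLogParseError(f"chat log {path} contains no messages")
    tid = team_id if team_id is not None else str(path)
    return ChatLog.from_messages(tid, messages, members=members)


def write_chat_log(log: ChatLog, path, *, delimiter: str = ",") -> None:
    """Write a chat log as delimited text with raw-second timestamps."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["time", "sender", "message", "sentiment"])
        for m in log.messages:
            writer.writerow(
                [
                    repr(m.time) if m.time != int(m.time) else int(m.time),
                    m.sender,
                    m.text,
                    "" if m.sentiment is None else repr(m.sentiment),
                ]
            )


def read_score_table(path) -> ScoreTable:
    """Read a teams × tasks score table (first column = team id)."""
    frame = pd.read_csv(path, index_col=0, sep=None, engine="python")
    return ScoreTable.from_frame(frame)


def write_score_table(table: ScoreTable, path) -> None:
    table.to_frame().to_csv(path, index_label="team_id")


def normalize_scores(
    raw_scores: pd.DataFrame,
    per_task_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> ScoreTable:
    """Linearly rescale raw task scores to [0, 1] per task.

    Each task has its own scale; ``x -> (x - min) / (max - min)`` maps the
    scale endpoints to 0 and 1 and preserves order within a task.  When
    ``per_task_ranges`` omits a task, the observed min/max across teams is
    used (and logged), since a theoretical range is not always known.
    """
    per_task_ranges = dict(per_task_ranges or {})
    out = raw_scores.astype(float).copy()
    for task in out.columns:
        col = out[task]
        if str(task) in per_task_ranges:
            lo, hi = per_task_ranges[str(task)]
        else:
            lo, hi = float(col.min()), float(col.max())
            logger.info("task %s: using observed score range [%g, %g]", task, lo, hi)
        if not hi > lo:
            raise ValueError(f"degenerate score range for task {task}: [{lo}, {hi}]")
        scaled = (col - lo) / (hi - lo)
        valid = scaled.dropna()
        if valid.size and ((valid < -1e-12) | (valid > 1 + 1e-12)).any():
            raise ValueError(f"task {task}: raw scores fall outside range [{lo}, {hi}]")
        out[task] = scaled.clip(0.0, 1.0)
    return ScoreTable.from_frame(out)


def read_annotations(path) -> list[ResponseAnnotation]:
    """Read response annotations: CSV with antecedent_index, candidate_index, label."""
    frame = pd.read_csv(path)
    truthy = {"true-response", "response", "1", "true", "yes"}
    out = []
    for _, row in frame.iterrows():
        out.append(
            ResponseAnnotation(
                antecedent=int(row["antecedent_index"]),
                candidate=int(row["candidate_index"]),
                is_response=str(row["label"]).strip().lower() in truthy,
            )
        )
    return out


def write_annotations(annotations: Sequence[ResponseAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["antecedent_index", "candidate_index", "label"])
        for a in annotations:
            writer.writerow(
                [a.antecedent, a.candidate, "true-response" if a.is_response else "non-response"]
            )
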