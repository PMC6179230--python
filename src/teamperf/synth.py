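"""Synthetic team data with the statistical structure the pipeline assumes.

The generator emulates all four study inputs so every stage is testable
end-to-end without the original data:

* **score tables** — each team has a latent quality q_i in [0, 1]; its score
  on task t is clip(q_i + slope_i (t-1) + noise, 0, 1) with the slope
  negatively coupled to quality (weak teams start low and improve, strong
  teams start high and stay flat);
* **chat logs** — a reply process with a planted member-affinity matrix A:
  base messages arrive one after another with exponential extra gaps, and
  after a base message by member i at most one other member replies, member
  j with probability proportional to A_ij, at a lag drawn uniformly inside
  the true response window;
* **response annotations** — labelled ordered message pairs whose ground
  truth is the planted reply relation, optionally flipped with some noise;
* **baseline features** — compositional features drawn with configurable
  correlation to latent quality.

Base messages are paced at least one true response window after the last
message, so every cross-sender pair inside the window is a planted reply.
This keeps the reply relation identifiable for window calibration and
affinity recovery; real chat is burstier (see the methods note).

All generators are deterministic given an explicit seed; per-team sub-seeds
are derived from the master seed with ``numpy.random.SeedSequence`` spawn
keys, so any single team can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BASELINE_FEATURE_NAMES,
    BaselineFeatures,
    ChatLog,
    Message,
    ResponseAnnotation,
    ScoreTable,
)
from .responses import ResponseWindow

__all__ = [
    "SyntheticSpec",
    "SyntheticChatLog",
    "SyntheticDataset",
    "gen_qualities",
    "gen_score_table",
    "gen_affinity",
    "gen_chat_log",
    "gen_annotations",
    "gen_baseline_features",
    "gen_dataset",
]

_VOCAB = (
    "ok yes no sure maybe water food salt mirror compass umbrella oil rope "
    "high low next first last think agree wait done ready go team plan idea"
).split()


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror the study conditions.

    68 four-member teams, 15 tasks, roughly hour-long chat sessions.  Latent
    qualities are uniform on [quality_low, quality_high]; ``trend_coupling``
    sets how strongly a low quality translates into a positive score trend
    (slope_i = trend_coupling * (0.5 - q_i) + N(0, slope_noise_sd) per task
    step).  ``reply_prob`` scales the planted affinities into reply
    probabilities; ``mean_gap`` is the mean of the exponential extra gap (s)
    between conversation rounds beyond the enforced quiet period of one
    response window.
    """

    n_teams: int = 68
    n_tasks: int = 15
    n_members: int = 4
    quality_low: float = 0.2
    quality_high: float = 0.8
    trend_coupling: float = 0.05
    slope_noise_sd: float = 0.005
    noise_sd: float = 0.1
    session_length: float = 3600.0
    mean_gap: float = 10.0
    reply_prob: float = 0.9
    affinity_low: float = 0.05
    affinity_high: float = 0.95
    true_window: ResponseWindow = field(default_factory=lambda: ResponseWindow(1.0, 17.0))
    words_per_message: float = 6.0
    include_sentiment: bool = True
    sentiment_sd: float = 0.3
    #: target Pearson correlation of each baseline feature with latent quality
    baseline_correlations: tuple[tuple[str, float], ...] = (
        ("proportion_female", 0.35),
        ("big5_openness", 0.0),
        ("big5_conscientiousness", 0.0),
        ("big5_extraversion", -0.2),
        ("big5_agreeableness", -0.2),
        ("big5_neuroticism", 0.0),
        ("social_perceptiveness", 0.4),
        ("communication_amount", 0.3),
        ("communication_distribution", -0.3),
    )

    def __post_init__(self) -> None:
        if not 0 <= self.reply_prob <= 1:
            raise ValueError("reply_prob must lie in [0, 1]")
        if self.mean_gap <= 0 or self.session_length <= 0:
            raise ValueError("rates and durations must be > 0")


@dataclass
class SyntheticChatLog:
    """A generated log plus its ground truth.

    ``reply_pairs`` are (antecedent_index, reply_index) pairs into
    ``log.messages``; ``base_indices`` are the positions of the base
    (non-reply) messages; ``affinity`` is the planted matrix A (rows:
    antecedent sender, columns: replier).
    """

    log: ChatLog
    reply_pairs: list[tuple[int, int]]
    base_indices: list[int]
    affinity: np.ndarray
    member_names: list[str]


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, generated under one master seed."""

    spec: SyntheticSpec
    qualities: np.ndarray
    scores: ScoreTable
    baseline: BaselineFeatures
    chat_logs: list[SyntheticChatLog]
    annotations: list[list[ResponseAnnotation]]


def _rng(seed: int, *key: int) -> np.random.Generator:
    # documented sub-seed derivation: master seed + spawn key
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _team_ids(n: int) -> list[str]:
    return [f"team{i:03d}" for i in range(n)]


def gen_qualities(spec: SyntheticSpec, seed: int) -> np.ndarray:
    """Latent team qualities, uniform on [quality_low, quality_high]."""
    rng = _rng(seed, 0)
    return rng.uniform(spec.quality_low, spec.quality_high, size=spec.n_teams)


def gen_score_table(
    spec: SyntheticSpec, seed: int, qualities: np.ndarray | None = None
) -> ScoreTable:
    """Bounded score series with latent quality, coupled trend and noise."""
    if qualities is None:
        qualities = gen_qualities(spec, seed)
    rng = _rng(seed, 1)
    slopes = spec.trend_coupling * (0.5 - qualities) + rng.normal(
        0.0, spec.slope_noise_sd, size=len(qualities))
    t = np.arange(spec.n_tasks)
    raw = qualities[:, None] + slopes[:, None] * t[None, :]
    raw += rng.normal(0.0, spec.noise_sd, size=raw.shape)
    return ScoreTable(
        team_ids=_team_ids(len(qualities)),
        task_ids=[f"task{j + 1:02d}" for j in range(spec.n_tasks)],
        scores=np.clip(raw, 0.0, 1.0),
    )


def gen_affinity(spec: SyntheticSpec, seed: int) -> np.ndarray:
    """A planted member-affinity matrix with zero diagonal.

    The off-diagonal entries are a random permutation of evenly spaced
    values in [affinity_low, affinity_high], so the planted ordering is
    strict and separated — reply counts in a finite log can then actually
    recover it, which clustered random draws would not allow.
    """
    rng = _rng(seed, 2)
    k = spec.n_members
    n_off = k * (k - 1)
    values = np.linspace(spec.affinity_low, spec.affinity_high, n_off)
    rng.shuffle(values)
    A = np.zeros((k, k))
    A[~np.eye(k, dtype=bool)] = values
    return A


def gen_chat_log(
    spec: SyntheticSpec,
    seed: int,
    team_id: str = "team000",
    affinity: np.ndarray | None = None,
) -> SyntheticChatLog:
    """Generate one team's chat log as a planted reply process.

    Base message senders are uniform over members.  After a base message by
    i, at most one member replies: member j is the replier with probability
    reply_prob * A_ij / (n_members - 1), at a lag uniform in the true
    response window.  Replies never trigger further replies, and the next
    base message waits at least one window after the last message, so the
    planted reply relation is exactly the set of cross-sender pairs inside
    the window and the expected edge weight of the extracted network is
    proportional to A_ij.  A zero affinity matrix yields a reply-free log.
    """
    if affinity is None:
        affinity = gen_affinity(spec, seed)
    k = spec.n_members
    if k < 2:
        raise ValueError("need at least 2 members")
    if affinity.shape != (k, k):
        raise ValueError("affinity matrix shape does not match n_members")
    rng = _rng(seed, 3)
    members = [f"m{i}" for i in range(k)]
    w = spec.true_window

    events: list[tuple[float, int, int | None]] = []  # (time, sender, base_event_idx)
    t = float(rng.exponential(spec.mean_gap))
    last_time = t
    while t <= spec.session_length:
        sender = int(rng.integers(k))
        base_event = len(events)
        events.append((t, sender, None))
        last_time = t
        u = rng.random()
        threshold = 0.0
        for j in range(k):
            if j == sender:
                continue
            threshold += spec.reply_prob * affinity[sender, j] / (k - 1)
            if u < threshold:
                lag = float(rng.uniform(w.t1, w.t2))
                events.append((t + lag, j, base_event))
                last_time = max(last_time, t + lag)
                break
        t = last_time + w.t2 + float(rng.exponential(spec.mean_gap))

    order = sorted(range(len(events)), key=lambda e: events[e][0])
    position = {orig: pos for pos, orig in enumerate(order)}
    messages, reply_pairs, base_indices = [], [], []
    for pos, orig in enumerate(order):
        time, sender, base_event = events[orig]
        n_words = max(1, int(rng.poisson(spec.words_per_message)))
        text = " ".join(rng.choice(_VOCAB, size=n_words))
        sentiment = (
            float(np.clip(rng.normal(0.0, spec.sentiment_sd), -1.0, 1.0))
            if spec.include_sentiment else None
        )
        messages.append(Message(sender=members[sender], time=time, text=text,
                                sentiment=sentiment))
        if base_event is None:
            base_indices.append(pos)
        else:
            reply_pairs.append((position[base_event], pos))
    log = ChatLog(team_id=team_id, members=frozenset(members), messages=tuple(messages))
    return SyntheticChatLog(log=log, reply_pairs=reply_pairs,
                            base_indices=base_indices, affinity=affinity,
                            member_names=members)


def gen_annotations(
    synthetic_log: SyntheticChatLog,
    flip_noise: float = 0.0,
    seed: int = 0,
    horizon: float = 30.0,
) -> list[ResponseAnnotation]:
    """Labelled (antecedent, candidate) pairs from the planted reply relation.

    Antecedents are the base messages; candidates are all strictly later
    messages within ``horizon`` seconds.  Labels equal the generating reply
    relation, each flipped independently with probability ``flip_noise``.
    """
    if not 0.0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must lie in [0, 0.5)")
    rng = _rng(seed, 4)
    msgs = synthetic_log.log.messages
    truth = set(synthetic_log.reply_pairs)
    out: list[ResponseAnnotation] = []
    for a in synthetic_log.base_indices:
        for c in range(a + 1, len(msgs)):
            delta = msgs[c].time - msgs[a].time
            if delta > horizon:
                break
            if delta <= 0:
                continue
            label = (a, c) in truth
            if flip_noise and rng.random() < flip_noise:
                label = not label
            out.append(ResponseAnnotation(antecedent=a, candidate=c, is_response=label))
    return out


def gen_baseline_features(
    spec: SyntheticSpec, qualities: np.ndarray, seed: int
) -> BaselineFeatures:
    """Baseline features correlated with latent quality.

    Each feature is r * z_q + sqrt(1 - r^2) * noise on the z-scale (so its
    Pearson correlation with quality approaches the target r), then mapped
    affinely onto a natural scale: share of women around 0.5, Big-5 averages
    around 3.5 on a 1-5 scale, social perceptiveness around 25 (an
    eyes-test score), communication amount around 2000 words.
    """
    rng = _rng(seed, 5)
    q = np.asarray(qualities, dtype=float)
    zq = (q - q.mean()) / (q.std() if q.std() > 0 else 1.0)
    scales = {
        "proportion_female": (0.5, 0.15, (0.0, 1.0)),
        "big5_openness": (3.5, 0.4, (1.0, 5.0)),
        "big5_conscientiousness": (3.5, 0.4, (1.0, 5.0)),
        "big5_extraversion": (3.5, 0.4, (1.0, 5.0)),
        "big5_agreeableness": (3.5, 0.4, (1.0, 5.0)),
        "big5_neuroticism": (3.5, 0.4, (1.0, 5.0)),
        "social_perceptiveness": (25.0, 4.0, (0.0, 36.0)),
        "communication_amount": (2000.0, 500.0, (0.0, None)),
        "communication_distribution": (500.0, 150.0, (0.0, None)),
    }
    columns = {}
    for name, r in spec.baseline_correlations:
        z = r * zq + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(size=len(q))
        center, spread, (lo, hi) = scales[name]
        values = center + spread * z
        columns[name] = np.clip(values, lo, hi if hi is not None else np.inf)
    table = pd.DataFrame(columns, index=_team_ids(len(q)))[list(BASELINE_FEATURE_NAMES)]
    return BaselineFeatures(table=table)


def gen_dataset(spec: SyntheticSpec, seed: int) -> SyntheticDataset:
    """Generate the full fixture set under one master seed.

    Team k's chat log uses the sub-seed spawn key (10, k), so individual
    teams are regenerable in isolation.
    """
    qualities = gen_qualities(spec, seed)
    scores = gen_score_table(spec, seed, qualities)
    baseline = gen_baseline_features(spec, qualities, seed)
    logs, annotations = [], []
    for k, team in enumerate(_team_ids(spec.n_teams)):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(10, k))
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        synth_log = gen_chat_log(spec, sub_seed, team_id=team)
        logs.append(synth_log)
        annotations.append(gen_annotations(synth_log, seed=sub_seed))
    return SyntheticDataset(spec=spec, qualities=qualities, scores=scores,
                            baseline=baseline, chat_logs=logs, annotations=annotations)
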