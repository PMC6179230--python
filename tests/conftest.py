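import numpy as np
import pytest

from teamperf import ChatLog, Message

# Nine-message excerpt of a real-style team chat (timestamps in seconds from
# session start, MM:SS counters 36:38..38:29); message text is placeholder.
EXCERPT_ROWS = [
    (2198, "nick"),
    (2220, "kate"),
    (2225, "nick"),
    (2231, "kate"),
    (2236, "nick"),
    (2293, "jeral"),
    (2297, "jeral"),
    (2305, "greg"),
    (2309, "kate"),
]


@pytest.fixture
def excerpt_log() -> ChatLog:
    msgs = [Message(sender=s, time=float(t), text=f"msg{k}") for k, (t, s) in enumerate(EXCERPT_ROWS)]
    return ChatLog.from_messages("excerpt", msgs)


def random_chat_log(rng: np.random.Generator, n_messages: int, n_members: int = 4,
                    max_gap: float = 30.0) -> ChatLog:
    """A random (non-planted) log for brute-force comparisons."""
    times = np.cumsum(rng.uniform(0.0, max_gap, size=n_messages))
    senders = rng.integers(0, n_members, size=n_messages)
    msgs = [
        Message(sender=f"m{senders[i]}", time=float(times[i]), text="x")
        for i in range(n_messages)
    ]
    return ChatLog.from_messages("random", msgs, members=[f"m{i}" for i in range(n_members)])
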