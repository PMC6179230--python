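"""Generate a small synthetic study: score tables, chat logs, features.

Each team gets a latent quality in [0, 1]; scores follow quality plus a
trend (weak teams improve over the battery) plus noise, chat logs follow a
planted reply process, and baseline features correlate with quality.
"""

import numpy as np

from teamperf.synth import SyntheticSpec, gen_dataset

spec = SyntheticSpec(n_teams=6, session_length=1200.0)
data = gen_dataset(spec, seed=42)

print(f"{spec.n_teams} teams x {spec.n_tasks} tasks")
print("score table head:")
print(data.scores.to_frame().round(2).head())

log = data.chat_logs[0].log
print(f"\nteam {log.team_id}: {len(log)} chat messages, "
      f"{len(data.chat_logs[0].reply_pairs)} planted replies")
print("first three messages:")
for m in log.messages[:3]:
    print(f"  t={m.time:7.1f}s  {m.sender}: {m.text[:40]}")

q = data.qualities
first = data.scores.scores[:, 0]
print(f"\nlatent qualities: {np.round(q, 2)}")
print(f"first-task scores: {np.round(first, 2)}")
print("scores track quality; the residual is trend plus noise.")
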