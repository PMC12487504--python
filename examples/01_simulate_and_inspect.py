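"""Simulate a labeled study and inspect one synthetic session.

Generates the default design — 30 high-quality and 10 low-quality sessions
from distinct ground-truth 3-state motivational models — and prints the
first session's score sequence. Positive scores are change talk, negative
scores sustain talk, zero neutral.
"""

from mihmm import SyntheticSpec, generate_dataset

sset = generate_dataset(SyntheticSpec(seed=7))
print(f"{len(sset)} sessions "
      f"({sum(s.quality.value == 'high' for s in sset)} high, "
      f"{sum(s.quality.value == 'low' for s in sset)} low)")

first = sset.sessions[0]
scores = first.client_scores()
print(f"\nsession {first.session_id} ({first.quality.value} quality, "
      f"{len(scores)} client utterances)")
print("first 20 strength scores:", scores[:20])
print("ground-truth hidden states:", sset.metadata["hidden_states"][first.session_id][:20])
print("\nStates 0/1/2 are Towards Change / Non-Determined / Away From Change;")
print("scores track the active state's emission mean (+3 / 0 / -3).")
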