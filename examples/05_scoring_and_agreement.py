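"""Score a text transcript with the lexicon scorer and measure agreement.

The lexicon scorer is a deterministic stand-in for an LLM rater: it sums
signed keyword weights and clips to [-5, +5]; the talk-type category is the
sign of the score. Agreement between two raters is summarized by accuracy
and Cohen's kappa (chance-corrected).
"""

from mihmm import (
    Quality, Session, Speaker, Utterance,
    agreement, fleiss_kappa, get_scorer, score_session,
)

texts = [
    "I really want to quit drinking",
    "it's fine the way it is",
    "maybe someday",
    "I can't change, I never could",
    "I am ready to try something new",
]
session = Session("demo", Quality.UNKNOWN, tuple(
    Utterance(index=i, speaker=Speaker.CLIENT, text=t) for i, t in enumerate(texts)
))

scored = score_session(session, get_scorer("lexicon"))
for u in scored.utterances:
    print(f"  {u.score:+d} ({u.category.value:7s})  {u.text}")

human = ["change", "sustain", "neutral", "sustain", "change"]
machine = [u.category.value for u in scored.utterances]
r = agreement(human, machine)
print(f"\nvs. a human rater: accuracy {r.accuracy:.2f}, Cohen's kappa {r.kappa:.2f}")

counts = [[3, 0, 0], [0, 2, 1], [1, 1, 1], [0, 0, 3], [3, 0, 0]]
print(f"Fleiss' kappa for 3 raters on 5 items: {fleiss_kappa(counts, 3):.2f}")
print("\nKappa near 1 means agreement beyond chance; near 0 means chance-level.")
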