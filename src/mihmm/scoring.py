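"""Score/category conventions and a deterministic lexicon scorer.

The numeric strength score is primary: the talk-type category is derived
from its sign (positive = change talk, zero = neutral, negative = sustain
talk). The :class:`LexiconScorer` is a deterministic stand-in for an
LLM-based scorer: it sums signed keyword weights and clips to [-5, +5].
Real scorers plug in through the same callable contract — they see the
utterance text plus only the session context *so far*, mirroring a
sequential, real-time evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

from .data import (
    SCORE_MAX,
    SCORE_MIN,
    Category,
    Session,
    SessionSet,
    Speaker,
    Utterance,
    _category_of_score,
)
from .errors import ValidationError


def category_from_score(score: int) -> Category:
    """Map a strength score onto its talk-type category by sign."""
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValidationError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return _category_of_score(score)


class Scorer(Protocol):
    """Contract for utterance scorers.

    ``context`` is the ordered list of prior utterances in the session;
    implementations must be stateless given ``(text, context)`` and must
    return an integer in [-5, +5].
    """

    name: str

    def __call__(self, text: str, context: Sequence[Utterance] = ()) -> int: ...


#: Small MI-flavored default lexicon (signed keyword weights).
DEFAULT_LEXICON: dict[str, int] = {
    "want": 2,
    "ready": 2,
    "will": 2,
    "can": 1,
    "quit": 1,
    "try": 1,
    "change": 1,
    "better": 1,
    "maybe": 0,
    "can't": -2,
    "cannot": -2,
    "won't": -2,
    "never": -2,
    "hate": -1,
    "fine": -1,
    "keep": -1,
    "pointless": -2,
}

_TOKEN_RE = re.compile(r"[a-z']+")


@dataclass(frozen=True)
class LexiconScorer:
    """Deterministic keyword scorer: sum of signed weights, clipped."""

    name: str = "lexicon"
    lexicon: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LEXICON))

    def __call__(self, text: str, context: Sequence[Utterance] = ()) -> int:
        total = sum(self.lexicon.get(tok, 0) for tok in _TOKEN_RE.findall(text.lower()))
        return max(SCORE_MIN, min(SCORE_MAX, total))


_SCORERS: dict[str, Scorer] = {"lexicon": LexiconScorer()}


def get_scorer(name: str) -> Scorer:
    """Look up a registered scorer plug-in by name."""
    try:
        return _SCORERS[name]
    except KeyError:
        raise ValidationError(
            f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}"
        ) from None


def register_scorer(scorer: Scorer) -> None:
    _SCORERS[scorer.name] = scorer


def score_session(session: Session, scorer: Scorer) -> Session:
    """Score every client utterance sequentially, deriving categories.

    Each call sees only the utterances before the current one, so a context-
    sensitive scorer behaves as it would in a streaming setting. Utterances
    without text, and therapist turns, are left untouched.
    """
    scored: list[Utterance] = []
    for u in session.utterances:
        if u.speaker is Speaker.CLIENT and u.text is not None:
            s = int(scorer(u.text, tuple(scored)))
            u = replace(u, score=s, category=category_from_score(s))
        scored.append(u)
    return Session(session.session_id, session.quality, tuple(scored))


def score_sessions(sset: SessionSet, scorer: Scorer) -> SessionSet:
    return SessionSet(
        [score_session(s, scorer) for s in sset.sessions],
        provenance=sset.provenance,
        metadata=dict(sset.metadata),
    )
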