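"""Session data model and transcript-cleaning rules.

A counseling session is an ordered list of utterances. Client utterances
carry an integer motivational *strength score* in [-5, +5] (positive =
movement towards change, negative = resistance, 0 = neutral) and/or a talk
type category (change / neutral / sustain). Sessions carry a quality label
(high / low / unknown). Only client utterances feed the downstream HMM
stages; therapist turns are kept in the model but filtered out before
scoring and fitting.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

SCORE_MIN = -5
SCORE_MAX = 5


class Speaker(str, enum.Enum):
    CLIENT = "client"
    THERAPIST = "therapist"


class Category(str, enum.Enum):
    CHANGE = "change"
    NEUTRAL = "neutral"
    SUSTAIN = "sustain"


class Quality(str, enum.Enum):
    HIGH = "high"
    LOW = "low"
    UNKNOWN = "unknown"


def _category_of_score(score: int) -> Category:
    # sign convention: score>0 -> change, 0 -> neutral, <0 -> sustain
    if score > 0:
        return Category.CHANGE
    if score < 0:
        return Category.SUSTAIN
    return Category.NEUTRAL


from .errors import ValidationError  # noqa: E402  (import after logger setup)


@dataclass(frozen=True)
class Utterance:
    """One turn in a session.

    ``score`` and ``category`` are both optional; when both are present they
    must agree with the sign convention.
    """

    index: int
    speaker: Speaker
    text: str | None = None
    category: Category | None = None
    score: int | None = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError(f"utterance index must be >= 0, got {self.index}")
        if self.score is not None:
            if not isinstance(self.score, (int,)) or isinstance(self.score, bool):
                raise ValidationError(
                    f"score must be an integer, got {self.score!r} at index {self.index}"
                )
            if not SCORE_MIN <= self.score <= SCORE_MAX:
                raise ValidationError(
                    f"score {self.score} outside [{SCORE_MIN}, {SCORE_MAX}] "
                    f"at index {self.index}"
                )
            if self.category is not None and self.category != _category_of_score(self.score):
                raise ValidationError(
                    f"category {self.category.value!r} inconsistent with score "
                    f"{self.score} at index {self.index}"
                )


@dataclass(frozen=True)
class Session:
    """An ordered session with a quality label."""

    session_id: str
    quality: Quality
    utterances: tuple[Utterance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "utterances", tuple(self.utterances))
        last = -1
        for u in self.utterances:
            if u.index <= last:
                raise ValidationError(
                    f"session {self.session_id!r}: utterance indices must be "
                    f"strictly increasing (saw {u.index} after {last})"
                )
            last = u.index

    def client_utterances(self) -> tuple[Utterance, ...]:
        return tuple(u for u in self.utterances if u.speaker is Speaker.CLIENT)

    def client_scores(self) -> list[int]:
        """Scores of client utterances that carry one, in order."""
        return [u.score for u in self.client_utterances() if u.score is not None]


@dataclass
class SessionSet:
    """A collection of sessions with free-form provenance metadata."""

    sessions: list[Session]
    provenance: str = "file"  # "file" | "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate session_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def by_quality(self, quality: Quality | str) -> "SessionSet":
        quality = Quality(quality)
        return SessionSet(
            [s for s in self.sessions if s.quality is quality],
            provenance=self.provenance,
            metadata=dict(self.metadata),
        )

    def score_sequences(self) -> list[list[int]]:
        """Per-session client score sequences (sessions without scores drop out)."""
        seqs = [s.client_scores() for s in self.sessions]
        return [q for q in seqs if q]


# ---------------------------------------------------------------------------
# Cleaning


@dataclass(frozen=True)
class CleaningRules:
    """Mechanical transcript-noise filters.

    ``noise_pattern`` is full-matched against the utterance text with all
    whitespace removed, case-insensitively; the default catches repetitive
    "n/a" filler such as ``n/an/an/an/an/a``. ``drop_unannotated_duplicates``
    removes an utterance that exactly repeats the previous surviving one
    (same speaker and text) while lacking a category annotation.
    """

    noise_pattern: str = r"(n/a){2,}"
    drop_unannotated_duplicates: bool = True


DEFAULT_CLEANING = CleaningRules()


def clean_session(raw: Session, rules: CleaningRules = DEFAULT_CLEANING) -> Session:
    """Apply the noise filters and re-index survivors from 0.

    Removals are logged; an empty result is permitted and logged as a warning.
    Cleaning is idempotent and never reorders surviving utterances.
    """
    noise_re = re.compile(rules.noise_pattern, re.IGNORECASE)
    kept: list[Utterance] = []
    for u in raw.utterances:
        if u.text is not None:
            stripped = re.sub(r"\s+", "", u.text)
            if stripped and noise_re.fullmatch(stripped):
                logger.info(
                    "clean_session %s: removed index %d (repetitive-noise pattern)",
                    raw.session_id, u.index,
                )
                continue
        if (
            rules.drop_unannotated_duplicates
            and kept
            and u.category is None
            and u.speaker is kept[-1].speaker
            and u.text == kept[-1].text
            and u.text is not None
        ):
            logger.info(
                "clean_session %s: removed index %d (unannotated duplicate line)",
                raw.session_id, u.index,
            )
            continue
        kept.append(u)
    if not kept:
        logger.warning("clean_session %s: no utterances survived cleaning", raw.session_id)
    reindexed = tuple(replace(u, index=i) for i, u in enumerate(kept))
    return Session(raw.session_id, raw.quality, reindexed)


def clean_sessions(sset: SessionSet, rules: CleaningRules = DEFAULT_CLEANING) -> SessionSet:
    return SessionSet(
        [clean_session(s, rules) for s in sset.sessions],
        provenance=sset.provenance,
        metadata=dict(sset.metadata),
    )
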