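"""Synthetic session generator.

Sessions are sampled from ground-truth 3-state Markov chains with state-
dependent Gaussian emissions: a latent path z_1 ~ pi, z_t ~ A[z_{t-1}], and
integer scores round(clip(Normal(mu_z, sigma_z), -5, +5)). Categories are
derived from the score sign and the hidden paths are retained in the
dataset metadata as ground truth, so decoding accuracy and parameter
recovery can be evaluated exactly.

The default profiles encode the qualitative contrast between session
qualities: the high-quality profile is "fluid" (every off-diagonal
transition >= 0.1 — clients move among motivational states), while the
low-quality profile is "sticky-Away" (Away-From-Change self-transition
>= 0.75 — persistence in resistance). The numeric values, the emission
parameters mu = (+3, 0, -3), sigma = (1, 1, 1) and the session length range
of 40-120 client utterances are this package's own invented defaults, not
values taken from any reference dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SCORE_MAX, SCORE_MIN, Category, Quality, Session, SessionSet, Speaker, Utterance
from .errors import ValidationError

#: Canonical state order used by all profiles: (Towards, Non-Determined, Away).
DEFAULT_HIGH_A = (
    (0.55, 0.30, 0.15),
    (0.35, 0.40, 0.25),
    (0.30, 0.35, 0.35),
)
DEFAULT_LOW_A = (
    (0.30, 0.35, 0.35),
    (0.15, 0.40, 0.45),
    (0.05, 0.15, 0.80),
)


@dataclass(frozen=True)
class GeneratorProfile:
    """Ground-truth model in (Towards, Non-Determined, Away) order."""

    name: str
    pi: tuple[float, ...]
    A: tuple[tuple[float, ...], ...]
    emission_means: tuple[float, ...] = (3.0, 0.0, -3.0)
    emission_sds: tuple[float, ...] = (1.0, 1.0, 1.0)
    length_range: tuple[int, int] = (40, 120)
    allow_gradient_violation: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        k = pi.size
        if a.shape != (k, k):
            raise ValidationError(f"profile {self.name!r}: A must be {k}x{k}")
        if abs(pi.sum() - 1.0) > 1e-12 or np.max(np.abs(a.sum(1) - 1.0)) > 1e-12:
            raise ValidationError(
                f"profile {self.name!r}: pi and rows of A must sum to 1 within 1e-12"
            )
        if np.any(pi < 0) or np.any(a < 0):
            raise ValidationError(f"profile {self.name!r}: probabilities must be >= 0")
        if np.any(np.asarray(self.emission_sds) <= 0):
            raise ValidationError(f"profile {self.name!r}: emission sds must be > 0")
        means = np.asarray(self.emission_means, dtype=float)
        if not self.allow_gradient_violation and not np.all(np.diff(means) < 0):
            raise ValidationError(
                f"profile {self.name!r}: emission means must be strictly decreasing "
                "(set allow_gradient_violation=True to override)"
            )
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"profile {self.name!r}: invalid length_range {self.length_range}")

    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)

    def A_array(self) -> np.ndarray:
        return np.asarray(self.A, dtype=float)


def default_high_profile() -> GeneratorProfile:
    return GeneratorProfile(name="fluid-high", pi=(0.4, 0.4, 0.2), A=DEFAULT_HIGH_A)


def default_low_profile() -> GeneratorProfile:
    return GeneratorProfile(name="sticky-away-low", pi=(0.15, 0.35, 0.5), A=DEFAULT_LOW_A)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study design: how many sessions per quality, from which profiles."""

    n_high: int = 30
    n_low: int = 10
    high_profile: GeneratorProfile = field(default_factory=default_high_profile)
    low_profile: GeneratorProfile = field(default_factory=default_low_profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_low < 0:
            raise ValidationError("n_high and n_low must be >= 0")


def _sample_path_and_scores(profile: GeneratorProfile, length: int, rng: np.random.Generator):
    k = len(profile.pi)
    a = profile.A_array()
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(k, p=profile.pi_array())
    for t in range(1, length):
        states[t] = rng.choice(k, p=a[states[t - 1]])
    raw = rng.normal(
        np.asarray(profile.emission_means)[states],
        np.asarray(profile.emission_sds)[states],
    )
    scores = np.clip(np.rint(raw), SCORE_MIN, SCORE_MAX).astype(int)
    return states, scores


def _session_from_scores(session_id: str, quality: Quality, scores: np.ndarray) -> Session:
    utts = []
    for i, s in enumerate(scores):
        s = int(s)
        cat = Category.CHANGE if s > 0 else Category.SUSTAIN if s < 0 else Category.NEUTRAL
        utts.append(Utterance(index=i, speaker=Speaker.CLIENT, category=cat, score=s))
    return Session(session_id, quality, tuple(utts))


def generate_session(
    profile: GeneratorProfile,
    length: int,
    seed: int = 0,
    session_id: str = "synthetic-000",
    quality: Quality = Quality.UNKNOWN,
) -> Session:
    """Sample one session of ``length`` client utterances (deterministic in seed)."""
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    _, scores = _sample_path_and_scores(profile, length, rng)
    return _session_from_scores(session_id, quality, scores)


def generate_dataset(spec: SyntheticSpec) -> SessionSet:
    """Sample a labeled study: n_high + n_low sessions, lengths uniform in range.

    Ground truth (profile parameters and per-session hidden state paths)
    goes into ``SessionSet.metadata`` under "profiles" and "hidden_states".
    """
    rng = np.random.default_rng(spec.seed)
    sessions: list[Session] = []
    hidden: dict[str, list[int]] = {}
    for quality, n, profile in (
        (Quality.HIGH, spec.n_high, spec.high_profile),
        (Quality.LOW, spec.n_low, spec.low_profile),
    ):
        lo, hi = profile.length_range
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            states, scores = _sample_path_and_scores(profile, length, rng)
            sid = f"{quality.value}-{i:03d}"
            sessions.append(_session_from_scores(sid, quality, scores))
            hidden[sid] = states.tolist()
    metadata = {
        "profiles": {
            "high": _profile_dict(spec.high_profile),
            "low": _profile_dict(spec.low_profile),
        },
        "hidden_states": hidden,
        "seed": spec.seed,
    }
    return SessionSet(sessions, provenance="synthetic", metadata=metadata)


def _profile_dict(p: GeneratorProfile) -> dict:
    return {
        "name": p.name,
        "pi": list(p.pi),
        "A": [list(r) for r in p.A],
        "emission_means": list(p.emission_means),
        "emission_sds": list(p.emission_sds),
        "length_range": list(p.length_range),
    }
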