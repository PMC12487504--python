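"""Group-level transition-matrix comparison.

One HMM is fitted per quality group on the pooled (multi-sequence) client
score sequences; the canonical (descending-emission-mean) transition
matrices are compared with the Frobenius norm of their element-wise
difference, D = ||A_high - A_low||_F. Significance comes from a label-
shuffling permutation test: session group labels are reshuffled with group
sizes preserved, both group models are refitted from scratch and
re-canonicalized, and the p-value is the proportion of permuted statistics
greater than or equal to the observed one. Gradient-invalid permuted fits
still contribute a statistic (their canonical ordering is deterministic);
they are counted, not discarded, to avoid biasing the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .data import Quality, SessionSet
from .errors import ValidationError
from .hmm import HMMConfig, HMMModel, LabeledHMM, fit_bank, fit_hmm, label_states, pad_sequences

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupFit:
    group_label: Quality
    sessions_used: tuple[str, ...]
    labeled_hmm: LabeledHMM


@dataclass
class PermutationResult:
    observed_D: float
    null_Ds: np.ndarray
    n_permutations: int
    p_value: float
    seed: int
    degenerate_fit_count: int
    convention: str
    high_fit: GroupFit
    low_fit: GroupFit
    extras: dict = field(default_factory=dict)


def transition_frobenius(A: np.ndarray, B: np.ndarray) -> float:
    """Frobenius norm of the element-wise matrix difference."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B))


def fit_group(sessions: SessionSet, config: HMMConfig = HMMConfig()) -> GroupFit:
    """Pooled multi-sequence fit for one quality group, canonically labeled."""
    qualities = {s.quality for s in sessions}
    if len(qualities) != 1:
        raise ValidationError(
            f"fit_group expects a single quality label, got {sorted(q.value for q in qualities)}"
        )
    usable = [(s.session_id, s.client_scores()) for s in sessions]
    usable = [(sid, sc) for sid, sc in usable if len(sc) >= 3]
    if len(usable) < 2:
        raise ValidationError(
            "fit_group requires >= 2 sessions with >= 3 client scores each"
        )
    ids, seqs = zip(*usable)
    labeled = label_states(fit_hmm(list(seqs), config))
    if not labeled.gradient_valid:
        logger.warning(
            "fit_group %s: emission means do not follow the motivational gradient; "
            "state labels are not interpretable",
            next(iter(qualities)).value,
        )
    return GroupFit(next(iter(qualities)), tuple(ids), labeled)


def _canonical_A_bank(bank) -> np.ndarray:
    """Canonically reorder every model in a bank by descending emission mean."""
    m = bank.n_models
    if bank.emission_probs is not None:
        values = np.arange(-5, 6, dtype=float)
        means = bank.emission_probs @ values
    else:
        means = bank.means
    order = np.argsort(-means, axis=1, kind="stable")
    rows = np.arange(m)[:, None, None]
    return bank.A[rows, order[:, :, None], order[:, None, :]]


def _gradient_valid_bank(bank) -> np.ndarray:
    means = bank.means
    srt = -np.sort(-means, axis=1)
    return np.all(np.diff(srt, axis=1) < 0, axis=1)


def permutation_test(
    sessions: SessionSet,
    n_permutations: int = 1000,
    config: HMMConfig = HMMConfig(),
    seed: int = 0,
    perm_config: HMMConfig | None = None,
    convention: str = "plain",
    chunk_size: int = 200,
) -> PermutationResult:
    """Label-shuffling permutation test on the group Frobenius statistic.

    ``perm_config`` optionally relaxes EM settings inside permutations
    (defaults to ``config``). ``convention`` is "plain" (#{null >= obs}/N)
    or "smoothed" ((#+1)/(N+1)).
    """
    if convention not in ("plain", "smoothed"):
        raise ValidationError(f"unknown p-value convention {convention!r}")
    perm_config = perm_config or config
    high = sessions.by_quality(Quality.HIGH)
    low = sessions.by_quality(Quality.LOW)
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("both quality groups must be non-empty")

    high_fit = fit_group(high, config)
    low_fit = fit_group(low, config)
    observed = transition_frobenius(high_fit.labeled_hmm.labeled_A, low_fit.labeled_hmm.labeled_A)

    # pooled sequences for the shuffled refits
    pool = [
        (s.session_id, s.client_scores(), s.quality)
        for s in sessions
        if len(s.client_scores()) >= 3
    ]
    labels = np.array([q is Quality.HIGH for _, _, q in pool])
    n_high = int(labels.sum())
    obs_arr, lengths, _ = pad_sequences([sc for _, sc, _ in pool])
    b = len(pool)

    rng = np.random.default_rng(seed)
    null_ds = np.empty(n_permutations)
    degenerate = 0
    for start in range(0, n_permutations, chunk_size):
        stop = min(start + chunk_size, n_permutations)
        p = stop - start
        w_high = np.zeros((p, b))
        for j in range(p):
            w_high[j, rng.permutation(b)[:n_high]] = 1.0
        weights = np.concatenate([w_high, 1.0 - w_high], axis=0)  # (2p, B)
        bank = fit_bank(obs_arr, lengths, weights, perm_config)
        canon = _canonical_A_bank(bank)
        null_ds[start:stop] = np.linalg.norm(canon[:p] - canon[p:], axis=(1, 2))
        valid = _gradient_valid_bank(bank)
        degenerate += int(((~valid) | (~bank.converged)).sum())

    n_ge = int(np.sum(null_ds >= observed))
    if convention == "plain":
        p_value = n_ge / n_permutations
    else:
        p_value = (n_ge + 1) / (n_permutations + 1)
    return PermutationResult(
        observed_D=observed,
        null_Ds=null_ds,
        n_permutations=n_permutations,
        p_value=float(p_value),
        seed=seed,
        degenerate_fit_count=degenerate,
        convention=convention,
        high_fit=high_fit,
        low_fit=low_fit,
    )
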