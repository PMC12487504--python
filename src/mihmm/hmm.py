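"""Gaussian-emission hidden Markov models over strength-score sequences.

The model: three latent motivational states with a start distribution pi, a
row-stochastic transition matrix A, and per-state emissions — Gaussian
(mu_k, sigma_k) by default, or a categorical distribution over the eleven
integer scores -5..+5. Parameters are estimated by Baum-Welch (EM) over
multiple independent sequences: per-sequence sufficient statistics are
summed, and each sequence restarts from pi. The forward-backward pass uses
per-step normalization (scaled alphas/betas), so session-length sequences
never underflow. States are interpreted *after* fitting by sorting on
emission mean: highest = "Towards Change", middle = "Non-Determined",
lowest = "Away From Change"; a fit whose sorted means are not strictly
decreasing is flagged gradient-invalid and should not be interpreted
clinically (its canonical ordering is still deterministic, so matrix
comparisons remain possible).

Implementation note: the EM core (:func:`fit_bank`) fits a whole bank of M
models in parallel over one shared padded observation array, each model
seeing the sequences selected by a 0/1 weight vector. Padded steps carry
emission likelihood 1, which leaves scaled alphas/betas, per-step log
normalizers and the masked sufficient statistics exactly equal to the
unpadded computation. Because every model's statistics are computed
independently, a bank fit reproduces M separate fits up to floating-point
round-off — :func:`fit_hmm` is simply the M=1 (plus restarts) wrapper. Banks are what
make label-shuffling permutation tests with full refits affordable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import SCORE_MAX, SCORE_MIN
from .errors import ValidationError

_LOG2PI = float(np.log(2.0 * np.pi))
_DENS_FLOOR = 1e-300
N_SCORE_VALUES = SCORE_MAX - SCORE_MIN + 1

STATE_LABELS_3 = ("Towards Change", "Non-Determined", "Away From Change")


@dataclass(frozen=True)
class HMMConfig:
    """Estimation settings.

    tol is the relative log-likelihood change below which EM stops;
    variance_floor bounds sigma^2 from below (so sigma >= sqrt(floor)).
    init_means seeds the per-state emission means at the expected
    motivational gradient (+3 towards, 0 non-determined, -3 away);
    n_restarts > 0 adds seeded random perturbations of the init means and
    keeps the best final log-likelihood. fix_start_from_first_score pins pi
    to the empirical sign distribution of first-utterance scores instead of
    estimating it by EM.

    discretization (Gaussian family only) controls how the bounded integer
    score scale is related to the latent continuous inclination:

    * "bins" (default): integer score v is the interval observation
      (v-1/2, v+1/2] of the latent Gaussian, with the scale ends -5/+5
      absorbing the open tails. Emission likelihoods are bin probabilities
      and the M-step uses truncated-normal conditional moments — the
      correctly specified model for round-and-clip integer scores. Applied
      only when all observations are integers; otherwise falls back to
      "censor".
    * "censor": only boundary observations (beyond +/-4.5) are treated as
      censored tails (Tobit moments); interior values keep the plain
      Gaussian density.
    * "none": plain Gaussian density everywhere. Boundary point masses then
      bias the transition estimates; useful for cross-checks against plain
      Gaussian-HMM implementations.
    """

    n_states: int = 3
    emission_family: str = "gaussian"  # "gaussian" | "categorical11"
    max_iter: int = 500
    tol: float = 1e-6
    variance_floor: float = 1e-2
    init_means: tuple[float, ...] = (3.0, 0.0, -3.0)
    init_sd: float = 1.5
    seed: int = 0
    n_restarts: int = 0
    restart_scale: float = 0.5
    fix_start_from_first_score: bool = False
    discretization: str = "bins"  # "bins" | "censor" | "none"

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError(f"n_states must be >= 2, got {self.n_states}")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.variance_floor <= 0:
            raise ValidationError("variance_floor must be > 0")
        if self.emission_family not in ("gaussian", "categorical11"):
            raise ValidationError(
                f"unknown emission_family {self.emission_family!r}"
            )
        if self.discretization not in ("bins", "censor", "none"):
            raise ValidationError(f"unknown discretization {self.discretization!r}")
        if len(self.init_means) != self.n_states:
            raise ValidationError("init_means length must equal n_states")


@dataclass
class HMMModel:
    """A fitted model: pi, A, emission parameters, and the EM record."""

    pi: np.ndarray
    A: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    emission_probs: np.ndarray | None  # (K, 11) for categorical11, else None
    log_likelihood_trace: list[float]
    converged: bool
    config: HMMConfig
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        k = self.pi.shape[0]
        if self.A.shape != (k, k):
            raise ValidationError(f"A must be {k}x{k}, got {self.A.shape}")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValidationError("pi must sum to 1 within 1e-9")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-9:
            raise ValidationError("rows of A must sum to 1 within 1e-9")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    def emission_means(self) -> np.ndarray:
        """Per-state emission means (computed from the pmf for categorical)."""
        if self.emission_probs is not None:
            values = np.arange(SCORE_MIN, SCORE_MAX + 1, dtype=float)
            return self.emission_probs @ values
        return self.means

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "emission_probs": None
            if self.emission_probs is None
            else self.emission_probs.tolist(),
            "log_likelihood_trace": [float(x) for x in self.log_likelihood_trace],
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
            "config": self.config.__dict__ | {"init_means": list(self.config.init_means)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        cfg = dict(d["config"])
        cfg["init_means"] = tuple(cfg["init_means"])
        return cls(
            pi=np.array(d["pi"], dtype=float),
            A=np.array(d["A"], dtype=float),
            means=np.array(d["means"], dtype=float),
            sds=np.array(d["sds"], dtype=float),
            emission_probs=None
            if d.get("emission_probs") is None
            else np.array(d["emission_probs"], dtype=float),
            log_likelihood_trace=list(d["log_likelihood_trace"]),
            converged=d["converged"],
            config=HMMConfig(**cfg),
            degenerate=d.get("degenerate", False),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    @classmethod
    def load(cls, path) -> "HMMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class LabeledHMM:
    """A model with states canonically ordered by descending emission mean."""

    model: HMMModel
    state_order: tuple[int, ...]
    labels: tuple[str, ...]
    gradient_valid: bool
    labeled_pi: np.ndarray
    labeled_A: np.ndarray
    labeled_means: np.ndarray


# ---------------------------------------------------------------------------
# Padding and validation helpers


def pad_sequences(sequences: Sequence[Sequence[float]]):
    """Stack ragged sequences into (obs, lengths, mask) with zero padding."""
    lengths = np.array([len(s) for s in sequences], dtype=int)
    if lengths.size == 0:
        raise ValidationError("at least one sequence is required")
    if np.any(lengths == 0):
        raise ValidationError("empty sequences are not allowed")
    b, tmax = lengths.size, int(lengths.max())
    obs = np.zeros((b, tmax), dtype=float)
    for i, s in enumerate(sequences):
        obs[i, : lengths[i]] = np.asarray(s, dtype=float)
    mask = np.arange(tmax)[None, :] < lengths[:, None]
    return obs, lengths, mask


def _check_scores(sequences) -> None:
    for i, s in enumerate(sequences):
        arr = np.asarray(s, dtype=float)
        if arr.size and (arr.min() < SCORE_MIN or arr.max() > SCORE_MAX):
            raise ValidationError(
                f"sequence {i}: scores outside [{SCORE_MIN}, {SCORE_MAX}]"
            )


# ---------------------------------------------------------------------------
# Banked EM core


@dataclass
class BankFit:
    """Result of fitting M models in parallel (arrays have leading axis M)."""

    pi: np.ndarray          # (M, K)
    A: np.ndarray           # (M, K, K)
    means: np.ndarray       # (M, K)
    sds: np.ndarray         # (M, K)
    emission_probs: np.ndarray | None  # (M, K, 11)
    loglik: np.ndarray      # (M,)
    traces: list[list[float]]
    converged: np.ndarray   # (M,) bool
    n_models: int


#: censoring thresholds: a score at the scale boundary represents the whole tail
_CENSOR_HI = SCORE_MAX - 0.5
_CENSOR_LO = SCORE_MIN + 0.5
_ZMAX = 37.0  # beyond this the normal tail underflows; clamp for stability

#: bin edges for the 11 integer scores: (-inf, -4.5], ..., (4.5, inf)
_BIN_EDGES = np.concatenate(
    [[-np.inf], np.arange(SCORE_MIN + 0.5, SCORE_MAX, 1.0), [np.inf]]
)


def _is_integer_scores(obs, mask) -> bool:
    vals = obs[mask]
    return bool(np.all(vals == np.rint(vals)))


def score_bin_tables(means, sds):
    """Bin probabilities and truncated-normal moments per model/state/score.

    Returns (prob, e1, e2), each of shape means.shape + (11,): the Gaussian
    probability of each integer-score bin and the conditional first/second
    moments of the latent value within the bin. Edge bins are open tails.
    """
    from scipy.special import ndtr

    mu = means[..., None]                                   # (..., K, 1)
    s = sds[..., None]
    z = np.clip((_BIN_EDGES - mu) / s, -_ZMAX, _ZMAX)       # (..., K, 12)
    cdf = ndtr(z)
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    # (edge + mu) * phi(z) -> 0 at infinite edges
    ephi = np.where(np.isfinite(_BIN_EDGES), (_BIN_EDGES + mu) * phi, 0.0)
    prob = np.diff(cdf, axis=-1)                            # (..., K, 11)
    zsafe = np.maximum(prob, _DENS_FLOOR)
    e1 = mu + s * (phi[..., :-1] - phi[..., 1:]) / zsafe
    e2 = mu * mu + s * s + s * (ephi[..., :-1] - ephi[..., 1:]) / zsafe
    return prob, e1, e2


def _emission_density(obs, mask, means, sds, probs, family, mode="none"):
    """Per-state observation likelihoods, =1 at padded steps. -> (M, B, T, K)

    ``mode`` (Gaussian only): "bins" uses integer-score bin probabilities,
    "censor" replaces boundary observations with tail probabilities, "none"
    is the plain density.
    """
    from scipy.special import ndtr

    if family == "gaussian" and mode == "bins":
        table, _, _ = score_bin_tables(means, sds)          # (M, K, 11)
        idx = np.clip(np.rint(obs).astype(int) - SCORE_MIN, 0, N_SCORE_VALUES - 1)
        dens = np.moveaxis(table[:, :, idx], 1, 3)          # (M, B, T, K)
    elif family == "gaussian":
        z = (obs[None, :, :, None] - means[:, None, None, :]) / sds[:, None, None, :]
        dens = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sds[:, None, None, :])
        if mode == "censor":
            zhi = np.clip((_CENSOR_HI - means) / sds, -_ZMAX, _ZMAX)  # (M, K)
            zlo = np.clip((_CENSOR_LO - means) / sds, -_ZMAX, _ZMAX)
            hi = (obs >= _CENSOR_HI) & mask
            lo = (obs <= _CENSOR_LO) & mask
            hb, ht = np.nonzero(hi)
            lb, lt = np.nonzero(lo)
            dens[:, hb, ht, :] = ndtr(-zhi)[:, None, :]
            dens[:, lb, lt, :] = ndtr(zlo)[:, None, :]
    else:
        idx = np.clip(obs.astype(int) - SCORE_MIN, 0, N_SCORE_VALUES - 1)
        dens = probs[:, :, idx]                     # (M, K, B, T)
        dens = np.moveaxis(dens, 1, 3)              # (M, B, T, K)
    dens = np.maximum(dens, _DENS_FLOOR)
    dens[:, ~mask, :] = 1.0
    return np.ascontiguousarray(dens)


def _censored_moments(means, sds):
    """Tail conditional moments (Tobit M-step), each (M, K)."""
    from scipy.special import ndtr

    mu, s = means, sds
    z_hi = np.clip((_CENSOR_HI - mu) / s, -_ZMAX, _ZMAX)
    z_lo = np.clip((_CENSOR_LO - mu) / s, -_ZMAX, _ZMAX)
    phi_hi = np.exp(-0.5 * z_hi * z_hi) / np.sqrt(2.0 * np.pi)
    phi_lo = np.exp(-0.5 * z_lo * z_lo) / np.sqrt(2.0 * np.pi)
    lam_hi = phi_hi / np.maximum(ndtr(-z_hi), _DENS_FLOOR)   # Mills ratio, right tail
    lam_lo = phi_lo / np.maximum(ndtr(z_lo), _DENS_FLOOR)    # left tail
    e1_hi = mu + s * lam_hi
    e2_hi = mu * mu + s * s + s * (_CENSOR_HI + mu) * lam_hi
    e1_lo = mu - s * lam_lo
    e2_lo = mu * mu + s * s - s * (_CENSOR_LO + mu) * lam_lo
    return e1_hi, e2_hi, e1_lo, e2_lo


def _forward_backward(dens, pi, A, mask):
    """Scaled forward-backward over a model bank.

    Returns (alpha, beta, c, loglik_per_seq): alpha/beta are the per-step
    normalized quantities, c the normalizers, and alpha*beta the state
    posterior. Padded steps have density 1, so their normalizers are exactly
    1 and contribute nothing to the log-likelihood.
    """
    m, b, t, k = dens.shape
    alpha = np.empty((m, b, t, k))
    c = np.empty((m, b, t))
    a0 = pi[:, None, :] * dens[:, :, 0, :]
    c[:, :, 0] = np.maximum(a0.sum(-1), _DENS_FLOOR)
    alpha[:, :, 0, :] = a0 / c[:, :, 0, None]
    for s in range(1, t):
        a = np.matmul(alpha[:, :, s - 1, :], A) * dens[:, :, s, :]
        c[:, :, s] = np.maximum(a.sum(-1), _DENS_FLOOR)
        alpha[:, :, s, :] = a / c[:, :, s, None]
    beta = np.empty_like(alpha)
    beta[:, :, t - 1, :] = 1.0
    at = np.swapaxes(A, 1, 2)
    for s in range(t - 2, -1, -1):
        tmp = dens[:, :, s + 1, :] * beta[:, :, s + 1, :] / c[:, :, s + 1, None]
        beta[:, :, s, :] = np.matmul(tmp, at)
    loglik_per_seq = np.where(mask[None, :, :], np.log(c), 0.0).sum(-1)
    return alpha, beta, c, loglik_per_seq


def fit_bank(
    obs: np.ndarray,
    lengths: np.ndarray,
    weights: np.ndarray,
    config: HMMConfig,
    init_means: np.ndarray | None = None,
    fixed_pi: np.ndarray | None = None,
) -> BankFit:
    """Fit M HMMs in parallel on shared padded sequences.

    ``weights[m, b]`` selects (0/1) or weights sequence ``b`` in model
    ``m``'s sufficient statistics. Each model's EM trajectory reproduces a
    standalone fit on its selected sequences up to round-off; models stop
    updating individually once their relative log-likelihood change drops
    below ``config.tol``.
    """
    obs = np.asarray(obs, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    weights = np.asarray(weights, dtype=float)
    m_total, b = weights.shape
    if obs.shape[0] != b:
        raise ValidationError("weights and obs disagree on the number of sequences")
    tmax = obs.shape[1]
    mask = np.arange(tmax)[None, :] < lengths[:, None]
    k = config.n_states
    family = config.emission_family

    # deterministic initialization (optionally perturbed upstream)
    if init_means is None:
        init_means = np.tile(np.asarray(config.init_means, dtype=float), (m_total, 1))
    means = np.array(init_means, dtype=float)
    sds = np.full((m_total, k), float(config.init_sd))
    if family == "categorical11":
        values = np.arange(SCORE_MIN, SCORE_MAX + 1, dtype=float)
        z = (values[None, None, :] - means[:, :, None]) / config.init_sd
        probs = np.exp(-0.5 * z * z)
        probs /= probs.sum(-1, keepdims=True)
    else:
        probs = None
    A = np.full((m_total, k, k), 1.0 / k)
    pi = np.full((m_total, k), 1.0 / k) if fixed_pi is None else np.array(fixed_pi, float)

    xi_mask = mask[:, 1:] if tmax > 1 else np.zeros((b, 0), dtype=bool)
    min_var = float(config.variance_floor)
    mode = "none"
    onehot = None
    cens_hi = cens_lo = None
    if family == "gaussian" and config.discretization != "none":
        if config.discretization == "bins" and _is_integer_scores(obs, mask):
            mode = "bins"
            idx = np.clip(np.rint(obs).astype(int) - SCORE_MIN, 0, N_SCORE_VALUES - 1)
            onehot = np.eye(N_SCORE_VALUES)[idx]    # (B, T, 11)
        else:
            mode = "censor"
            cens_hi = (obs >= _CENSOR_HI) & mask
            cens_lo = (obs <= _CENSOR_LO) & mask
            if not (cens_hi.any() or cens_lo.any()):
                mode = "none"

    loglik = np.full(m_total, -np.inf)
    converged = np.zeros(m_total, dtype=bool)
    done = np.zeros(m_total, dtype=bool)
    traces: list[list[float]] = [[] for _ in range(m_total)]

    for it in range(config.max_iter + 1):
        act = np.nonzero(~done)[0]
        if act.size == 0:
            break
        dens = _emission_density(
            obs, mask, means[act], sds[act],
            None if probs is None else probs[act], family, mode=mode,
        )
        alpha, beta, c, ll_seq = _forward_backward(dens, pi[act], A[act], mask)
        ll = (weights[act] * ll_seq).sum(-1)
        for j, mi in enumerate(act):
            traces[mi].append(float(ll[j]))
        prev = loglik[act]
        with np.errstate(invalid="ignore"):
            rel = np.abs(ll - prev) / np.maximum(np.abs(prev), 1e-300)
        just_conv = np.isfinite(prev) & (rel < config.tol)
        loglik[act] = ll
        converged[act[just_conv]] = True
        done[act[just_conv]] = True
        if it == config.max_iter:
            done[act] = True
            break
        upd = act[~just_conv]
        if upd.size == 0:
            continue
        sel = ~just_conv
        gamma = alpha[sel] * beta[sel]                     # (Mu, B, T, K)
        w = weights[upd]                                   # (Mu, B)
        # start distribution from t=0 posteriors
        if fixed_pi is None:
            p0 = (w[:, :, None] * gamma[:, :, 0, :]).sum(1)
            pi[upd] = p0 / np.maximum(p0.sum(-1, keepdims=True), _DENS_FLOOR)
        # transition counts
        if tmax > 1:
            v = dens[sel][:, :, 1:, :] * beta[sel][:, :, 1:, :] / c[sel][:, :, 1:, None]
            aw = alpha[sel][:, :, :-1, :] * (w[:, :, None] * xi_mask[None])[:, :, :, None]
            sxi = A[upd] * np.einsum("mbti,mbtj->mij", aw, v, optimize=True)
            rows = sxi.sum(-1, keepdims=True)
            A[upd] = np.where(rows > 0, sxi / np.maximum(rows, _DENS_FLOOR), A[upd])
        # emissions
        g = gamma * (w[:, :, None] * mask[None])[:, :, :, None]
        nk = g.sum((1, 2))                                 # (Mu, K)
        nk_safe = np.maximum(nk, _DENS_FLOOR)
        if family == "gaussian":
            if mode == "bins":
                # per-bin posterior mass, then truncated-normal moments
                cnt = np.einsum("mbtk,btv->mkv", g, onehot, optimize=True)
                _, e1t, e2t = score_bin_tables(means[upd], sds[upd])
                s1 = (cnt * e1t).sum(-1)
                s2 = (cnt * e2t).sum(-1)
            else:
                s1 = np.einsum("mbtk,bt->mk", g, obs, optimize=True)
                s2 = np.einsum("mbtk,bt->mk", g, obs * obs, optimize=True)
                if mode == "censor":
                    # swap boundary observations for their censored-normal moments
                    e1h, e2h, e1l, e2l = _censored_moments(means[upd], sds[upd])
                    for cm, e1, e2 in ((cens_hi, e1h, e2h), (cens_lo, e1l, e2l)):
                        bi, ti = np.nonzero(cm)
                        if bi.size == 0:
                            continue
                        gc = g[:, bi, ti, :]                   # (Mu, n, K)
                        oc = obs[bi, ti]                       # (n,)
                        gsum = gc.sum(1)                       # (Mu, K)
                        s1 += gsum * e1 - np.einsum("mnk,n->mk", gc, oc, optimize=True)
                        s2 += gsum * e2 - np.einsum("mnk,n->mk", gc, oc * oc, optimize=True)
            mu = s1 / nk_safe
            var = np.maximum(s2 / nk_safe - mu * mu, min_var)
            means[upd] = np.where(nk > 0, mu, means[upd])
            sds[upd] = np.where(nk > 0, np.sqrt(var), sds[upd])
        else:
            idx = np.clip(obs.astype(int) - SCORE_MIN, 0, N_SCORE_VALUES - 1)
            onehot = np.eye(N_SCORE_VALUES)[idx]           # (B, T, 11)
            cnt = np.einsum("mbtk,btv->mkv", g, onehot, optimize=True)
            new_probs = cnt / nk_safe[:, :, None]
            probs[upd] = np.where(nk[:, :, None] > 0, new_probs, probs[upd])
            means[upd] = probs[upd] @ np.arange(SCORE_MIN, SCORE_MAX + 1, dtype=float)

    return BankFit(pi, A, means, sds, probs, loglik, traces, converged, m_total)


# ---------------------------------------------------------------------------
# Public single-model operations


def fit_hmm(sequences: Sequence[Sequence[float]], config: HMMConfig = HMMConfig()) -> HMMModel:
    """Baum-Welch estimation on pooled independent score sequences."""
    if len(sequences) == 0:
        raise ValidationError("fit_hmm requires at least one sequence")
    _check_scores(sequences)
    obs, lengths, _ = pad_sequences(sequences)
    total = int(lengths.sum())
    if total < 3 * config.n_states:
        raise ValidationError(
            f"insufficient data: {total} observations < 3 x {config.n_states} states"
        )
    degenerate = False
    flat = np.concatenate([np.asarray(s, float) for s in sequences])
    if config.emission_family == "categorical11" and np.unique(flat).size == 1:
        degenerate = True
        warnings.warn(
            "all observations are constant; categorical emission fit is degenerate",
            stacklevel=2,
        )

    m = config.n_restarts + 1
    init_means = np.tile(np.asarray(config.init_means, float), (m, 1))
    if config.n_restarts > 0:
        rng = np.random.default_rng(config.seed)
        init_means[1:] += rng.normal(
            scale=config.restart_scale, size=(config.n_restarts, config.n_states)
        )
    fixed_pi = None
    if config.fix_start_from_first_score:
        firsts = np.array([float(s[0]) for s in sequences])
        fracs = np.array([(firsts > 0).mean(), (firsts == 0).mean(), (firsts < 0).mean()])
        if config.n_states != 3:
            raise ValidationError("fix_start_from_first_score requires n_states = 3")
        order = np.argsort(-np.asarray(config.init_means), kind="stable")
        pi0 = np.empty(3)
        pi0[order] = fracs
        fixed_pi = np.tile(pi0, (m, 1))

    weights = np.ones((m, len(sequences)))
    bank = fit_bank(obs, lengths, weights, config, init_means=init_means, fixed_pi=fixed_pi)
    best = int(np.argmax(bank.loglik))
    return HMMModel(
        pi=bank.pi[best],
        A=bank.A[best],
        means=bank.means[best],
        sds=bank.sds[best],
        emission_probs=None if bank.emission_probs is None else bank.emission_probs[best],
        log_likelihood_trace=bank.traces[best],
        converged=bool(bank.converged[best]),
        config=config,
        degenerate=degenerate,
    )


def _single_density(model: HMMModel, seq) -> np.ndarray:
    obs = np.asarray(seq, dtype=float).reshape(1, -1)
    if obs.size == 0:
        raise ValidationError("sequence must be non-empty")
    mask = np.ones_like(obs, dtype=bool)
    probs = None if model.emission_probs is None else model.emission_probs[None]
    family = "gaussian" if model.emission_probs is None else "categorical11"
    mode = "none"
    if family == "gaussian" and model.config.discretization != "none":
        if model.config.discretization == "bins" and _is_integer_scores(obs, mask):
            mode = "bins"
        else:
            mode = "censor"
    dens = _emission_density(
        obs, mask, model.means[None], model.sds[None], probs, family, mode=mode
    )
    return dens[0, 0]  # (T, K)


def log_likelihood(model: HMMModel, sequence: Sequence[float]) -> float:
    """log P(sequence | model) by the scaled forward algorithm."""
    dens = _single_density(model, sequence)
    alpha = model.pi * dens[0]
    c0 = alpha.sum()
    ll = np.log(max(c0, _DENS_FLOOR))
    alpha = alpha / c0
    for t in range(1, dens.shape[0]):
        alpha = (alpha @ model.A) * dens[t]
        ct = alpha.sum()
        ll += np.log(max(ct, _DENS_FLOOR))
        alpha = alpha / ct
    return float(ll)


def viterbi_decode(model: HMMModel, sequence: Sequence[float]) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index."""
    dens = _single_density(model, sequence)
    logdens = np.log(np.maximum(dens, _DENS_FLOOR))
    with np.errstate(divide="ignore"):
        logpi = np.log(np.maximum(model.pi, _DENS_FLOOR))
        loga = np.log(np.maximum(model.A, _DENS_FLOOR))
    t_len, k = logdens.shape
    delta = logpi + logdens[0]
    psi = np.zeros((t_len, k), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + loga            # (from, to)
        psi[t] = np.argmax(cand, axis=0)        # first max -> lower index
        delta = cand[psi[t], np.arange(k)] + logdens[t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def canonical_order(means: np.ndarray) -> np.ndarray:
    """State ordering by descending emission mean (stable; ties keep raw order)."""
    return np.argsort(-np.asarray(means, dtype=float), kind="stable")


def label_states(model: HMMModel) -> LabeledHMM:
    """Order states by descending emission mean and attach motivational labels."""
    means = model.emission_means()
    order = canonical_order(means)
    sorted_means = means[order]
    gradient_valid = bool(np.all(np.diff(sorted_means) < 0))
    if model.n_states == 3:
        labels = STATE_LABELS_3
    else:
        labels = tuple(f"rank-{i}" for i in range(model.n_states))
    return LabeledHMM(
        model=model,
        state_order=tuple(int(i) for i in order),
        labels=labels,
        gradient_valid=gradient_valid,
        labeled_pi=model.pi[order],
        labeled_A=model.A[np.ix_(order, order)],
        labeled_means=sorted_means,
    )
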