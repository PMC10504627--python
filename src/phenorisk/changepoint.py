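"""Bayesian online change-point detection over daily-profile sequences.

A latent run length counts the exact number of days since the last
change point.  Each behavioral pattern (run) draws its own categorical
distribution over profiles from a Dirichlet prior, so the per-run
posterior predictive is Dirichlet-categorical.  The filter maintains
P(run length | data) day by day under a constant per-day hazard of
change.

Profile uncertainty: either average the recursion over sample paths
drawn from the per-day profile posterior (``n_profile_samples > 0``) or
run a single pass feeding the expected profile simplex
(``n_profile_samples = 0``).

Totally missing days are marginalized exactly: the observation factor
is 1 for every hypothesis, so the run-length row evolves by hazard
mixing alone and no predictive count is updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import spawn_rng

__all__ = [
    "BocpdConfig",
    "BocpdState",
    "RunLengthPosterior",
    "predictive_prob",
    "bocpd_step",
    "run_bocpd",
    "change_window_probability",
    "MISSING",
]

#: Sentinel observation for a totally missing day.
MISSING = None


@dataclass
class BocpdConfig:
    """Hazard, prior, and sampling settings for the run-length filter."""

    hazard: float = 1.0 / 60.0
    alpha: float | np.ndarray = 1.0
    n_profile_samples: int = 30
    seed: int = 0
    run_length_cap: int = 365

    def __post_init__(self):
        if not 0.0 < self.hazard < 1.0:
            raise ValueError(f"hazard must be in (0, 1), got {self.hazard}")
        if np.any(np.asarray(self.alpha, dtype=float) <= 0):
            raise ValueError("dirichlet alpha must be positive")
        if self.n_profile_samples < 0:
            raise ValueError("n_profile_samples must be >= 0")
        if self.run_length_cap < 1:
            raise ValueError("run_length_cap must be >= 1")

    def alpha_vector(self, n_profiles: int) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim == 0:
            return np.full(n_profiles, float(a))
        if a.shape != (n_profiles,):
            raise ValueError(f"alpha has shape {a.shape}, expected ({n_profiles},)")
        return a.copy()


@dataclass
class BocpdState:
    """Filter state after absorbing day ``t``.

    ``probs[r]`` = P(run length = r | data); ``counts[r]`` holds the
    per-profile observation counts accumulated by the hypothesis that
    the current run covers the last ``r + 1`` days (missing days add
    nothing).
    """

    probs: np.ndarray
    counts: np.ndarray

    @property
    def support(self) -> int:
        return len(self.probs)


@dataclass
class RunLengthPosterior:
    """Row ``t`` is P(run length at day t = r | days 0..t); zero beyond
    the attainable support min(t, cap)."""

    probs: np.ndarray

    @property
    def n_days(self) -> int:
        return self.probs.shape[0]

    def mode(self) -> np.ndarray:
        """Most probable run length per day."""
        return self.probs.argmax(axis=1)


def predictive_prob(run_length_counts: np.ndarray, alpha: np.ndarray, observation) -> float:
    """Dirichlet-categorical posterior predictive of one day's profile.

    With a profile label ``k``: (alpha_k + count_k) / (sum alpha + n).
    With a simplex vector: the simplex-weighted mixture of those values.
    """
    counts = np.asarray(run_length_counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    post = alpha + counts
    norm = post.sum(axis=-1)
    if np.isscalar(observation) or np.ndim(observation) == 0:
        return float(post[..., int(observation)] / norm)
    w = np.asarray(observation, dtype=float)
    return float((post @ w) / norm)


def _predictives(counts: np.ndarray, alpha: np.ndarray, observation) -> np.ndarray:
    """Vectorized predictive for every run-length hypothesis (L,K) counts."""
    post = alpha[None, :] + counts
    norm = post.sum(axis=1)
    if np.isscalar(observation) or np.ndim(observation) == 0:
        return post[:, int(observation)] / norm
    w = np.asarray(observation, dtype=float)
    return (post @ w) / norm


def _obs_vector(observation, n_profiles: int) -> np.ndarray:
    if np.isscalar(observation) or np.ndim(observation) == 0:
        v = np.zeros(n_profiles)
        v[int(observation)] = 1.0
        return v
    return np.asarray(observation, dtype=float)


def bocpd_step(state: BocpdState | None, observation, config: BocpdConfig,
               n_profiles: int | None = None) -> BocpdState:
    """One day of the growth/change recursion.

    ``observation`` is a profile label, a profile simplex, or
    :data:`MISSING` for a totally missing day.  ``state=None`` starts a
    record: the first day has run length 0 with probability 1.

    Growth mass for r+1 is prior_mass(r) * (1-h) * predictive under the
    r-run's counts; change mass (r=0) pools h * predictive under the
    bare prior, since a change means the day opens a fresh pattern.
    """
    h = config.hazard
    if state is None:
        if n_profiles is None and (observation is MISSING or np.ndim(observation) == 0):
            raise ValueError("n_profiles required to start a record from a label/missing day")
        K = n_profiles if n_profiles is not None else len(observation)
        config.alpha_vector(K)  # validate shape early
        counts = np.zeros((1, K))
        if observation is not MISSING:
            counts[0] = _obs_vector(observation, K)
        return BocpdState(probs=np.ones(1), counts=counts)

    K = state.counts.shape[1]
    alpha = config.alpha_vector(K)
    L = state.support
    if observation is MISSING:
        pred = np.ones(L)
        prior_pred = 1.0
    else:
        pred = _predictives(state.counts, alpha, observation)
        prior_pred = predictive_prob(np.zeros(K), alpha, observation)

    new = np.empty(L + 1)
    new[0] = h * prior_pred * state.probs.sum()
    new[1:] = state.probs * (1.0 - h) * pred

    new_counts = np.zeros((L + 1, K))
    new_counts[1:] = state.counts
    if observation is not MISSING:  # missing days never touch the counts
        new_counts += _obs_vector(observation, K)[None, :]

    cap = config.run_length_cap
    if len(new) > cap + 1:  # truncate beyond the cap and renormalize
        new = new[:cap + 1]
        new_counts = new_counts[:cap + 1]
    total = new.sum()
    if total <= 0:
        raise FloatingPointError("run-length posterior collapsed to zero mass")
    return BocpdState(probs=new / total, counts=new_counts)


def _single_pass(observations, config: BocpdConfig, n_profiles: int,
                 missing: np.ndarray) -> np.ndarray:
    T = len(observations)
    width = min(T, config.run_length_cap + 1)
    out = np.zeros((T, width))
    state: BocpdState | None = None
    for t in range(T):
        obs = MISSING if missing[t] else observations[t]
        state = bocpd_step(state, obs, config, n_profiles=n_profiles)
        out[t, :state.support] = state.probs
    return out


def run_bocpd(profile_posterior, config: BocpdConfig | None = None) -> RunLengthPosterior:
    """Run-length posterior for one patient's profile-posterior sequence.

    Accepts a :class:`~phenorisk.profiling.ProfilePosterior` or a bare
    (T, K) row-stochastic array (optionally with a ``missing`` boolean
    attribute marking totally missing days).

    With ``n_profile_samples = S > 0`` the filter is run over S label
    paths sampled from the per-day posteriors and the resulting
    run-length posteriors are averaged; with S = 0 a single pass feeds
    the expected profile simplex each day.  Deterministic given
    ``config.seed``.
    """
    config = config or BocpdConfig()
    probs = np.asarray(getattr(profile_posterior, "probs", profile_posterior), dtype=float)
    if probs.size == 0:
        return RunLengthPosterior(probs=np.zeros((0, 0)))
    T, K = probs.shape
    missing = np.asarray(
        getattr(profile_posterior, "missing", np.zeros(T, dtype=bool)), dtype=bool)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("profile posterior rows must lie on the simplex")

    S = config.n_profile_samples
    if S == 0:
        return RunLengthPosterior(_single_pass(list(probs), config, K, missing))

    rng = spawn_rng(config.seed)
    cum = probs.cumsum(axis=1)
    u = rng.random((S, T))
    labels = (u[:, :, None] > cum[None, :, :]).sum(axis=2)  # (S, T)
    width = min(T, config.run_length_cap + 1)
    acc = np.zeros((T, width))
    for s in range(S):
        acc += _single_pass(list(labels[s]), config, K, missing)
    return RunLengthPosterior(probs=acc / S)


def change_window_probability(rlp: RunLengthPosterior, w: int = 7) -> np.ndarray:
    """P(a change occurred within the previous ``w`` days) per day.

    A change in the last w days is exactly run length < w, so the value
    at day d is the run-length posterior mass below w.  Saturates at 1
    for days d < w.
    """
    if w <= 0:
        raise ValueError(f"window must be positive, got {w}")
    return rlp.probs[:, :w].sum(axis=1)
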