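"""Per-patient daily-profile models: heterogeneous mixtures with BIC.

Each day is a 192-dimensional mixed observation — 96 continuous
log-scale bins (distance, steps) and 96 binary bins (home, app).
Components factorize over dimensions (diagonal Gaussian x independent
Bernoulli), which makes marginalization of partially missing dimensions
exact: unobserved dimensions simply drop out of the per-component
likelihood product.  A day with (almost) nothing observed contributes a
constant likelihood to every component and its profile posterior equals
the mixture weights.

The number of profiles is selected per patient by BIC over K = 1..10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._utils import spawn_rng
from .preprocess import DailyFeatureMatrix

__all__ = [
    "HeterogeneousMixtureModel",
    "ProfilePosterior",
    "InsufficientDataError",
    "day_loglik",
    "em_fit",
    "bic_score",
    "select_profiles",
    "MAX_PROFILES",
    "VARIANCE_FLOOR",
    "BERNOULLI_EPS",
    "MIN_OBSERVED_FRACTION",
]

MAX_PROFILES = 10
VARIANCE_FLOOR = 1e-4
BERNOULLI_EPS = 1e-3
#: Days with fewer than this fraction of the 4x48 grid observed are
#: treated as totally missing for profiling.
MIN_OBSERVED_FRACTION = 0.1

_LOG_2PI = float(np.log(2.0 * np.pi))


class InsufficientDataError(ValueError):
    """Fewer usable (non-fully-missing) days than mixture components."""


@dataclass
class HeterogeneousMixtureModel:
    """K-component mixture over mixed continuous/binary daily vectors.

    ``cont_*`` arrays are (K, 96) with columns [distance bins, steps
    bins]; ``bern_probs`` is (K, 96) with columns [home bins, app bins].
    """

    weights: np.ndarray
    cont_means: np.ndarray
    cont_vars: np.ndarray
    bern_probs: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.cont_means = np.atleast_2d(np.asarray(self.cont_means, dtype=float))
        self.cont_vars = np.atleast_2d(np.asarray(self.cont_vars, dtype=float))
        self.bern_probs = np.atleast_2d(np.asarray(self.bern_probs, dtype=float))
        self.validate()

    def validate(self) -> None:
        K = self.n_components
        if not (1 <= K <= MAX_PROFILES):
            raise ValueError(f"K must be in [1, {MAX_PROFILES}], got {K}")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1 within 1e-9")
        if self.cont_means.shape != self.cont_vars.shape:
            raise ValueError("cont_means and cont_vars shapes differ")
        if np.any(self.cont_vars < VARIANCE_FLOOR * (1 - 1e-12)):
            raise ValueError(f"variances below floor {VARIANCE_FLOOR}")
        if np.any(self.bern_probs < BERNOULLI_EPS - 1e-12) or \
           np.any(self.bern_probs > 1 - BERNOULLI_EPS + 1e-12):
            raise ValueError("Bernoulli probabilities outside clip range")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_continuous(self) -> int:
        return self.cont_means.shape[1]

    @property
    def n_binary(self) -> int:
        return self.bern_probs.shape[1]

    @property
    def n_params(self) -> int:
        """Free parameters: (K-1) weights + per-component means,
        variances, and Bernoulli probabilities."""
        K = self.n_components
        return (K - 1) + K * (2 * self.n_continuous + self.n_binary)

    def permuted(self, order) -> "HeterogeneousMixtureModel":
        order = np.asarray(order)
        return HeterogeneousMixtureModel(
            weights=self.weights[order], cont_means=self.cont_means[order],
            cont_vars=self.cont_vars[order], bern_probs=self.bern_probs[order])

    def to_json(self) -> str:
        return json.dumps({
            "weights": self.weights.tolist(),
            "cont_means": self.cont_means.tolist(),
            "cont_vars": self.cont_vars.tolist(),
            "bern_probs": self.bern_probs.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "HeterogeneousMixtureModel":
        d = json.loads(text)
        return cls(weights=np.array(d["weights"]), cont_means=np.array(d["cont_means"]),
                   cont_vars=np.array(d["cont_vars"]), bern_probs=np.array(d["bern_probs"]))


@dataclass
class ProfilePosterior:
    """Per-day responsibilities over the selected profiles.

    ``probs`` is (n_days, K), each row on the simplex; ``missing`` marks
    days treated as totally missing (their rows equal the mixture
    weights exactly).
    """

    days: np.ndarray
    probs: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.missing is None:
            self.missing = np.zeros(self.probs.shape[0], dtype=bool)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1 within 1e-9")

    @property
    def n_days(self) -> int:
        return self.probs.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.probs.shape[1]

    def map_labels(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# design-matrix plumbing


def split_features(features: DailyFeatureMatrix):
    """(xc, mc, xb, mb): continuous values/mask (n, 96) and binary
    values/mask (n, 96), columns [distance|steps] and [home|app]."""
    xc = np.hstack([features.distance, features.steps])
    mc = np.hstack([features.mask[:, 0, :], features.mask[:, 2, :]])
    xb = np.hstack([features.home, features.app])
    mb = np.hstack([features.mask[:, 1, :], features.mask[:, 3, :]])
    return xc, mc, xb, mb


def _usable_days(mc: np.ndarray, mb: np.ndarray,
                 min_observed_frac: float = MIN_OBSERVED_FRACTION) -> np.ndarray:
    frac = (mc.sum(axis=1) + mb.sum(axis=1)) / (mc.shape[1] + mb.shape[1])
    return frac >= min_observed_frac


def _component_logliks(model: HeterogeneousMixtureModel, xc, mc, xb, mb) -> np.ndarray:
    """(n_days, K) log p(observed dims of day | component)."""
    mu, var, p = model.cont_means, model.cont_vars, model.bern_probs
    xc0 = np.where(mc, xc, 0.0)
    # Gaussian part, masked: sum over observed continuous dims
    diff2 = (xc0[:, None, :] - mu[None, :, :]) ** 2
    g = -0.5 * (_LOG_2PI + np.log(var)[None, :, :] + diff2 / var[None, :, :])
    ll = np.einsum("nkd,nd->nk", g, mc.astype(float))
    # Bernoulli part
    xb0 = np.where(mb, xb, 0.0)
    b = xb0[:, None, :] * np.log(p)[None, :, :] + (1 - xb0[:, None, :]) * np.log1p(-p)[None, :, :]
    ll += np.einsum("nkd,nd->nk", b, mb.astype(float))
    return ll


def day_loglik(model: HeterogeneousMixtureModel, day_features: dict | tuple,
               day_mask=None) -> np.ndarray:
    """Per-component log-likelihood of a single day.

    ``day_features`` may be ``(cont_values, bin_values)`` with
    ``day_mask = (cont_mask, bin_mask)``, or a dict with keys
    ``cont``/``binary`` and masks ``cont_mask``/``binary_mask``.
    Unobserved dimensions are marginalized out exactly; a fully missing
    day yields zeros for every component.
    """
    if isinstance(day_features, dict):
        xc = np.asarray(day_features["cont"], dtype=float)
        xb = np.asarray(day_features["binary"], dtype=float)
        mc = np.asarray(day_features.get("cont_mask", np.ones_like(xc)), dtype=bool)
        mb = np.asarray(day_features.get("binary_mask", np.ones_like(xb)), dtype=bool)
    else:
        xc, xb = (np.asarray(a, dtype=float) for a in day_features)
        if day_mask is None:
            mc, mb = np.ones_like(xc, dtype=bool), np.ones_like(xb, dtype=bool)
        else:
            mc, mb = (np.asarray(m, dtype=bool) for m in day_mask)
    return _component_logliks(model, xc[None], mc[None], xb[None], mb[None])[0]


def _responsibilities(model, xc, mc, xb, mb):
    """(resp (n,K), total observed-data loglik)."""
    ll = _component_logliks(model, xc, mc, xb, mb) + np.log(model.weights)[None, :]
    norm = logsumexp(ll, axis=1)
    return np.exp(ll - norm[:, None]), float(norm.sum())


# ---------------------------------------------------------------------------
# EM


def _m_step(resp, xc, mc, xb, mb, old: HeterogeneousMixtureModel | None = None):
    n, K = resp.shape
    w = resp.mean(axis=0)
    w = np.maximum(w, 1e-12)
    w /= w.sum()

    mcf = mc.astype(float)
    mbf = mb.astype(float)
    nk_c = resp.T @ mcf  # (K, C) effective counts per dim
    xc0 = np.where(mc, xc, 0.0)
    sums = resp.T @ xc0
    safe = np.maximum(nk_c, 1e-12)
    means = sums / safe
    sq = resp.T @ (xc0 ** 2)
    var = sq / safe - means ** 2
    if old is not None:  # dims a component never sees keep old params
        dead = nk_c < 1e-8
        means = np.where(dead, old.cont_means, means)
        var = np.where(dead, old.cont_vars, var)
    var = np.maximum(var, VARIANCE_FLOOR)

    nk_b = np.maximum(resp.T @ mbf, 1e-12)
    xb0 = np.where(mb, xb, 0.0)
    p = (resp.T @ xb0) / nk_b
    if old is not None:
        p = np.where(resp.T @ mbf < 1e-8, old.bern_probs, p)
    p = np.clip(p, BERNOULLI_EPS, 1 - BERNOULLI_EPS)
    return HeterogeneousMixtureModel(weights=w, cont_means=means, cont_vars=var, bern_probs=p)


def _kmeanspp_init(xc, mc, xb, mb, K, rng) -> HeterogeneousMixtureModel:
    """Seed from k-means++ on zero-imputed z-scores of all dims."""
    z_parts = []
    for x, m in ((xc, mc), (xb, mb)):
        mu = np.where(m.sum(0) > 0, np.where(m, x, 0).sum(0) / np.maximum(m.sum(0), 1), 0.0)
        sd = np.sqrt(np.maximum(
            np.where(m, (x - mu) ** 2, 0).sum(0) / np.maximum(m.sum(0), 1), 1e-6))
        z_parts.append(np.where(m, (x - mu) / sd, 0.0))
    z = np.hstack(z_parts)
    n = z.shape[0]
    centers = [int(rng.integers(n))]
    d2 = ((z - z[centers[0]]) ** 2).sum(axis=1)
    for _ in range(1, K):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        c = int(rng.choice(n, p=probs))
        centers.append(c)
        d2 = np.minimum(d2, ((z - z[c]) ** 2).sum(axis=1))
    assign = np.argmin(
        ((z[:, None, :] - z[centers][None, :, :]) ** 2).sum(axis=2), axis=1)
    resp = np.full((n, K), 0.01 / max(K - 1, 1))
    resp[np.arange(n), assign] = 0.99 if K > 1 else 1.0
    resp /= resp.sum(axis=1, keepdims=True)
    return _m_step(resp, xc, mc, xb, mb)


def em_fit(features: DailyFeatureMatrix, K: int, n_restarts: int = 5,
           tol: float = 1e-5, max_iter: int = 200, seed: int = 0,
           init_model: HeterogeneousMixtureModel | None = None,
           return_history: bool = False):
    """Maximum-likelihood EM fit of a K-component heterogeneous mixture.

    Days below the observed-fraction cutoff are excluded from fitting.
    The best of ``n_restarts`` k-means++-seeded runs is returned
    (deterministic given ``seed``); the observed-data log-likelihood is
    non-decreasing across iterations by construction.
    """
    xc, mc, xb, mb = split_features(features)
    usable = _usable_days(mc, mb)
    xc, mc, xb, mb = xc[usable], mc[usable], xb[usable], mb[usable]
    n = xc.shape[0]
    if n < K:
        raise InsufficientDataError(
            f"{n} usable day(s) but K={K} components requested")

    best = None
    best_ll = -np.inf
    best_hist: list[float] = []
    restarts = 1 if init_model is not None else n_restarts
    for r in range(restarts):
        rng = spawn_rng(seed, K, r)
        model = init_model if init_model is not None else _kmeanspp_init(xc, mc, xb, mb, K, rng)
        prev_ll = -np.inf
        history = []
        for _ in range(max_iter):
            resp, ll = _responsibilities(model, xc, mc, xb, mb)
            history.append(ll)
            if np.isfinite(prev_ll) and ll - prev_ll <= tol * abs(prev_ll):
                break
            prev_ll = ll
            model = _m_step(resp, xc, mc, xb, mb, old=model)
        _, final_ll = _responsibilities(model, xc, mc, xb, mb)
        if final_ll > best_ll:
            best, best_ll, best_hist = model, final_ll, history
    if return_history:
        return best, best_hist
    return best


def bic_score(model: HeterogeneousMixtureModel, features: DailyFeatureMatrix) -> float:
    """BIC = -2 loglik + n_params * log(n usable days); lower is better."""
    xc, mc, xb, mb = split_features(features)
    usable = _usable_days(mc, mb)
    _, ll = _responsibilities(model, xc[usable], mc[usable], xb[usable], mb[usable])
    n = int(usable.sum())
    return -2.0 * ll + model.n_params * float(np.log(n)) if n >= 1 else 0.0


def select_profiles(features: DailyFeatureMatrix, K_max: int = MAX_PROFILES,
                    n_restarts: int = 5, tol: float = 1e-5, max_iter: int = 200,
                    seed: int = 0):
    """Fit K = 1..K_max, keep the BIC-minimizing model, and return it
    with the per-day profile posterior (fully missing days get the
    mixture weights as their row)."""
    if not 1 <= K_max <= MAX_PROFILES:
        raise ValueError(f"K_max must be in [1, {MAX_PROFILES}], got {K_max}")
    xc, mc, xb, mb = split_features(features)
    usable = _usable_days(mc, mb)
    n_usable = int(usable.sum())
    if n_usable < 1:
        raise InsufficientDataError("no usable days")

    best_model, best_bic = None, np.inf
    for K in range(1, min(K_max, n_usable) + 1):
        model = em_fit(features, K, n_restarts=n_restarts, tol=tol,
                       max_iter=max_iter, seed=seed)
        bic = bic_score(model, features)
        if bic < best_bic:
            best_model, best_bic = model, bic

    probs = np.tile(best_model.weights, (features.n_days, 1))
    if n_usable:
        resp, _ = _responsibilities(best_model, xc[usable], mc[usable],
                                    xb[usable], mb[usable])
        probs[usable] = resp
    posterior = ProfilePosterior(days=features.days.copy(), probs=probs,
                                 missing=~usable)
    return best_model, posterior
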