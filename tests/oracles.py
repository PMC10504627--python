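"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the package's own code paths: exhaustive
enumeration for the run-length posterior, textbook spherical trig for
distances, and direct tallies for everything else.
"""

from itertools import product
from math import asin, cos, lgamma, log, radians, sin, sqrt

import numpy as np

ORACLE_EARTH_RADIUS_M = 6_371_000.0


def haversine_oracle_m(lat1, lon1, lat2, lon2):
    p1, l1, p2, l2 = map(radians, (lat1, lon1, lat2, lon2))
    a = sin((p2 - p1) / 2) ** 2 + cos(p1) * cos(p2) * sin((l2 - l1) / 2) ** 2
    return 2 * ORACLE_EARTH_RADIUS_M * asin(sqrt(a))


def runlength_posterior_oracle(labels, n_profiles, alpha, hazard, missing=None):
    """P(run length at the last day = r) by enumerating all 2^(T-1)
    segmentations with Dirichlet-categorical marginal likelihoods.

    ``labels[t]`` is the observed profile on day t; days flagged in
    ``missing`` contribute no likelihood and no counts but still extend
    run lengths.
    """
    T = len(labels)
    missing = list(missing) if missing is not None else [False] * T
    a = (np.full(n_profiles, float(alpha)) if np.ndim(alpha) == 0
         else np.asarray(alpha, dtype=float))

    def seg_loglik(days):
        counts = np.zeros(n_profiles)
        for d in days:
            if not missing[d]:
                counts[labels[d]] += 1
        n = counts.sum()
        ll = lgamma(a.sum()) - lgamma(a.sum() + n)
        ll += sum(lgamma(a[k] + counts[k]) - lgamma(a[k]) for k in range(n_profiles))
        return ll

    post: dict[int, float] = {}
    total = 0.0
    for bits in product([0, 1], repeat=T - 1):
        bounds = [0] + [t + 1 for t, b in enumerate(bits) if b] + [T]
        lp = sum(b * log(hazard) + (1 - b) * log(1 - hazard) for b in bits)
        lp += sum(seg_loglik(range(s, e)) for s, e in zip(bounds, bounds[1:]))
        w = np.exp(lp)
        r = T - bounds[-2] - 1
        post[r] = post.get(r, 0.0) + w
        total += w
    out = np.zeros(T)
    for r, v in post.items():
        out[r] = v / total
    return out


def hazard_only_runlength(T, hazard):
    """Closed-form run-length distribution with no data: geometric decay
    P(r) = h (1-h)^r for r < t and (1-h)^t at the ceiling r = t."""
    rows = np.zeros((T, T))
    for t in range(T):
        for r in range(t):
            rows[t, r] = hazard * (1 - hazard) ** r
        rows[t, t] = (1 - hazard) ** t
    return rows


def confusion_oracle(alarm_days, event_day, first_day, last_day, horizon=7):
    """Direct per-day tally of TP/FP/FN/TN over [first_day, last_day]."""
    tp = fp = fn = tn = 0
    alarm_days = set(alarm_days)
    for d in range(first_day, last_day + 1):
        positive = event_day is not None and d < event_day <= d + horizon
        if d in alarm_days and positive:
            tp += 1
        elif d in alarm_days:
            fp += 1
        elif positive:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
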