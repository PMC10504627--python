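"""Shared constants and small numeric helpers."""

from __future__ import annotations

import numpy as np

#: Number of half-hour bins in one day.
N_BINS = 48

#: Seconds per bin.
BIN_SECONDS = 1800

#: Daily feature variables, in canonical order.  Index into the
#: ``(day, variable, bin)`` mask of a feature matrix.
VARIABLES = ("distance", "home", "steps", "app")

#: Mean Earth radius in meters (spherical model).
EARTH_RADIUS_M = 6_371_000.0

#: Meters per degree of latitude under the spherical model above.
M_PER_DEG_LAT = EARTH_RADIUS_M * np.pi / 180.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between coordinate pairs (degrees).

    Vectorized over numpy-broadcastable inputs.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def spawn_rng(*keys) -> np.random.Generator:
    """Deterministic generator from an integer key path.

    Splittable seeding: ``spawn_rng(cohort_seed, patient_index, stage)``
    yields independent streams regardless of generation order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in keys]))
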