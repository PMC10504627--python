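"""Raw sensor streams to half-hourly daily feature matrices.

Each monitored day is summarized as four 48-dimensional vectors (one
component per 30-minute slot):

* ``distance`` — log1p of meters traveled, from differenced GPS traces;
* ``home``     — 1 if the patient was within the home radius at any point
  in the slot, else 0;
* ``steps``    — log1p of steps taken in the slot;
* ``app``      — 1 if any app was used in the slot, else 0.

Every variable carries a per-bin observed/missing mask.  Totally missing
days are preserved as all-missing rows — downstream change-point
inference needs to see them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import BIN_SECONDS, M_PER_DEG_LAT, N_BINS, VARIABLES, haversine_m

__all__ = [
    "GpsFix",
    "RawStream",
    "HomeLocation",
    "DailyFeatureMatrix",
    "PreprocessConfig",
    "HomeUndeterminableError",
    "infer_home",
    "bin_distance",
    "bin_home",
    "bin_steps",
    "bin_app_usage",
    "build_daily_features",
]


class HomeUndeterminableError(ValueError):
    """Raised when no night-time GPS fixes exist to locate home."""


@dataclass(frozen=True)
class GpsFix:
    timestamp: datetime
    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of [-90, 90]: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of [-180, 180]: {self.longitude}")


@dataclass
class RawStream:
    """Per-patient raw sensor log.

    ``gps_fixes``: GpsFix records; ``step_events``: (timestamp, count)
    pairs, zero counts acting as source heartbeats; ``app_events``:
    timestamps of app usage.  Timestamps must be non-decreasing within
    each list (naive, single local time zone per patient).
    """

    patient_id: str
    gps_fixes: list = field(default_factory=list)
    step_events: list = field(default_factory=list)
    app_events: list = field(default_factory=list)

    def validate(self) -> None:
        for name, ts in (
            ("gps_fixes", [f.timestamp for f in self.gps_fixes]),
            ("step_events", [t for t, _ in self.step_events]),
            ("app_events", list(self.app_events)),
        ):
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{name} timestamps are not non-decreasing")
        if any(c < 0 for _, c in self.step_events):
            raise ValueError("negative step count")

    @property
    def n_events(self) -> int:
        return len(self.gps_fixes) + len(self.step_events) + len(self.app_events)

    def all_timestamps(self):
        yield from (f.timestamp for f in self.gps_fixes)
        yield from (t for t, _ in self.step_events)
        yield from self.app_events


@dataclass(frozen=True)
class HomeLocation:
    latitude: float
    longitude: float
    support_nights: int

    def __post_init__(self):
        if self.support_nights < 1:
            raise ValueError("support_nights must be >= 1")


@dataclass
class PreprocessConfig:
    """Tunable preprocessing knobs (defaults are deliberate choices,
    not sourced from any external definition)."""

    night_start_hour: int = 0
    night_end_hour: int = 6
    home_grid_m: float = 50.0
    home_radius_m: float = 200.0


@dataclass
class DailyFeatureMatrix:
    """Half-hourly daily summaries for one patient.

    ``distance``/``steps`` are log1p-scale non-negative reals,
    ``home``/``app`` binary; all are ``(n_days, 48)``.  ``mask`` is
    ``(n_days, 4, 48)`` with ``True`` = observed, variables ordered as
    :data:`phenorisk._utils.VARIABLES`.
    """

    patient_id: str
    days: np.ndarray
    distance: np.ndarray
    home: np.ndarray
    steps: np.ndarray
    app: np.ndarray
    mask: np.ndarray
    start_date: date | None = None

    def __post_init__(self):
        n = len(self.days)
        for name in ("distance", "home", "steps", "app"):
            arr = getattr(self, name)
            if arr.shape != (n, N_BINS):
                raise ValueError(f"{name} must be (n_days, {N_BINS}), got {arr.shape}")
        if self.mask.shape != (n, len(VARIABLES), N_BINS):
            raise ValueError(f"mask must be (n_days, 4, {N_BINS}), got {self.mask.shape}")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def variable(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def fully_missing(self) -> np.ndarray:
        """Boolean (n_days,): no variable observed at all that day."""
        return ~self.mask.any(axis=(1, 2))

    def observed_fraction(self) -> np.ndarray:
        """Fraction of the 4x48 grid observed, per day."""
        return self.mask.mean(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: patient_id, day, variable, bin, value, observed."""
        rows = []
        for vi, var in enumerate(VARIABLES):
            vals = self.variable(var)
            obs = self.mask[:, vi, :]
            day_idx, bin_idx = np.indices(vals.shape)
            rows.append(pd.DataFrame({
                "patient_id": self.patient_id,
                "day": self.days[day_idx.ravel()],
                "variable": var,
                "bin": bin_idx.ravel(),
                "value": vals.ravel(),
                "observed": obs.ravel(),
            }))
        return pd.concat(rows, ignore_index=True).sort_values(
            ["day", "variable", "bin"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, patient_id: str | None = None) -> "DailyFeatureMatrix":
        if patient_id is not None:
            frame = frame[frame["patient_id"] == patient_id]
        elif frame["patient_id"].nunique() > 1:
            raise ValueError("frame holds multiple patients; pass patient_id")
        else:
            patient_id = str(frame["patient_id"].iloc[0])
        days = np.array(sorted(frame["day"].unique()), dtype=int)
        pos = {d: i for i, d in enumerate(days)}
        arrs = {v: np.zeros((len(days), N_BINS)) for v in VARIABLES}
        mask = np.zeros((len(days), len(VARIABLES), N_BINS), dtype=bool)
        vi = {v: i for i, v in enumerate(VARIABLES)}
        d = frame["day"].map(pos).to_numpy()
        b = frame["bin"].to_numpy(dtype=int)
        for var, sub in frame.groupby("variable"):
            di = sub["day"].map(pos).to_numpy()
            bi = sub["bin"].to_numpy(dtype=int)
            arrs[var][di, bi] = sub["value"].to_numpy(dtype=float)
            mask[di, vi[var], bi] = sub["observed"].to_numpy(dtype=bool)
        return cls(patient_id=patient_id, days=days, mask=mask, **arrs)


# ---------------------------------------------------------------------------
# home inference


def _night_dwell(fixes: Sequence[GpsFix], night_start: int, night_end: int):
    """(night fix, dwell seconds) pairs.

    Dwell of a fix is the time to the next fix in the full trace, capped
    at one bin; the final fix gets a nominal 5 minutes.
    """
    out = []
    for i, f in enumerate(fixes):
        if not night_start <= f.timestamp.hour < night_end:
            continue
        if i + 1 < len(fixes):
            gap = (fixes[i + 1].timestamp - f.timestamp).total_seconds()
            dwell = min(max(gap, 0.0), float(BIN_SECONDS))
        else:
            dwell = 300.0
        out.append((f, dwell))
    return out


def infer_home(gps_fixes: Sequence[GpsFix], config: PreprocessConfig | None = None) -> HomeLocation:
    """Home = dwell-weighted centroid of the densest night-time grid cell.

    Night fixes are binned on a ``home_grid_m`` square grid; the cell
    with the largest total dwell time wins (ties: earliest-observed
    cell).  Raises :class:`HomeUndeterminableError` with no night fixes.
    """
    config = config or PreprocessConfig()
    pairs = _night_dwell(gps_fixes, config.night_start_hour, config.night_end_hour)
    if not pairs:
        raise HomeUndeterminableError(
            f"no GPS fixes in night window "
            f"[{config.night_start_hour:02d}:00, {config.night_end_hour:02d}:00)")
    lat0 = float(np.mean([f.latitude for f, _ in pairs]))
    m_per_deg_lon = M_PER_DEG_LAT * math.cos(math.radians(lat0))
    cells: dict[tuple, dict] = {}
    for f, dwell in pairs:
        key = (math.floor(f.latitude * M_PER_DEG_LAT / config.home_grid_m),
               math.floor(f.longitude * m_per_deg_lon / config.home_grid_m))
        cell = cells.setdefault(key, {"dwell": 0.0, "first": f.timestamp, "fixes": []})
        cell["dwell"] += dwell
        cell["first"] = min(cell["first"], f.timestamp)
        cell["fixes"].append((f, dwell))
    best = min(cells.values(), key=lambda c: (-c["dwell"], c["first"]))
    w = np.array([d for _, d in best["fixes"]])
    w = w / w.sum() if w.sum() > 0 else np.full(len(w), 1.0 / len(w))
    lat = float(np.sum(w * [f.latitude for f, _ in best["fixes"]]))
    lon = float(np.sum(w * [f.longitude for f, _ in best["fixes"]]))
    nights = {f.timestamp.date() for f, _ in best["fixes"]}
    return HomeLocation(latitude=lat, longitude=lon, support_nights=len(nights))


# ---------------------------------------------------------------------------
# per-day binning


def _bin_of(ts: datetime) -> int:
    return (ts.hour * 3600 + ts.minute * 60 + ts.second) // BIN_SECONDS


def _fix_presence_mask(fixes: Sequence[GpsFix]) -> np.ndarray:
    mask = np.zeros(N_BINS, dtype=bool)
    for f in fixes:
        mask[_bin_of(f.timestamp)] = True
    return mask


def bin_distance(gps_fixes_for_day: Sequence[GpsFix], day: date | None = None,
                 prev_fix: GpsFix | None = None, next_fix: GpsFix | None = None):
    """48-bin log1p distance (m) plus observed mask for one day.

    Each consecutive-fix segment's haversine length is charged to the
    bin containing the segment midpoint in time; segments whose midpoint
    falls outside ``day`` are skipped.  ``prev_fix``/``next_fix`` give
    cross-midnight context.  A bin is observed iff it contains a fix.
    """
    fixes = list(gps_fixes_for_day)
    mask = _fix_presence_mask(fixes)
    values = np.zeros(N_BINS)
    if not fixes:
        return values, mask
    day = day or fixes[0].timestamp.date()
    seq = ([prev_fix] if prev_fix else []) + fixes + ([next_fix] if next_fix else [])
    meters = np.zeros(N_BINS)
    for a, b in zip(seq, seq[1:]):
        mid = a.timestamp + (b.timestamp - a.timestamp) / 2
        if mid.date() != day:
            continue
        meters[_bin_of(mid)] += haversine_m(a.latitude, a.longitude, b.latitude, b.longitude)
    values = np.log1p(meters)
    values[~mask] = 0.0
    return values, mask


def bin_home(gps_fixes_for_day: Sequence[GpsFix], home: HomeLocation,
             radius_m: float = 200.0):
    """Binary at-home indicator per bin: 1 iff any fix within radius."""
    fixes = list(gps_fixes_for_day)
    mask = _fix_presence_mask(fixes)
    values = np.zeros(N_BINS)
    for f in fixes:
        if haversine_m(f.latitude, f.longitude, home.latitude, home.longitude) <= radius_m:
            values[_bin_of(f.timestamp)] = 1.0
    return values, mask


def bin_steps(step_events_for_day: Sequence[tuple]):
    """48-bin log1p step counts.

    The whole day is observed iff the step source produced at least one
    event (zero-count heartbeats included); otherwise all-missing —
    distinguishing a still day from a dead sensor.
    """
    events = list(step_events_for_day)
    if any(c < 0 for _, c in events):
        raise ValueError("negative step count")
    if not events:
        return np.zeros(N_BINS), np.zeros(N_BINS, dtype=bool)
    counts = np.zeros(N_BINS)
    for ts, c in events:
        counts[_bin_of(ts)] += c
    return np.log1p(counts), np.ones(N_BINS, dtype=bool)


def bin_app_usage(app_events_for_day: Sequence[datetime], phone_alive: bool = True):
    """Binary app-usage indicator; observed iff the phone was alive that
    day (any sensor event — zero usage is a valid observation then)."""
    events = list(app_events_for_day)
    values = np.zeros(N_BINS)
    for ts in events:
        values[_bin_of(ts)] = 1.0
    alive = phone_alive or bool(events)
    mask = np.full(N_BINS, alive, dtype=bool)
    return values, mask


# ---------------------------------------------------------------------------
# full matrix


def build_daily_features(stream: RawStream, config: PreprocessConfig | None = None,
                         home: HomeLocation | None = None) -> DailyFeatureMatrix:
    """Compose the four binning operations over every calendar day from
    first to last observation (0-based day index from enrollment).

    If home inference fails the ``home`` variable is fully missing;
    totally silent days are kept as all-missing rows.
    """
    config = config or PreprocessConfig()
    stream.validate()
    all_ts = list(stream.all_timestamps())
    if not all_ts:
        return DailyFeatureMatrix(
            patient_id=stream.patient_id, days=np.array([], dtype=int),
            distance=np.zeros((0, N_BINS)), home=np.zeros((0, N_BINS)),
            steps=np.zeros((0, N_BINS)), app=np.zeros((0, N_BINS)),
            mask=np.zeros((0, len(VARIABLES), N_BINS), dtype=bool))
    start = min(all_ts).date()
    end = max(all_ts).date()
    n_days = (end - start).days + 1
    days = np.arange(n_days)

    if home is None:
        try:
            home = infer_home(stream.gps_fixes, config)
        except HomeUndeterminableError:
            home = None

    fixes_by_day: dict[int, list] = {}
    for f in stream.gps_fixes:
        fixes_by_day.setdefault((f.timestamp.date() - start).days, []).append(f)
    steps_by_day: dict[int, list] = {}
    for ts, c in stream.step_events:
        steps_by_day.setdefault((ts.date() - start).days, []).append((ts, c))
    apps_by_day: dict[int, list] = {}
    for ts in stream.app_events:
        apps_by_day.setdefault((ts.date() - start).days, []).append(ts)

    distance = np.zeros((n_days, N_BINS))
    home_arr = np.zeros((n_days, N_BINS))
    steps_arr = np.zeros((n_days, N_BINS))
    app_arr = np.zeros((n_days, N_BINS))
    mask = np.zeros((n_days, len(VARIABLES), N_BINS), dtype=bool)

    for d in range(n_days):
        day_date = start + timedelta(days=d)
        fixes = fixes_by_day.get(d, [])
        prev_f = fixes_by_day.get(d - 1, [])
        next_f = fixes_by_day.get(d + 1, [])
        dist, dist_m = bin_distance(fixes, day=day_date,
                                    prev_fix=prev_f[-1] if prev_f else None,
                                    next_fix=next_f[0] if next_f else None)
        distance[d], mask[d, 0] = dist, dist_m
        if home is not None:
            home_arr[d], mask[d, 1] = bin_home(fixes, home, config.home_radius_m)
        sev = steps_by_day.get(d, [])
        steps_arr[d], mask[d, 2] = bin_steps(sev)
        aev = apps_by_day.get(d, [])
        alive = bool(fixes or sev or aev)
        app_arr[d], mask[d, 3] = bin_app_usage(aev, phone_alive=alive)

    return DailyFeatureMatrix(patient_id=stream.patient_id, days=days,
                              distance=distance, home=home_arr, steps=steps_arr,
                              app=app_arr, mask=mask, start_date=start)
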