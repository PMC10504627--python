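"""Synthetic cohort generator: raw sensor streams with planted truth.

Each patient gets a piecewise-constant behavioral pattern: segments of
days sharing one distribution over latent daily profiles, separated by
planted change points.  Per day, a profile is drawn and the four
half-hourly variables are sampled from that profile's emission
parameters (Gaussian in log space for distance/steps, Bernoulli for
home/app).  The day is then rendered as a realistic raw stream — GPS
fixes every 5 simulated minutes around a fixed home coordinate, step
events, app events — whose half-hourly aggregation through the
preprocessing module reproduces the sampled values.

Risk events are temporally coupled to change points: a configurable
fraction of change points is followed, ``event_lag_days`` later, by an
event; an independent background rate plants events with no preceding
change.  Partial (per sensor source per day) and total (whole day)
missingness is injected by dropping raw observations, with the removals
recorded in the ground truth.

All randomness flows from splittable ``(cohort_seed, patient_index,
stage)`` seed paths, so outputs are byte-identical given the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
import numpy as np

from ._utils import BIN_SECONDS, M_PER_DEG_LAT, N_BINS, VARIABLES, spawn_rng
from .evaluation import EVENT_TYPES, RiskEvent
from .preprocess import DailyFeatureMatrix, GpsFix, RawStream

__all__ = [
    "ProfileEmission",
    "ScenarioConfig",
    "GroundTruth",
    "ScenarioError",
    "generate_patient",
    "generate_cohort",
    "generate_cohort_truths",
    "inject_missingness",
    "sample_ground_truth",
    "sample_feature_matrix",
    "two_profile_scenario",
    "weekly_inversion_segments",
]

# stream-rendering geometry
_FIX_INTERVAL_S = 300            # one GPS fix per 5 simulated minutes
_FIXES_PER_BIN = BIN_SECONDS // _FIX_INTERVAL_S
_AWAY_OFFSET_M = 320.0           # "away" excursions anchored here, east of home
_EPS_S = 0.5                     # boundary-fix offset around bin edges


class ScenarioError(ValueError):
    """A scenario config violates one of its invariants."""


def _as_bins(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(N_BINS, float(arr))
    if arr.shape != (N_BINS,):
        raise ScenarioError(f"{name} must be scalar or length-{N_BINS}, got {arr.shape}")
    return arr


@dataclass
class ProfileEmission:
    """Per-profile emission parameters for the 4 half-hourly variables.

    Continuous parameters are on the log1p scale the pipeline models;
    scalars broadcast to all 48 bins.
    """

    distance_log_mean: np.ndarray = 5.0
    distance_log_sd: np.ndarray = 0.3
    home_prob: np.ndarray = 0.5
    steps_log_mean: np.ndarray = 5.0
    steps_log_sd: np.ndarray = 0.3
    app_prob: np.ndarray = 0.5

    def __post_init__(self):
        self.distance_log_mean = _as_bins(self.distance_log_mean, "distance_log_mean")
        self.distance_log_sd = _as_bins(self.distance_log_sd, "distance_log_sd")
        self.home_prob = _as_bins(self.home_prob, "home_prob")
        self.steps_log_mean = _as_bins(self.steps_log_mean, "steps_log_mean")
        self.steps_log_sd = _as_bins(self.steps_log_sd, "steps_log_sd")
        self.app_prob = _as_bins(self.app_prob, "app_prob")
        for name in ("home_prob", "app_prob"):
            p = getattr(self, name)
            if np.any(p < 0) or np.any(p > 1):
                raise ScenarioError(f"{name} must lie in [0, 1]")
        for name in ("distance_log_sd", "steps_log_sd"):
            if np.any(getattr(self, name) < 0):
                raise ScenarioError(f"{name} must be non-negative")


@dataclass
class ScenarioConfig:
    """Cohort-level generative scenario.

    ``pattern_segments`` is a list of ``(start_day, profile_distribution)``
    pairs defining the piecewise-constant profile distribution; starts
    must be strictly increasing beginning at 0, each distribution sums
    to 1, and consecutive distributions must differ (segment starts > 0
    are exactly the planted change points).
    """

    n_patients: int = 1
    days_per_patient: int = 120
    n_true_profiles: int = 2
    profile_emission_params: list = field(default_factory=list)
    pattern_segments: list = field(default_factory=lambda: [(0, None)])
    event_lag_days: int = 3
    p_event_given_change: float = 0.6
    background_event_rate: float = 0.0
    attempt_fraction: float = 0.5
    partial_missing_rate: float = 0.0
    total_missing_rate: float = 0.0
    rng_seed: int = 0
    start_date: date = date(2021, 1, 4)
    home_latitude: float = 40.42
    home_longitude: float = -3.70

    def __post_init__(self):
        if not self.profile_emission_params:
            self.profile_emission_params = _default_profiles(self.n_true_profiles)
        if len(self.pattern_segments) == 1 and self.pattern_segments[0][1] is None:
            uniform = np.full(self.n_true_profiles, 1.0 / self.n_true_profiles)
            self.pattern_segments = [(0, uniform)]
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ScenarioError("n_patients must be >= 0")
        if self.days_per_patient < 0:
            raise ScenarioError("days_per_patient must be >= 0")
        if not 1 <= self.n_true_profiles <= 10:
            raise ScenarioError("n_true_profiles must be in [1, 10]")
        if len(self.profile_emission_params) != self.n_true_profiles:
            raise ScenarioError(
                f"need {self.n_true_profiles} profile_emission_params, "
                f"got {len(self.profile_emission_params)}")
        for rate_name in ("p_event_given_change", "background_event_rate",
                          "attempt_fraction", "partial_missing_rate",
                          "total_missing_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ScenarioError(f"{rate_name} must lie in [0, 1], got {r}")
        if self.event_lag_days < 0:
            raise ScenarioError("event_lag_days must be >= 0")
        starts = [s for s, _ in self.pattern_segments]
        if not starts or starts[0] != 0:
            raise ScenarioError("pattern_segments must start at day 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ScenarioError("pattern_segments start_days must be strictly increasing")
        prev = None
        for s, dist in self.pattern_segments:
            d = np.asarray(dist, dtype=float)
            if d.shape != (self.n_true_profiles,):
                raise ScenarioError(
                    f"profile_distribution at day {s} must have length {self.n_true_profiles}")
            if abs(d.sum() - 1.0) > 1e-9:
                raise ScenarioError(
                    f"profile_distribution at day {s} must sum to 1 within 1e-9")
            if np.any(d < 0):
                raise ScenarioError(f"profile_distribution at day {s} has negative mass")
            if prev is not None and np.allclose(d, prev):
                raise ScenarioError(
                    f"segment at day {s} repeats the previous profile_distribution "
                    "(would not be a change point)")
            prev = d

    @property
    def change_point_days(self) -> np.ndarray:
        return np.array([s for s, _ in self.pattern_segments
                         if 0 < s < self.days_per_patient], dtype=int)


#: Bins covering 00:00-06:00; scenario helpers keep patients home then
#: so night-based home inference is well-posed.
_NIGHT_BINS = slice(0, 12)


def _with_home_nights(day_home_prob: float, night_prob: float = 0.97) -> np.ndarray:
    p = np.full(N_BINS, float(day_home_prob))
    p[_NIGHT_BINS] = night_prob
    return p


def _default_profiles(n: int) -> list:
    """Evenly spread generic profiles, alternating activity levels."""
    out = []
    for k in range(n):
        lvl = k / max(n - 1, 1)
        out.append(ProfileEmission(
            distance_log_mean=3.0 + 5.0 * lvl, distance_log_sd=0.3,
            home_prob=_with_home_nights(0.9 - 0.8 * lvl),
            steps_log_mean=2.0 + 5.0 * lvl, steps_log_sd=0.3,
            app_prob=0.2 + 0.6 * lvl))
    return out


def two_profile_scenario(change_day: int | None = 60, days: int = 120,
                         high_first: bool = True, **kwargs) -> ScenarioConfig:
    """Well-separated home-body vs active profiles, optionally with a
    single planted change."""
    lo = ProfileEmission(distance_log_mean=2.5, distance_log_sd=0.25,
                         home_prob=_with_home_nights(0.92),
                         steps_log_mean=2.0, steps_log_sd=0.25, app_prob=0.75)
    hi = ProfileEmission(distance_log_mean=8.0, distance_log_sd=0.25,
                         home_prob=_with_home_nights(0.12),
                         steps_log_mean=7.0, steps_log_sd=0.25, app_prob=0.25)
    d_a = np.array([0.15, 0.85]) if high_first else np.array([0.85, 0.15])
    d_b = d_a[::-1].copy()
    segments = [(0, d_a)] if change_day is None else [(0, d_a), (change_day, d_b)]
    return ScenarioConfig(days_per_patient=days, n_true_profiles=2,
                          profile_emission_params=[lo, hi],
                          pattern_segments=segments, **kwargs)


def weekly_inversion_segments(change_day: int = 60):
    """5:2 high/low-activity weekly mix that suddenly inverts to 2:5
    (profile 0 = low activity, profile 1 = high activity)."""
    before = np.array([2.0 / 7.0, 5.0 / 7.0])
    after = np.array([5.0 / 7.0, 2.0 / 7.0])
    return [(0, before), (change_day, after)]


@dataclass
class GroundTruth:
    """Planted latent state for one synthetic patient.

    ``missing`` is (n_days, 4) with True = removed from the raw stream,
    variables ordered as :data:`phenorisk._utils.VARIABLES`.
    """

    patient_id: str
    profile_labels: np.ndarray
    change_point_days: np.ndarray
    events: list
    missing: np.ndarray

    def __post_init__(self):
        n = len(self.profile_labels)
        if np.any((self.change_point_days < 1) | (self.change_point_days >= max(n, 1))):
            raise ValueError("change_point_days must lie in [1, days_per_patient)")

    @property
    def n_days(self) -> int:
        return len(self.profile_labels)

    @property
    def event_days(self) -> np.ndarray:
        return np.array([e.day for e in self.events], dtype=int)


def _patient_id(index: int) -> str:
    return f"P{index:04d}"


def sample_ground_truth(config: ScenarioConfig, patient_index: int) -> GroundTruth:
    """Latent labels, change points, and risk events for one patient
    (missing mask left all-False; filled by :func:`inject_missingness`)."""
    config.validate()
    rng = spawn_rng(config.rng_seed, patient_index, 0)
    D = config.days_per_patient
    labels = np.zeros(D, dtype=int)
    bounds = [s for s, _ in config.pattern_segments] + [D]
    for (s, dist), e in zip(config.pattern_segments, bounds[1:]):
        if s >= D:
            break
        e = min(e, D)
        labels[s:e] = rng.choice(config.n_true_profiles, size=e - s,
                                 p=np.asarray(dist, dtype=float))
    cps = config.change_point_days

    pid = _patient_id(patient_index)
    events: list[RiskEvent] = []
    for cp in cps:
        ev_day = cp + config.event_lag_days
        if ev_day < D and rng.random() < config.p_event_given_change:
            events.append(RiskEvent(pid, int(ev_day), _event_type(rng, config)))
    if config.background_event_rate > 0:
        hits = np.flatnonzero(rng.random(D) < config.background_event_rate)
        taken = {e.day for e in events}
        for d in hits:
            if int(d) not in taken:
                events.append(RiskEvent(pid, int(d), _event_type(rng, config)))
    events.sort(key=lambda e: e.day)
    return GroundTruth(patient_id=pid, profile_labels=labels,
                       change_point_days=cps, events=events,
                       missing=np.zeros((D, len(VARIABLES)), dtype=bool))


def _event_type(rng, config) -> str:
    return EVENT_TYPES[0] if rng.random() < config.attempt_fraction else EVENT_TYPES[1]


def _sample_emissions(config: ScenarioConfig, labels: np.ndarray, rng):
    """Feature-space draws per (day, bin) given latent profiles."""
    D = len(labels)
    prof = config.profile_emission_params
    dist_mu = np.array([prof[z].distance_log_mean for z in labels])
    dist_sd = np.array([prof[z].distance_log_sd for z in labels])
    step_mu = np.array([prof[z].steps_log_mean for z in labels])
    step_sd = np.array([prof[z].steps_log_sd for z in labels])
    home_p = np.array([prof[z].home_prob for z in labels])
    app_p = np.array([prof[z].app_prob for z in labels])
    if D == 0:
        shape = (0, N_BINS)
        z = np.zeros(shape)
        return {"distance": z, "home": z.copy(), "steps": z.copy(), "app": z.copy()}
    return {
        "distance": np.maximum(rng.normal(dist_mu, dist_sd), 0.0),
        "home": (rng.random((D, N_BINS)) < home_p).astype(float),
        "steps": np.maximum(rng.normal(step_mu, step_sd), 0.0),
        "app": (rng.random((D, N_BINS)) < app_p).astype(float),
    }


def sample_feature_matrix(config: ScenarioConfig, patient_index: int):
    """(DailyFeatureMatrix, GroundTruth) sampled directly in feature
    space — same emission draws as :func:`generate_patient`, skipping
    the raw-stream rendering round trip.  Missingness is applied to the
    mask only."""
    truth = sample_ground_truth(config, patient_index)
    rng = spawn_rng(config.rng_seed, patient_index, 1)
    emis = _sample_emissions(config, truth.profile_labels, rng)
    missing = _sample_missing_plan(config, patient_index, truth.n_days)
    truth.missing = missing
    D = truth.n_days
    mask = np.ones((D, len(VARIABLES), N_BINS), dtype=bool)
    for vi in range(len(VARIABLES)):
        mask[missing[:, vi], vi, :] = False
    features = DailyFeatureMatrix(
        patient_id=truth.patient_id, days=np.arange(D),
        distance=emis["distance"], home=emis["home"],
        steps=emis["steps"], app=emis["app"], mask=mask,
        start_date=config.start_date)
    return features, truth


def _sample_missing_plan(config: ScenarioConfig, patient_index: int, n_days: int) -> np.ndarray:
    """(n_days, 4) True = missing.  Total missingness wipes the whole
    day; partial missingness hits per sensor source (GPS drives both
    distance and home; app-only dropout is unobservable, so partial
    missingness applies to the GPS and step sources)."""
    rng = spawn_rng(config.rng_seed, patient_index, 2)
    missing = np.zeros((n_days, len(VARIABLES)), dtype=bool)
    if n_days == 0:
        return missing
    total = rng.random(n_days) < config.total_missing_rate
    gps_out = rng.random(n_days) < config.partial_missing_rate
    steps_out = rng.random(n_days) < config.partial_missing_rate
    missing[total] = True
    missing[gps_out, 0] = True   # distance
    missing[gps_out, 1] = True   # home
    missing[steps_out, 2] = True
    return missing


# ---------------------------------------------------------------------------
# raw-stream rendering


def _render_stream(config: ScenarioConfig, patient_index: int,
                   emissions: dict) -> RawStream:
    """Deterministically render feature-space draws as raw sensor logs.

    The GPS trajectory is planned so that, under midpoint segment
    assignment and log1p binning, each bin's aggregated distance matches
    its sampled value: zig-zag walks around the home coordinate (home
    bins) or an away anchor offset east (away bins), with transition
    jumps charged to the away-state bin and compensated in its walk
    budget.  Step counts are spread over 5-minute heartbeat events
    (zero counts included); app usage emits one event per active bin.
    """
    pid = _patient_id(patient_index)
    D = emissions["distance"].shape[0]
    home_lat = config.home_latitude + 0.01 * (patient_index % 97)
    home_lon = config.home_longitude + 0.01 * (patient_index // 97 % 97)
    m_per_deg_lon = M_PER_DEG_LAT * math.cos(math.radians(home_lat))
    away_dlon = _AWAY_OFFSET_M / m_per_deg_lon

    at_home = emissions["home"].reshape(-1).astype(bool)      # (D*48,)
    dist_m = np.expm1(emissions["distance"].reshape(-1))
    n_bins = D * N_BINS
    t0 = datetime.combine(config.start_date, time.min)

    gps: list[GpsFix] = []
    steps_ev: list[tuple] = []
    app_ev: list[datetime] = []

    def pos(i: int, north_m: float) -> tuple:
        lat = home_lat + north_m / M_PER_DEG_LAT
        lon = home_lon if at_home[i] else home_lon + away_dlon
        return lat, lon

    for i in range(n_bins):
        bin_start = t0 + timedelta(seconds=i * BIN_SECONDS)
        prev_state = at_home[i - 1] if i > 0 else None
        next_state = at_home[i + 1] if i + 1 < n_bins else None
        E_in = _AWAY_OFFSET_M if (prev_state is True and not at_home[i]) else 0.0
        target = dist_m[i]
        n_seg_internal = _FIXES_PER_BIN - 1  # 5 segments between the 6 fixes

        if at_home[i]:
            # charged: 5 internal + outbound of length delta (same-state
            # hop or hop to the pre-transition boundary fix)
            delta = target / (n_seg_internal + 1) if next_state is not None else \
                target / n_seg_internal if n_seg_internal else 0.0
        else:
            if next_state is None:
                delta = max((target - E_in) / n_seg_internal, 0.0)
            elif next_state == at_home[i]:
                delta = max((target - E_in) / (n_seg_internal + 1), 0.0)
            else:  # away -> home jump charged here; refine sqrt term twice
                delta = max((target - E_in - _AWAY_OFFSET_M) / n_seg_internal, 0.0)
                for _ in range(2):
                    jump = math.hypot(_AWAY_OFFSET_M, delta)
                    delta = max((target - E_in - jump) / n_seg_internal, 0.0)

        first_offset = _EPS_S if E_in else 0.0
        for k in range(_FIXES_PER_BIN):
            ts = bin_start + timedelta(seconds=k * _FIX_INTERVAL_S + (first_offset if k == 0 else 0))
            north = delta if k % 2 == 1 else 0.0
            lat, lon = pos(i, north)
            gps.append(GpsFix(ts, lat, lon))
        if next_state is not None and at_home[i] and next_state is False:
            # pre-transition boundary fix at the home anchor, so the
            # home->away jump's midpoint lands in the away bin
            ts = bin_start + timedelta(seconds=BIN_SECONDS - _EPS_S)
            lat, lon = pos(i, 0.0)
            gps.append(GpsFix(ts, lat, lon))

    step_counts = np.round(np.expm1(emissions["steps"])).astype(int)
    for d in range(D):
        for b in range(N_BINS):
            bin_start = t0 + timedelta(days=d, seconds=b * BIN_SECONDS)
            c = int(step_counts[d, b])
            base, rem = divmod(c, _FIXES_PER_BIN)
            for k in range(_FIXES_PER_BIN):
                ts = bin_start + timedelta(seconds=k * _FIX_INTERVAL_S + 1)
                steps_ev.append((ts, base + (rem if k == 0 else 0)))
            if emissions["app"][d, b] > 0:
                app_ev.append(bin_start + timedelta(seconds=720))

    return RawStream(patient_id=pid, gps_fixes=gps, step_events=steps_ev,
                     app_events=app_ev)


def inject_missingness(stream: RawStream, config: ScenarioConfig,
                       patient_index: int = 0,
                       plan: np.ndarray | None = None):
    """Drop raw observations per the missingness plan.

    Returns ``(stream, missing_mask)`` with the removals recorded as a
    (n_days, 4) True-=-missing mask.  Totally missing days lose every
    sensor; partial missingness removes whole sensor-source days (GPS
    removal blanks both distance and home).  Rates of 0 leave the
    stream untouched.
    """
    all_ts = list(stream.all_timestamps())
    if not all_ts:
        return stream, np.zeros((0, len(VARIABLES)), dtype=bool)
    start = min(all_ts).date()
    n_days = (max(all_ts).date() - start).days + 1
    if plan is None:
        plan = _sample_missing_plan(config, patient_index, n_days)

    def day_of(ts: datetime) -> int:
        return (ts.date() - start).days

    def keep(ts: datetime, vi: int) -> bool:
        d = day_of(ts)
        return not (0 <= d < n_days and plan[d, vi])

    out = RawStream(
        patient_id=stream.patient_id,
        gps_fixes=[f for f in stream.gps_fixes if keep(f.timestamp, 0)],
        step_events=[e for e in stream.step_events if keep(e[0], 2)],
        app_events=[t for t in stream.app_events if keep(t, 3)],
    )
    return out, plan.copy()


def generate_patient(config: ScenarioConfig, patient_index: int):
    """(RawStream, GroundTruth) for one patient.

    The stream's half-hourly aggregation reproduces the latent
    profile's emission parameters in expectation; the ground truth
    records labels, change points, events, and injected missingness.
    """
    config.validate()
    truth = sample_ground_truth(config, patient_index)
    rng = spawn_rng(config.rng_seed, patient_index, 1)
    emis = _sample_emissions(config, truth.profile_labels, rng)
    stream = _render_stream(config, patient_index, emis)
    plan = _sample_missing_plan(config, patient_index, truth.n_days)
    stream, missing = inject_missingness(stream, config, patient_index, plan=plan)
    if missing.shape[0]:
        truth.missing = missing
    return stream, truth


def generate_cohort(config: ScenarioConfig):
    """All patients' (RawStream, GroundTruth) pairs; deterministic given
    ``config.rng_seed`` with per-patient splittable seeding."""
    return [generate_patient(config, i) for i in range(config.n_patients)]


def generate_cohort_truths(config: ScenarioConfig):
    """Ground truths only (fast path: no raw-stream rendering)."""
    out = []
    for i in range(config.n_patients):
        truth = sample_ground_truth(config, i)
        truth.missing = _sample_missing_plan(config, i, truth.n_days)
        out.append(truth)
    return out
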