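"""Plain-text readers/writers for every pipeline artifact.

Raw streams travel as JSONL (one record per sensor observation), all
tabular artifacts as CSV, models as JSON, configs as YAML or JSON.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .evaluation import RiskEvent, RocResult
from .preprocess import DailyFeatureMatrix, GpsFix, RawStream
from .profiling import ProfilePosterior
from .synthetic import GroundTruth

__all__ = [
    "write_stream_jsonl", "read_streams_jsonl",
    "write_features_csv", "read_features_csv",
    "write_truth_csv", "write_events_csv", "read_events_csv",
    "write_posterior_csv", "read_posterior_csv",
    "write_runlength_csv", "write_series_csv", "read_series_csv",
    "write_roc", "load_config_file",
]

_ISO = "%Y-%m-%dT%H:%M:%S.%f"


def write_stream_jsonl(streams: Iterable[RawStream], path) -> None:
    with open(path, "w") as fh:
        for s in streams:
            for f in s.gps_fixes:
                fh.write(json.dumps({
                    "patient_id": s.patient_id, "t": f.timestamp.strftime(_ISO),
                    "sensor": "gps",
                    "payload": {"lat": f.latitude, "lon": f.longitude}}) + "\n")
            for ts, c in s.step_events:
                fh.write(json.dumps({
                    "patient_id": s.patient_id, "t": ts.strftime(_ISO),
                    "sensor": "steps", "payload": {"steps": int(c)}}) + "\n")
            for ts in s.app_events:
                fh.write(json.dumps({
                    "patient_id": s.patient_id, "t": ts.strftime(_ISO),
                    "sensor": "app", "payload": {}}) + "\n")


def read_streams_jsonl(path) -> list[RawStream]:
    by_pid: dict[str, RawStream] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            s = by_pid.setdefault(rec["patient_id"], RawStream(patient_id=rec["patient_id"]))
            ts = datetime.strptime(rec["t"], _ISO)
            if rec["sensor"] == "gps":
                s.gps_fixes.append(GpsFix(ts, rec["payload"]["lat"], rec["payload"]["lon"]))
            elif rec["sensor"] == "steps":
                s.step_events.append((ts, rec["payload"]["steps"]))
            elif rec["sensor"] == "app":
                s.app_events.append(ts)
            else:
                raise ValueError(f"unknown sensor {rec['sensor']!r}")
    streams = list(by_pid.values())
    for s in streams:
        s.gps_fixes.sort(key=lambda f: f.timestamp)
        s.step_events.sort(key=lambda e: e[0])
        s.app_events.sort()
    return streams


def write_features_csv(features: Iterable[DailyFeatureMatrix], path) -> None:
    pd.concat([f.to_frame() for f in features], ignore_index=True).to_csv(path, index=False)


def read_features_csv(path) -> list[DailyFeatureMatrix]:
    frame = pd.read_csv(path)
    return [DailyFeatureMatrix.from_frame(frame, patient_id=pid)
            for pid in sorted(frame["patient_id"].unique())]


def write_truth_csv(truths: Iterable[GroundTruth], path) -> None:
    rows = []
    for t in truths:
        for d in range(t.n_days):
            rows.append({
                "patient_id": t.patient_id, "day": d,
                "profile": int(t.profile_labels[d]),
                "is_change_point": bool(d in set(t.change_point_days.tolist())),
                "missing_distance": bool(t.missing[d, 0]),
                "missing_home": bool(t.missing[d, 1]),
                "missing_steps": bool(t.missing[d, 2]),
                "missing_app": bool(t.missing[d, 3]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_events_csv(events: Iterable[RiskEvent], path) -> None:
    pd.DataFrame([{"patient_id": e.patient_id, "day": e.day, "type": e.type}
                  for e in events]).to_csv(path, index=False)


def read_events_csv(path) -> list[RiskEvent]:
    frame = pd.read_csv(path)
    if frame.empty:
        return []
    return [RiskEvent(str(r.patient_id), int(r.day), str(r.type))
            for r in frame.itertuples(index=False)]


def write_posterior_csv(posteriors: Mapping[str, ProfilePosterior], path) -> None:
    rows = []
    for pid, post in posteriors.items():
        for i, day in enumerate(post.days):
            for k in range(post.n_profiles):
                rows.append({"patient_id": pid, "day": int(day), "profile": k,
                             "probability": float(post.probs[i, k]),
                             "missing": bool(post.missing[i])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_posterior_csv(path) -> dict[str, ProfilePosterior]:
    frame = pd.read_csv(path)
    out = {}
    for pid, sub in frame.groupby("patient_id"):
        days = np.array(sorted(sub["day"].unique()))
        K = int(sub["profile"].max()) + 1
        probs = np.zeros((len(days), K))
        missing = np.zeros(len(days), dtype=bool)
        pos = {d: i for i, d in enumerate(days)}
        for r in sub.itertuples(index=False):
            probs[pos[r.day], int(r.profile)] = r.probability
            missing[pos[r.day]] = bool(r.missing)
        out[str(pid)] = ProfilePosterior(days=days, probs=probs, missing=missing)
    return out


def write_runlength_csv(rlps: Mapping[str, "np.ndarray"], path,
                        min_prob: float = 1e-12) -> None:
    """Sparse long format (patient_id, day, run_length, probability)."""
    rows = []
    for pid, rlp in rlps.items():
        probs = getattr(rlp, "probs", rlp)
        for t in range(probs.shape[0]):
            nz = np.flatnonzero(probs[t] > min_prob)
            for r in nz:
                rows.append({"patient_id": pid, "day": t, "run_length": int(r),
                             "probability": float(probs[t, r])})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_series_csv(series_by_patient: Mapping[str, "np.ndarray"], path,
                     value_name: str = "change_probability") -> None:
    rows = []
    for pid, series in series_by_patient.items():
        for d, v in enumerate(np.asarray(series, dtype=float)):
            rows.append({"patient_id": pid, "day": d, value_name: float(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_series_csv(path, value_name: str = "change_probability") -> dict[str, np.ndarray]:
    frame = pd.read_csv(path)
    return {str(pid): sub.sort_values("day")[value_name].to_numpy()
            for pid, sub in frame.groupby("patient_id")}


def write_roc(roc: RocResult, csv_path, json_path=None) -> None:
    pd.DataFrame(roc.to_records()).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(
            {"auc": roc.auc, "n_thresholds": len(roc.thresholds)}, indent=2))


def load_config_file(path) -> dict:
    """YAML or JSON config file (YAML is a JSON superset here)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
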