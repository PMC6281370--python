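"""Plain-text session interchange.

A session directory holds:

* ``emg_<channel>.csv``   — column ``amplitude`` (fixed rate declared in the
  sidecar) or ``time_s,amplitude``;
* ``spikes.csv``          — ``unit_id,structure,time_s``;
* ``events.csv``          — ``label,time_s``;
* ``states.csv``          — ``start_s,end_s,label`` (optional);
* ``session.json``        — id, duration, group, per-channel rate/t0/
  rectified flags, provenance notes;
* ``ground_truth/``       — same formats, for synthetic sessions.

All times are seconds written with six fractional digits; intervals are
half-open [start, end). Reading validates every data-model invariant and
rejects (never silently repairs) unsorted inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    AnalysisConfig,
    Bout,
    EventTrain,
    FormatError,
    SampledSignal,
    Session,
    SpikeTrain,
    StateIntervals,
    ValidationError,
)
from .synthetic import SyntheticGroundTruth, UnitSpec

__all__ = ["read_session", "write_session", "load_config", "save_config"]

_TIME_FMT = "%.6f"


def save_config(config: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> AnalysisConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError:
        raise FormatError(f"config file not found: {path}")
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} is not a mapping")
    return AnalysisConfig.from_dict(data)


def _read_csv(path: Path, required: List[str]) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing mandatory file: {path.name}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    return df


def write_session(session: Session, path, overwrite: bool = False) -> dict:
    """Write a session directory; returns a manifest of files written."""
    out = Path(path)
    sidecar = out / "session.json"
    if sidecar.exists() and not overwrite:
        raise FileExistsError(
            f"{out} already holds a session (pass overwrite=True to replace)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"files": [], "omitted": []}

    channels = {}
    for sig in session.emg:
        name = f"emg_{sig.channel}.csv"
        pd.DataFrame({"amplitude": sig.samples}).to_csv(
            out / name, index=False, float_format="%.6g")
        channels[sig.channel] = {
            "rate": sig.rate, "t0": sig.t0, "rectified": sig.rectified}
        manifest["files"].append(name)

    rows = [(st.unit_id, st.structure, t)
            for st in session.spikes for t in st.times]
    units_meta = {st.unit_id: {"structure": st.structure,
                               "quality_flags": list(st.quality_flags)}
                  for st in session.spikes}
    pd.DataFrame(rows, columns=["unit_id", "structure", "time_s"]).to_csv(
        out / "spikes.csv", index=False, float_format=_TIME_FMT)
    manifest["files"].append("spikes.csv")

    ev_rows = [(ev.label, t) for ev in session.events for t in ev.times]
    pd.DataFrame(ev_rows, columns=["label", "time_s"]).to_csv(
        out / "events.csv", index=False, float_format=_TIME_FMT)
    manifest["files"].append("events.csv")

    if session.states is not None:
        _write_states(session.states, out / "states.csv")
        manifest["files"].append("states.csv")
    else:
        manifest["omitted"].append("states.csv")

    meta = {
        "id": session.id,
        "duration_s": session.duration,
        "group": session.group,
        "channels": channels,
        "units": units_meta,
        "event_labels": [ev.label for ev in session.events],
        "threshold_used": (session.states.threshold_used
                           if session.states is not None else None),
        "provenance": "written by precereb.session_io",
    }
    gt = session.ground_truth
    if gt is not None:
        gtdir = out / "ground_truth"
        gtdir.mkdir(exist_ok=True)
        _write_states(gt.true_states, gtdir / "states.csv")
        ev_rows = [(tr.label, t) for tr in gt.true_twitches.values()
                   for t in tr.times]
        ev_rows += [("wake_onset", t) for t in gt.true_wake_onsets.times]
        pd.DataFrame(ev_rows, columns=["label", "time_s"]).to_csv(
            gtdir / "events.csv", index=False, float_format=_TIME_FMT)
        specs = [{"unit_id": u.unit_id, "archetype": u.archetype,
                  "base_rate_by_state": u.base_rate_by_state,
                  "event_kernels": [list(k) for k in u.event_kernels],
                  "plateau": list(u.plateau) if u.plateau else None,
                  "trigger_muscle": u.trigger_muscle,
                  "structure": u.structure}
                 for u in gt.unit_specs]
        (gtdir / "unit_specs.json").write_text(json.dumps(
            {"atonia_baseline": gt.atonia_baseline, "unit_specs": specs},
            indent=2))
        manifest["files"] += ["ground_truth/states.csv",
                              "ground_truth/events.csv",
                              "ground_truth/unit_specs.json"]
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    manifest["files"].append("session.json")
    return manifest


def _write_states(states: StateIntervals, path: Path) -> None:
    rows = [(b.start, b.end, b.label) for b in states.intervals]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]).to_csv(
        path, index=False, float_format=_TIME_FMT)


def _read_states(path: Path, threshold: Optional[float]) -> StateIntervals:
    df = _read_csv(path, ["start_s", "end_s", "label"])
    return StateIntervals(
        tuple(Bout(float(r.start_s), float(r.end_s), str(r.label))
              for r in df.itertuples()),
        threshold_used=threshold)


def read_session(path, config: Optional[AnalysisConfig] = None) -> Session:
    """Read and fully validate a session directory.

    Out-of-order spike or event times raise a :class:`ValidationError`
    naming the offending record; missing mandatory files raise
    :class:`FormatError`.
    """
    src = Path(path)
    sidecar = src / "session.json"
    if not sidecar.exists():
        raise FormatError(f"missing mandatory file: session.json in {src}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"session.json is not valid JSON: {e}")
    for key in ("id", "duration_s", "channels"):
        if key not in meta:
            raise FormatError(f"session.json: missing key {key!r}")
    duration = float(meta["duration_s"])

    emg = []
    for channel, info in meta["channels"].items():
        p = src / f"emg_{channel}.csv"
        df = _read_csv(p, ["amplitude"])
        emg.append(SampledSignal(
            channel=channel, rate=float(info["rate"]),
            samples=df["amplitude"].to_numpy(),
            t0=float(info.get("t0", 0.0)),
            rectified=bool(info.get("rectified", False))))

    sp = _read_csv(src / "spikes.csv", ["unit_id", "structure", "time_s"])
    spikes = []
    units_meta = meta.get("units", {})
    for unit_id, grp in sp.groupby("unit_id", sort=True):
        info = units_meta.get(str(unit_id), {})
        structure = (info.get("structure")
                     or (str(grp["structure"].iloc[0]) if len(grp) else "other"))
        spikes.append(SpikeTrain(
            unit_id=str(unit_id), times=grp["time_s"].to_numpy(),
            structure=structure,
            quality_flags=tuple(info.get("quality_flags", ()))))
    for unit_id in units_meta:       # units may legitimately have zero spikes
        if unit_id not in set(sp["unit_id"].astype(str)):
            info = units_meta[unit_id]
            spikes.append(SpikeTrain(
                unit_id=unit_id, times=np.empty(0),
                structure=info.get("structure", "other"),
                quality_flags=tuple(info.get("quality_flags", ()))))

    ev = _read_csv(src / "events.csv", ["label", "time_s"])
    events = []
    for label in meta.get("event_labels",
                          list(dict.fromkeys(ev["label"].astype(str)))):
        times = ev.loc[ev["label"] == label, "time_s"].to_numpy()
        events.append(EventTrain(str(label), times, duration))

    threshold = meta.get("threshold_used")
    states = (_read_states(src / "states.csv", threshold)
              if (src / "states.csv").exists() else None)

    ground_truth = None
    gtdir = src / "ground_truth"
    if gtdir.exists():
        gstates = _read_states(gtdir / "states.csv", None)
        gev = _read_csv(gtdir / "events.csv", ["label", "time_s"])
        twitches = {}
        wake = EventTrain("wake_onset", np.empty(0), duration)
        for label in dict.fromkeys(gev["label"].astype(str)):
            times = gev.loc[gev["label"] == label, "time_s"].to_numpy()
            if label.startswith("twitch_"):
                twitches[label.removeprefix("twitch_")] = EventTrain(
                    label, times, duration)
            elif label == "wake_onset":
                wake = EventTrain(label, times, duration)
        spec_meta = json.loads((gtdir / "unit_specs.json").read_text()) \
            if (gtdir / "unit_specs.json").exists() else {}
        specs = tuple(
            UnitSpec(unit_id=u["unit_id"], archetype=u["archetype"],
                     base_rate_by_state=u["base_rate_by_state"],
                     event_kernels=tuple(tuple(k) for k in u["event_kernels"]),
                     plateau=tuple(u["plateau"]) if u.get("plateau") else None,
                     trigger_muscle=u.get("trigger_muscle", "nuchal"),
                     structure=u.get("structure", "IO"))
            for u in spec_meta.get("unit_specs", ()))
        ground_truth = SyntheticGroundTruth(
            true_states=gstates, true_twitches=twitches,
            true_wake_onsets=wake, unit_specs=specs,
            atonia_baseline=float(spec_meta.get("atonia_baseline", np.nan)))

    return Session(
        id=str(meta["id"]), duration=duration, emg=emg, spikes=spikes,
        events=events, states=states, group=str(meta.get("group", "none")),
        ground_truth=ground_truth)
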