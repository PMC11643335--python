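"""Serialization of domain objects to plain-text formats (CSV/JSON).

All writers are deterministic: equal objects produce byte-identical files,
which is what makes scenario re-runs reproducible end to end.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dimensionality import DimensionalityPMF, ValuationProfile
from .exceptions import InvalidParameterError
from .inference import SessionDataset
from .spikes import SpikeTrain

__all__ = [
    "write_activity",
    "read_activity",
    "write_spike_trains",
    "read_spike_trains",
    "write_pmf",
    "read_pmf",
    "write_profile",
    "read_profile",
    "write_sessions",
    "read_sessions",
    "validate_roundtrip",
]


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, default=_json_default, indent=1, sort_keys=True))


def write_activity(activity: np.ndarray, path, neuron_ids=None) -> None:
    """Cortical activity matrix as CSV: rows = time/trial, columns = neurons."""
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    if neuron_ids is None:
        neuron_ids = [f"n{i}" for i in range(activity.shape[1])]
    pd.DataFrame(activity, columns=list(neuron_ids)).to_csv(path, index=False)


def read_activity(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)


def write_spike_trains(trains, path) -> None:
    """Spike trains as CSV: neuron_id, time_s, compartment, duration."""
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append((tr.neuron_id, repr(float(t)), tr.compartment, repr(float(tr.duration))))
        if tr.times.size == 0:  # keep empty trains representable
            rows.append((tr.neuron_id, "", tr.compartment, repr(float(tr.duration))))
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s", "compartment", "duration"])
    df.to_csv(path, index=False)


def read_spike_trains(path) -> list[SpikeTrain]:
    df = pd.read_csv(path, dtype={"time_s": str, "duration": str})
    trains = []
    for (nid, comp), grp in df.groupby(["neuron_id", "compartment"], sort=False):
        times = np.array(
            [float(t) for t in grp.time_s if isinstance(t, str) and t != ""]
        )
        trains.append(
            SpikeTrain(
                neuron_id=int(nid),
                compartment=str(comp),
                times=times,
                duration=float(grp.duration.iloc[0]),
            )
        )
    return trains


def write_pmf(pmf: DimensionalityPMF, path) -> None:
    write_json({"probs": pmf.probs, "pmf": pmf.pmf}, path)


def read_pmf(path) -> DimensionalityPMF:
    d = json.loads(Path(path).read_text())
    return DimensionalityPMF(probs=np.array(d["probs"]), pmf=np.array(d["pmf"]))


def write_profile(profile: ValuationProfile, path) -> None:
    write_json({**profile.as_dict(), "thresholds": profile.thresholds}, path)


def read_profile(path) -> ValuationProfile:
    d = json.loads(Path(path).read_text())
    thresholds = d.pop("thresholds", {})
    return ValuationProfile(thresholds=thresholds, **d)


def write_sessions(ds: SessionDataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def read_sessions(path) -> SessionDataset:
    df = pd.read_csv(path)
    input_cols = [c for c in df.columns if c.startswith("input")]
    return SessionDataset(
        inputs=df[input_cols].to_numpy(),
        activity=df.activity.to_numpy(),
        labels=df.label.to_numpy(),
        choices=df.choice.to_numpy(),
    )


def validate_roundtrip(obj, directory) -> bool:
    """write(obj) then read it back; True iff the result equals the input."""
    directory = Path(directory)
    if isinstance(obj, SpikeTrain):
        p = directory / "train.csv"
        write_spike_trains([obj], p)
        back = read_spike_trains(p)[0]
        return (
            back.neuron_id == obj.neuron_id
            and back.compartment == obj.compartment
            and back.duration == obj.duration
            and np.array_equal(back.times, obj.times)
        )
    if isinstance(obj, DimensionalityPMF):
        p = directory / "pmf.json"
        write_pmf(obj, p)
        back = read_pmf(p)
        return np.array_equal(back.probs, obj.probs) and np.array_equal(back.pmf, obj.pmf)
    if isinstance(obj, ValuationProfile):
        p = directory / "profile.json"
        write_profile(obj, p)
        back = read_profile(p)
        return back.as_dict() == obj.as_dict() and back.thresholds == obj.thresholds
    if isinstance(obj, SessionDataset):
        p = directory / "sessions.csv"
        write_sessions(obj, p)
        back = read_sessions(p)
        return (
            np.allclose(back.inputs, obj.inputs)
            and np.allclose(back.activity, obj.activity)
            and np.array_equal(back.labels.astype(str), obj.labels.astype(str))
            and np.array_equal(back.choices, obj.choices)
        )
    raise InvalidParameterError(f"no round-trip serializer for {type(obj).__name__}")
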