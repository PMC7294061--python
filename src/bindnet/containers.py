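"""Core data containers: epoched EEG, electrode montages, trial metadata.

The central object is :class:`EpochSet`, a channels x samples x trials array
with a sampling rate, an epoch window expressed relative to the second
stimulus (S2) onset, an electrode montage and per-trial metadata.  Epochs are
stored either in scalp-potential units (microvolt) or, after the surface
Laplacian, in current source density units (microvolt per square metre).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "ParadigmTiming",
    "Montage",
    "EpochSet",
    "make_equidistant_montage",
]

_FEATURE_NAMES = ("orientation", "location", "color")
_FEATURE_LEVELS = {
    "orientation": ("vert", "horiz"),
    "location": ("top", "bottom"),
    "color": ("red", "green"),
}


@dataclass(frozen=True)
class TrialRecord:
    """One S1-S2 trial of the event-file binding paradigm.

    ``overlap`` counts the stimulus features (orientation, location, color)
    shared between S1 and S2; ``response_relation`` is ``"repeat"`` when the
    two keypresses use the same hand and ``"alternate"`` otherwise.
    """

    index: int
    s1_features: tuple[str, str, str]
    s2_features: tuple[str, str, str]
    overlap: int
    response_relation: str
    r1_side: str
    r2_side: str
    rt_ms: float = float("nan")
    correct: bool = True

    def __post_init__(self) -> None:
        n_shared = sum(a == b for a, b in zip(self.s1_features, self.s2_features))
        if n_shared != self.overlap:
            raise ValueError(
                f"overlap={self.overlap} but {n_shared} features are shared"
            )
        rel = "repeat" if self.r1_side == self.r2_side else "alternate"
        if rel != self.response_relation:
            raise ValueError(
                f"response_relation={self.response_relation!r} inconsistent with "
                f"r1={self.r1_side!r}, r2={self.r2_side!r}"
            )

    @property
    def condition(self) -> tuple[int, str]:
        """(overlap, response_relation) cell label."""
        return (self.overlap, self.response_relation)


@dataclass(frozen=True)
class ParadigmTiming:
    """Nominal trial timing (ms).  The inter-trial interval is jittered
    uniformly within ``iti_ms``."""

    cue_ms: float = 1500.0
    blank1_ms: float = 1000.0
    s1_ms: float = 500.0
    blank2_ms: float = 2000.0
    s2_max_ms: float = 2000.0
    iti_ms: tuple[float, float] = (1500.0, 2000.0)

    def __post_init__(self) -> None:
        for name in ("cue_ms", "blank1_ms", "s1_ms", "blank2_ms", "s2_max_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.iti_ms
        if not (0 < lo <= hi):
            raise ValueError("iti_ms interval must be positive and ordered")


@dataclass(frozen=True)
class Montage:
    """Electrode positions in head-centred spherical coordinates.

    ``theta`` is the polar angle from the vertex (Cz) in degrees, ``phi`` the
    azimuth in degrees (0 = nasion direction, counter-clockwise seen from
    above).  Electrodes are assumed to lie on a unit sphere.
    """

    names: tuple[str, ...]
    theta: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.theta) == len(self.phi)):
            raise ValueError("names, theta and phi must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    def positions(self) -> np.ndarray:
        """Unit-sphere Cartesian positions, shape (n_channels, 3)."""
        th = np.radians(np.asarray(self.theta, dtype=float))
        ph = np.radians(np.asarray(self.phi, dtype=float))
        return np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as err:
            raise KeyError(f"channel {name!r} not in montage") from err

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"name": self.names, "theta": self.theta, "phi": self.phi}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Montage":
        df = pd.read_csv(path, sep="\t")
        return cls(
            names=tuple(df["name"].astype(str)),
            theta=df["theta"].to_numpy(float),
            phi=df["phi"].to_numpy(float),
        )


def make_equidistant_montage(n_channels: int = 60, max_theta: float = 100.0) -> Montage:
    """Approximately equidistant electrode layout on a spherical cap.

    Channels are placed on a sunflower (golden-angle) spiral covering polar
    angles up to ``max_theta`` degrees, which mimics an equidistant 60-channel
    cap.  The first channel sits at the vertex and is named ``Cz``; the rest
    get generic ``E##`` labels.
    """

    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    idx = np.arange(n_channels, dtype=float)
    # equal-area spacing in cos(theta) over the cap, golden-angle azimuth
    cos_max = np.cos(np.radians(max_theta))
    cos_th = 1.0 - (1.0 - cos_max) * idx / max(n_channels - 1, 1)
    theta = np.degrees(np.arccos(np.clip(cos_th, -1.0, 1.0)))
    golden = 180.0 * (3.0 - np.sqrt(5.0))
    phi = np.mod(idx * golden, 360.0)
    names = ["Cz"] + [f"E{i:02d}" for i in range(2, n_channels + 1)]
    return Montage(names=tuple(names), theta=theta, phi=phi)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecords to one row per trial."""
    rows = []
    for t in trials:
        row = {
            "index": t.index,
            "overlap": t.overlap,
            "response_relation": t.response_relation,
            "r1_side": t.r1_side,
            "r2_side": t.r2_side,
            "rt_ms": t.rt_ms,
            "correct": t.correct,
        }
        for i, name in enumerate(_FEATURE_NAMES):
            row[f"s1_{name}"] = t.s1_features[i]
            row[f"s2_{name}"] = t.s2_features[i]
        rows.append(row)
    return pd.DataFrame(rows)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for _, row in df.iterrows():
        trials.append(
            TrialRecord(
                index=int(row["index"]),
                s1_features=tuple(str(row[f"s1_{n}"]) for n in _FEATURE_NAMES),
                s2_features=tuple(str(row[f"s2_{n}"]) for n in _FEATURE_NAMES),
                overlap=int(row["overlap"]),
                response_relation=str(row["response_relation"]),
                r1_side=str(row["r1_side"]),
                r2_side=str(row["r2_side"]),
                rt_ms=float(row["rt_ms"]),
                correct=bool(row["correct"]),
            )
        )
    return trials


@dataclass
class EpochSet:
    """Epoched multichannel EEG locked to the S2 stimulus.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples, n_trials).  Units are
        microvolt while ``units == "potential"`` and microvolt/m**2 after the
        current-source-density transform (``units == "csd"``).
    srate
        Sampling rate in Hz.
    window_ms
        (start, end) of the epoch in ms relative to S2 onset; sample ``i``
        sits at ``window_ms[0] + i / srate * 1000``.
    montage
        Electrode montage; its length must match ``data.shape[0]``.
    trials
        Per-trial metadata, one :class:`TrialRecord` per trial.
    """

    data: np.ndarray
    srate: float
    window_ms: tuple[float, float]
    montage: Montage
    trials: list[TrialRecord] = field(default_factory=list)
    units: str = "potential"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        if len(self.montage) != self.data.shape[0]:
            raise ValueError(
                f"montage has {len(self.montage)} channels but data has "
                f"{self.data.shape[0]}"
            )
        if self.trials and len(self.trials) != self.data.shape[2]:
            raise ValueError("number of TrialRecords must match trial axis")
        if self.units not in ("potential", "csd"):
            raise ValueError("units must be 'potential' or 'csd'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to S2 onset."""
        return self.window_ms[0] + np.arange(self.n_samples) / self.srate * 1000.0

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def copy_with(self, data: np.ndarray | None = None, **kwargs) -> "EpochSet":
        out = dataclasses.replace(self, **kwargs)
        if data is not None:
            out.data = np.asarray(data, dtype=float)
        return out

    def select_trials(self, keep: np.ndarray) -> "EpochSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        trials = [self.trials[i] for i in keep] if self.trials else []
        return EpochSet(
            data=self.data[:, :, keep],
            srate=self.srate,
            window_ms=self.window_ms,
            montage=self.montage,
            trials=trials,
            units=self.units,
        )

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write to an HDF5 container (datasets: data, theta, phi; attrs:
        srate, window, units, channel names, trial table as JSON)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("theta", data=np.asarray(self.montage.theta, float))
            f.create_dataset("phi", data=np.asarray(self.montage.phi, float))
            f.attrs["srate"] = float(self.srate)
            f.attrs["window_ms"] = list(self.window_ms)
            f.attrs["units"] = self.units
            f.attrs["channel_names"] = list(self.montage.names)
            if self.trials:
                records = trials_to_frame(self.trials).to_dict("records")
                f.attrs["trials_json"] = json.dumps(
                    records, default=lambda o: o.item()
                )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            montage = Montage(
                names=tuple(str(n) for n in f.attrs["channel_names"]),
                theta=f["theta"][()],
                phi=f["phi"][()],
            )
            trials: list[TrialRecord] = []
            if "trials_json" in f.attrs:
                df = pd.DataFrame(json.loads(f.attrs["trials_json"]))
                trials = trials_from_frame(df)
            return cls(
                data=f["data"][()],
                srate=float(f.attrs["srate"]),
                window_ms=tuple(float(x) for x in f.attrs["window_ms"]),
                montage=montage,
                trials=trials,
                units=str(f.attrs["units"]),
            )
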