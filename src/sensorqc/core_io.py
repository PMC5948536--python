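"""Shared domain types and on-disk formats.

All container types are thin frozen dataclasses over numpy arrays with
validated invariants, so alignment mistakes between pipeline stages fail
loudly rather than silently shifting labels against features.

Index conventions are 0-based and half-open throughout.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

SCHEMA_VERSION = "sensorqc-v1"

ADHERENCE = 1
VIOLATION = 2


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected schema."""


class DataError(ValueError):
    """Raised when a file parses but its contents violate a precondition."""


@dataclasses.dataclass(frozen=True)
class SensorRecording:
    """Timestamped multi-channel raw sensor samples.

    Parameters
    ----------
    timestamps : array of float
        Sample times in seconds, strictly increasing.
    samples : array of shape (T, d)
        One row per timestamp; d=3 for accelerometer data (m/s^2),
        d=1 for audio (dimensionless, scaled to [-1, 1]).
    nominal_rate : float
        Nominal sampling rate in Hz (> 0).  Raw recordings may be
        jittered around this rate; resampled recordings are exact.
    modality : {"accel", "audio"}
    meta : dict
        Free-form test/subject tags.
    """

    timestamps: np.ndarray
    samples: np.ndarray
    nominal_rate: float
    modality: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        xs = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if xs.shape[0] == 1 and ts.size > 1:
            xs = xs.T
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "samples", xs)
        if ts.ndim != 1:
            raise DataError("timestamps must be one-dimensional")
        if xs.shape[0] != ts.size:
            raise DataError(
                f"{xs.shape[0]} sample rows but {ts.size} timestamps"
            )
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise DataError("timestamps must be strictly increasing")
        if not self.nominal_rate > 0:
            raise DataError("nominal_rate must be positive")
        if self.modality not in ("accel", "audio"):
            raise DataError(f"unknown modality {self.modality!r}")
        if self.modality == "accel" and xs.shape[1] != 3:
            raise DataError("accel recordings must have 3 channels")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclasses.dataclass(frozen=True)
class GravityTrend:
    """Estimated gravitational trend g_1..g_T (m/s^2) and its penalty."""

    trend: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        tr = np.atleast_2d(np.asarray(self.trend, dtype=float))
        object.__setattr__(self, "trend", tr)
        if self.lam < 0:
            raise DataError("lambda must be nonnegative")

    def __len__(self) -> int:
        return self.trend.shape[0]


@dataclasses.dataclass(frozen=True)
class FeatureSeries:
    """The univariate preprocessed sequence x_1..x_T fed to segmenters."""

    values: np.ndarray
    rate: float
    feature_kind: str
    meta: dict = dataclasses.field(default_factory=dict)

    _KINDS = ("magnitude", "log10_magnitude", "frame_energy")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise DataError("feature values must be finite")
        if not self.rate > 0:
            raise DataError("rate must be positive")
        if self.feature_kind not in self._KINDS:
            raise DataError(f"unknown feature_kind {self.feature_kind!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclasses.dataclass(frozen=True)
class LabelSeries:
    """Per-time-point adherence (1) / violation (2) codes u_1..u_T."""

    u: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=int).ravel()
        object.__setattr__(self, "u", u)
        if u.size and not np.all(np.isin(u, (ADHERENCE, VIOLATION))):
            bad = sorted(set(u.tolist()) - {ADHERENCE, VIOLATION})
            raise DataError(f"labels must be 1 or 2, found {bad}")

    def __len__(self) -> int:
        return self.u.size


@dataclasses.dataclass(frozen=True)
class BehaviorSeries:
    """Per-time-point free-text behavior tags b_1..b_T."""

    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=object).ravel())

    def __len__(self) -> int:
        return self.b.size


@dataclasses.dataclass(frozen=True)
class StateSeries:
    """Per-time-point state indicators z_t in 1..L with optional posteriors.

    ``probs`` (if given) is a T x L row-stochastic matrix; the argmax of
    each row must agree with ``z``.
    """

    z: np.ndarray
    probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=int).ravel()
        object.__setattr__(self, "z", z)
        if z.size and z.min() < 1:
            raise DataError("state indicators are 1-based")
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            object.__setattr__(self, "probs", p)
            if p.shape[0] != z.size:
                raise DataError("probs rows must match state sequence length")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise DataError("probs rows must sum to 1")
            if not np.array_equal(p.argmax(axis=1) + 1, z):
                raise DataError("argmax of probs rows must equal z")

    def __len__(self) -> int:
        return self.z.size


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ACCEL_COLS = ["time", "ax", "ay", "az"]


def read_accel_csv(path, *, dedup: bool = False) -> SensorRecording:
    """Read a tri-axial accelerometer CSV (columns time, ax, ay, az).

    Time is in seconds, acceleration in m/s^2.  Duplicated timestamps are
    rejected unless ``dedup`` is set, in which case the first row of each
    duplicate group is kept.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _ACCEL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"accel CSV missing columns {missing}")
    if dedup:
        df = df.drop_duplicates(subset="time", keep="first")
    t = df["time"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise DataError("accel CSV timestamps not strictly increasing")
    xyz = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    dt = np.median(np.diff(t)) if t.size > 1 else 1.0
    return SensorRecording(t, xyz, nominal_rate=1.0 / dt, modality="accel")


def write_accel_csv(path, rec: SensorRecording) -> None:
    if rec.modality != "accel":
        raise DataError("write_accel_csv expects an accel recording")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        fh.write(",".join(_ACCEL_COLS) + "\n")
        for t, (x, y, z) in zip(rec.timestamps, rec.samples):
            fh.write(f"{t:.9f},{x:.9f},{y:.9f},{z:.9f}\n")


def read_wav(path, *, mixdown: bool = False) -> SensorRecording:
    """Read a mono WAV file into an audio SensorRecording.

    Integer PCM is rescaled to [-1, 1]; float data is passed through.
    Multi-channel input is an error unless ``mixdown`` averages channels.
    """
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if not mixdown:
            raise FormatError(
                f"expected mono WAV, got {data.shape[1]} channels"
            )
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    t = np.arange(data.size) / rate
    return SensorRecording(t, data[:, None], nominal_rate=float(rate),
                           modality="audio")


def write_wav(path, rec: SensorRecording) -> None:
    if rec.modality != "audio":
        raise DataError("write_wav expects an audio recording")
    x = np.clip(rec.samples[:, 0], -1.0, 1.0)
    pcm = np.round(x * 32768.0).astype(np.int32)
    pcm = np.clip(pcm, -32768, 32767).astype(np.int16)
    wavfile.write(path, int(rec.nominal_rate), pcm)


def read_labels_csv(path, *, mode: str = "adherence"):
    """Read per-time-point labels (columns index, label).

    ``mode="adherence"`` returns a :class:`LabelSeries` and enforces
    labels in {1, 2}; ``mode="behavior"`` returns a :class:`BehaviorSeries`
    of free-text tags.  Indices must be 0-based, dense and increasing;
    gaps are an error.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("index", "label"):
        if col not in df.columns:
            raise FormatError(f"labels CSV missing column {col!r}")
    idx = df["index"].to_numpy(dtype=int)
    if not np.array_equal(idx, np.arange(idx.size)):
        raise DataError("labels CSV indices must be dense 0..T-1")
    if mode == "adherence":
        return LabelSeries(df["label"].to_numpy(dtype=int))
    if mode == "behavior":
        return BehaviorSeries(df["label"].to_numpy(dtype=object))
    raise ValueError(f"unknown labels mode {mode!r}")


def write_labels_csv(path, series) -> None:
    vals = series.u if isinstance(series, LabelSeries) else series.b
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        fh.write("index,label\n")
        for i, v in enumerate(vals):
            fh.write(f"{i},{v}\n")


def write_features_csv(path, fs: FeatureSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        fh.write(f"# rate: {fs.rate!r}\n")
        fh.write(f"# kind: {fs.feature_kind}\n")
        fh.write("index,value\n")
        for i, v in enumerate(fs.values):
            fh.write(f"{i},{v:.12g}\n")


def read_features_csv(path) -> FeatureSeries:
    rate, kind = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# rate:"):
                rate = float(line.split(":", 1)[1])
            elif line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
    if rate is None or kind is None:
        raise FormatError("features CSV missing rate/kind header comments")
    df = pd.read_csv(path, comment="#")
    if "value" not in df.columns:
        raise FormatError("features CSV missing 'value' column")
    return FeatureSeries(df["value"].to_numpy(dtype=float), rate=rate,
                         feature_kind=kind)


def write_states_csv(path, states: StateSeries) -> None:
    """States CSV: index, z_mode, and posterior columns p_1..p_L."""
    L = states.probs.shape[1] if states.probs is not None else \
        int(states.z.max())
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        cols = ",".join(f"p_{k}" for k in range(1, L + 1))
        fh.write(f"index,z_mode,{cols}\n")
        for i, z in enumerate(states.z):
            if states.probs is not None:
                p = ",".join(f"{v:.9f}" for v in states.probs[i])
            else:
                p = ",".join("1.000000000" if k == z else "0.000000000"
                             for k in range(1, L + 1))
            fh.write(f"{i},{z},{p}\n")


def read_states_csv(path) -> StateSeries:
    df = pd.read_csv(path, comment="#")
    if "z_mode" not in df.columns:
        raise FormatError("states CSV missing 'z_mode' column")
    pcols = [c for c in df.columns if c.startswith("p_")]
    z = df["z_mode"].to_numpy(dtype=int)
    probs = None
    if pcols:
        probs = df[sorted(pcols, key=lambda c: int(c[2:]))].to_numpy(float)
        probs = probs / probs.sum(axis=1, keepdims=True)
        # round-tripped rows can disagree with z at print precision
        mism = probs.argmax(axis=1) + 1 != z
        for i in np.flatnonzero(mism):
            probs[i, z[i] - 1] = probs[i].max() + 1e-9
            probs[i] /= probs[i].sum()
    return StateSeries(z, probs=probs)


def align_labels_to_features(labels, n_raw: int, n_out: int):
    """Map raw-sample labels to feature-series resolution by majority vote.

    Each output index k covers the half-open block of raw indices
    [floor(k*n_raw/n_out), floor((k+1)*n_raw/n_out)); its label is the
    majority label within the block (ties go to the violation code for
    adherence labels, and to the lexicographically first tag otherwise).
    """
    if len(labels) != n_raw:
        raise DataError(f"labels length {len(labels)} != n_raw {n_raw}")
    if n_out < 1 or n_out > n_raw:
        raise DataError("n_out must be in [1, n_raw]")
    vals = labels.u if isinstance(labels, LabelSeries) else labels.b
    edges = (np.arange(n_out + 1) * n_raw) // n_out
    out = []
    for k in range(n_out):
        block = vals[edges[k]:edges[k + 1]]
        counts = Counter(block.tolist())
        top = max(counts.values())
        winners = sorted(v for v, c in counts.items() if c == top)
        if isinstance(labels, LabelSeries):
            out.append(VIOLATION if len(winners) > 1 else winners[0])
        else:
            out.append(winners[0])
    if isinstance(labels, LabelSeries):
        return LabelSeries(np.asarray(out, dtype=int))
    return BehaviorSeries(np.asarray(out, dtype=object))
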