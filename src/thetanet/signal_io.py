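"""Session I/O: load multi-channel LFP recordings, carve period-aligned segments.

A *session* is one continuous multi-channel recording (microvolts) together
with its sampling rate, an ordered list of brain-region channel labels and a
named event timeline (Base, Enc1..Enc5, Post1..Post5, Tone1.., Stim1.. or
custom labels).  Sessions are described on disk by a small JSON manifest that
points at either an EDF file or a plain tabular text file of samples.

Time convention: seconds from recording start; a period covers the half-open
sample interval ``[round(start_s*fs), round(end_s*fs))`` so adjacent periods
never share a boundary sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MANIFEST_SCHEMA = "thetanet-session-v1"


class ValidationError(ValueError):
    """Raised when a session, manifest or parameter set violates its contract."""


@dataclass(frozen=True)
class Period:
    """A named time interval within a session, in seconds from recording start."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"period {self.name!r}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Session:
    """Multi-channel LFP recording with region labels and an event timeline.

    Attributes
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts.
    fs : float
        Sampling rate in Hz.
    regions : list of str
        Ordered, unique channel labels (e.g. MOB, AOB, MeA, LS, Pir).
    timeline : list of Period
        Named periods; all must lie within the recording.
    meta : dict
        Free-form annotations (may carry per-encounter investigation times).
    """

    signals: np.ndarray
    fs: float
    regions: list[str]
    timeline: list[Period]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.signals.ndim != 2:
            raise ValidationError("signals must be a 2-D (n_channels, n_samples) matrix")
        if len(self.regions) != self.signals.shape[0]:
            raise ValidationError(
                f"{len(self.regions)} region labels for {self.signals.shape[0]} channels"
            )
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("region labels must be unique")
        names = [p.name for p in self.timeline]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate period names in timeline: {dup}")
        t_max = self.n_samples / self.fs
        for p in self.timeline:
            if p.start_s < 0 or p.end_s > t_max + 0.5 / self.fs:
                raise ValidationError(
                    f"period {p.name!r} [{p.start_s}, {p.end_s}] s exceeds recording "
                    f"length {t_max:g} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def period(self, name: str) -> Period:
        for p in self.timeline:
            if p.name == name:
                return p
        raise KeyError(f"no period named {name!r}; have {[p.name for p in self.timeline]}")

    def channel(self, region: str) -> np.ndarray:
        try:
            return self.signals[self.regions.index(region)]
        except ValueError:
            raise KeyError(f"no region {region!r}; have {self.regions}") from None


@dataclass
class Segment:
    """A period-aligned cut of a session: matrix (n_channels, m) plus sampling rate."""

    data: np.ndarray
    fs: float
    regions: list[str]
    name: str = ""

    def channel(self, region: str) -> np.ndarray:
        return self.data[self.regions.index(region)]


def extract_period(session: Session, name: str) -> Segment:
    """Cut the named period out of the session.

    The returned segment covers samples ``[round(start_s*fs), round(end_s*fs))``,
    so its length depends only on the period duration and fs, never on the
    start offset.
    """
    p = session.period(name)
    i0 = int(round(p.start_s * session.fs))
    i1 = int(round(p.end_s * session.fs))
    i1 = min(i1, session.n_samples)
    return Segment(session.signals[:, i0:i1], session.fs, list(session.regions), name)


# ---------------------------------------------------------------------------
# Manifest + tabular / EDF readers
# ---------------------------------------------------------------------------

def _timeline_from_manifest(entries: Iterable[Mapping[str, Any]]) -> list[Period]:
    return [Period(str(e["name"]), float(e["start_s"]), float(e["end_s"])) for e in entries]


def load_session(manifest_path: str | Path) -> Session:
    """Load a session from its JSON manifest.

    The manifest declares ``fs``, a ``timeline``, an optional microvolt
    ``scale`` factor (default 1.0, honored but never inferred), optional
    ``meta``, and a ``signals`` entry with ``format`` ("csv" or "edf") and a
    ``path`` relative to the manifest.  CSV signal files carry one header row
    of region labels and one column per region.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    if man.get("schema") != MANIFEST_SCHEMA:
        raise ValidationError(
            f"manifest schema {man.get('schema')!r} != {MANIFEST_SCHEMA!r}"
        )
    fs = float(man["fs"])
    scale = float(man.get("scale", 1.0))
    sig = man["signals"]
    path = manifest_path.parent / sig["path"]
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = sig.get("format", "csv")
    if fmt == "csv":
        regions, data = _read_tabular(path)
    elif fmt == "edf":
        regions, data, fs_edf = _read_edf(path)
        if abs(fs_edf - fs) > 1e-9:
            raise ValidationError(
                f"fs mismatch: manifest declares {fs} Hz but EDF header says {fs_edf} Hz"
            )
        channel_map = man.get("channel_map")
        if channel_map:  # EDF label -> region label
            order = [regions.index(k) for k in channel_map]
            data = data[order]
            regions = [channel_map[k] for k in channel_map]
    else:
        raise ValidationError(f"unknown signal format {fmt!r}")
    timeline = _timeline_from_manifest(man.get("timeline", []))
    return Session(data * scale, fs, regions, timeline, dict(man.get("meta", {})))


def _read_tabular(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return list(df.columns), df.to_numpy(dtype=float).T


def _read_edf(path: Path) -> tuple[list[str], np.ndarray, float]:
    """Read an EDF file through MNE; returns microvolt data."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts; sessions are in microvolts
    return list(raw.ch_names), data, float(raw.info["sfreq"])


def save_session(session: Session, out_dir: str | Path, fmt: str = "csv",
                 name: str = "session") -> Path:
    """Write a session as signal file + manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        sig_name = f"{name}_signals.csv"
        df = pd.DataFrame(session.signals.T, columns=session.regions)
        df.to_csv(out_dir / sig_name, index=False, float_format="%.6f")
    elif fmt == "edf":
        sig_name = f"{name}_signals.edf"
        write_edf(out_dir / sig_name, session.signals, session.fs, session.regions)
    else:
        raise ValidationError(f"unknown signal format {fmt!r}")
    man = {
        "schema": MANIFEST_SCHEMA,
        "fs": session.fs,
        "scale": 1.0,
        "signals": {"format": fmt, "path": sig_name},
        "timeline": [
            {"name": p.name, "start_s": p.start_s, "end_s": p.end_s}
            for p in session.timeline
        ],
        "meta": session.meta,
    }
    manifest_path = out_dir / f"{name}_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)
    return manifest_path


def write_edf(path: str | Path, signals: np.ndarray, fs: float,
              labels: Sequence[str]) -> None:
    """Write a minimal continuous EDF file (16-bit) readable by standard EDF tools.

    Each channel is quantized to int16 over its own physical range; one data
    record holds one second of samples.  fs must be an integer for this writer.
    """
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samp = signals.shape
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = signals

    phys_min = np.floor(padded.min(axis=1)) - 1.0
    phys_max = np.ceil(padded.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > n:
            b = b[:n]
        return b.ljust(n)

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        (16, [f"{lab}" for lab in labels]),
        (80, ["" for _ in labels]),
        (8, ["uV" for _ in labels]),
        (8, [f"{v:.1f}" if abs(v) < 99999 else f"{v:.0f}" for v in phys_min]),
        (8, [f"{v:.1f}" if abs(v) < 99999 else f"{v:.0f}" for v in phys_max]),
        (8, [str(dig_min) for _ in labels]),
        (8, [str(dig_max) for _ in labels]),
        (80, ["" for _ in labels]),
        (8, [str(spr) for _ in labels]),
        (32, ["" for _ in labels]),
    ]
    for width, vals in fields:
        header += b"".join(pad(v, width) for v in vals)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(rows: Sequence[Mapping[str, Any]] | pd.DataFrame,
                path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as UTF-8 CSV with a deterministic column order.

    An empty record list with explicit ``columns`` yields a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if columns is None:
            columns = list(rows[0].keys()) if rows else []
        df = pd.DataFrame(rows, columns=list(columns))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False, encoding="utf-8")
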