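"""Data model and I/O for tri-axial accelerometer recordings.

A recording is a timestamped sequence of (ax, ay, az) samples in units of g
captured at a fixed device rate (16 or 25 Hz for the phones modelled here).
An activity log is a 9-second recording with a single annotated activity
(labels A1..A7) placed at its centre; analysis windows of a chosen length
are cut out around that centre before feature extraction.

File formats are plain CSV: a recording file has columns t,ax,ay,az (header
optional on read), and a dataset directory holds one recording file per log
plus a ``labels.csv`` sidecar (log_id, label, center_seconds, device, rate).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

#: The seven activity labels: inertial locomotion states A1-A4
#: (stationary, walking, jogging, sprinting) and game activities A5-A7
#: (hitting the ball, standing tackle, dribbling).
ACTIVITY_LABELS: tuple[str, ...] = ("A1", "A2", "A3", "A4", "A5", "A6", "A7")

#: Nominal duration of one annotated activity log, in seconds.
LOG_DURATION_S: float = 9.0


class SignalValidationError(ValueError):
    """Raised when a recording or log violates its structural invariants."""


class MalformedInputError(ValueError):
    """Raised when an input file cannot be parsed as a recording."""


@dataclass(frozen=True)
class DeviceProfile:
    """Capture-device characteristics.

    Parameters
    ----------
    name : str
        Device identifier (e.g. ``"nexus_one"``).
    sampling_rate : float
        Samples per second; the phones modelled sample at 16 or 25 Hz.
    resolution_bits : int
        ADC resolution; 8-bit for the modelled devices.
    range_g : float
        Symmetric full-scale range, so values live in [-range_g, +range_g].
    noise_sd : float
        Standard deviation of additive sensor noise, in g.
    """

    name: str
    sampling_rate: float
    resolution_bits: int = 8
    range_g: float = 4.0
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.resolution_bits < 1:
            raise ValueError("resolution_bits must be >= 1")


#: Device profiles for the two handsets used to capture the original data.
NEXUS_ONE = DeviceProfile(name="nexus_one", sampling_rate=16.0)
HTC_DESIRE = DeviceProfile(name="htc_desire", sampling_rate=25.0)

DEVICE_PROFILES: dict[str, DeviceProfile] = {
    p.name: p for p in (NEXUS_ONE, HTC_DESIRE)
}


@dataclass(frozen=True)
class AccelerometerRecording:
    """Validated tri-axial accelerometer time series at a fixed rate."""

    device_id: str
    sampling_rate: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if self.sampling_rate <= 0:
            raise SignalValidationError("sampling_rate must be positive")
        n = len(t)
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise SignalValidationError(f"{name} length != timestamp length")
        if n < 2:
            raise MalformedInputError("a recording needs at least 2 samples")
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            row = int(bad[0]) + 2  # 1-based row of the offending sample
            raise SignalValidationError(
                f"timestamps not strictly increasing at row {row} "
                f"(t={float(t[bad[0] + 1])})"
            )
        nominal = 1.0 / self.sampling_rate
        med = float(np.median(dt))
        if abs(med - nominal) > 0.2 * nominal:
            raise SignalValidationError(
                f"median inter-sample interval {med:.4f}s deviates more than "
                f"20% from nominal {nominal:.4f}s"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Time span from first to last sample, seconds."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class ActivityLog:
    """A 9-second recording annotated with one centred activity."""

    recording: AccelerometerRecording
    label: str
    activity_center: float
    log_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise SignalValidationError(
                f"unknown label {self.label!r}; expected one of {ACTIVITY_LABELS}"
            )
        period = 1.0 / self.recording.sampling_rate
        if abs(self.recording.duration - LOG_DURATION_S) > period + 1e-9:
            raise SignalValidationError(
                f"log duration {self.recording.duration:.4f}s is not "
                f"{LOG_DURATION_S}s within one sample period"
            )
        t = self.recording.t
        if not (t[0] <= self.activity_center <= t[-1]):
            raise SignalValidationError("activity_center outside the log span")


@dataclass(frozen=True)
class ActivityWindow:
    """Fixed-length per-axis sample vectors cut from a log.

    ``len(window)`` is ``round(length * source_rate)`` samples.
    """

    length: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    source_rate: float
    label: Optional[str] = None
    window_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.y) == len(self.z) == n):
            raise SignalValidationError("axis vectors must have equal length")
        expected = int(round(self.length * self.source_rate))
        if n != expected:
            raise SignalValidationError(
                f"window has {n} samples, expected round({self.length} x "
                f"{self.source_rate}) = {expected}"
            )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.x, self.y, self.z)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_rows(path: Path) -> list[tuple[float, float, float, float]]:
    rows: list[tuple[float, float, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, raw in enumerate(reader):
            if not raw or all(not c.strip() for c in raw):
                continue
            if len(raw) < 4:
                raise MalformedInputError(
                    f"{path}: row {i + 1} has {len(raw)} columns, need 4"
                )
            try:
                rows.append(tuple(float(c) for c in raw[:4]))  # type: ignore[arg-type]
            except ValueError:
                if i == 0:
                    continue  # optional header row
                raise MalformedInputError(
                    f"{path}: non-numeric field in row {i + 1}: {raw!r}"
                )
    return rows


def read_recording(path: str | Path, device: DeviceProfile) -> AccelerometerRecording:
    """Read a t,ax,ay,az CSV into a validated recording.

    A single header row is tolerated and skipped; any other non-numeric
    row raises :class:`MalformedInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = _parse_rows(path)
    if len(rows) < 2:
        raise MalformedInputError(f"{path}: fewer than 2 data rows")
    arr = np.asarray(rows, dtype=float)
    return AccelerometerRecording(
        device_id=device.name,
        sampling_rate=device.sampling_rate,
        t=arr[:, 0],
        ax=arr[:, 1],
        ay=arr[:, 2],
        az=arr[:, 3],
    )


def write_recording(rec: AccelerometerRecording, path: str | Path,
                    decimals: int = 6) -> None:
    """Write a recording as a t,ax,ay,az CSV with a header row."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "ax", "ay", "az"])
        for i in range(len(rec)):
            w.writerow([
                f"{rec.t[i]:.{decimals}f}",
                f"{rec.ax[i]:.{decimals}f}",
                f"{rec.ay[i]:.{decimals}f}",
                f"{rec.az[i]:.{decimals}f}",
            ])


def write_dataset(logs: Sequence[ActivityLog], directory: str | Path) -> None:
    """Write one recording CSV per log plus a labels.csv sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["log_id", "label", "center_seconds", "device", "rate"])
        for i, log in enumerate(logs):
            log_id = log.log_id or f"log{i:04d}"
            write_recording(log.recording, directory / f"{log_id}.csv")
            w.writerow([
                log_id, log.label, f"{log.activity_center:.6f}",
                log.recording.device_id, log.recording.sampling_rate,
            ])


def read_dataset(directory: str | Path) -> list[ActivityLog]:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    sidecar = directory / "labels.csv"
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    logs: list[ActivityLog] = []
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            device = DeviceProfile(
                name=row["device"], sampling_rate=float(row["rate"])
            )
            rec = read_recording(directory / f"{row['log_id']}.csv", device)
            logs.append(ActivityLog(
                recording=rec,
                label=row["label"],
                activity_center=float(row["center_seconds"]),
                log_id=row["log_id"],
            ))
    return logs


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def segment_window(log: ActivityLog, length: float) -> ActivityWindow:
    """Cut a window of ``length`` seconds centred on the annotated activity.

    The centre sample is the one nearest ``activity_center`` (index
    floor(N/2) for a standard centred log); the window covers sample
    indices [c - floor(Nw/2), c + ceil(Nw/2)), giving round(length x rate)
    samples.  Windows of increasing length are nested around the same
    centre, so shrinking the window never shifts the activity.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    rec = log.recording
    rate = rec.sampling_rate
    n = len(rec)
    nw = int(round(length * rate))
    if nw > n:
        raise ValueError(
            f"window of {length}s ({nw} samples) exceeds the log span "
            f"({n} samples)"
        )
    center = int(np.argmin(np.abs(rec.t - log.activity_center)))
    lo = center - nw // 2
    hi = lo + nw
    if lo < 0 or hi > n:
        raise ValueError(
            f"window of {length}s does not fit around the activity centre"
        )
    return ActivityWindow(
        length=length,
        x=rec.ax[lo:hi].copy(),
        y=rec.ay[lo:hi].copy(),
        z=rec.az[lo:hi].copy(),
        source_rate=rate,
        label=log.label,
        window_id=log.log_id,
    )


def segment_dataset(logs: Iterable[ActivityLog], length: float) -> list[ActivityWindow]:
    """Window every log in a dataset at the same length."""
    return [segment_window(log, length) for log in logs]


def write_windows(windows: Sequence[ActivityWindow], path: str | Path) -> None:
    """Dump windows as CSV (id, label, L, rate, then flattened samples)."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["window_id", "label", "length", "rate", "samples_xyz"])
        for win in windows:
            flat = np.concatenate(win.axes)
            w.writerow([win.window_id, win.label, win.length, win.source_rate]
                       + [f"{v:.6f}" for v in flat])
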