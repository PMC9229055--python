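"""Multi-axial IMU recordings: sensor specification, streams, windows and CSV I/O.

The data model mirrors a cage-floor-mounted MEMS IMU: tri-axial accelerometer
samples in g and tri-axial gyroscope samples in degrees per second (dps).
Acceleration carries the activity signal; gyroscope channels are carried
through I/O for completeness but are not consumed by feature extraction.

Streams are analysed in consecutive, non-overlapping windows of fixed length
(15 s by default); a trailing partial window is discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, FormatError, ParseError

#: Default analysis window length in seconds.
WINDOW_S = 15.0

ACCEL_COLUMNS = ("ax", "ay", "az")
GYRO_COLUMNS = ("gx", "gy", "gz")


@dataclass(frozen=True)
class SensorSpec:
    """Manufacturer-style specification of the IMU channels.

    Defaults describe the accelerometer/gyroscope configuration used for
    cage-vibration sensing: 4500 samples/s with a 1248 Hz 3 dB bandwidth and
    61.04 µg/LSB resolution on the accelerometer; 7.63 mdps/LSB and
    15 mdps/√Hz on the gyroscope. The gyroscope bandwidth is the datasheet
    figure (12106 Hz) and is used only in the closed-form noise RMS
    ``density * sqrt(bandwidth)``; it is not checked against Nyquist.

    The accelerometer full scale is ±2 g, consistent with 61.04 µg/LSB over
    a 16-bit signed range.
    """

    accel_rate: float = 4500.0          # samples/s
    accel_bandwidth: float = 1248.0     # Hz, 3 dB cutoff
    accel_lsb: float = 61.04e-6         # g per count
    accel_noise_density: float = 190e-6  # g/sqrt(Hz)
    accel_full_scale: float = 2.0       # g
    gyro_rate: float = 4500.0           # samples/s
    gyro_bandwidth: float = 12106.0     # Hz, as printed on the datasheet
    gyro_lsb: float = 7.63e-3           # dps per count
    gyro_noise_density: float = 15e-3   # dps/sqrt(Hz)

    def __post_init__(self):
        for name in (
            "accel_rate", "accel_bandwidth", "accel_lsb", "accel_noise_density",
            "accel_full_scale", "gyro_rate", "gyro_bandwidth", "gyro_lsb",
            "gyro_noise_density",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"SensorSpec.{name} must be strictly positive")
        if self.accel_bandwidth > self.accel_rate / 2:
            raise ConfigError("accel_bandwidth must not exceed accel Nyquist (rate/2)")

    @property
    def accel_noise_rms(self) -> float:
        """Theoretical accelerometer noise RMS in g (density × √bandwidth)."""
        return self.accel_noise_density * math.sqrt(self.accel_bandwidth)

    @property
    def gyro_noise_rms(self) -> float:
        """Theoretical gyroscope noise RMS in dps (density × √bandwidth)."""
        return self.gyro_noise_density * math.sqrt(self.gyro_bandwidth)


@dataclass
class ImuStream:
    """A contiguous multi-axial IMU recording in physical units (g / dps)."""

    spec: SensorSpec
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray
    gyro_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    gyro_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    gyro_z: np.ndarray = field(default_factory=lambda: np.empty(0))
    start_time: float = 0.0  # seconds since epoch

    def __post_init__(self):
        if not (len(self.accel_x) == len(self.accel_y) == len(self.accel_z)):
            raise ContractError("accelerometer axis arrays must have equal length")
        if not (len(self.gyro_x) == len(self.gyro_y) == len(self.gyro_z)):
            raise ContractError("gyroscope axis arrays must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.accel_x)

    @property
    def duration(self) -> float:
        """Stream duration in seconds, from the accelerometer channel."""
        return self.n_samples / self.spec.accel_rate

    def accel(self, axis: str) -> np.ndarray:
        return {"x": self.accel_x, "y": self.accel_y, "z": self.accel_z}[axis]

    @property
    def has_gyro(self) -> bool:
        return len(self.gyro_x) > 0


@dataclass
class Window:
    """One fixed-length analysis window of the three accelerometer axes."""

    index: int
    start_time: float
    duration: float
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray

    def accel(self, axis: str) -> np.ndarray:
        return {"x": self.accel_x, "y": self.accel_y, "z": self.accel_z}[axis]

    @property
    def n_samples(self) -> int:
        return len(self.accel_x)


def segment_windows(stream: ImuStream, window_s: float = WINDOW_S) -> list[Window]:
    """Cut a stream into consecutive non-overlapping windows of ``window_s`` seconds.

    Windows are anchored at the stream start; window i starts at
    ``start_time + i * window_s``. The trailing partial window is discarded,
    so a stream shorter than one window yields an empty list. Each window
    holds exactly ``round(window_s * accel_rate)`` samples.
    """
    if window_s <= 0:
        raise ContractError("window_s must be positive")
    per = int(round(window_s * stream.spec.accel_rate))
    n_windows = stream.n_samples // per
    out = []
    for i in range(n_windows):
        sl = slice(i * per, (i + 1) * per)
        out.append(
            Window(
                index=i,
                start_time=stream.start_time + i * window_s,
                duration=window_s,
                accel_x=stream.accel_x[sl],
                accel_y=stream.accel_y[sl],
                accel_z=stream.accel_z[sl],
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O: one delimited table per stream, header naming axes, plus a sidecar
# key-value metadata file <path>.meta carrying start_time and sample rates.
# ---------------------------------------------------------------------------

def _meta_path(path) -> str:
    return f"{path}.meta"


def write_imu_table(stream: ImuStream, path) -> None:
    """Write a per-sample CSV (``ax,ay,az[,gx,gy,gz]``) and its ``.meta`` sidecar."""
    cols = {"ax": stream.accel_x, "ay": stream.accel_y, "az": stream.accel_z}
    if stream.has_gyro:
        cols.update({"gx": stream.gyro_x, "gy": stream.gyro_y, "gz": stream.gyro_z})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    with open(_meta_path(path), "w") as fh:
        fh.write(f"start_time={stream.start_time!r}\n")
        fh.write(f"accel_rate={stream.spec.accel_rate!r}\n")
        fh.write(f"gyro_rate={stream.spec.gyro_rate!r}\n")


def _read_meta(path) -> dict[str, float]:
    meta: dict[str, float] = {}
    try:
        with open(_meta_path(path)) as fh:
            for line in fh:
                line = line.strip()
                if not line or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                meta[key.strip()] = float(value)
    except FileNotFoundError:
        pass
    return meta


def read_imu_table(path, spec: SensorSpec, start_time: float | None = None) -> ImuStream:
    """Read a per-sample CSV written in the :func:`write_imu_table` dialect.

    The table must carry one column per accelerometer axis (``ax,ay,az``);
    gyroscope columns are optional. Values are physical units (g / dps).
    Samples outside the accelerometer full scale are flagged with a warning
    (they indicate clipping at acquisition), never silently altered.

    Raises :class:`FormatError` on a missing axis column and
    :class:`ParseError` (with the first offending row) on a non-numeric cell.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed CSV structure
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in ACCEL_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing accelerometer column {col!r} in {path}")

    def _numeric(col: str) -> np.ndarray:
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(np.isnan(values) & ~table[col].isna().to_numpy())[0]
        if bad.size:
            raise ParseError(f"non-numeric value in column {col!r}", row=int(bad[0]))
        if np.isnan(values).any():
            raise ParseError(f"empty cell in column {col!r}",
                             row=int(np.nonzero(np.isnan(values))[0][0]))
        return values

    accel = [_numeric(c) for c in ACCEL_COLUMNS]
    if any(np.abs(a).max(initial=0.0) > spec.accel_full_scale for a in accel):
        warnings.warn(
            "accelerometer samples exceed the configured full scale "
            f"(±{spec.accel_full_scale} g); acquisition clipping suspected",
            stacklevel=2,
        )
    gyro = (
        [_numeric(c) for c in GYRO_COLUMNS]
        if all(c in table.columns for c in GYRO_COLUMNS)
        else [np.empty(0)] * 3
    )
    meta = _read_meta(path)
    if start_time is None:
        start_time = meta.get("start_time", 0.0)
    return ImuStream(spec, *accel, *gyro, start_time=start_time)
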