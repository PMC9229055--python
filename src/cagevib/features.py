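"""The eleven spectral/time-domain predictors computed per 15-s window.

Each accelerometer axis of a window is mean-removed and transformed with a
single rectangular-window real FFT (frequency resolution 1/15 ≈ 0.067 Hz, so
spectral leakage is negligible against the ≥ 4 Hz-wide bands). Bin
magnitudes are RMS-scaled so that Parseval's identity holds exactly:

    mean((x − x̄)²)  =  Σ_bins magnitude²

hence a pure sinusoid of amplitude A concentrates a magnitude of A/√2 in its
bin, and the time-domain RMS equals the root of the summed bin powers.

The feature set (fixed order):

====  ====  =======================================================
 #    axis  feature
====  ====  =======================================================
 1     X    relative average of FFT magnitudes, 23–27 Hz
 2     X    absolute average of FFT magnitudes, 23–27 Hz
 3     X    RMS of the time-domain signal
 4     Y    relative average, 62–80 Hz
 5     Y    absolute average, 62–80 Hz
 6     Y    RMS
 7     Z    relative average, 80–120 Hz
 8     Z    absolute average, 80–120 Hz
 9     Z    relative average, 60–180 Hz
10     Z    absolute average, 60–180 Hz
11     Z    RMS
====  ====  =======================================================

"Relative average" is the band mean magnitude divided by the mean magnitude
over all bins (DC excluded): ≈ 1 on a flat (white-noise) spectrum and
invariant under amplitude scaling, so it isolates band shape from overall
vibration level. The divisor convention is configurable (``power=True``
averages squared magnitudes instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .imu import Window

__all__ = [
    "Spectrum", "BandSpec", "spectrum", "band_absolute_average",
    "band_relative_average", "rms", "extract_features", "features_table",
    "FEATURE_NAMES", "TABLE_BANDS", "AXIS_FEATURES",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band on one axis; bins with lo <= f <= hi are selected."""

    axis: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ContractError("band must satisfy 0 < lo < hi")


#: The four analysis bands, matched to the observed cage modes.
TABLE_BANDS = {
    "x_23_27": BandSpec("x", 23.0, 27.0),
    "y_62_80": BandSpec("y", 62.0, 80.0),
    "z_80_120": BandSpec("z", 80.0, 120.0),
    "z_60_180": BandSpec("z", 60.0, 180.0),
}

FEATURE_NAMES = (
    "x_rel_23_27", "x_abs_23_27", "x_rms",
    "y_rel_62_80", "y_abs_62_80", "y_rms",
    "z_rel_80_120", "z_abs_80_120", "z_rel_60_180", "z_abs_60_180", "z_rms",
)

#: Feature indices contributed by each accelerometer axis.
AXIS_FEATURES = {"x": (0, 1, 2), "y": (3, 4, 5), "z": (6, 7, 8, 9, 10)}


@dataclass
class Spectrum:
    """One-sided magnitude spectrum (RMS amplitude per bin, DC excluded)."""

    freqs: np.ndarray      # Hz, ascending, first positive bin to Nyquist
    magnitude: np.ndarray  # g per bin

    def __post_init__(self):
        if len(self.freqs) != len(self.magnitude):
            raise ContractError("freqs and magnitude must have equal length")


def spectrum(samples: np.ndarray, rate: float) -> Spectrum:
    """Mean-removed real-input DFT, RMS-scaled so Parseval holds exactly.

    ``sum(magnitude**2) == mean((x - mean(x))**2)`` up to floating point.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ContractError("spectrum requires at least two samples")
    x = x - x.mean()
    n = x.size
    coef = np.fft.rfft(x)
    mag = np.abs(coef) * (np.sqrt(2.0) / n)
    if n % 2 == 0:
        mag[-1] /= np.sqrt(2.0)  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return Spectrum(freqs[1:], mag[1:])


def _band_mask(s: Spectrum, band: BandSpec) -> np.ndarray:
    mask = (s.freqs >= band.lo) & (s.freqs <= band.hi)
    if not mask.any():
        raise ContractError(f"band [{band.lo}, {band.hi}] Hz selects no spectrum bins")
    return mask


def band_absolute_average(s: Spectrum, band: BandSpec, power: bool = False) -> float:
    """Arithmetic mean of the bin magnitudes with lo <= f <= hi (inclusive)."""
    m = s.magnitude[_band_mask(s, band)]
    return float(np.mean(m**2)) if power else float(m.mean())


def band_relative_average(s: Spectrum, band: BandSpec, power: bool = False) -> float:
    """Band average divided by the whole-spectrum (DC-excluded) average.

    Dimensionless and amplitude-invariant; exactly 1 on a flat spectrum.
    Defined as 0 on an all-zero spectrum.
    """
    m = s.magnitude**2 if power else s.magnitude
    total = m.mean()
    if total == 0:
        return 0.0
    return float(m[_band_mask(s, band)].mean() / total)


def rms(samples: np.ndarray) -> float:
    """Root-mean-square of the mean-removed samples (gravity/DC excluded)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ContractError("rms requires a non-empty window")
    x = x - x.mean()
    return float(np.sqrt(np.mean(x**2)))


def extract_features(window: Window, power: bool = False) -> np.ndarray:
    """The 11 predictors of one window, ordered as :data:`FEATURE_NAMES`.

    The sample rate is recovered from the window itself
    (``n_samples / duration``).
    """
    rate = window.n_samples / window.duration
    spectra = {a: spectrum(window.accel(a), rate) for a in ("x", "y", "z")}

    def pair(key: str) -> tuple[float, float]:
        band = TABLE_BANDS[key]
        s = spectra[band.axis]
        return (band_relative_average(s, band, power),
                band_absolute_average(s, band, power))

    x_rel, x_abs = pair("x_23_27")
    y_rel, y_abs = pair("y_62_80")
    z1_rel, z1_abs = pair("z_80_120")
    z2_rel, z2_abs = pair("z_60_180")
    return np.array([
        x_rel, x_abs, rms(window.accel_x),
        y_rel, y_abs, rms(window.accel_y),
        z1_rel, z1_abs, z2_rel, z2_abs, rms(window.accel_z),
    ])


def features_table(windows, power: bool = False) -> pd.DataFrame:
    """Feature matrix of many windows with bookkeeping columns.

    Columns: ``window_index``, ``start_time`` and the 11 named features.
    """
    rows = [extract_features(w, power=power) for w in windows]
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table.insert(0, "start_time", [w.start_time for w in windows])
    table.insert(0, "window_index", [w.index for w in windows])
    return table
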