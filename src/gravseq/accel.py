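"""Accelerometer signal processing.

Turns a raw triaxial acceleration recording into the quantities used by the
downstream statistics:

* an orientation-independent magnitude ``g = sqrt(gx^2 + gy^2 + gz^2)``,
* a zero-phase high-pass filtered vibration series ``g_f`` (the high-pass
  removes the quasi-static gravito-inertial component and the band where a
  piezoelectric sensor's response is not unity),
* root-mean-square vibration in fixed-width (default 1 s) bins, and
* Welch power spectral densities.

The high-pass is a minimum-order elliptic IIR designed to a stopband /
passband / ripple specification (defaults: stopband edge 5 Hz at 60 dB,
passband edge 10 Hz with 1 dB ripple, 5 kHz sample rate) and applied
forward-backward, so the effective attenuation doubles in dB and the phase
delay is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, InputError

__all__ = [
    "AccelTrace",
    "FilterSpec",
    "VibrationSeries",
    "PSDResult",
    "vibration_magnitude",
    "design_highpass",
    "zero_phase_filter",
    "rms_bins",
    "welch_psd",
    "process_vibration",
    "read_accel_csv",
    "write_accel_csv",
]


@dataclass
class AccelTrace:
    """Uniformly sampled triaxial acceleration, in Earth-g units."""

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    sample_rate: float = 5000.0

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        self.gz = np.asarray(self.gz, dtype=float)
        if not (len(self.gx) == len(self.gy) == len(self.gz)):
            raise InputError(
                "axis series must have equal length, got "
                f"({len(self.gx)}, {len(self.gy)}, {len(self.gz)})"
            )
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.gx)

    @property
    def t(self) -> np.ndarray:
        """Elapsed time of each sample, seconds from recording start."""
        return np.arange(len(self.gx)) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return len(self.gx) / self.sample_rate


@dataclass(frozen=True)
class FilterSpec:
    """High-pass design specification (frequencies in Hz, levels in dB)."""

    stop_hz: float = 5.0
    pass_hz: float = 10.0
    stop_atten_db: float = 60.0
    pass_ripple_db: float = 1.0
    sample_rate: float = 5000.0

    def __post_init__(self) -> None:
        if not (0 < self.stop_hz < self.pass_hz < self.sample_rate / 2):
            raise InputError(
                "need 0 < stop_hz < pass_hz < Nyquist, got "
                f"stop={self.stop_hz}, pass={self.pass_hz}, fs={self.sample_rate}"
            )
        if self.stop_atten_db <= 0:
            raise InputError("stop_atten_db must be positive")


@dataclass
class VibrationSeries:
    """Magnitude, filtered magnitude, and binned RMS vibration."""

    g: np.ndarray
    g_f: np.ndarray
    sample_rate: float
    bin_start_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    rms_g: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_s: float = 1.0


@dataclass
class PSDResult:
    """One-sided power spectral density, power in g^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray


def vibration_magnitude(trace: AccelTrace) -> np.ndarray:
    """Orientation-independent acceleration magnitude per sample.

    Elementwise Euclidean norm of the three axes; invariant under any
    rotation of the sensor because rotations preserve vector norms.
    """
    return np.sqrt(trace.gx**2 + trace.gy**2 + trace.gz**2)


def design_highpass(spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Minimum-order elliptic high-pass meeting ``spec``, as SOS.

    ``scipy.signal.ellipord`` finds the smallest order whose single-pass
    magnitude response is within ``pass_ripple_db`` of unity above
    ``pass_hz`` and at least ``stop_atten_db`` down at ``stop_hz``; the
    filter is returned as second-order sections for numerical stability.
    """
    order, wn = signal.ellipord(
        spec.pass_hz, spec.stop_hz, spec.pass_ripple_db, spec.stop_atten_db,
        fs=spec.sample_rate,
    )
    return signal.ellip(
        order, spec.pass_ripple_db, spec.stop_atten_db, wn,
        btype="highpass", output="sos", fs=spec.sample_rate,
    )


def filter_order(sos: np.ndarray) -> int:
    """Effective filter order of an SOS cascade."""
    return 2 * len(np.atleast_2d(sos))


def zero_phase_filter(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    """Apply ``sos`` forward and backward (zero phase delay).

    Edge transients are suppressed by odd-reflective padding of
    3 x filter order samples. Output length equals input length; the
    effective magnitude response is |H|^2, so stated stopband attenuations
    double in dB.
    """
    x = np.asarray(x, dtype=float)
    padlen = 3 * filter_order(sos)
    if len(x) <= padlen:
        raise InputError(
            f"signal length {len(x)} must exceed filter warm-up ({padlen} samples)"
        )
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def rms_bins(x: np.ndarray, sample_rate: float, bin_s: float = 1.0):
    """Root-mean-square of ``x`` over consecutive ``bin_s``-second bins.

    Bins are aligned to the recording start (t = 0); a trailing partial
    bin is dropped. Returns ``(bin_start_s, rms)`` arrays.
    """
    if bin_s <= 0:
        raise InputError("bin_s must be positive")
    x = np.asarray(x, dtype=float)
    per_bin = int(round(bin_s * sample_rate))
    n_bins = len(x) // per_bin
    if n_bins == 0:
        return np.empty(0), np.empty(0)
    trimmed = x[: n_bins * per_bin].reshape(n_bins, per_bin)
    rms = np.sqrt(np.mean(trimmed**2, axis=1))
    starts = np.arange(n_bins) * bin_s
    return starts, rms


def welch_psd(
    x: np.ndarray,
    sample_rate: float,
    n_segments: int = 8,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PSDResult:
    """One-sided Welch PSD with pwelch-style defaults.

    The signal is split into ``n_segments`` segments with the given
    fractional ``overlap`` (so the segment length is
    ``floor(N / (n_segments*(1-overlap) + overlap))``), each windowed
    (Hamming by default), periodograms averaged.
    """
    x = np.asarray(x, dtype=float)
    denom = n_segments * (1 - overlap) + overlap
    nperseg = int(len(x) // denom)
    if nperseg < 2:
        raise InputError(
            f"signal too short ({len(x)} samples) for {n_segments} Welch segments"
        )
    freqs, power = signal.welch(
        x, fs=sample_rate, window=window, nperseg=nperseg,
        noverlap=int(nperseg * overlap), scaling="density",
    )
    return PSDResult(freqs=freqs, power=power)


def process_vibration(
    trace: AccelTrace,
    spec: FilterSpec | None = None,
    bin_s: float = 1.0,
) -> VibrationSeries:
    """Magnitude -> zero-phase high-pass -> 1-s RMS, in one call."""
    if spec is None:
        spec = FilterSpec(sample_rate=trace.sample_rate)
    g = vibration_magnitude(trace)
    sos = design_highpass(spec)
    g_f = zero_phase_filter(g, sos)
    starts, rms = rms_bins(g_f, trace.sample_rate, bin_s)
    return VibrationSeries(
        g=g, g_f=g_f, sample_rate=trace.sample_rate,
        bin_start_s=starts, rms_g=rms, bin_s=bin_s,
    )


def read_accel_csv(path) -> AccelTrace:
    """Read a ``t,gx,gy,gz`` CSV/TSV (header required, units Earth-g)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"t", "gx", "gy", "gz"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: time must be strictly increasing and uniform")
    return AccelTrace(
        gx=df["gx"].to_numpy(float), gy=df["gy"].to_numpy(float),
        gz=df["gz"].to_numpy(float), sample_rate=1.0 / steps[0],
    )


def write_accel_csv(trace: AccelTrace, path) -> None:
    pd.DataFrame(
        {"t": trace.t, "gx": trace.gx, "gy": trace.gy, "gz": trace.gz}
    ).to_csv(path, index=False, float_format="%.6f")


def write_psd_tsv(psd: PSDResult, path) -> None:
    pd.DataFrame({"freq_hz": psd.freqs, "power": psd.power}).to_csv(
        path, sep="\t", index=False
    )


def write_rms_tsv(bin_start_s: np.ndarray, rms_g: np.ndarray, path) -> None:
    pd.DataFrame({"bin_start_s": bin_start_s, "rms_g": rms_g}).to_csv(
        path, sep="\t", index=False
    )


def read_rms_tsv(path):
    df = pd.read_csv(path, sep="\t")
    if not {"bin_start_s", "rms_g"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns bin_start_s, rms_g")
    return df["bin_start_s"].to_numpy(float), df["rms_g"].to_numpy(float)
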