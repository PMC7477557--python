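"""Joint timeline of sequencing and acceleration data.

Reads and bases carry instrument-clock timestamps; the accelerometer has
its own elapsed-time origin. This module shifts sequencing records onto
the accelerometer clock, assigns each read a flight phase (a read belongs
to a phase only if its whole interval lies inside one period — otherwise
it is "spanning"), and builds the 1-s joint bin series that every
regression and ANOVA consumes:

* ``median_q_pbar``: median representative quality over all reads whose
  interval overlaps the bin (NaN if none);
* ``median_norm_std``: median per-base ionic-current noise over bases
  whose timestamp falls in the bin (NaN if none);
* ``rms_g``: 1-s RMS of the high-pass filtered vibration;
* ``mean_g``: mean unfiltered magnitude (the g level);
* ``phase``: label of the period containing the bin midpoint.

Boundary convention: a point exactly on a bin or period boundary belongs
to the earlier interval; an interval whose endpoint coincides with a
period edge still counts as wholly within (closed containment).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accel import VibrationSeries, rms_bins
from .errors import InputError
from .segmentation import PhasePeriod

__all__ = [
    "apply_time_offset",
    "assign_phase",
    "assign_phases",
    "build_bins",
    "truncate_elapsed",
    "BIN_COLUMNS",
]

BIN_COLUMNS = [
    "bin_start_s", "elapsed_s", "median_q_pbar", "median_norm_std",
    "rms_g", "mean_g", "phase",
]


def apply_time_offset(records: pd.DataFrame, offset_s: float,
                      columns: Sequence[str] = ("start_s",)) -> pd.DataFrame:
    """Shift time columns by ``offset_s`` (instrument -> accelerometer clock)."""
    if not np.isfinite(offset_s):
        raise InputError("offset must be finite")
    out = records.copy()
    for col in columns:
        out[col] = out[col] + offset_s
    return out


def assign_phase(start_s: float, end_s: float,
                 periods: Sequence[PhasePeriod]) -> str:
    """Phase label of ``[start_s, end_s]`` or "spanning".

    Closed containment: the interval must lie inside one period, with
    endpoints allowed to touch the period's edges. A zero-length interval
    sitting exactly on a shared boundary belongs to the earlier period.
    Intervals outside the covered range are "spanning".
    """
    if start_s > end_s:
        raise InputError(f"interval start {start_s} > end {end_s}")
    for p in sorted(periods, key=lambda q: q.start_s):
        if p.start_s <= start_s and end_s <= p.end_s:
            if start_s == end_s == p.start_s and any(
                q.end_s == p.start_s for q in periods
            ):
                continue  # boundary point belongs to the earlier period
            return p.label
    return "spanning"


def assign_phases(reads: pd.DataFrame, periods: Sequence[PhasePeriod]) -> pd.Series:
    """Vectorised :func:`assign_phase` over read intervals.

    Expects ``start_s`` and ``duration_s`` columns; returns a label
    series aligned with ``reads``.
    """
    ordered = sorted(periods, key=lambda p: p.start_s)
    starts = np.array([p.start_s for p in ordered])
    ends = np.array([p.end_s for p in ordered])
    labels = np.array([p.label for p in ordered], dtype=object)
    s = reads["start_s"].to_numpy(float)
    e = s + reads["duration_s"].to_numpy(float)
    # candidate period: last one starting at or before s; a point exactly
    # at a shared boundary goes to the earlier period, so use side="right"
    # minus one, then step back when s == e == candidate.start.
    idx = np.searchsorted(starts, s, side="right") - 1
    out = np.full(len(s), "spanning", dtype=object)
    valid = idx >= 0
    point_on_edge = valid & (s == e) & (s == starts[np.clip(idx, 0, None)]) & (idx > 0)
    idx = np.where(point_on_edge, idx - 1, idx)
    inside = valid & (e <= ends[np.clip(idx, 0, None)])
    out[inside] = labels[np.clip(idx, 0, None)][inside]
    return pd.Series(out, index=reads.index, name="phase")


def _bin_phase(midpoints: np.ndarray, periods: Sequence[PhasePeriod]) -> np.ndarray:
    ordered = sorted(periods, key=lambda p: p.start_s)
    starts = np.array([p.start_s for p in ordered])
    ends = np.array([p.end_s for p in ordered])
    labels = np.array([p.label for p in ordered], dtype=object)
    idx = np.searchsorted(starts, midpoints, side="right") - 1
    out = np.full(len(midpoints), "other", dtype=object)
    ok = (idx >= 0) & (midpoints < ends[np.clip(idx, 0, None)])
    out[ok] = labels[np.clip(idx, 0, None)][ok]
    return out


def build_bins(
    reads: pd.DataFrame,
    bases: pd.DataFrame,
    vib: VibrationSeries,
    periods: Iterable[PhasePeriod],
    bin_s: float = 1.0,
) -> pd.DataFrame:
    """Build the joint 1-s bin series on the accelerometer clock.

    ``reads``/``bases`` must already be offset onto the accelerometer
    clock and mux reads excluded upstream. The number of bins follows the
    vibration series; records outside it are ignored.
    """
    periods = list(periods)
    if len(vib.rms_g) == 0:
        starts, rms = rms_bins(vib.g_f, vib.sample_rate, bin_s)
    else:
        starts, rms = vib.bin_start_s, vib.rms_g
    n_bins = len(starts)
    per_bin = int(round(bin_s * vib.sample_rate))
    mean_g = (
        vib.g[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
        if n_bins
        else np.empty(0)
    )

    med_q = np.full(n_bins, np.nan)
    if len(reads):
        s = reads["start_s"].to_numpy(float)
        e = s + reads["duration_s"].to_numpy(float)
        q = reads["q_pbar"].to_numpy(float)
        # bins overlapped by [s, e]: k from floor(s/bin) to floor(e/bin),
        # a point exactly at a bin edge belonging to the earlier bin
        k0 = np.floor(s / bin_s).astype(int)
        k1 = np.floor(e / bin_s).astype(int)
        edge = (e == k1 * bin_s) & (k1 > k0)
        k1 = np.where(edge, k1 - 1, k1)
        k0 = np.clip(k0, 0, n_bins)  # may exceed range; filtered below
        counts = np.maximum(0, np.minimum(k1, n_bins - 1) - k0 + 1)
        keep = counts > 0
        bin_idx = np.concatenate(
            [np.arange(a, a + c) for a, c in zip(k0[keep], counts[keep])]
        ) if keep.any() else np.empty(0, dtype=int)
        q_rep = np.repeat(q[keep], counts[keep])
        med_q_series = pd.Series(q_rep).groupby(bin_idx).median()
        med_q[med_q_series.index.to_numpy()] = med_q_series.to_numpy()

    med_noise = np.full(n_bins, np.nan)
    if len(bases):
        t = bases["t_s"].to_numpy(float)
        k = np.floor(t / bin_s).astype(int)
        on_edge = (t == k * bin_s) & (k > 0)
        k = np.where(on_edge, k - 1, k)
        ok = (k >= 0) & (k < n_bins)
        med = pd.Series(bases["norm_std"].to_numpy(float)[ok]).groupby(k[ok]).median()
        med_noise[med.index.to_numpy()] = med.to_numpy()

    midpoints = starts + bin_s / 2
    return pd.DataFrame(
        {
            "bin_start_s": starts,
            "elapsed_s": starts,
            "median_q_pbar": med_q,
            "median_norm_std": med_noise,
            "rms_g": rms,
            "mean_g": mean_g,
            "phase": _bin_phase(midpoints, periods),
        },
        columns=BIN_COLUMNS,
    )


def truncate_elapsed(bins: pd.DataFrame, max_s: float = 4000.0) -> pd.DataFrame:
    """Keep bins with ``elapsed_s <= max_s`` (inclusive).

    The tail of a recording (aircraft descent and landing) confounds the
    time trend, so regressions run on the truncated series.
    """
    if max_s <= 0:
        raise InputError("max_s must be positive")
    return bins[bins["elapsed_s"] <= max_s].reset_index(drop=True)


def write_bins(bins: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        bins.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_bins(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
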