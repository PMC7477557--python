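"""Flight-phase segmentation of an acceleration-magnitude timeline.

A parabolic flight alternates between roughly 1-g cruise ("other"),
~1.8-g pull-up/pull-out arcs ("hypergravity"), reduced-g plateaus
("parabola", targeting e.g. Mars 0.378 g, Lunar 0.166 g, or 0 g), and the
brief ramps between a hypergravity arc and a parabola ("transition").

The classifier thresholds a smoothed magnitude profile:

1. block-average the magnitude down to a coarse profile (20 Hz) — vibration
   averages out and the moving median becomes cheap;
2. centred 1-s moving median;
3. hypergravity: smoothed g >= ``hyper_thresh`` sustained >= ``hyper_min_s``;
4. parabola: smoothed g < ``parabola_max_g`` and within ``plateau_tol`` of
   the nearest configured target, sustained >= ``parabola_min_s``; the
   period's target is the configured target nearest its median smoothed g
   (ties toward the lower g);
5. transition: any gap between a hypergravity period and an adjacent
   parabola period;
6. other: the remainder.

Periods are non-overlapping, cover the analysed interval, and re-running on
the same input is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = [
    "PhasePeriod",
    "SegmentationParams",
    "segment_phases",
    "read_periods",
    "write_periods",
    "PHASE_LABELS",
]

PHASE_LABELS = ("parabola", "transition", "hypergravity", "other")


@dataclass(frozen=True)
class PhasePeriod:
    """A labeled half-open interval [start_s, end_s) of the flight."""

    start_s: float
    end_s: float
    label: str
    target_g: float | None = None

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise InputError(f"unknown phase label {self.label!r}")
        if not self.start_s < self.end_s:
            raise InputError(f"empty period [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SegmentationParams:
    hyper_thresh: float = 1.2
    hyper_min_s: float = 2.0
    plateau_tol: float = 0.07
    parabola_max_g: float = 0.5
    parabola_min_s: float = 5.0
    targets: tuple[float, ...] = (0.0, 0.166, 0.378)
    smooth_s: float = 1.0
    profile_rate: float = 20.0


def _nearest_target(g: float, targets: tuple[float, ...]) -> float:
    # ties broken toward the lower g: stable sort on (distance, target)
    return min(sorted(targets), key=lambda t: (abs(g - t)))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop index pairs (half-open) of True runs in a boolean mask."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def segment_phases(
    magnitude: np.ndarray,
    sample_rate: float,
    params: SegmentationParams = SegmentationParams(),
) -> list[PhasePeriod]:
    """Classify a magnitude series into flight-phase periods.

    Returns periods sorted by start, non-overlapping, covering
    ``[0, len(magnitude)/sample_rate)``. A trace with no excursions yields
    a single "other" period.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.size == 0:
        raise InputError("empty magnitude series")
    if np.any(magnitude < 0):
        raise InputError("magnitude must be nonnegative")
    total_s = len(magnitude) / sample_rate

    # coarse profile by block means, then centred moving median
    block = max(1, int(round(sample_rate / params.profile_rate)))
    n_blocks = len(magnitude) // block
    if n_blocks < 2:
        return [PhasePeriod(0.0, total_s, "other")]
    profile = magnitude[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    dt = block / sample_rate
    win = max(1, int(round(params.smooth_s / dt)) | 1)  # odd window
    smooth = (
        pd.Series(profile).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    t_mid = (np.arange(n_blocks) + 0.5) * dt

    hyper_runs = [
        (i, j)
        for i, j in _runs(smooth >= params.hyper_thresh)
        if (j - i) * dt >= params.hyper_min_s
    ]

    near = np.full(n_blocks, False)
    for tgt in params.targets:
        near |= np.abs(smooth - tgt) <= params.plateau_tol
    para_mask = near & (smooth < params.parabola_max_g)
    para_runs = [
        (i, j)
        for i, j in _runs(para_mask)
        if (j - i) * dt >= params.parabola_min_s
    ]

    labeled: list[PhasePeriod] = []
    for i, j in hyper_runs:
        labeled.append(PhasePeriod(i * dt, j * dt, "hypergravity"))
    for i, j in para_runs:
        med = float(np.median(smooth[i:j]))
        labeled.append(
            PhasePeriod(i * dt, j * dt, "parabola",
                        target_g=_nearest_target(med, params.targets))
        )
    labeled.sort(key=lambda p: p.start_s)

    # transitions: gaps between adjacent hypergravity and parabola periods
    out: list[PhasePeriod] = []
    cursor = 0.0
    for k, p in enumerate(labeled):
        if p.start_s > cursor:
            prev = labeled[k - 1] if k > 0 and labeled[k - 1].end_s == cursor else None
            gap_is_transition = (
                prev is not None
                and {prev.label, p.label} == {"hypergravity", "parabola"}
            )
            out.append(
                PhasePeriod(cursor, p.start_s,
                            "transition" if gap_is_transition else "other")
            )
        out.append(p)
        cursor = p.end_s
    if cursor < total_s:
        out.append(PhasePeriod(cursor, total_s, "other"))
    if not out:
        out = [PhasePeriod(0.0, total_s, "other")]
    return out


def write_periods(periods: list[PhasePeriod], path) -> None:
    """Write a periods table: TSV with start_s, end_s, label, target_g."""
    _check_disjoint(periods)
    rows = [
        {
            "start_s": f"{p.start_s:.3f}",
            "end_s": f"{p.end_s:.3f}",
            "label": p.label,
            "target_g": "" if p.target_g is None else f"{p.target_g:g}",
        }
        for p in periods
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label", "target_g"]).to_csv(
        path, sep="\t", index=False
    )


def read_periods(path) -> list[PhasePeriod]:
    """Read a periods.txt-style table written by :func:`write_periods`."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    periods = []
    for _, row in df.iterrows():
        label = row["label"]
        if label not in PHASE_LABELS:
            raise FormatError(f"{path}: unknown label {label!r}")
        tg = row.get("target_g")
        target = None if tg is None or pd.isna(tg) else float(tg)
        try:
            periods.append(
                PhasePeriod(float(row["start_s"]), float(row["end_s"]), label, target)
            )
        except InputError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    _check_disjoint(periods, path)
    return periods


def _check_disjoint(periods: list[PhasePeriod], path=None) -> None:
    ordered = sorted(periods, key=lambda p: p.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - 1e-9:
            where = f"{path}: " if path else ""
            raise FormatError(
                f"{where}overlapping periods [{a.start_s}, {a.end_s}) and "
                f"[{b.start_s}, {b.end_s})"
            )
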