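"""Synthetic parabolic-flight accelerometer traces with ground truth.

The generator builds a low-frequency gravito-inertial profile from a flight
plan — sets of parabolas, each bracketed by ~1.8-g hypergravity arcs, with
smooth cosine ramps between plateau levels — and superimposes aircraft-like
vibration: a set of narrowband sinusoidal peaks (default near 120, 260,
495, 620 and 876 Hz) plus broadband noise, attenuated during parabolas
(freefall is the quietest phase of the flight).

Ground truth is returned as the exact construction intervals:

* parabola = the reduced-g plateau;
* hypergravity = where the ideal profile is >= ``hyper_entry_g`` (1.2 g),
  i.e. ramp tails above the threshold belong to the arc;
* transition = the below-threshold part of a ramp joining a hypergravity
  arc to a parabola;
* other = everything else (cruise, and ramp tails below threshold next to
  cruise).

Zero-g plateaus sit at a small residual level (default 0.041 g with 0.005 g
spread) rather than exactly zero, as real parabolas do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..accel import AccelTrace
from ..errors import InputError
from ..segmentation import PhasePeriod

__all__ = ["FlightPlan", "VibrationModel", "make_flight", "flight_truth_rms"]

#: per-target default parabola plateau durations, seconds (reduced-g arcs
#: at higher residual g are flown longer)
_DEFAULT_PARABOLA_S = {0.0: 22.0, 0.166: 26.0, 0.378: 33.0}


@dataclass(frozen=True)
class FlightPlan:
    """Parabola schedule and phase durations (seconds, Earth-g)."""

    sets: tuple[int, ...] = (5, 6, 4, 5)
    #: target g per parabola, flattened over sets; defaults to the flown
    #: schedule: first set Mars, Mars, Lunar, 0, 0; all others 0 g.
    targets: tuple[float, ...] | None = None
    hyper_g: float = 1.8
    base_g: float = 1.0
    hyper_entry_g: float = 1.2
    hyper_s: float = 20.0
    transition_s: float = 3.0
    ramp_s: float = 3.0
    parabola_s: dict = field(default_factory=lambda: dict(_DEFAULT_PARABOLA_S))
    parabola_jitter_s: float = 10.0
    lead_in_s: float = 90.0
    between_sets_s: float = 120.0
    lead_out_s: float = 60.0
    zero_g_residual: float = 0.041
    zero_g_residual_sd: float = 0.005

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.sets):
            raise InputError("parabola counts must be positive")
        tg = self.resolved_targets()
        if any(not (0 <= t < 1) for t in tg):
            raise InputError("targets must lie in [0, 1)")

    def resolved_targets(self) -> tuple[float, ...]:
        if self.targets is not None:
            if len(self.targets) != sum(self.sets):
                raise InputError(
                    f"{len(self.targets)} targets for {sum(self.sets)} parabolas"
                )
            return tuple(self.targets)
        first = [0.378, 0.378, 0.166, 0.0, 0.0]
        n = sum(self.sets)
        tg = (first + [0.0] * n)[: self.sets[0]] + [0.0] * (n - self.sets[0])
        return tuple(tg[:n])


@dataclass(frozen=True)
class VibrationModel:
    """Spectral model of aircraft vibration (g units, Hz)."""

    peak_freqs: tuple[float, ...] = (120.0, 260.0, 495.0, 620.0, 876.0)
    peak_rms: tuple[float, ...] = (0.015, 0.010, 0.008, 0.008, 0.005)
    broadband_rms: float = 0.02
    #: per-phase-label RMS multiplier; labels absent here default to 1.0
    phase_scale: dict = field(default_factory=lambda: {"parabola": 0.5})
    freq_jitter_hz: float = 2.0
    #: unit vector distributing vibration over (x, y, z)
    axis_weights: tuple[float, float, float] = (0.15, 0.15, 0.977)

    def __post_init__(self) -> None:
        if len(self.peak_rms) != len(self.peak_freqs):
            raise InputError("peak_rms and peak_freqs must have equal length")
        if any(r < 0 for r in self.peak_rms) or self.broadband_rms < 0:
            raise InputError("RMS values must be nonnegative")

    def scale_for(self, label: str) -> float:
        return float(self.phase_scale.get(label, 1.0))


def flight_truth_rms(vib: VibrationModel, label: str) -> float:
    """Expected filtered 1-s RMS for a phase, from variance additivity.

    Independent components add in mean square, so the total RMS is
    ``scale * sqrt(sum(peak_rms^2) + broadband_rms^2)``.
    """
    if label not in {"parabola", "transition", "hypergravity", "other"}:
        raise InputError(f"unknown phase label {label!r}")
    base = math.sqrt(sum(r**2 for r in vib.peak_rms) + vib.broadband_rms**2)
    return vib.scale_for(label) * base


class _ProfileBuilder:
    """Accumulates plateau/ramp segments and the truth period list."""

    def __init__(self, sample_rate: float):
        self.fs = sample_rate
        self.chunks: list[np.ndarray] = []
        self.n = 0  # samples so far

    @property
    def t(self) -> float:
        return self.n / self.fs

    def plateau(self, g: float, duration_s: float) -> None:
        m = int(round(duration_s * self.fs))
        self.chunks.append(np.full(m, g))
        self.n += m

    def ramp(self, g0: float, g1: float, duration_s: float) -> None:
        m = int(round(duration_s * self.fs))
        if m < 2:
            raise InputError("ramp shorter than 2 samples")
        u = (np.arange(m) + 0.5) / m
        self.chunks.append(g0 + (g1 - g0) * (1 - np.cos(np.pi * u)) / 2)
        self.n += m

    def concat(self) -> np.ndarray:
        return np.concatenate(self.chunks) if self.chunks else np.empty(0)


def _ramp_crossing(g0: float, g1: float, duration_s: float, level: float) -> float:
    """Time within a cosine ramp at which it crosses ``level``."""
    frac = (level - g0) / (g1 - g0)
    return duration_s / math.pi * math.acos(1 - 2 * frac)


def make_flight(
    plan: FlightPlan = FlightPlan(),
    vib: VibrationModel = VibrationModel(),
    seed: int = 0,
    sample_rate: float = 5000.0,
) -> tuple[AccelTrace, list[PhasePeriod]]:
    """Generate a triaxial trace and its true phase periods.

    Deterministic per ``seed``. Raises if any vibration peak (after jitter)
    would exceed the Nyquist frequency.
    """
    if any(f + vib.freq_jitter_hz >= sample_rate / 2 for f in vib.peak_freqs):
        raise InputError("vibration peak frequencies must stay below Nyquist")
    min_phase = 2.0 / sample_rate
    for d in (plan.hyper_s, plan.transition_s, plan.ramp_s, plan.lead_in_s):
        if d < min_phase:
            raise InputError("phase durations must be at least 2 samples long")

    rng = np.random.default_rng(seed)
    b = _ProfileBuilder(sample_rate)
    truth: list[PhasePeriod] = []
    targets = plan.resolved_targets()

    def mark(start: float, end: float, label: str, target=None) -> None:
        if end > start:
            truth.append(PhasePeriod(start, end, label, target))

    # entry/exit crossing offsets inside ramps
    up_cross = _ramp_crossing(plan.base_g, plan.hyper_g, plan.ramp_s, plan.hyper_entry_g)
    other_end = 0.0  # running start of the current 'other' stretch
    idx = 0
    for si, count in enumerate(plan.sets):
        cruise = plan.lead_in_s if si == 0 else plan.between_sets_s
        b.plateau(plan.base_g, cruise)
        # cruise -> first pull-up: other until the ramp crosses hyper_entry_g
        mark(other_end, b.t + up_cross, "other")
        hyper_start = b.t + up_cross
        b.ramp(plan.base_g, plan.hyper_g, plan.ramp_s)
        b.plateau(plan.hyper_g, plan.hyper_s)
        for pi in range(count):
            target = targets[idx]
            idx += 1
            level = target
            if target == 0.0:
                level = max(0.0, rng.normal(plan.zero_g_residual,
                                            plan.zero_g_residual_sd))
            dur = plan.parabola_s.get(target, 22.0) + rng.uniform(
                -plan.parabola_jitter_s, plan.parabola_jitter_s
            )
            dur = max(8.0, dur)
            # hyper ends where the down-ramp crosses hyper_entry_g
            down_cross = _ramp_crossing(plan.hyper_g, level,
                                        plan.transition_s, plan.hyper_entry_g)
            mark(hyper_start, b.t + down_cross, "hypergravity")
            mark(b.t + down_cross, b.t + plan.transition_s, "transition")
            b.ramp(plan.hyper_g, level, plan.transition_s)
            para_start = b.t
            b.plateau(level, dur)
            mark(para_start, b.t, "parabola", target)
            # pull-out ramp back to hypergravity
            out_cross = _ramp_crossing(level, plan.hyper_g,
                                       plan.transition_s, plan.hyper_entry_g)
            mark(b.t, b.t + out_cross, "transition")
            hyper_start = b.t + out_cross
            b.ramp(level, plan.hyper_g, plan.transition_s)
            b.plateau(plan.hyper_g, plan.hyper_s)
        # final pull-out back to cruise
        down_cross = _ramp_crossing(plan.hyper_g, plan.base_g,
                                    plan.ramp_s, plan.hyper_entry_g)
        mark(hyper_start, b.t + down_cross, "hypergravity")
        other_end = b.t + down_cross
        b.ramp(plan.hyper_g, plan.base_g, plan.ramp_s)
    b.plateau(plan.base_g, plan.lead_out_s)
    mark(other_end, b.t, "other")

    profile = b.concat()
    n = len(profile)
    total_s = n / sample_rate
    truth.sort(key=lambda p: p.start_s)

    # per-sample vibration scale from truth labels
    scale = np.ones(n)
    for p in truth:
        s = vib.scale_for(p.label)
        if s != 1.0:
            i0 = int(round(p.start_s * sample_rate))
            i1 = int(round(p.end_s * sample_rate))
            scale[i0:i1] = s

    t = np.arange(n) / sample_rate
    vib_total = np.zeros(n)
    for f0, r in zip(vib.peak_freqs, vib.peak_rms):
        if r == 0:
            continue
        f = f0 + rng.uniform(-vib.freq_jitter_hz, vib.freq_jitter_hz)
        phase = rng.uniform(0, 2 * np.pi)
        vib_total += (r * math.sqrt(2)) * np.sin(2 * np.pi * f * t + phase)
    if vib.broadband_rms > 0:
        vib_total += rng.normal(0.0, vib.broadband_rms, n)
    vib_total *= scale

    wx, wy, wz = vib.axis_weights
    norm = math.sqrt(wx**2 + wy**2 + wz**2)
    wx, wy, wz = wx / norm, wy / norm, wz / norm
    trace = AccelTrace(
        gx=wx * vib_total,
        gy=wy * vib_total,
        gz=profile + wz * vib_total,
        sample_rate=sample_rate,
    )

    # truth periods must tile [0, total_s); snap the last end
    if truth and truth[-1].end_s < total_s:
        last = truth[-1]
        truth[-1] = PhasePeriod(last.start_s, total_s, last.label, last.target_g)
    return trace, truth
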