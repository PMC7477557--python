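"""End-to-end pipeline: accelerometer -> segmentation -> metrics ->
integration -> statistics, with deterministic, config-hashed outputs.

The stages mirror how the flight analysis proceeds: process vibration,
segment (or load) flight phases, parse the event table, place records on
the accelerometer clock, build the 1-s joint bins, truncate the tail, and
run the regressions / ANOVA / KS battery. Identical config plus seeds
yields byte-identical reports; every output declares the config hash it
was produced from.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accel, events, integration, segmentation, stats
from .errors import GravSeqError, InputError

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("gravseq")


@dataclass
class PipelineConfig:
    accel_path: str = ""
    events_path: str = ""
    periods_path: str | None = None      # load instead of segmenting
    ground_events_path: str | None = None  # enables the ground-vs-flight KS
    out_dir: str = "gravseq_out"
    offset_s: float = 0.0
    signal_rate: float = events.DEFAULT_SIGNAL_RATE
    bin_s: float = 1.0
    max_elapsed_s: float = 4000.0
    genome_length: int = 48502
    stop_hz: float = 5.0
    pass_hz: float = 10.0
    stop_atten_db: float = 60.0
    pass_ripple_db: float = 1.0
    exclude_transition_anova: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("accel_path", "events_path"):
            if not getattr(self, name):
                raise InputError(f"config field {name!r} is required")
            if not Path(getattr(self, name)).exists():
                raise InputError(f"config field {name!r}: no such file "
                                 f"{getattr(self, name)!r}")
        if self.signal_rate <= 0 or self.bin_s <= 0:
            raise InputError("rates and bin width must be positive")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _regression_report(result: stats.RegressionResult) -> dict:
    return {
        "terms": result.terms,
        "coefficients": result.coefficients,
        "p_values": result.p_values,
        "r2": result.r2,
        "adj_r2": result.adj_r2,
        "n_obs": result.n_obs,
        "history": result.history,
    }


def _write_json(obj: dict, path: Path, config_hash: str) -> None:
    obj = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; writes the report bundle and returns it in memory."""
    config.validate()
    chash = config.hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict = {"config_hash": chash}

    def stage(name):
        log.info("stage %s (config %s)", name, chash)

    try:
        stage("accel")
        trace = accel.read_accel_csv(config.accel_path)
        spec = accel.FilterSpec(
            stop_hz=config.stop_hz, pass_hz=config.pass_hz,
            stop_atten_db=config.stop_atten_db,
            pass_ripple_db=config.pass_ripple_db,
            sample_rate=trace.sample_rate,
        )
        vib = accel.process_vibration(trace, spec, config.bin_s)
    except GravSeqError as exc:
        raise GravSeqError(f"stage accel failed: {exc}") from exc

    try:
        if config.periods_path:
            stage("segment (load)")
            periods = segmentation.read_periods(config.periods_path)
        else:
            stage("segment")
            magnitude = accel.vibration_magnitude(trace)
            periods = segmentation.segment_phases(magnitude, trace.sample_rate)
        segmentation.write_periods(periods, out / "periods.txt")
    except GravSeqError as exc:
        raise GravSeqError(f"stage segment failed: {exc}") from exc

    try:
        stage("metrics")
        reads, bases = events.parse_event_table(config.events_path,
                                                config.signal_rate)
        reads = integration.apply_time_offset(reads, config.offset_s)
        bases = integration.apply_time_offset(bases, config.offset_s,
                                              columns=("t_s",))
        genome = events.GenomeRef(length=config.genome_length)
        coverage = events.phase_coverage(bases, periods, genome)
        coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    except GravSeqError as exc:
        raise GravSeqError(f"stage metrics failed: {exc}") from exc

    try:
        stage("integrate")
        run_reads = reads[~reads["is_mux"]]
        run_bases = bases[bases["read_id"].isin(run_reads["read_id"])]
        bins = integration.build_bins(run_reads, run_bases, vib, periods,
                                      config.bin_s)
        bins = integration.truncate_elapsed(bins, config.max_elapsed_s)
        integration.write_bins(bins, out / "bins.tsv",
                               header_comment=f"config_hash={chash}")
    except GravSeqError as exc:
        raise GravSeqError(f"stage integrate failed: {exc}") from exc

    try:
        stage("stats")
        candidates = {
            "elapsed_s": bins["elapsed_s"].to_numpy(float),
            "rms_g": bins["rms_g"].to_numpy(float),
            "mean_g": bins["mean_g"].to_numpy(float),
        }
        reg_quality = stats.stepwise_lm(bins["median_q_pbar"], candidates)
        reg_noise = stats.stepwise_lm(bins["median_norm_std"], candidates)
        _write_json({"response": "median_q_pbar",
                     **_regression_report(reg_quality)},
                    out / "regression_quality.json", chash)
        _write_json({"response": "median_norm_std",
                     **_regression_report(reg_noise)},
                    out / "regression_noise.json", chash)
        reports["regression_quality"] = _regression_report(reg_quality)
        reports["regression_noise"] = _regression_report(reg_noise)

        run_reads = run_reads.assign(
            phase=integration.assign_phases(run_reads, periods)
        )
        keep = ~run_reads["phase"].isin(["spanning"])
        if config.exclude_transition_anova:
            keep &= run_reads["phase"] != "transition"
        groups = {
            lbl: grp["q_pbar"].to_numpy(float)
            for lbl, grp in run_reads[keep].groupby("phase")
            if len(grp) >= 2
        }
        anova_report: dict = {"value": "q_pbar"}
        if len(groups) >= 2:
            an = stats.anova_oneway(groups)
            tk = stats.tukey_hsd(groups)
            anova_report.update(
                {
                    "groups": an.labels,
                    "means": an.means,
                    "ns": an.ns,
                    "f": an.f,
                    "p_value": an.p_value,
                    "tukey": tk.comparisons.to_dict(orient="records"),
                }
            )
        else:
            anova_report["note"] = "fewer than 2 phases with >= 2 reads"
        _write_json(anova_report, out / "anova_quality.json", chash)
        reports["anova_quality"] = anova_report

        ks_report: dict = {}
        if config.ground_events_path:
            g_reads, g_bases = events.parse_event_table(
                config.ground_events_path, config.signal_rate
            )
            g_run = g_bases[
                g_bases["read_id"].isin(g_reads.loc[~g_reads["is_mux"], "read_id"])
            ]
            ks = stats.ks_two_sample(
                g_run["trans_ms"].to_numpy(), run_bases["trans_ms"].to_numpy()
            )
            ks_report = {
                "d": ks.d, "p_value": ks.p_value,
                "n_ground": ks.n_x, "n_flight": ks.n_y,
                "mean_ground_ms": float(g_run["trans_ms"].mean()),
                "mean_flight_ms": float(run_bases["trans_ms"].mean()),
                "median_ground_ms": float(g_run["trans_ms"].median()),
                "median_flight_ms": float(run_bases["trans_ms"].median()),
            }
            _write_json(ks_report, out / "ks.json", chash)
            reports["ks"] = ks_report
    except GravSeqError as exc:
        raise GravSeqError(f"stage stats failed: {exc}") from exc

    summary = [
        f"gravseq pipeline summary (config {chash})",
        f"  trace: {len(vib.g)} samples @ {trace.sample_rate:g} Hz",
        f"  periods: {len(periods)} "
        f"({sum(1 for p in periods if p.label == 'parabola')} parabolas)",
        f"  reads: {len(reads)} ({int(reads['is_mux'].sum())} mux, excluded)",
        f"  bases: {len(bases)}",
        f"  bins: {len(bins)} (truncated at {config.max_elapsed_s:g} s)",
        f"  quality regression terms: {reg_quality.terms} "
        f"(adj R2 = {reg_quality.adj_r2:.3f})",
        f"  noise regression terms: {reg_noise.terms} "
        f"(adj R2 = {reg_noise.adj_r2:.3f})",
    ]
    if ks_report:
        summary.append(
            f"  KS ground vs flight: D = {ks_report['d']:.4f}, "
            f"p = {ks_report['p_value']:.3g}"
        )
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    reports["summary"] = summary
    return reports


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
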