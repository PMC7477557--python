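"""Simulate the flight and ground sequencing sessions over the flight.

The flight arm runs over the full synthetic flight (dwell mean 2.4035 ms);
the ground arm is a separate session with the ground dwell mean
(2.2786 ms), both with the 1.8 ms median. Writes per-base tables to
scratch (parquet; they are millions of rows), the per-read table and
per-parabola coverage to results, and reports session-level metrics.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (BASES_FLIGHT, BASES_GROUND, GROUND_SEED, PERIODS_TRUE,
                     READS_FLIGHT, READS_SEED, RESULTS, ensure_dirs)

from gravseq.events import phase_coverage
from gravseq.segmentation import read_periods
from gravseq.simulate import ReadModel, simulate_reads
from gravseq.simulate.reads import flight_model, ground_model

MODEL = ReadModel(read_len_mean=2000.0)


def main() -> None:
    ensure_dirs()
    truth = read_periods(PERIODS_TRUE)
    duration = max(p.end_s for p in truth)

    reads, bases, _ = simulate_reads(flight_model(MODEL), truth, duration,
                                     seed=READS_SEED)
    g_reads, g_bases, _ = simulate_reads(ground_model(MODEL), truth, duration,
                                         seed=GROUND_SEED)
    bases.to_parquet(BASES_FLIGHT)
    g_bases.to_parquet(BASES_GROUND)
    reads.to_parquet(READS_FLIGHT)
    reads.drop(columns=["q_pbar"]).join(reads["q_pbar"].round(3)).to_csv(
        RESULTS / "reads_flight.tsv", sep="\t", index=False,
        float_format="%.4f",
    )

    cov = phase_coverage(bases, [p for p in truth if p.label == "parabola"])
    cov.to_csv(RESULTS / "coverage_parabolas.tsv", sep="\t", index=False)

    run = reads[~reads["is_mux"]]
    print(f"flight: {len(reads)} reads ({int(reads['is_mux'].sum())} mux), "
          f"{len(bases)} bases; ground: {len(g_reads)} reads")
    print(f"median q_pbar (non-mux): {run['q_pbar'].median():.2f}")
    print(f"median dwell: flight {bases['trans_ms'].median():.2f} ms, "
          f"ground {g_bases['trans_ms'].median():.2f} ms")
    print(f"parabola coverage: {cov['coverage'].min():.1f}-"
          f"{cov['coverage'].max():.1f}x of the lambda genome")
    print(f"wrote {RESULTS / 'coverage_parabolas.tsv'} and scratch tables")


if __name__ == "__main__":
    main()
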