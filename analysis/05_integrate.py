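"""Build the 1-s joint bin series (quality, noise, vibration, g, phase).

Reads the scratch tables from steps 01/04, excludes mux reads, bins on the
accelerometer timeline, truncates the tail, and writes results/bins.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (BASES_FLIGHT, BINS_TSV, PERIODS_TRUE, READS_FLIGHT,
                     TRACE_CSV, ensure_dirs)

from gravseq.accel import FilterSpec, process_vibration, read_accel_csv
from gravseq.integration import build_bins, truncate_elapsed
from gravseq.segmentation import read_periods


def main() -> None:
    ensure_dirs()
    trace = read_accel_csv(TRACE_CSV)
    vib = process_vibration(trace, FilterSpec(sample_rate=trace.sample_rate))
    periods = read_periods(PERIODS_TRUE)
    reads = pd.read_parquet(READS_FLIGHT)
    bases = pd.read_parquet(BASES_FLIGHT)

    run = reads[~reads["is_mux"]]
    bins = build_bins(run, bases[bases["read_id"].isin(run["read_id"])],
                      vib, periods)
    bins = truncate_elapsed(bins, 4000.0)
    bins.to_csv(BINS_TSV, sep="\t", index=False, float_format="%.6g")

    print(f"{len(bins)} bins; phases: "
          f"{bins['phase'].value_counts().to_dict()}")
    print(f"bins with reads: {bins['median_q_pbar'].notna().sum()}, "
          f"with bases: {bins['median_norm_std'].notna().sum()}")
    print(f"wrote {BINS_TSV}")


if __name__ == "__main__":
    main()
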