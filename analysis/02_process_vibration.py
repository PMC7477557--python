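"""Vibration processing: magnitude, zero-phase high-pass, 1-s RMS, PSDs.

Reads scratch/trace.csv, writes the binned RMS series (results/rms.tsv)
and a table of detected spectral peaks in the filtered vibration
(results/vibration_peaks.tsv), and reports the flight/parabola RMS
contrast the study's "smoother freefall" observation rests on.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (PERIODS_TRUE, RESULTS, RMS_TSV, SESSION_VIB, TRACE_CSV,
                     ensure_dirs)

from gravseq.accel import (FilterSpec, process_vibration, read_accel_csv,
                           welch_psd, write_rms_tsv)
from gravseq.segmentation import read_periods


def main() -> None:
    ensure_dirs()
    trace = read_accel_csv(TRACE_CSV)
    vib = process_vibration(trace, FilterSpec(sample_rate=trace.sample_rate))
    write_rms_tsv(vib.bin_start_s, vib.rms_g, RMS_TSV)

    psd = welch_psd(vib.g_f, trace.sample_rate)
    p = psd.power
    is_max = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
    cand = pd.DataFrame({"freq_hz": psd.freqs[1:-1][is_max],
                         "power": p[1:-1][is_max]})
    # keep the strongest maximum within each 5 Hz neighbourhood
    cand["cluster"] = (cand["freq_hz"] // 5).astype(int)
    peaks = (cand.sort_values("power", ascending=False)
             .groupby("cluster").head(1)
             .nlargest(5, "power")[["freq_hz", "power"]]
             .sort_values("freq_hz"))
    peaks.to_csv(RESULTS / "vibration_peaks.tsv", sep="\t", index=False)

    periods = read_periods(PERIODS_TRUE)
    mid = vib.bin_start_s + 0.5
    label = np.full(len(mid), "other", dtype=object)
    for per in periods:
        label[(mid >= per.start_s) & (mid < per.end_s)] = per.label
    by_phase = pd.Series(vib.rms_g).groupby(label).mean()
    print("mean 1-s RMS vibration by phase [g]:")
    print(by_phase.to_string(float_format="%.4f"))
    print(f"configured peaks {SESSION_VIB.peak_freqs} -> top detected peaks "
          f"at {peaks['freq_hz'].round(1).tolist()} Hz")
    print(f"wrote {RMS_TSV} and {RESULTS / 'vibration_peaks.tsv'}")


if __name__ == "__main__":
    main()
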