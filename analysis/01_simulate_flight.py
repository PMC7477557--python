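"""Generate the synthetic parabolic flight and its ground-truth periods.

Writes the triaxial trace (scratch/trace.csv) and the true phase table
(results/periods_true.txt), and reports the flight's structure.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (FLIGHT_SEED, PERIODS_TRUE, SAMPLE_RATE, SESSION_VIB,
                     TRACE_CSV, ensure_dirs)

from gravseq.accel import write_accel_csv
from gravseq.segmentation import write_periods
from gravseq.simulate import make_flight


def main() -> None:
    ensure_dirs()
    trace, truth = make_flight(vib=SESSION_VIB, seed=FLIGHT_SEED,
                               sample_rate=SAMPLE_RATE)
    write_accel_csv(trace, TRACE_CSV)
    write_periods(truth, PERIODS_TRUE)

    para = [p for p in truth if p.label == "parabola"]
    print(f"flight: {trace.duration_s:.0f} s at {SAMPLE_RATE:g} Hz "
          f"({len(trace.gx)} samples)")
    print(f"periods: {len(truth)} total, {len(para)} parabolas "
          f"(targets of first set: {[p.target_g for p in para[:5]]})")
    print(f"parabola durations: {min(p.duration_s for p in para):.1f}-"
          f"{max(p.duration_s for p in para):.1f} s")
    print(f"wrote {TRACE_CSV} and {PERIODS_TRUE}")


if __name__ == "__main__":
    main()
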