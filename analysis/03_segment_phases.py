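"""Segment the flight profile and compare with the generator's truth.

Writes results/periods_detected.txt and reports label agreement and the
worst boundary error.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import PERIODS_DETECTED, PERIODS_TRUE, TRACE_CSV, ensure_dirs

from gravseq.accel import read_accel_csv, vibration_magnitude
from gravseq.segmentation import read_periods, segment_phases, write_periods


def main() -> None:
    ensure_dirs()
    trace = read_accel_csv(TRACE_CSV)
    detected = segment_phases(vibration_magnitude(trace), trace.sample_rate)
    write_periods(detected, PERIODS_DETECTED)

    truth = read_periods(PERIODS_TRUE)
    labels_ok = [p.label for p in detected] == [p.label for p in truth]
    print(f"detected {len(detected)} periods "
          f"({sum(1 for p in detected if p.label == 'parabola')} parabolas)")
    print(f"label sequence matches truth: {labels_ok}")
    if labels_ok:
        worst = max(
            max(abs(a.start_s - b.start_s), abs(a.end_s - b.end_s))
            for a, b in zip(detected, truth)
        )
        targets = [p.target_g for p in detected if p.label == "parabola"]
        print(f"worst boundary error: {worst:.2f} s")
        print(f"first-set targets recovered: {targets[:5]}")
    print(f"wrote {PERIODS_DETECTED}")


if __name__ == "__main__":
    main()
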