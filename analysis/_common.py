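"""Shared paths and the study configuration for the analysis scripts.

The session is a desk-scale stand-in for the flight experiment: the flown
parabola plan (5+6+4+5; first set Mars, Mars, Lunar, 0, 0) sampled at
500 Hz with the vibration peaks moved below the Nyquist frequency, and a
read model at the session's configured dwell/quality/noise targets with
2-kb reads. Everything is seeded, so each script can be re-run alone.
"""

from pathlib import Path

from gravseq.simulate import VibrationModel

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

FLIGHT_SEED = 0
READS_SEED = 0
GROUND_SEED = 1
SAMPLE_RATE = 500.0

#: spectral peaks scaled below the 250 Hz Nyquist of the 500 Hz session
SESSION_VIB = VibrationModel(
    peak_freqs=(60.0, 120.0, 200.0), peak_rms=(0.015, 0.010, 0.008)
)

TRACE_CSV = SCRATCH / "trace.csv"
PERIODS_TRUE = RESULTS / "periods_true.txt"
PERIODS_DETECTED = RESULTS / "periods_detected.txt"
RMS_TSV = RESULTS / "rms.tsv"
BASES_FLIGHT = SCRATCH / "bases_flight.parquet"
BASES_GROUND = SCRATCH / "bases_ground.parquet"
READS_FLIGHT = SCRATCH / "reads_flight.parquet"
BINS_TSV = RESULTS / "bins.tsv"


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
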