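"""Optional HDF5 (fast5-dialect) adapter for event-aligned reads.

Layout (one file, many reads), mirroring the shape of a tombo-annotated
single-read container without claiming byte compatibility:

    /reads/<read_id>
        attrs: channel (int), start_s (float), is_mux (0/1)
        /Alignment            attrs: mapped_start (int), genome (str)
        Events                structured dataset with fields
                              (start, length, norm_mean, norm_stdev, qual)

``genome_pos`` of the i-th event is ``mapped_start + i`` (0-based,
contiguous alignment). :func:`read_fast5_events` returns the same
``(reads, bases)`` frames as :func:`gravseq.events.parse_event_table`.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError
from .events import DEFAULT_SIGNAL_RATE, _derive

__all__ = ["read_fast5_events", "write_fast5_events"]

_EVENT_DTYPE = np.dtype(
    [
        ("start", "<i8"),
        ("length", "<i8"),
        ("norm_mean", "<f8"),
        ("norm_stdev", "<f8"),
        ("qual", "<i4"),
    ]
)


def write_fast5_events(reads: pd.DataFrame, bases: pd.DataFrame, path) -> None:
    """Write (reads, bases) to the HDF5 dialect above."""
    with h5py.File(path, "w") as fh:
        root = fh.create_group("reads")
        for _, read in reads.iterrows():
            grp = root.create_group(str(read["read_id"]))
            grp.attrs["channel"] = int(read["channel"])
            grp.attrs["start_s"] = float(read["start_s"])
            grp.attrs["is_mux"] = int(bool(read["is_mux"]))
            sub = bases[bases["read_id"] == read["read_id"]].sort_values("genome_pos")
            ev = np.zeros(len(sub), dtype=_EVENT_DTYPE)
            lengths = sub["event_len"].to_numpy(np.int64)
            ev["length"] = lengths
            ev["start"] = np.concatenate(([0], np.cumsum(lengths)[:-1]))
            ev["norm_mean"] = sub["norm_mean"].to_numpy(float)
            ev["norm_stdev"] = sub["norm_std"].to_numpy(float)
            ev["qual"] = sub["qual"].to_numpy(np.int32)
            grp.create_dataset("Events", data=ev)
            aln = grp.create_group("Alignment")
            aln.attrs["mapped_start"] = int(sub["genome_pos"].iloc[0]) if len(sub) else 0
            aln.attrs["genome"] = "lambda"


def read_fast5_events(
    path, signal_rate: float = DEFAULT_SIGNAL_RATE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the HDF5 dialect into (reads, bases); contract matches
    :func:`gravseq.events.parse_event_table`."""
    read_rows, base_frames = [], []
    with h5py.File(path, "r") as fh:
        if "reads" not in fh:
            raise FormatError(f"{path}: missing group /reads")
        for read_id, grp in fh["reads"].items():
            if "Alignment" not in grp:
                raise FormatError(f"{path}: /reads/{read_id}/Alignment missing")
            if "Events" not in grp:
                raise FormatError(f"{path}: /reads/{read_id}/Events missing")
            ev = grp["Events"][()]
            read_rows.append(
                {
                    "read_id": read_id,
                    "channel": int(grp.attrs["channel"]),
                    "start_s": float(grp.attrs["start_s"]),
                    "is_mux": bool(grp.attrs["is_mux"]),
                }
            )
            mapped_start = int(grp["Alignment"].attrs["mapped_start"])
            base_frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_id,
                        "genome_pos": mapped_start + np.arange(len(ev)),
                        "event_len": ev["length"].astype(np.int64),
                        "norm_mean": ev["norm_mean"],
                        "norm_std": ev["norm_stdev"],
                        "qual": ev["qual"],
                    }
                )
            )
    reads = pd.DataFrame(
        read_rows, columns=["read_id", "channel", "start_s", "is_mux"]
    )
    if not read_rows:
        reads = pd.DataFrame(columns=["read_id", "channel", "start_s", "is_mux",
                                      "q_pbar", "n_bases", "duration_s"])
        bases = pd.DataFrame(columns=["read_id", "genome_pos", "event_len",
                                      "norm_mean", "norm_std", "qual",
                                      "trans_ms", "t_s"])
        return reads, bases
    bases = pd.concat(base_frames, ignore_index=True)
    return _derive(reads, bases, signal_rate)
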