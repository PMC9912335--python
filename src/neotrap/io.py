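"""Trace file I/O: HDF5 and CSV dialects with lossless round-tripping.

HDF5 stores the samples as float64 plus the full generator/acquisition
metadata as a JSON attribute; CSV stores (time_s, current_pA) rows with
the same JSON on a comment line, printed with repr-exact floats so the
samples round-trip bit-exactly through either format.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .trace_synthesis import AcquisitionSpec, CurrentTrace, VoltageProtocol

__all__ = ["TraceFormatError", "read_trace", "write_trace"]

_CSV_MAGIC = "# neotrap-trace v1"


class TraceFormatError(ValueError):
    """Raised for unknown extensions or malformed trace files."""


def _meta_to_objects(meta: dict) -> tuple[AcquisitionSpec, VoltageProtocol, dict]:
    acq = AcquisitionSpec(**meta["acquisition"])
    segments = tuple(
        (np.inf if d == "inf" else float(d), float(v)) for d, v in meta["protocol"]
    )
    return acq, VoltageProtocol(segments), meta.get("params", {})


def write_trace(trace: CurrentTrace, path: str | os.PathLike) -> None:
    """Write a trace as .h5/.hdf5 or .csv, keyed by the file extension."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("current_pA", data=trace.samples, dtype="f8")
            ds.attrs["sample_rate_hz"] = trace.sample_rate
            fh.attrs["metadata"] = trace.metadata_json()
    elif ext == ".csv":
        t = trace.time
        with open(path, "w") as fh:
            fh.write(_CSV_MAGIC + "\n")
            fh.write("# " + trace.metadata_json() + "\n")
            fh.write("time_s,current_pA\n")
            for ti, xi in zip(t, trace.samples):
                # 17 significant digits round-trip IEEE doubles exactly
                fh.write(f"{ti:.17g},{xi:.17g}\n")
    else:
        raise TraceFormatError(f"unknown trace extension {ext!r} (use .h5/.hdf5/.csv)")


def read_trace(path: str | os.PathLike) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "current_pA" not in fh or "metadata" not in fh.attrs:
                raise TraceFormatError("not a neotrap trace HDF5 file")
            samples = fh["current_pA"][...]
            meta = json.loads(fh.attrs["metadata"])
    elif ext == ".csv":
        with open(path) as fh:
            magic = fh.readline().rstrip("\n")
            if magic != _CSV_MAGIC:
                raise TraceFormatError("missing neotrap CSV header line")
            meta_line = fh.readline()
            if not meta_line.startswith("# "):
                raise TraceFormatError("missing metadata comment line")
            meta = json.loads(meta_line[2:])
            header = fh.readline().rstrip("\n")
            if header != "time_s,current_pA":
                raise TraceFormatError(f"unexpected CSV column header {header!r}")
            samples = np.array([float(line.split(",")[1]) for line in fh if line.strip()])
    else:
        raise TraceFormatError(f"unknown trace extension {ext!r} (use .h5/.hdf5/.csv)")
    acq, protocol, params = _meta_to_objects(meta)
    return CurrentTrace(samples=np.asarray(samples, dtype=np.float64),
                        acquisition=acq, protocol=protocol, params=params)
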