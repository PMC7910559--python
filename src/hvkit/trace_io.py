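"""Plain-text episodic trace format.

A recording is stored as a UTF-8 file with ``#key=value`` header lines
followed by one whitespace-separated row per sample::

    #format=hvkit-episodic-v1
    #dt_ms=2.0
    #current_unit=pA
    #voltage_unit=mV
    #pH_i=6.0
    #pH_o=6.0
    #temperature_K=297.0
    #n_sweeps=2
    #protocol={...json...}        (optional)
    #seed=0                        (optional)
    #label=SlHv1                   (optional)
    sweep	time_ms	voltage_mV	current_pA
    0	0.0	-80.0	-0.123456789

Time is in milliseconds, zero-based at the start of each sweep; sweep
indices are zero-based.  Numbers are written at full double precision so a
write/read round trip is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MetadataError
from .model import Solutions
from .protocol import VoltageProtocol

__all__ = ["Recording", "write_recording", "read_recording"]

FORMAT_TAG = "hvkit-episodic-v1"
REQUIRED_KEYS = (
    "format",
    "dt_ms",
    "current_unit",
    "voltage_unit",
    "pH_i",
    "pH_o",
    "temperature_K",
    "n_sweeps",
)


@dataclass
class Recording:
    """Episodic recording: stacked current sweeps plus command voltages.

    currents and voltages are (n_sweeps, n_samples) arrays in pA and mV.
    """

    dt: float  # ms
    currents: np.ndarray
    voltages: np.ndarray
    solutions: Solutions = field(default_factory=Solutions)
    protocol: VoltageProtocol | None = None
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.currents.ndim != 2:
            raise ValueError("currents must be a (n_sweeps, n_samples) array")
        if self.currents.shape != self.voltages.shape:
            raise ValueError("command voltages must match sweep shape")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.currents.shape[0] == 0 or self.currents.shape[1] == 0:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_sweeps(self) -> int:
        return self.currents.shape[0]

    @property
    def n_samples(self) -> int:
        return self.currents.shape[1]

    def times(self) -> np.ndarray:
        """Sample times within a sweep, ms, zero-based."""
        return np.arange(self.n_samples) * self.dt

    def epoch_slice(self, epoch: int) -> slice:
        """Sample slice of protocol epoch ``epoch`` (requires a protocol)."""
        if self.protocol is None:
            raise MetadataError("recording carries no protocol metadata")
        start, stop = self.protocol.epoch_bounds(epoch)
        return slice(start, stop)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Serialize to the episodic text format (full double precision)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"#format={FORMAT_TAG}\n")
    buf.write(f"#dt_ms={float(recording.dt)!r}\n")
    buf.write("#current_unit=pA\n")
    buf.write("#voltage_unit=mV\n")
    buf.write(f"#pH_i={recording.solutions.pH_i!r}\n")
    buf.write(f"#pH_o={recording.solutions.pH_o!r}\n")
    buf.write(f"#temperature_K={recording.solutions.T!r}\n")
    buf.write(f"#n_sweeps={recording.n_sweeps}\n")
    if recording.protocol is not None:
        buf.write(f"#protocol={recording.protocol.to_json()}\n")
    if recording.seed is not None:
        buf.write(f"#seed={recording.seed}\n")
    if recording.label:
        buf.write(f"#label={recording.label}\n")
    buf.write("sweep\ttime_ms\tvoltage_mV\tcurrent_pA\n")
    t = recording.times()
    for s in range(recording.n_sweeps):
        v = recording.voltages[s]
        i = recording.currents[s]
        for k in range(recording.n_samples):
            buf.write(f"{s}\t{float(t[k])!r}\t{float(v[k])!r}\t{float(i[k])!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_recording(path: str | Path) -> Recording:
    """Parse and validate an episodic trace file."""
    path = Path(path)
    header: dict[str, str] = {}
    data_start = 0
    with path.open(encoding="utf-8") as fh:
        lines = fh.readlines()
    for n, line in enumerate(lines):
        if line.startswith("#"):
            if "=" not in line:
                raise MetadataError(f"{path}: malformed header line {n + 1}")
            key, _, value = line[1:].rstrip("\n").partition("=")
            header[key] = value
        else:
            data_start = n
            break
    else:
        raise MetadataError(f"{path}: no data section")

    missing = [k for k in REQUIRED_KEYS if k not in header]
    if missing:
        raise MetadataError(f"{path}: missing required header keys {missing}")
    if header["format"] != FORMAT_TAG:
        raise MetadataError(f"{path}: unknown format {header['format']!r}")
    if (header["current_unit"], header["voltage_unit"]) != ("pA", "mV"):
        raise MetadataError(f"{path}: units must be pA and mV")

    body = pd.read_csv(
        io.StringIO("".join(lines[data_start:])),
        sep=r"\s+",
        dtype={"sweep": int},
        float_precision="round_trip",
    )
    expected_cols = ["sweep", "time_ms", "voltage_mV", "current_pA"]
    if list(body.columns) != expected_cols:
        raise MetadataError(f"{path}: expected columns {expected_cols}")

    dt = float(header["dt_ms"])
    n_sweeps = int(header["n_sweeps"])
    groups = body.groupby("sweep", sort=True)
    if sorted(groups.groups) != list(range(n_sweeps)):
        raise MetadataError(
            f"{path}: sweep indices do not form 0..{n_sweeps - 1}"
        )
    lengths = groups.size().to_numpy()
    if len(set(lengths)) != 1:
        raise MetadataError(f"{path}: ragged sweeps (lengths {sorted(set(lengths))})")
    n_samples = int(lengths[0])

    currents = np.empty((n_sweeps, n_samples))
    voltages = np.empty((n_sweeps, n_samples))
    for s, grp in groups:
        t = grp["time_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise MetadataError(f"{path}: non-monotone time in sweep {s}")
        currents[s] = grp["current_pA"].to_numpy()
        voltages[s] = grp["voltage_mV"].to_numpy()

    protocol = None
    if "protocol" in header:
        protocol = VoltageProtocol.from_json(header["protocol"])
    seed = int(header["seed"]) if "seed" in header else None
    return Recording(
        dt=dt,
        currents=currents,
        voltages=voltages,
        solutions=Solutions(
            pH_i=float(header["pH_i"]),
            pH_o=float(header["pH_o"]),
            T=float(header["temperature_K"]),
        ),
        protocol=protocol,
        label=header.get("label", ""),
        seed=seed,
    )
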