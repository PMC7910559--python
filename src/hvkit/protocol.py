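"""Episodic voltage protocols: ordered epochs of holds, steps, and ramps."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError

__all__ = [
    "Epoch",
    "VoltageProtocol",
    "standard_step_protocol",
    "ramp_protocol",
    "reversal_protocol",
]


@dataclass(frozen=True)
class Epoch:
    """One protocol segment. ``kind`` is 'hold', 'step', or 'ramp'."""

    kind: str
    v_start: float  # mV
    v_end: float  # mV
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp"):
            raise ProtocolError(f"unknown epoch kind {self.kind!r}")
        if self.duration <= 0:
            raise ProtocolError("epoch durations must be positive")
        if self.kind in ("hold", "step") and self.v_start != self.v_end:
            raise ProtocolError(f"{self.kind} epoch must have v_start == v_end")

    @property
    def ramp_rate(self) -> float:
        """Ramp rate in mV/ms ((v_end - v_start)/duration)."""
        return (self.v_end - self.v_start) / self.duration


@dataclass(frozen=True)
class VoltageProtocol:
    """Episodic protocol: epochs applied identically in every sweep except
    for a per-sweep voltage increment on one designated epoch.

    dt is the sampling interval in ms; each epoch contributes
    round(duration/dt) samples, left-aligned at the epoch start.
    """

    segments: tuple[Epoch, ...]
    n_sweeps: int = 1
    sweep_increment: float = 0.0  # mV added per sweep to the stepped epoch
    step_epoch: int | None = None  # index of the incremented epoch
    dt: float = 1.0  # ms

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ProtocolError("protocol needs at least one epoch")
        if self.dt <= 0:
            raise ProtocolError("sampling interval dt must be positive")
        if self.n_sweeps < 1:
            raise ProtocolError("n_sweeps must be >= 1")
        if self.step_epoch is not None and not (
            0 <= self.step_epoch < len(self.segments)
        ):
            raise ProtocolError("step_epoch out of range")

    @property
    def n_samples(self) -> int:
        return sum(self.epoch_samples(i) for i in range(len(self.segments)))

    def epoch_samples(self, index: int) -> int:
        n = int(round(self.segments[index].duration / self.dt))
        if n < 1:
            raise ProtocolError(
                f"epoch {index} shorter than one sampling interval"
            )
        return n

    def epoch_bounds(self, index: int) -> tuple[int, int]:
        """Half-open sample range [start, stop) of epoch ``index``."""
        start = sum(self.epoch_samples(i) for i in range(index))
        return start, start + self.epoch_samples(index)

    def epoch_voltage(self, index: int, sweep: int) -> tuple[float, float]:
        ep = self.segments[index]
        dv = self.sweep_increment * sweep if index == self.step_epoch else 0.0
        return ep.v_start + dv, ep.v_end + dv

    def sweep_waveform(self, sweep: int) -> np.ndarray:
        """Command voltage at every sample of one sweep."""
        parts = []
        for i, ep in enumerate(self.segments):
            n = self.epoch_samples(i)
            v0, v1 = self.epoch_voltage(i, sweep)
            if ep.kind == "ramp":
                # voltage at the *start* of each sampling interval
                parts.append(v0 + (v1 - v0) * np.arange(n) / n)
            else:
                parts.append(np.full(n, v0))
        return np.concatenate(parts)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                [e.kind, e.v_start, e.v_end, e.duration] for e in self.segments
            ],
            "n_sweeps": self.n_sweeps,
            "sweep_increment": self.sweep_increment,
            "step_epoch": self.step_epoch,
            "dt": self.dt,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            segments=tuple(Epoch(*seg) for seg in d["segments"]),
            n_sweeps=int(d.get("n_sweeps", 1)),
            sweep_increment=float(d.get("sweep_increment", 0.0)),
            step_epoch=d.get("step_epoch"),
            dt=float(d["dt"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "VoltageProtocol":
        return cls.from_dict(json.loads(s))


def standard_step_protocol(
    v_hold: float = -80.0,
    v_leak: float = -100.0,
    v_ref: float = 60.0,
    v_test_start: float = -20.0,
    sweep_increment: float = 10.0,
    n_sweeps: int = 13,
    test_duration: float = 1500.0,
    tail_duration: float = 300.0,
    ref_duration: float = 300.0,
    dt: float = 2.0,
) -> VoltageProtocol:
    """Depolarizing-step family used throughout the fixture suite.

    Epochs: 0 hold, 1 subthreshold leak probe, 2 fixed reference
    depolarization (rundown normalization), 3 recovery hold, 4 incremented
    test step, 5 repolarizing tail, in that order.
    """
    segs = (
        Epoch("hold", v_hold, v_hold, 100.0),
        Epoch("step", v_leak, v_leak, 100.0),
        Epoch("step", v_ref, v_ref, ref_duration),
        Epoch("hold", v_hold, v_hold, 400.0),
        Epoch("step", v_test_start, v_test_start, test_duration),
        Epoch("step", v_hold, v_hold, tail_duration),
    )
    return VoltageProtocol(
        segments=segs,
        n_sweeps=n_sweeps,
        sweep_increment=sweep_increment,
        step_epoch=4,
        dt=dt,
    )


# epoch roles in standard_step_protocol
LEAK_EPOCHS = (0, 1)
REFERENCE_EPOCH = 2
TEST_EPOCH = 4
TAIL_EPOCH = 5


def ramp_protocol(
    v_start: float = -80.0,
    v_end: float = -20.0,
    ramp_duration: float = 10_000.0,
    v_prepulse: float | None = None,
    prepulse_duration: float = 500.0,
    dt: float = 2.0,
) -> VoltageProtocol:
    """Slow ramp for limiting-slope gating-charge measurements, optionally
    preceded by a pre-pulse that drives the channel to maximal conductance."""
    segs: list[Epoch] = [Epoch("hold", v_start, v_start, 200.0)]
    if v_prepulse is not None:
        segs.append(Epoch("step", v_prepulse, v_prepulse, prepulse_duration))
        segs.append(Epoch("hold", v_start, v_start, 500.0))
    segs.append(Epoch("ramp", v_start, v_end, ramp_duration))
    return VoltageProtocol(segments=tuple(segs), n_sweeps=1, dt=dt)


def reversal_protocol(
    v_hold: float = -80.0,
    v_prepulse: float = 100.0,
    prepulse_duration: float = 500.0,
    v_tail_start: float = -40.0,
    sweep_increment: float = 5.0,
    n_sweeps: int = 17,
    tail_duration: float = 100.0,
    dt: float = 0.5,
) -> VoltageProtocol:
    """Tail-current family for reversal-potential measurements: a fixed
    depolarization opens the channels, then each sweep repolarizes to a
    different voltage; the instantaneous tail currents cross zero at V_rev."""
    segs = (
        Epoch("hold", v_hold, v_hold, 50.0),
        Epoch("step", v_prepulse, v_prepulse, prepulse_duration),
        Epoch("step", v_tail_start, v_tail_start, tail_duration),
        Epoch("hold", v_hold, v_hold, 50.0),
    )
    return VoltageProtocol(
        segments=segs,
        n_sweeps=n_sweeps,
        sweep_increment=sweep_increment,
        step_epoch=2,
        dt=dt,
    )


#: epoch roles in reversal_protocol
REVERSAL_TAIL_EPOCH = 2
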