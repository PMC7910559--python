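"""Configuration-driven end-to-end runs and the packaged fixture suite.

A run is described by a small YAML/dict config: either simulate a preset
under stated solutions or load an episodic trace file, then push the
recording through leak subtraction, rundown correction, G-V construction,
Boltzmann/kinetic fits, and write a machine-readable report plus tidy CSV
tables and a manifest sufficient to reproduce every number.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import HvkitError
from .model import Solutions, effective_v_half, nernst_potential
from .presets import available_presets, load_preset
from .protocol import (
    LEAK_EPOCHS,
    REFERENCE_EPOCH,
    TAIL_EPOCH,
    TEST_EPOCH,
    standard_step_protocol,
)
from .pipeline import (
    correct_rundown,
    derive_gv,
    fit_activation,
    fit_boltzmann,
    half_deactivation_time,
    steady_iv,
    subtract_leak,
)
from .simulate import NoiseRundown, simulate_recording
from .trace_io import Recording, read_recording, write_recording

__all__ = ["AnalysisConfig", "run_config", "generate_fixture_suite"]

DEFAULT_PARAMS = {
    "lag_fraction": 0.1,
    "exclusion_mV": 5.0,
    "isochronal_ms": 5.0,
    "po_max": 0.02,
    "noise_floor_pA": 0.5,
    "min_rise_pA": 5.0,
}


@dataclasses.dataclass
class AnalysisConfig:
    """Validated end-to-end run description."""

    label: str
    simulate: dict | None = None
    input_path: str | None = None
    analyses: tuple[str, ...] = ("boltzmann",)
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {"label", "simulate", "input", "analyses", "params", "seed"}
        unknown = set(d) - known
        if unknown:
            raise HvkitError(f"unknown config keys: {sorted(unknown)}")
        sim = d.get("simulate")
        inp = d.get("input")
        if (sim is None) == (inp is None):
            raise HvkitError(
                "config must provide exactly one of 'simulate' or 'input'"
            )
        if sim is not None:
            preset = sim.get("preset")
            if preset is None:
                raise HvkitError("simulate config needs a 'preset'")
            if preset.lower() not in {p.lower() for p in available_presets()}:
                raise HvkitError(f"unknown preset {preset!r}")
        if inp is not None and not Path(inp).exists():
            raise HvkitError(f"input file {inp} does not exist")
        params = {**DEFAULT_PARAMS, **d.get("params", {})}
        bad = set(params) - set(DEFAULT_PARAMS)
        if bad:
            raise HvkitError(f"unknown analysis parameters: {sorted(bad)}")
        return cls(
            label=d.get("label", "run"),
            simulate=sim,
            input_path=inp,
            analyses=tuple(d.get("analyses", ("boltzmann",))),
            params=params,
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _simulate_stage(cfg: AnalysisConfig) -> Recording:
    sim = cfg.simulate
    model = load_preset(sim["preset"])
    solutions = Solutions(
        pH_i=float(sim.get("pH_i", 6.0)),
        pH_o=float(sim.get("pH_o", 6.0)),
        T=float(sim.get("T", 297.0)),
    )
    v_half = effective_v_half(model, solutions)
    protocol = standard_step_protocol(
        v_test_start=float(sim.get("v_test_start", round(v_half - 60.0))),
        sweep_increment=float(sim.get("sweep_increment", 10.0)),
        n_sweeps=int(sim.get("n_sweeps", 13)),
        v_ref=float(sim.get("v_ref", round(v_half + 30.0))),
        test_duration=float(sim.get("test_duration", 1500.0)),
    )
    nr = NoiseRundown(
        sigma_I=float(sim.get("sigma_I", 2.0)),
        rundown_per_sweep=float(sim.get("rundown_per_sweep", 0.98)),
        g_leak=float(sim.get("g_leak", 0.2)),
        seed=cfg.seed,
    )
    return simulate_recording(model, protocol, solutions, nr)


def run_config(
    config: "AnalysisConfig | dict | str | Path", out_dir: str | Path
) -> dict:
    """Execute a configured analysis and write its result bundle.

    Writes ``report.json`` (all fitted quantities), ``gv.csv`` (tidy G-V
    table), and ``manifest.json`` (config, parameters, seeds, version) into
    ``out_dir``.  Identical config + seed give byte-identical numeric
    output.  Stage failures are re-raised with the stage name attached.
    """
    if isinstance(config, (str, Path)):
        cfg = AnalysisConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = AnalysisConfig.from_dict(config)
    else:
        cfg = config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"label": cfg.label}
    log: list[dict] = []

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise HvkitError(f"stage {name!r} failed: {exc}") from exc
        log.append({"stage": name, "elapsed_s": round(time.perf_counter() - t0, 4)})
        return result

    if cfg.simulate is not None:
        recording = stage("simulate", _simulate_stage, cfg)
    else:
        recording = stage("load", read_recording, cfg.input_path)

    p = cfg.params
    recording, leak = stage("subtract_leak", subtract_leak, recording, list(LEAK_EPOCHS))
    recording, scale = stage(
        "correct_rundown",
        correct_rundown,
        recording,
        REFERENCE_EPOCH,
        p["isochronal_ms"],
        p["noise_floor_pA"],
    )
    report["leak"] = {"g_nS_mean": float(leak.g.mean()), "E_mV_mean": float(leak.E.mean())}
    report["rundown_scale"] = [float(x) for x in scale]

    sol = recording.solutions
    v_rev = nernst_potential(sol.pH_i, sol.pH_o, sol.T)
    gv_table = None
    if "boltzmann" in cfg.analyses:
        iv = stage("steady_iv", steady_iv, recording, TEST_EPOCH, p["isochronal_ms"])
        gv = stage("derive_gv", derive_gv, iv, v_rev, p["exclusion_mV"])
        fit = stage("fit_boltzmann", fit_boltzmann, gv)
        report["boltzmann"] = {
            "v_half_mV": fit.v_half,
            "s_mV": fit.s,
            "g_max": fit.g_max,
            "v_half_err": fit.v_half_err,
            "s_err": fit.s_err,
        }
        report["v_rev_used_mV"] = v_rev
        gv_table = pd.DataFrame(
            {"voltage_mV": gv.voltages, "g_nS": gv.g, "g_norm": gv.g_norm}
        )
    if "activation" in cfg.analyses:
        sl = recording.epoch_slice(TEST_EPOCH)
        fits = []
        for s in range(recording.n_sweeps):
            try:
                f = fit_activation(
                    recording.currents[s, sl],
                    recording.dt,
                    p["lag_fraction"],
                    min_rise=p["min_rise_pA"],
                )
                fits.append(
                    {
                        "sweep": s,
                        "voltage_mV": recording.protocol.epoch_voltage(TEST_EPOCH, s)[0],
                        "tau_on_ms": f.tau_on,
                        "t0_ms": f.t0,
                    }
                )
            except HvkitError:
                continue
        report["activation"] = fits
    if "tails" in cfg.analyses:
        sl = recording.epoch_slice(TAIL_EPOCH)
        tails = []
        for s in range(recording.n_sweeps):
            try:
                m = half_deactivation_time(recording.currents[s, sl], recording.dt)
                tails.append(
                    {"sweep": s, "I_o_pA": m.I_o, "t_half_ms": m.t_half}
                )
            except ValueError:
                continue
        report["tails"] = tails

    # timings go to a separate log so report.json stays byte-identical
    # for identical config + seed
    (out_dir / "run.log").write_text(
        "\n".join(
            f"stage={entry['stage']} elapsed_s={entry['elapsed_s']}"
            for entry in log
        )
        + "\n"
    )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if gv_table is not None:
        gv_table.to_csv(out_dir / "gv.csv", index=False)
    manifest = {
        "hvkit_version": __version__,
        "label": cfg.label,
        "seed": cfg.seed,
        "simulate": cfg.simulate,
        "input": cfg.input_path,
        "analyses": list(cfg.analyses),
        "params": cfg.params,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# fixture suite

#: synthetic toy sequences for the divergence-mapping stages (not real
#: channel sequences; hand-made so the expected alignment is obvious)
SYNTHETIC_FASTA = {
    "toyA": "MKTLLVAGAVLLSERFDGKWQHPYNCRE",
    "toyB": "MKTLIVGGAVLSSDRFDGWQHPYNARE",
}


def _synthetic_pdb_text(n_residues: int = 28) -> str:
    """Minimal CA-only synthetic model matching the toy reference length."""
    lines = ["HEADER    SYNTHETIC TOY MODEL"]
    for i in range(1, n_residues + 1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
            f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_fixture_suite(
    seed: int = 0,
    out_dir: str | Path = "fixtures",
    presets: "list[str] | None" = None,
    dphs: tuple[float, ...] = (-1.0, 0.0, 1.0),
    n_sweeps: int = 9,
    include_sequences: bool = True,
    include_blockers: bool = False,
) -> list[Path]:
    """Write a deterministic set of episodic recordings plus toy
    FASTA/PDB fixtures for the divergence-mapping stage.

    Recordings cover each preset at every transmembrane pH gradient in
    ``dphs`` (pH_o fixed at 6.0, pH_i = 6.0 - DpH), with test voltages
    centered on the condition's half-activation voltage.  With
    ``include_blockers`` the wild-type presets are additionally recorded
    under an open-channel blocker at its Kd and under a closed-state
    stabilizer, both at DpH = 0.  Seeds are derived deterministically
    from ``seed``.
    """
    from .model import BlockerModel, apply_blocker
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    presets = presets or available_presets()
    written: list[Path] = []
    for k, name in enumerate(presets):
        model = load_preset(name)
        for j, dph in enumerate(dphs):
            solutions = Solutions(pH_i=6.0 - dph, pH_o=6.0)
            v_half = effective_v_half(model, solutions)
            protocol = standard_step_protocol(
                v_test_start=round(v_half - 60.0),
                n_sweeps=n_sweeps,
                sweep_increment=round(120.0 / (n_sweeps - 1)),
                v_ref=round(v_half + 30.0),
                test_duration=1200.0,
            )
            nr = NoiseRundown(seed=seed + 1000 * k + j)
            rec = simulate_recording(model, protocol, solutions, nr)
            safe = name.lower().replace("+", "_plus_")
            path = out_dir / f"{safe}_dph{dph:+.0f}.txt"
            write_recording(rec, path)
            written.append(path)
        if include_blockers and name in ("SlHv1", "AoHv1"):
            blockers = {
                "openblock": BlockerModel(mode="open-channel", conc=200.0, Kd=200.0),
                "closedblock": BlockerModel(
                    mode="closed-state", conc=100.0, Kd=100.0,
                    dV_half=20.0, slow_factor=2.5,
                ),
            }
            solutions = Solutions(pH_i=6.0, pH_o=6.0)
            v_half = effective_v_half(model, solutions)
            protocol = standard_step_protocol(
                v_test_start=round(v_half - 60.0),
                n_sweeps=n_sweeps,
                sweep_increment=round(120.0 / (n_sweeps - 1)),
                v_ref=round(v_half + 30.0),
                test_duration=1200.0,
            )
            for tag, blk in blockers.items():
                rec = simulate_recording(
                    apply_blocker(model, blk), protocol, solutions,
                    NoiseRundown(seed=seed + 1000 * k + 500 + len(tag)),
                )
                path = out_dir / f"{name.lower()}_{tag}.txt"
                write_recording(rec, path)
                written.append(path)
    if include_sequences:
        fasta = out_dir / "toy_pair.fasta"
        with fasta.open("w") as fh:
            for sid, seq in SYNTHETIC_FASTA.items():
                fh.write(f">{sid} synthetic\n{seq}\n")
        written.append(fasta)
        pdb = out_dir / "toy_model_synthetic.pdb"
        pdb.write_text(_synthetic_pdb_text(len(SYNTHETIC_FASTA["toyA"])))
        written.append(pdb)
    return written
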