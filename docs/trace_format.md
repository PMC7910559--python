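# Episodic trace format (`hvkit-episodic-v1`)

Plain-text, UTF-8, newline-terminated. A file is a header followed by a
column title line and the sample table.

## Grammar

```
file        := header column-line sample-line+
header      := required-line+ optional-line*
required-line :=
      "#format=hvkit-episodic-v1" NL
    | "#dt_ms=" FLOAT NL            ; sampling interval, ms
    | "#current_unit=pA" NL
    | "#voltage_unit=mV" NL
    | "#pH_i=" FLOAT NL
    | "#pH_o=" FLOAT NL
    | "#temperature_K=" FLOAT NL
    | "#n_sweeps=" INT NL
optional-line :=
      "#protocol=" JSON NL          ; VoltageProtocol.to_json()
    | "#seed=" INT NL               ; generator seed (provenance)
    | "#label=" TEXT NL             ; free-text channel/condition tag
column-line := "sweep" TAB "time_ms" TAB "voltage_mV" TAB "current_pA" NL
sample-line := INT TAB FLOAT TAB FLOAT TAB FLOAT NL
```

Header lines may appear in any order; unknown `#key=value` lines are
preserved on read but ignored.

## Constraints

- Sweep indices are 0-based and must form exactly `0 .. n_sweeps-1`.
- Time is in milliseconds, 0-based at the start of each sweep, strictly
  increasing within a sweep.
- All sweeps must have the same number of samples (no ragged sweeps).
- Currents are pA, voltages mV; other units are rejected.
- Floats are written with `repr` (shortest round-tripping form), so
  write → read → write is byte-identical.

Violation of any constraint raises `hvkit.MetadataError` with the file
and the offending detail.

## Example

```
#format=hvkit-episodic-v1
#dt_ms=0.5
#current_unit=pA
#voltage_unit=mV
#pH_i=5.5
#pH_o=6.5
#temperature_K=297.0
#n_sweeps=1
sweep	time_ms	voltage_mV	current_pA
0	0.0	-80.0	-12.5
0	0.5	-80.0	-11.25
0	1.0	60.0	340.75
```

An import adapter for tab-separated text exported by acquisition software
(ATF-like) is a documented extension point: such files carry the same
sample table and need only a header-mapping shim.
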