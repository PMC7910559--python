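# Methods

## The gating model

A channel is a linear kinetic scheme C_{n−1} ⇌ … ⇌ C₁ ⇌ O. Transition j
carries a gating charge z_j (elementary charges, e₀). Its equilibrium
constant at membrane voltage V is

    K_j(V) = exp( z_j (V − V₀) / V_T ),      V_T = k_B T / e₀,

with a single offset V₀ chosen by root-finding so that the equilibrium
open probability equals ½ at the channel's half-activation voltage V½.
Rates split the charge symmetrically across the barrier,

    α_j(V) = r_j exp(+z_j (V − V₀)/2V_T),   β_j(V) = r_j exp(−z_j (V − V₀)/2V_T),

so the prefactor r_j (1/ms) sets kinetics without touching the
equilibrium. For a two-state scheme the open probability is exactly the
Boltzmann function 1/(1 + exp((V½ − V)/s)) with s = V_T/z: slope factor
and gating charge are two views of one parameter (s = 7.6 mV ↔ 3.37 e₀
at 297 K), and the package enforces that identity.

Two-state schemes are the default for presets because they make the
simulator's equilibrium G–V *exactly* the preset Boltzmann, so parameter-
recovery tests have a sharp truth to recover. Sequential schemes with
n > 2 states are first-class: they produce the sigmoidal activation lag
characteristic of multimeric channels and let the total charge Σz_j
(what the limiting-slope method estimates) exceed the charge implied by
the Boltzmann slope — the sequential "SlHv1-seq" preset carries 5 e₀ in
two equal steps for exactly this purpose. Deactivation is scheme
relaxation; no separate tail model is imposed.

### pH coupling

The half-activation voltage under solutions (pH_i, pH_o, T) is
phenomenological and linear:

    V½ = V½(ref) + c_sym (pH_i − 6) + c_ΔpH (pH_o − pH_i),

anchored at the reference condition pH_i = pH_o = 6.0. The coupling is a
description of the measured shifts, not a mechanism. Signs: c_ΔpH is
negative (raising the outward gradient left-shifts activation, as in
animal Hvs) and c_sym is positive for SlHv1 (V½ grows with symmetric
pH); both are per-preset configuration, since the measurements constrain
magnitude more tightly than direction conventions.

### Preset parameters

| preset | V½ (mV) | s (mV) | c_ΔpH | c_sym | τ_on (ms) @ V_ref |
|---|---|---|---|---|---|
| SlHv1 | 46.5 | 7.6 | −85 | +19 | 300 @ 50 |
| AoHv1 | −13.9 | 7.4 | −90 | 0 | 50 @ −10 |
| hHv1 | 53 | 11.6 | −40 | 0 | 200 @ 60 |
| ChL1-2 | 11.4 | 11.0 | −85 | +19 | 60 @ 60 |
| ChL1-2a | 45.5 | 7.8 | −85 | +19 | 80 @ 60 |
| ChL1-2b | 17.6 | 10.3 | −85 | +19 | 60 @ 60 |
| ChL2-3 | 90.0 | 15.3 | −85 | 0 | 300 @ 90 |
| ChL3-4 | 33.1 | 9.4 | −85 | +19 | 300 @ 60 |
| ChCT1 | 64.9 | 17.1 | −85 | +19 | 80 @ 60 |
| ChCT2 | 41.5 | 7.0 | −85 | +19 | 300 @ 60 |
| ChCT3 | 50.5 | 8.2 | −85 | +19 | 300 @ 60 |
| ChL1-2b+L3-4 | 12.7 | 13.9 | −85 | +19 | 60 @ 60 |
| SlHv1-seq | 46.5 | 7.6 | −85 | +19 | 50 @ 46.5 (3 states, Σz = 5) |

(V½, s) are published Boltzmann fits for each construct. Absolute τ_on
values are this package's choice — the published comparison is relative
(AoHv1 about sixfold faster than SlHv1; the S1–S2-loop and S4-CCD-linker
chimeras accelerated) — as are g_max = 100 nS and the chimera pH
couplings, which inherit the SlHv1 values except ChL2-3, where the
symmetric-pH sensitivity is lost along with the S2–S3-loop insertion that
carries it. Temperature defaults to 297 K, which makes the Nernst slope
the conventional 58.9 mV/pH; it is a configuration field everywhere.

### Blockers

Open-channel block divides g_max by (1 + c/K_d) and leaves the scheme
untouched. Closed-state stabilization shifts V½ depolarized by
ΔV½·c/(c + K_d) and divides every rate prefactor by `slow_factor`. A
master-equation model cannot slow opening alone without also changing the
equilibrium, so `slow_factor` scales both directions; the observable
consequence — τ_on(+)/τ_on(−) ≈ slow_factor at a fixed test voltage —
is what the pharmacology quantification measures.

## Simulation

State probabilities are propagated per sampling interval with the matrix
exponential of the generator at the (constant) epoch voltage; ramps are
integrated with piecewise-constant sub-steps of at most 1 ms evaluated at
sub-step midpoints. Two-state schemes use the closed-form relaxation
instead. Initial occupancies are the equilibrium at the first epoch's
voltage. Occupancies are renormalized at epoch boundaries against
accumulated round-off and conserve probability to better than 1e−9.
Current assembly adds ohmic leak (default 0.2 nS to 0 mV), geometric
rundown (default retention 0.98 per sweep), and white Gaussian noise
(default 2 pA); every stochastic entry point takes one integer seed and
identical seeds give bit-identical recordings.

What the generator deliberately does *not* emulate: capacitive
transients, series-resistance error, seal instability, non-stationary
(pink) noise, channel flicker, and any inactivation process. Passing
tests therefore certify the analysis chain under the model's assumptions
— Boltzmann-gated, perfectly proton-selective, ohmic-leak recordings —
not robustness to every artifact of real patches.

## Analysis choices

- **Leak** is fitted per sweep as I = g(V − E) over user-designated
  subthreshold samples (the standard step protocol reserves a hold and a
  hyperpolarized probe epoch for this); a window reaching above a stated
  closed-state voltage flags the fit as biased.
- **Rundown** rescales each sweep by the isochronal current (mean of the
  final 5 ms) of a fixed reference depolarization relative to sweep 0.
- **Activation fits** exclude the initial lag by starting at the first
  crossing of 10% of the steady rise (configurable), then fit
  a·exp(−(t−t₀)/τ_on) + c by least squares. The first 0.5 ms after any
  voltage change are blanked from all fits.
- **G–V** uses G = I/(V − V_rev) with V_rev = E_H by default (the
  high-selectivity approximation) and masks points within 5 mV of V_rev,
  where the quotient is ill-conditioned. Instantaneous tail amplitudes
  are used directly (they are proportional to conductance).
- **Boltzmann fits** initialize from the half-maximum crossing and the
  10–90% rise width (width = 2 ln 9 · s); uncertainties are the square
  roots of the covariance diagonal. Data whose conductance falls with
  voltage are refused, not silently fitted.
- **V_threshold** is operationalized as the voltage where normalized
  conductance crosses 0.02, since "first observable current" is
  noise-dependent.
- **Limiting slope** fits ln(P_o) vs V by OLS on the window
  0 < P_o ≤ 0.02 (default) and multiplies by V_T. The ramp recipe bins
  samples in 1-mV windows and averages current *before* the logarithm:
  averaging after the log (or discarding negative noisy samples) biases
  the slope shallow at very low P_o. Its window is P_o ∈ [10⁻³, 10⁻²],
  the decade where the synthetic recordings keep adequate signal-to-noise.
  Recovered z_g on the 5 e₀ sequential preset is ≈ 4.9: the strict
  limiting slope is reached only asymptotically as P_o → 0, and a few
  percent deficit at P_o ~ 10⁻² is the expected curvature of a
  sequential scheme, not estimator error.
- **Statistics**: Welch's t for two groups; one-way ANOVA with Tukey HSD
  otherwise, with the studentized-range distribution evaluated
  numerically (scipy), never from tables.

## Divergence mapping

Sequences are aligned globally with BLOSUM62 and affine gap penalties
(opening 8, extension 1; a gap of length L costs 8 + (L−1) — the
published penalties do not fix this convention, so it is explicit and
configurable). User-supplied aligned FASTA is accepted in place of the
built-in aligner, because published alignments often carry manual,
structure-preserving edits no aligner reproduces. Column scores are the
matrix value for residue pairs and −open/−extend for gap runs. The
per-residue divergence of the reference sequence is d_i = mean(w) − w_i;
columns gapped in the reference donate their penalty to the preceding
reference residue (the following one at the N-terminus) — a declared
convention, since the published method does not specify the projection.
The order of operations is deviation → 5-residue centered moving average
(window truncated symmetrically at the termini) → min-max rescale, which
guarantees the advertised [0, 1] range *after* smoothing; the alternative
order is a configuration switch. A constant profile maps to all zeros.
Scale values ×100 (2 decimals) are written into the B-factor column of
the chosen chain via gemmi; unmatched residues are zeroed and reported.

## Problem sizes and determinism

The self-validation runs at desk scale by design: 5 G–V replicates per
recovery target (noise sd 0.03 on normalized conductance), 13-sweep step
families, a 20-s simulated ramp (3 mV/s — faster than the published
0.2–0.5 mV/s ramps, compensated by faster preset kinetics so the ramp
stays quasi-stationary), and 1000-replicate null calibrations for the
statistics. Every random draw is seeded; configuration plus seed
reproduces every number byte-for-byte, and each orchestrated run writes a
manifest sufficient to do so.

## Known limitations

- The two-state default cannot show an activation lag and its
  deactivation accelerates steeply with hyperpolarization (symmetric
  barrier); analyses sensitive to tail kinetics should use sequential
  presets and sub-millisecond sampling.
- ΔpH and symmetric-pH couplings are linear extrapolations of
  measurements made over ~1 pH unit; nothing constrains them far outside
  pH 5–8.
- The mechanosensitive facilitated state is representable only as a
  preset change (shifted V½, faster τ); tension kinetics are out of
  scope, as are single-channel stochastics and subunit-resolved
  cooperativity beyond the total gating charge.
- Percent identity depends on the alignment and denominator convention;
  the default (identities over full alignment length, end gaps scored)
  is one of several defensible choices, all exposed by flag.
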