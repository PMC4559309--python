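# Methods

This note documents the model, the numerical and analysis choices, and the
known limitations of `tcalpha`. It is the authoritative description of what
the package computes; the README gives the quick tour.

## The reduced bursting neural mass

The building block is a population of Hindmarsh–Rose (HR) neurons with
dispersed input currents. A single HR neuron has a fast membrane variable
x, a fast recovery variable y and a slow adaptation variable z; with the
standard constants (a, b, c, d, r, s) = (1, 3, 1, 5, 0.006, 4) and
x_rest = −1.6 it rests below I ≈ 1.3, bursts for I ≈ 1.3–3.2 (two
timescales: fast spikes riding a slow duty cycle) and spikes tonically
above. Time is measured in milliseconds: with these constants the burst
rhythm of the coupled populations falls in the alpha range (~10 Hz).

The population is closed into three interacting "modes" by a Galerkin
projection. Input currents are Gaussian, I ~ N(μ = 3.1, σ = 0.5). The
projection basis is three rectangular functions, one per equal-probability
third of the distribution, orthonormalized in plain L² over a quantile grid
(n_quad = 1500 points spanning the central 1 − 2/1501 probability mass; the
truncation range is fixed so refining n_quad converges). Because the modes
are disjoint, the cubic and quadratic nonlinearities project diagonally
(aᵢ = a∫Vᵢ⁴, bᵢ = b∫Vᵢ³, …), the per-mode inputs are IEᵢ = ∫ I Vᵢ(I) dI,
and the intra-node mean-field coupling — every neuron feels the
density-weighted population mean — produces rank-one matrices
Aᵢₖ = ∫Vᵢ · ∫gVₖ (and likewise B, C across the excitatory/inhibitory
pair). The slow-equation offsets are mᵢ = nᵢ = r·s·x_rest·∫Vᵢ. The
inhibitory population shares the same excitability distribution, so its
coefficients mirror the excitatory ones. Uncoupled, each mode is exactly an
HR neuron with I equal to the mean input of its third — the low mode rests
or bursts, the middle mode sits in the chaotic spike-adding band, the high
mode spikes tonically; the intrinsic couplings (K₁₁ = 0.5, K₁₂ = 0.25,
K₂₁ = 0.5; all zero for the inhibitory-only reticular node) mix these
repertoires into the population rhythm.

Two transcription ambiguities in the printed mode equations are resolved in
favour of the original reduced model: the K₁₁/K₁₂ brackets are linear (not
absolute values) and the K₁₁ mean-field term enters with a positive sign;
the stray "−ηᵢ" closing the γ̇ equation is read as the per-mode constant nᵢ
(the mirror of mᵢ), restoring excitatory/inhibitory symmetry. The resting
offset printed as "x0 = 21.6" is not dynamically viable; the conventional
x_rest = −1.6 is the default and the field is configurable.

## Network, delays, integration

Node order is (cortex, thalamus, reticular). Signed weights w(target ←
source): thalamus→cortex 2, thalamus→reticular 0.5, cortex→thalamus 1,
cortex→reticular 1, reticular→thalamus −2; all scaled by the connectivity
scaling factor (CSF). Distances: thalamus–cortex 8.8, thalamus–reticular 0
(co-located), hence cortex–reticular also 8.8 (configurable); delays are
distance × (1/7) ≈ 1.26 ms, rounded to the nearest integration step (error
≤ 0.025 ms).

**Coupling convention.** The delayed coupling is *mode-wise*: mode i of the
source's principal membrane potential (ξ for full nodes, α for the
reticular node) drives mode i of the target's corresponding equation. The
alternative — summing ξ over modes and broadcasting the scalar — is
available (`NetworkSpec(coupling="summed")`) but triples the effective
coupling strength and carries a large DC component; under it the network
loses its alpha rhythm at CSF 0.6 and diverges from CSF ≈ 3.2, whereas the
mode-wise convention reproduces the expected phenomenology across the whole
ladder: alpha-band power decreasing with CSF, saturation near CSF 6.4, and
complete collapse (hyper-excitation) at CSF 12.8. The mode-wise form is
also how the publicly distributed implementation of this neural mass
couples nodes.

**Noise.** Additive white Gaussian noise, independent per node and state
variable, is injected into all six mode equations by default. The amplitude
convention is a continuous-time intensity: increment sd = 0.1·√dt per step.
Two alternatives are switchable in `IntegrationConfig`: restricting
injection to the membrane-potential equations (`noise_all_states=False`)
and reading 0.1 as the per-step increment sd at the native step
(`noise_mode="per_step_native"`). The defaults were fixed by requiring the
model's published qualitative behaviour: membrane-only injection produces a
*positive* alpha–firing correlation (slow excitability fluctuations, which
the slow-variable noise provides, are what let the system wander between
bursting episodes — high alpha, low firing — and tonic episodes — low
alpha, high firing); per-step-scaled all-state noise destabilizes the
CSF = 6.4 condition that must remain usable.

**Integrator.** Stochastic Heun (explicit trapezoidal predictor–corrector
with the same noise increment in both stages), dt = 0.05 ms, 300-s runs,
2-s burn-in (several times the slowest intrinsic timescale 1/r ≈ 167 ms).
The delayed drive is evaluated once per step from the ring-buffered history
and held across the two stages (error O(dt) against the ~1.26 ms delays).
Initial conditions are uniform in ±0.1 per state variable, drawn from
per-node RNG streams (Philox, spawn-keyed by node index) so that a
disconnected network is *bit-identical* to independent single-node runs.
Divergence (non-finite state or |state| > 10⁵, checked per 100k-step chunk)
raises `SimulationBlowUp` with the divergence time — the expected outcome
at CSF 12.8. The production path is a numba kernel; a pure-Python reference
stepper built from the public per-node API is kept as an equivalence oracle
in the tests.

## Signal extraction and analysis

Raw ξ/α traces (20 kHz) are decimated to 2 kHz with zero-phase FIR
anti-alias stages (≤10× per stage). Per node, the principal membrane
potential is the sum of ξ over modes (α for the reticular node); the LFP is
its 5–60 Hz band and the MUA its 500–900 Hz band, both 2nd-order
Butterworth applied forward–backward (zero phase, −6 dB at the band edges).
A config flag allows the literal sum over all excitatory state variables
(ξ + η + τ) for sensitivity analyses; it does not change the sign structure
of the results.

Alpha power is the mean squared modulus of a 3-cycle Morlet wavelet
transform over 8–12 Hz (1-Hz grid); alpha phase is taken at the 10 Hz band
centre (circular mean across the band is available). The MUA firing-rate
proxy is the squared band-passed signal smoothed by a centred ±375 ms
moving average, defined in time units so it is rate-invariant; for phase
binning the *unsmoothed* power is used, since averaging across alpha cycles
would erase the phase structure by construction. Phase–MUA coupling is
summarized by mean MUA in 20 uniform phase bins.

The predicted BOLD signal convolves the weighted membrane potentials (2/3
excitatory + 1/3 inhibitory; only the inhibitory term exists for the
reticular node) with the canonical double-gamma HRF (response delay 6 s,
undershoot delay 16 s, dispersions 1, ratio 6, length 32 s; empirical peak
≈ 5 s) and decimates to 1 Hz. The "alpha BOLD regressor" applies the same
kernel to the alpha-power time course. Alpha–MUA correlations are Pearson r
at 2 kHz (1-s edge trim); alpha–BOLD correlations are Pearson r at 1 Hz
(33-s leading trim for the kernel ramp). Coherence between cortical and
thalamic LFPs is Welch magnitude-squared coherence with 2-s Hann segments
at 50% overlap (0.5 Hz resolution, ~300 segments per 300-s run).

Across repetitions (n = 10, randomized initial conditions and noise), each
correlation is summarized by its mean, a two-sided one-sample t-test of the
Fisher-z-transformed values against zero, and the 95% t-interval half-width
mapped back to the r scale (a plain-r variant is switchable). The CSF sweep
repeats the full pipeline over the ladder {0.0, 0.1, 0.2, 0.4, 0.6, 0.8,
1.6, 3.2, 6.4} — a doubling ladder spanning the usable range — and also
aggregates per-level LFP spectra and cortex–thalamus coherence; blown-up
repetitions are recorded and excluded.

## Surrogate generators

`tcalpha.surrogates` provides fixtures with known answers for every
analysis operation: `make_correlated_pair` produces Gaussian pairs with an
*exact* sample correlation (orthogonalize-then-mix), and `make_surrogate`
produces an LFP-like amplitude-modulated 10 Hz carrier (plus pink noise)
and an MUA-like 500–900 Hz noise train whose instantaneous power follows
the carrier phase (controllable lock depth) and whose slow rate envelope
has an imposed sample correlation with the slow carrier-power envelope.
Slow components are band-limited (< 0.4 Hz) stationary Gaussian processes
built by FFT synthesis — no filter edge transients — and the imposed
correlation is made exact on the interior region the analysis evaluates
(2-s edges excluded); after envelope estimation and smoothing the realized
correlation recovers the target within about ±0.02. The surrogates emulate
only the statistical features the analysis assumes (narrowband carrier,
phase-locked bursts, controllable amplitude–rate correlation), not the
spectrum or nonstationarity of the simulated network; passing fixture tests
validates the analysis chain, not the model.

## Problem sizes used in the checks

The packaged test suite exercises the simulator at 22–122 s per run and the
acceptance script at the full 10 × 300 s reference condition (a few minutes
on one CPU; both are scaled by flags). The compiled kernel simulates 300 s
of the three-node system in ~10 s.

## Reproduction status and limitations

With every published parameter, the model reproduces the qualitative
claims: a narrowband ~10–12 Hz cortical LFP at CSF 0.6 whose power
fluctuates; negative alpha–MUA and alpha–BOLD correlations across most of
the CSF range; phase-locked MUA with a sinusoidal phase profile that
disappears across disconnected nodes; alpha power decreasing with CSF;
usable dynamics to CSF 6.4 and collapse at 12.8; and HRF low-pass
enhancement (|r| larger at the BOLD level than at the MUA level for the
cortical node in most seeds).

Quantitatively, the across-repetition mean correlations carry the right
signs but are roughly 2–4× weaker than the published reference values
(e.g. cortical alpha–MUA ≈ −0.01…−0.07 across seeds vs. −0.06 ± 0.03;
cortical alpha–BOLD fluctuates around −0.1 with across-repetition sd ≈ 0.2
vs. −0.25 ± 0.12), and the reticular-node correlations hover around zero.
The per-repetition spread matches the published confidence intervals; the
gap is in the means. The most likely cause is that the exact closed-form
mode-coefficient formulas live in an external supplement that is not part
of the sources available here; the Galerkin construction implemented above
is derived from first principles and validated by quadrature-convergence
and Monte-Carlo oracles, but may differ in detail (basis normalization,
truncation, inhibitory input offsets) from the original derivation, and the
correlation magnitudes are sensitive to the resulting operating point —
specifically to how much slow (multi-second) structure the alpha envelope
carries. Runs shorter than ~300 s make the 1-Hz BOLD correlations very
noisy (≈ 30 effective samples per repetition after HRF smoothing).

Other limitations: no forward model to scalp EEG; the hemodynamic step is a
linear canonical-HRF convolution, not a nonlinear hemodynamic state model;
three nodes only, with static weights; and the delay contract rounds to the
integration step.
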