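# Methods

## Models

The immature cell is the Paci 2013 ventricular-like hiPSC-CM model
(18 states; SI units internally, V and s), the adult reference the
ten Tusscher 2006 epicardial model (19 states; mV and ms).  Both are hand
transcriptions of the published equation sets, restructured so that every
scalable current or flux carries a named multiplicative prefactor: with a
parameter vector of ones the right-hand side is the published model, and the
membrane equation has the form v' = −Σ qᵢ Iᵢ(v, s).  The scalable set
comprises I_Na, I_CaL, I_to, I_Ks, I_Kr, I_K1, I_NaCa, I_NaK, I_pCa, I_f,
I_bNa, I_bCa and the SR fluxes J_leak, J_up, J_rel (the adult model adds
I_pK; it has no funny current, so its I_f entry is a zero-conductance
placeholder kept only so parameter vectors align by key with the 17-entry
adult maturation diagonal).  A separate geometry factor scales the
surface-to-volume relation, i.e. the membrane-current terms of the
intracellular concentration balances; it is not a current and does not enter
the voltage equation.

Deviations from the published immature model can be supplied as a plain-text
conductance patch (`build_base_model(patch=...)`); overrides are recorded in
a machine-readable changelog on the model object.  With no patch, the
published 2013 parameterization is used unchanged.  Under that
parameterization one paced beat yields per-current |I| integrals of
314 (I_K1), 226 (I_CaL), 152 (I_Kr), 108 (I_Na), 11.8 (I_to) and
3.4 (I_Ks) nC/µF — the canonical ordering of current contributions, with
magnitudes within ~20% of the reference table this package reproduces.

## Pacing and integration

Both models are paced with a square depolarizing pulse at 1 Hz; the pulse
uses each model's published strength (immature: 5.5 A/F for 5 ms; adult:
52 A/F for 1 ms), overridable per protocol.  Integration uses LSODA with
rtol 1e-6 / atol 1e-8 and per-segment restarts at the stimulus edges; output
is resampled to a uniform 1 ms grid (the optical acquisition is ~100 Hz, so
1 ms oversamples the data regime by an order of magnitude).  Simulation is
deterministic: identical inputs give bitwise-identical traces, and a 10×
tolerance tightening moves APD80 by well under 0.01 ms.

The quasi-steady 1 Hz paced state of the unscaled base model (50 pre-pacing
beats) is computed once and cached.  Every cost evaluation — and every
synthetic target — then simulates **one conditioning beat under the candidate
parameters from that cached state and measures the following beat**.  Using
the identical protocol on both sides of the cost makes self-inversion exact
by construction and keeps a full inversion (5 500 beat simulations) around
two minutes on one CPU.  The alternative of pacing each candidate to its own
steady state changes recovered blocks by well under the search scatter (we
probed 0/1/3 conditioning beats; the identified Verapamil-style I_Kr block
moved from −0.16 to −0.20 against a −0.25 truth, with the residual gap
attributable to search resolution, not protocol bias).

## Waveform features and cost

Eight features per beat: the voltage integral over the 30% transient
(between the APD30 crossings), APD_V,30/50/80, the maximal calcium upstroke
velocity, and APD_Ca,30/50/80.  Transient durations are measured between
linearly interpolated crossings of the x%-repolarization level relative to
the baseline-to-peak amplitude; the baseline is the pre-upstroke minimum
(samples up to the maximum discrete dF/dt).  This makes every duration
feature invariant under positive affine rescaling — the property that lets
arbitrary-unit optical traces be compared with simulated traces.  For
measured traces both channels are min–max normalized before the two
scale-dependent features (voltage integral, calcium upstroke velocity) are
computed; inside the cost the simulated candidate is produced on the
measured target's sampling grid and normalized identically, so the H-terms
compare like with like (the discrete upstroke-velocity estimator is
grid-dependent).  Voltage upstroke velocity is
deliberately not a feature: optical voltage does not resolve the upstroke.

Each Hⱼ is the absolute relative mismatch of one feature, with the
denominator taken from the target; H1's integration bounds come from each
trace's own APD30 crossings.  The aggregate cost is the square root of the
selected Hⱼ sum (voltage-only: H1–H4; calcium-only: H5–H8; combined: all
eight) plus the penalty ε Σ λᵢ², ε = 0.2.  Simulations that fail or produce
non-repolarizing beats map to a large finite sentinel (10⁶) so the random
search can step past them; evaluations are cached keyed by λ rounded to
1e-6.

## Search

The minimizer follows the shrinking-box scheme exactly: N uniform draws from
the initial box ([−0.5, 0.5]⁶ free mode; [−0.99, 0]⁶ drug mode), retain the
global best five, center five boxes on them with per-dimension lengths
shrunk to 90% per iteration, draw N/5 from each, re-rank globally, repeat.
Refined boxes may leave the initial box; the only hard clips are λ > −1 and,
in drug mode, λ ≤ 0.  Ties break by evaluation order.  One master seed feeds
per-iteration child streams, so changing N does not reorder other
iterations' draws.  Reference scale is N = 5000 × 10 iterations; the
desk-scale default used throughout the tests is N = 500 × 10.

At N = 500 the four high-charge currents (I_Na, I_CaL, I_Kr, I_K1) are
recovered to within ≈0.05–0.1 of truth.  The two minor currents carry so
little charge that only the penalty constrains them, and a best-of-100 draw
per box cannot resolve the 0.2 λ² gradient beneath the feature-mismatch
scatter: their estimates wander by up to a few tenths.  This is a property
of the published algorithm at reduced N — at the reference N = 5000 the same
flat dimensions resolve to ≈0.05 — and it is why the package reports minor
currents as weakly identifiable rather than zero.

## Maturation map

Maturation is modeled as multiplication: for a single channel species with
conductance g = N g₀ / A, invariance of the single-channel conductance g₀
under maturation gives g_M = (q_N / q_A) g_IM, one positive factor per
protein species plus one geometry factor — hence a diagonal map Q with
p_M = Q p_IM.  The printed immature (16-entry) and adult (17-entry)
diagonals are pinned in `paci_map()` / `tt_map()`.  The workflow updates Q
so it sends the inverted control cell onto the mature reference
(Qᵢ = p_M,ᵢ / p_IM,C,ᵢ), maps the drugged parameterization with the updated
map, and reports per-current fractional changes — which equal the identified
λ exactly, because diagonal maps commute with fractional blocks.  The
default mature reference is the base model scaled by the immature diagonal
(single-model pipeline); cross-family mapping onto the ten Tusscher model is
available but not the default path.

## Synthetic data

`simulate_drug_dataset` generates control/drug beat pairs with known
ground-truth blocks under the canonical protocol.  Noise-free, physical-unit
pairs are the default (matching the simulated-data experiments this package
reproduces).  Optical-style datasets add per-channel positive affine
rescaling into arbitrary units, resampling to 100 frames/s, and additive
Gaussian noise, default 1% of amplitude — the residual level after averaging
5–7 beats, which is what the inversion actually consumes.
`make_optical_recording` tiles a beat into a jittered multi-beat recording
for exercising the preprocessing chain.  The generator does not model
photobleaching, dye kinetics or motion artifacts; passing tests therefore
demonstrate correct recovery under the model's own family plus acquisition-
style distortions, not robustness to biological model mismatch.

## Preprocessing of optical recordings

3-point median filter (endpoints pass through); beat detection at per-beat
maxima of the discrete dF/dt separated by at least half a pacing period;
exclusion of beats whose inter-upstroke interval deviates >20% from the
pacing period; windows of one pacing period aligned at the upstroke sample
with a fixed 100 ms pre-upstroke margin; outlier exclusion of beats whose
RMS deviation from the provisional mean exceeds 3× the median RMS deviation
(a documented stand-in — the upstream protocol only specifies discarding
clearly deviant traces); pointwise averaging.  All exclusions are logged.

## Numerical and design notes

- Crossing interpolation is linear; flat threshold segments resolve to the
  earliest time.  Duration errors against a 1 µs dense-scan oracle are
  below 0.1 ms on randomized beats.
- The calcium upstroke velocity uses central differences on the sampling
  grid; at 1 ms it sits within 2% of a cubic-spline derivative maximum once
  the grid resolves the derivative peak (0.2 ms for the immature model).
- Multiple-beat detection inside the feature extractor uses a 5%-amplitude
  hysteresis, so percent-level noise does not trigger false beat counts.
- Degenerate inputs raise typed errors: non-repolarizing traces, empty
  search boxes after clipping, non-positive parameters or maturation
  factors, unknown identifiers (named in the message).
- Known limitations: single-cell ODEs only (no tissue or extracellular-
  potential modeling); drugs are pure conductance scalers (no state-
  dependent binding kinetics); minor-current blocks are structurally hard to
  identify from these waveforms; maturation is a static map, not a
  trajectory.
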