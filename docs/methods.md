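# Methods

## Gating model

The kinetic scheme is a linear three-state continuous-time Markov chain

    O  ⇌  C2  ⇌  C1

with generator (states ordered O, C2, C1; rates in s⁻¹)

    Q = [ −k_oc            k_oc              0    ]
        [  k_co   −(k_co + k_21)            k_21  ]
        [   0              k_12            −k_12  ]

O is conducting; C2 is the pre-open closed state entered at every closure;
C1 is a long-lived closed state reachable only through C2. The chain
topology excludes a direct O↔C1 transition: the model is identified from
dwell-time distributions alone, and a linear chain is the minimal scheme
consistent with one open and two closed exponential components. Key analytic
quantities (all implemented and unit-tested against independent oracles):

- stationary occupancy π solves πQ = 0, Σπ = 1; by detailed balance on the
  chain, π ∝ (1, k_oc/k_co, k_oc·k_21/(k_co·k_12));
- open probability Po = π_O = 1/(1 + k_oc/k_co + k_oc·k_21/(k_co·k_12));
- open dwells ~ Exp(k_oc), so the closing rate constant is k_oc = 1/τ_O;
- closed dwells are phase-type with entry at C2: the density is a mixture of
  two exponentials whose rates are the eigenvalues of the negated closed
  sub-generator Qc = [[−(k_co+k_21), k_21], [k_12, −k_12]].

Rates are voltage-independent (recordings are at a fixed step potential);
there are no sublevels and no ligand dependence.

### Reference parameter sets

The recordings the pipeline emulates are not deposited, so the generator's
default conditions are fixed once, from the published per-patch summary
statistics, and not tuned thereafter:

- `WT_LIKE_RATES = (100, 70, 24.5, 15)` s⁻¹ — chosen so the analytic
  Po equals the wild-type value 0.21 exactly, with a 10 ms mean open time
  and closed time constants of ≈10 ms and ≈94 ms (ms-scale, well above the
  dead time);
- `G579A_LIKE_RATES = (100, 30, 43.5, 5)` s⁻¹ — Po = 0.03 exactly (the
  rigid-hinge, low-activity phenotype) with the same mean open time, since
  the mutant's unitary amplitude and open time are not significantly
  changed;
- the algebraically convenient set (100, 50, 20, 10) s⁻¹ with
  π = (1/7, 2/7, 4/7) is used as the main test oracle.

### Synthetic traces

`simulate_states` is an exact Gillespie realization (stationary initial
state; final dwell truncated at the sweep end and flagged so fits can censor
it). `render_trace` samples the path at the acquisition interval (default
dt = 100 µs), adds white Gaussian noise (default sd 0.5 pA) to the
piecewise-constant current (unitary amplitude 5.5 pA, closed level 0), and
smooths with a Gaussian FIR whose −3 dB point matches the recording filter
(default 5 kHz; σ_t = √(ln 2)/(2π f_c) ≈ 0.1325/f_c). A hardware Bessel
filter is not exactly reproducible offline; the Gaussian FIR is a standard,
documented approximation with the same −3 dB point. Noise is white and
additive; 1/f and seal-leak components are out of scope. Multi-channel
patches (`superpose_channels`, 1–3 channels typical) sum independent gating
paths and share one noise draw. Every stochastic operation is
bit-reproducible given (inputs, seed).

## Idealization

Baseline = mode of the all-points amplitude histogram (valid for Po < 0.5).
Amplitude statistics come from a k-component Gaussian-mixture EM fit
(scikit-learn backend, quantile-spaced deterministic initialization,
tol 1e-8, max 500 iterations); the component nearest the baseline is the
closed level and the unitary amplitude is the nearest open mean minus the
closed mean.

Event detection is half-amplitude thresholding: sample-wise assignment to
conductance level k when the deviation from baseline rounds to k·A
(thresholds at (k−½)·A), run-length encoding into events, then dead-time
imposition: every event shorter than the dead time is absorbed into its
predecessor (a leading short event joins its successor) and equal adjacent
levels are coalesced. The operation is idempotent and preserves total
duration. Default dead time = 2·dt (0.2 ms at 100 µs sampling), the
conventional resolvability bound. Half-amplitude idealization was chosen
over hidden-Markov idealization for determinism and testability; a
model-based idealizer is an extension point, and no equivalence with any
commercial event detector is claimed.

## Dwell-time inference

All densities are left-truncated at the dead time d and renormalized on
[d, ∞): unresolvable events are censored, not corrected for. Exact
missed-event corrections (e.g. joint open-closed missed-event likelihoods)
are deliberately out of scope; the truncation approach is transparent and
its bias grows only as dwell time constants approach the dead time (the
fitted regimes here keep τ ≥ 5·d, where recovery is accurate to well within
20%).

- `fit_exp_mixture`: k-exponential mixture MLE by quasi-Newton (L-BFGS-B) on
  (log τ, weight logits); k = 1 uses the closed form τ̂ = mean − d (exact
  under memorylessness); 5 deterministic-plus-seeded starts; degenerate
  all-equal samples return a flagged single component with a warning.
- `select_n_components`: fits k = 1..k_max and selects by BIC (default) or
  sequential likelihood-ratio tests (α = 0.05, df = 2 per extra component);
  fewer than 20 events force k = 1 with a warning.
- `fit_three_state`: joint MLE of the four rates — open dwells Exp(k_oc),
  closed dwells the entry-at-C2 biexponential of Qc — optimized on log-rates
  (bounds 1e−4..1e7 s⁻¹) from 5 starts seeded by a moment-matched mixture
  fit; convergence tol 1e-12 on the objective. Identifiability: if the
  biexponential closed law does not beat a single exponential by a
  likelihood-ratio margin (χ², df 2, α = 0.05), or k_21 hits its lower
  bound, the fit is flagged as collapsed to two states.
- Edge dwells (first/last event of a sweep) are censored by default.
- `empirical_open_probability`: NPo = Σ level·duration / T, Po = NPo/N with
  N defaulting to the maximum observed level.

Times are seconds internally and milliseconds in reports, avoiding unit
drift inside the likelihoods.

## Whole-cell processing

Steady-state current per voltage step is the mean over a window defaulting
to the final 25% of the step (the protocol itself does not fix a window;
it is configurable). %I_max normalization divides by the signed current at
the −100 mV reference and multiplies by 100, so inward-rectifying curves
read +100 at the reference; it is idempotent and preserves current ratios.
The EGTA-sensitive current is the pointwise difference of divalent-free and
nominally divalent-free curves on a matching voltage grid. Current density
is I/C (pA/pF). Series-resistance compensation, capacitance transients and
junction potentials are hardware-side corrections and out of scope. The
synthetic step generator uses a Boltzmann-rectified ohmic form
I(V) = g·(V − E_rev)/(1 + exp(V/40 mV)) purely as a plausible
inward-rectifying test shape.

## Pore geometry

`read_pdb` (Biopython backend) keeps the highest-occupancy altloc, skips
waters, and assigns Bondi van der Waals radii by element (unknown → 1.7 Å
with a warning; the radius table is configurable because published
pore-radius numbers depend on the radius set used). Hydrogens absent from
the input are simply ignored — united-atom radii are not applied.

The pore axis is the line through the selected atoms' centroid that
minimizes the variance of their perpendicular distances (exact for rings
and cylinders of pore-lining atoms); a declared symmetry axis takes
precedence. The radius profile maximizes, at each axial position z, the
probe radius min_a(‖p − x_a‖ − vdw_a) over lateral offsets: a coarse local
grid (0.25 Å) around the previous z's optimum plus Nelder-Mead refinement.
The path-following start keeps the probe on the connected pore line rather
than letting it jump to cavities outside the protein; positions bounded
only by the lateral search bound (default 10 Å) are flagged "open".
Profiles match an independent fine brute-force grid search to < 0.05 Å on
all analytic fixtures and are invariant under rigid-body motion.

Rotamers: `set_symmetric_rotamer` rigidly rotates the side chain beyond Cβ
so that χ1 (N–Cα–Cβ–Cγ) and χ2 (Cα–Cβ–Cγ–Cδ1) reach their targets,
identically in every listed chain; bond lengths and angles are exactly
preserved, and C4 symmetry of a symmetric input is maintained. The built-in
tryptophan rotamer table uses the canonical χ1 classes t/m/p (180°, −60°,
+60°) with χ2 = 90°; on the bundled gate fixture these correspond to the
side chains facing each other, pointing up, and pointing down.

Gate rule: for facing side chains a minimum inter-subunit distance d apart
(diagonal pairs for a tetramer), the free aperture is max(0, d − 2·r_eff).
The default effective surface radius r_eff = 1.15 Å is an explicit
calibration chosen so that d = 3.1 Å maps to a 0.8 Å passage — the
published mapping — and is configurable; it is not claimed to equal any
specific vdW convention. Permeation: permeable iff aperture ≥ ion diameter
(boundary permeable), default ion the dehydrated Ca²⁺ at 0.99 Å.

`make_toy_pore` builds deterministic fixtures with known analytic geometry:
a 12-atom carbon ring (pore radius R − vdw at the plane), a stacked-ring
cylinder (constant profile), an hourglass (quadratic radius law, analytic
waist), and a C4 pseudo-tryptophan `tetramer_gate` whose facing-rotamer
side-chain distance is calibrated to 3.1 Å by construction (solved by root
finding on the rigid radial placement of the subunits). The fixture is a
synthetic stand-in with idealized bond geometry, not a homology model: it
exercises the rotamer/aperture/profile machinery, not structural claims
about any real channel.

## What the synthetic data do and do not show

Passing tests demonstrate that the inference machinery is correct and
well-calibrated *under the generator's assumptions*: Markov gating,
stationary baseline, white noise, a known filter, no drift. Real patch
records add seal instability, 1/f noise, mode shifts and occasional
sublevels, none of which are modeled; the pipeline's numbers on real data
therefore inherit the usual caveats of half-amplitude idealization and
truncation-only missed-event handling. Problem sizes in the test suite
(30 × 10 s sweeps per fit, 2·10⁴ dwells for model selection, 20 seeds per
claim) were chosen as the point where Monte-Carlo error is comfortably
below the asserted tolerances.

## Known limitations

- No missed-event correction beyond left truncation; biased for τ ≲ 5·d.
- Half-amplitude idealization misclassifies during heavy filter ringing or
  low signal-to-noise (< ~5); amplitudes below ~2 noise sd are not
  resolvable.
- The closed-dwell entry distribution assumes every closure lands in C2 —
  correct for the linear chain, not for branched schemes.
- The pore profiler reports the inscribed-sphere radius along a single
  connected path; side pockets and multi-pore topologies are not traversed.
- Rigid rotamer setting does not repack neighboring side chains or
  minimize energy; clashes are reported as small or zero pore radii, which
  is the intended reading.
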