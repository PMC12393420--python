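# Methods

## Model formalism

`dyrknet` implements a logic-based differential-equation (LDE) network
model. Species activities are dimensionless, normalized to a nominal
maximum of 1, and evolve by first-order relaxation toward a gate-driven
target:

    dY_i/dt = (Y_max,i · g_i(Y) − Y_i) / τ_i.

Regulatory influence enters through the normalized Hill function
f(x) = B·xⁿ/(Kⁿ + xⁿ) with B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1) and
K = (B − 1)^(1/n), the unique parameterization satisfying f(0) = 0,
f(EC50) = ½ and f(1) = 1. This triple makes unit activity of a regulator
drive unit gate output, so a chain of default edges transmits full
activation losslessly. The constants are evaluated in the
cancellation-free forms B = (1 − e)/(1 − 2e), Kⁿ = e/(1 − 2e) with
e = EC50ⁿ, which stay accurate near the admissible boundary
EC50 → 0.5^(1/n) and for very small EC50.

Gate algebra: AND within a rule is the product of regulator terms
(inhibitors contribute 1 − f); OR across rules for one product is the
inclusive-or fold a + b − ab, applied in rule-declaration order (the fold
is associative/commutative, the fixed order just keeps output
byte-stable). Each regulator term is clamped to [0, 1] before
combination. The clamp matters only during overexpression, where
activities reach 10 and raw f(x) would exceed 1, making the
inclusive-or non-monotone; clamping caps an overexpressed regulator's
influence at full activation without changing any direction of effect.

Default parameters: w = 1, n = 1.4, EC50 = 0.5 per rule; Y_init = 0,
Y_max = 1, τ = 1 per species. Time and τ are in arbitrary units; all
activities are dimensionless fractions of nominal maximal activation.

## Numerics

Integration uses LSODA with rtol 1e-8 / atol 1e-10. The stiffness
driver is the overexpression clamp (τ = 10⁹ against τ = 1 elsewhere);
a stiff-capable method with tight tolerances keeps trajectories
tolerance-converged to well under 1e-6 (checked by a tolerance-halving
test). Steady state is declared when, across a check window of 1 time
unit, every species' relative change is below 5×10⁻⁴ (0.05%); for
activities below 10⁻³, where relative change is ill-posed, an absolute
criterion of 5×10⁻⁷ per window substitutes. Default integration horizon
is 1000 time units; non-convergence within it is reported as a flag,
never an exception, so screens can record oscillatory or slow grid
points. Tests that compare against the acyclic fixed-point oracle
tighten the stopping thresholds (relative 10⁻⁹) since the default
protocol's 0.05% endpoint deliberately stops earlier than numerical
convergence.

A planar (two-node) LDE network cannot oscillate: the vector field's
divergence is −Σ 1/τ_i < 0 everywhere, so Bendixson–Dulac rules out
limit cycles. The non-convergence fixture is therefore a three-node
inhibitory ring with a steep Hill coefficient (n = 4), which sustains
repressilator-style oscillations.

## The DYRK1A cell-cycle network

The shipped network (13 species, 17 rules) encodes: DYRK1A → pLIN52 →
DREAM assembly, opposed by B-Myb competition and by cyclin-D-dependent
DREAM disassembly; DYRK1A-mediated cyclin D destabilization
(`!DYRK1A => CycD`); E2F1/2/3-driven cyclin E with a weak basal source;
cyclin E/CDK2 complex formation; RB-1 active only while both cyclin arms
are low (AND of two inhibitions, making cyclin D and cyclin E/CDK2
redundant RB inactivators); E2F activation requiring release from both
RB-1 and DREAM; and a DNA-replication output driven by the three E2Fs
jointly OR by cyclin E/CDK2.

Design choices that were genuinely open, and why they were resolved this
way:

* **Input calibration.** Inputs are held below saturation so baseline
  perturbations have somewhere to go: DYRK1A Y_max = 0.9, B-Myb 0.1,
  CDK2 0.8. With CDK2 at 1.0, f(CDK2) is already 1 and CDK2
  overexpression would be a literal no-op under the flux clamp.
* **E2F redundancy vs. joint requirement.** The knockout screen must
  show each single E2F knockout attenuating the DYRK1A-KO response. An
  OR gate cannot: under full DYRK1A knockout every E2F saturates at
  exactly 1 (a consequence of the f(0) = 0, f(1) = 1 identities), and an
  inclusive-or of a 1 is 1 regardless of the other inputs. The E2Fs
  therefore gate DNA replication (and act on cyclin E transcription)
  as a joint requirement, with the cyclin E/CDK2 arm as an OR bypass
  that keeps single-E2F loss partial (≈18% attenuation) rather than
  total.
* **Basal cyclin E.** A weak source rule (w = 0.18) represents
  E2F-independent basal cyclin E transcription. It sets the quiescent
  operating tone of the CDK2 arm: without it the baseline output sits at
  a multiplicative floor (~10⁻³) where neither CDK2 overexpression nor
  DYRK1A overexpression can move it measurably.
* **Cyclin D feedback on DREAM.** Cyclin-D-associated kinase activity
  phosphorylates the RB-like DREAM subunit and disassembles the complex;
  including `!CycD` in the DREAM rule both reflects that biology and
  couples baseline DREAM to DYRK1A's cyclin D arm.

At baseline the network rests in a quiescent attractor (DREAM 0.82,
RB-1 0.86, DNA replication 0.09); DREAM, being independent of the
E2F–cyclin E–RB positive feedback loop, caps E2F activity and makes the
quiescent state unique while DYRK1A is active. Removing DYRK1A removes
the cap and the loop flips the network to the proliferative attractor.

## Perturbation protocols

Knockdown of fraction k multiplies the target's Y_max by (1 − k); k = 1
is full knockout. The graded form is the unique reading consistent with
1%-increment concentration responses while reducing to Y_max = 0 at
k = 1. Overexpression sets Y_max = 10 for inputs; other nodes get
Y_init = 10 with τ = 10⁹, a clamp that holds them near 10 over any
practical horizon. All perturbed runs restart from the pre-perturbation
steady state (continuation), with overexpressed non-input nodes lifted to
their clamped initial value; knocked-down nodes keep their steady-state
activity and decay under the reduced Y_max. Continuation matches the
perturb-after-steady-state protocol and avoids basin artifacts in the
bistable regime.

## Analyses

* **Concentration response**: knockdown grid 0, 0.01, …, 1.00; each
  point re-run to steady state from baseline. Half-max points use
  min–max normalization between each node's 0%- and 100%-knockdown
  activities — the one formula that defines EC50 (rising nodes) and IC50
  (falling nodes) alike — taking the first 0.5-crossing with linear
  interpolation between bracketing grid points. Nodes whose end-to-end
  change is below 10⁻³ are reported as non-responding. Half-max
  estimates are grid-stable to < 0.005 against a half-step grid.
* **Knockout screen**: 100% single-node knockouts on top of a context
  (packaged analysis: 100% DYRK1A knockdown, matching the screen that
  interrogates modulators of the knockout response). Entries are raw
  steady-state activity changes against the context reference;
  normalization is left to presentation. The 10%-of-rise attenuation
  threshold used in tests is an interpretation convention; the screen
  itself emits raw deltas.
* **Dose protocol**: knockdowns of 15/30/45% emulate low/medium/high
  inhibitor concentrations; the table reports all nodes at each dose
  plus dose 0.
* **Validation harness**: each literature experiment is simulated and
  the readout's direction classified with an absolute threshold of 0.01
  activity units — an order of magnitude above the steady-state stopping
  tolerance, so numerical drift can never register as a direction.
  Accuracy is rounded half-up to integer percent (matching how such
  accuracies are conventionally printed); experiments naming unknown
  species are excluded from the denominator with a warning.

## Synthetic fixtures

The fixture module generates cascades, fan-ins, inhibitory rings, and
random (acyclic or cyclic) networks, all fully determined by their seed.
Random parameters span n ∈ [1, 4], EC50 ∈ (0.1, 0.9·0.5^(1/n)),
w ∈ (0.2, 1], input Y_max ∈ [0.3, 1], τ ∈ [0.5, 2] — wide enough to
exercise the admissible region while staying clear of its singular edge.
Acyclic fixtures come with an independent steady-state oracle
(topological fixed-point composition, no ODE solver), and the validation
suite generator plants a known number of direction mismatches so the
accuracy arithmetic has exact ground truth. These fixtures validate the
engine's math and bookkeeping; they do not emulate biological topology
(no scale-free structure, no omics-fitted parameters), so passing them
certifies the simulator, not the biological fidelity of any particular
network.

## Problem sizes and determinism

The packaged analyses are small by construction: 13 species, 101-point
concentration grids, 13-row screens; every analysis completes in seconds
and is exactly reproducible — identical inputs yield byte-identical
CSV/JSON, and all stochastic fixtures are seed-determined.

## Known limitations

* The network is a literature reconstruction validated behaviorally
  (knockout/overexpression directions, screen attenuation pattern,
  sensitivity ordering); alternative edge lists satisfying the same
  contract exist, and the file-based asset is designed to be replaced
  wholesale as curation improves.
* Only the five cardiomyocyte-context validation experiments ship with
  ground truth; the cancer-context suite file is an empty template
  pending curation, so the packaged 13-experiment accuracy check runs on
  synthetic suites with planted mismatches.
* No stochasticity, delays, spatial structure, or parameter fitting;
  overexpression magnitudes (not directions) depend on the flux-clamp
  convention.
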