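# Methods

## Model structure

The model is the Lipniacki-type ODE description of canonical NF-κB
signaling: a TNF-activated IKK cascade (neutral → active → inactive, with
constitutive synthesis and common degradation), IKK-dependent and
-independent IκBα degradation, cytoplasmic and nuclear IκBα·NF-κB complex
formation, nucleocytoplasmic shuttling of NF-κB, IκBα and their complex,
and NF-κB-induced transcription of IκBα, A20 and a generic control gene.
A20 feeds back by promoting TNF-dependent IKK inactivation. The 15 species
obey 28 mass-action reactions; total NF-κB is conserved, so the system is
integrated as 14 ODEs with free cytoplasmic NF-κB eliminated algebraically:

    NF-κB = NF-κB_total − [IKKa·IκBα·NF-κB] − [IκBα·NF-κB]
            − ([NF-κBₙ] + [IκBαₙ·NF-κBₙ]) / kv

where kv is the cytoplasmic-to-nuclear volume ratio. Eliminating rather
than integrating the 15th equation keeps the conservation drift at the
level of floating-point rounding (measured < 10⁻¹⁵ relative over 630 min,
versus the 10⁻⁶ requirement).

β-TrCP extends the base model as a dimensionless multiplicative factor
(β-TrCP / 1 nM) on the rate constants of the two IKK-dependent IκBα
degradation reactions (reactions 8 and 10). This mass-action form is forced
by two constraints: the extension must reduce exactly to the base model at
the 1 nM reference, and both reactions must vanish at zero β-TrCP.
Saturating forms satisfy neither without extra, unconstrained parameters.

TNF is a binary indicator that switches 0 → 1 at t = 0 exactly (no ramp).

## Units and the nuclear-concentration convention

All rate constants are stored and integrated in the base model's published
units (µM, seconds) to keep the transcription verbatim; the public surface
converts to nM and minutes. Internally, nuclear species are per-nuclear-
volume concentrations and the conservation relation weights them by 1/kv.
All *reported* nuclear NF-κB values are whole-cell equivalents — the
per-nucleus concentration divided by kv = 5 — because that is the scale on
which the reproduced results are stated (resting ≈ 0.46 nM, stimulated
steady state ≈ 16.7 nM, first peak ≈ 56 nM at 1 nM β-TrCP; all three match
on this scale and are 5× off on the per-nucleus scale). Both views are
accessible (`StateVector.__getitem__("NFkBn")` vs
`StateVector.nuclear_nfkb`).

## Parameter provenance

The packaged fixture (`data/lipniacki2004_params.yaml`) transcribes the
published base-model constants (µM/s): IKK turnover (kprod, kdeg, k1, k2,
k3), association constants (a1, a2, a3), the β-TrCP-scaled degradation
rates (t1, t2), transcription/translation/turnover constants for IκBα, A20
and the control gene (c-series), transport rates (i1, i1a, e1a, e2a),
kv = 5 and total NF-κB = 0.06 µM. The transcription is validated in two
ways: structurally, by an independent 15-ODE re-derivation used as a test
oracle, and numerically, by reproducing the full set of published anchor
values (steady states, peak heights, fold-change, Hopf locations, period
range) without any fitting. `crosscheck_sbml` additionally compares a
fixture against any SBML L2/L3 encoding of the base model and aborts with
a per-parameter diff at > 10⁻⁶ relative deviation; the test suite
exercises it against a synthetic SBML file generated from the same
constants, since no curated file is bundled.

## Numerical choices

* **Integration.** LSODA with the analytic Jacobian, rtol 10⁻⁸, atol
  10⁻¹⁰ µM, dense output every 0.5 min. The system is stiff (sub-second
  binding vs hour-scale transcription). Halving the tolerances moves the
  nuclear NF-κB series by < 0.1% sup-norm. Negative concentrations are
  never clipped (clipping would break conservation); the integrator's own
  step control keeps states above −10⁻⁹ nM.
* **Jacobian.** Closed-form, assembled per rate law; the
  conservation-eliminated NF-κB contributes through the chain rule
  (∂N/∂pool = −1 cytoplasmic, −1/kv nuclear). Verified entrywise against
  central finite differences at random states (the rate laws are bilinear,
  so central differences are exact up to rounding).
* **Steady states.** Damped (backtracking) Newton on the analytic
  Jacobian, iterated to the smallest achievable residual (certification
  bound ‖rhs‖∞ < 10⁻¹⁰ µM/s; in practice ~10⁻¹⁷). Iterating only to the
  certification bound would leave ~10⁻⁵ relative slack along slow
  eigenmodes, defeating root deduplication. The deterministic path seeds
  Newton from a long LSODA relaxation (10⁷ s); a 20-point log-uniform
  multistart (seed 42 by default) searches for additional roots, discards
  unphysical ones (any negative pool, including the eliminated free
  NF-κB), and deduplicates at 10⁻⁶ relative tolerance. Across the scanned
  β-TrCP range the search finds exactly one physical root per parameter
  value — one branch.
* **Continuation.** The branch over β-TrCP is computed on a log grid (200
  points over [5×10⁻⁵, 2] nM by default), each solve seeded from its
  neighbor. This tracks the branch through the unstable interval, where
  forward integration cannot. A lost grid point triggers a from-scratch
  relaxation; if that also fails the value is recorded as a gap and the
  scan continues.
* **Hopf localization.** Sign changes of the leading eigenvalue real part
  on the coarse branch are refined by bisection in log-parameter to
  relative bracket width < 10⁻³. At the refined points the critical pair's
  |Re λ| is ~10⁻⁹ s⁻¹, well below the 10⁻⁶ s⁻¹ certification bound, with
  all other eigenvalues strictly stable.
* **Limit cycles.** Simulated for 10,000 min, first 2,000 discarded as
  transient (≥ 70 cycles retained); period from the detrended series'
  DFT peak with quadratic bin interpolation; envelope from the last 10
  periods. A post-transient span < 10⁻² nM raises a no-limit-cycle error
  with the measured decay rate instead of returning a bogus period. The
  DFT estimate agrees with the mean peak-to-peak interval within 1 min.
* **Measures.** Derivatives by central differences on the dense 0.5-min
  grid (no spline smoothing — reproducible and grid-converged below 0.5%
  at this density). The duration formula's raw moment expression has units
  of min²; the square root is returned so durations are in minutes,
  consistent with the reported 80–190 min range and with the standard
  definition of duration as the spread of the response; the raw variance
  is exposed alongside. AUC defaults to the initial-value baseline (the
  response over rest), with the zero baseline selectable, and both are
  reported.
* **Peak counting.** Local maxima filtered at a default prominence of
  0.1 nM (~0.2% of the principal response at 1 nM β-TrCP). The damped
  oscillation mathematically produces ever-smaller ripples within the
  630-min window (the 6th extremum has a prominence of ~0.08 nM, invisible
  at figure or experimental resolution); 0.1 nM counts the 1 + 4 peaks the
  dynamics resolve. A much smaller threshold (e.g. 10⁻³ nM) would count
  the sub-resolution ripple as a fifth minor peak. The threshold is a
  parameter of every peak-based function.

## Drug perturbations

Drug action is a time-varying dimensionless factor composing
multiplicatively with the baseline β-TrCP level: step, exponential decay
of the effect back to baseline (rate in 1/min), or a finite pulse; the
factor is 1 before onset. "Abundance" and "binding-rate" modes differ only
in interpretation: because β-TrCP enters the model solely through the
reaction-8/10 factor, equal factor trajectories give bit-identical inputs,
which is the formal content of the abundance/binding-rate equivalence —
and why a binding-specific inhibitor can mimic any abundance modulation
while sparing β-TrCP's other substrates. Integration is split at the
profile's discontinuity times so the stiff solver never steps across a
jump. These shapes are representative pharmacokinetic profiles, not
compartmental PK/PD models.

## Synthetic signals and what the tests show

The generator produces analytic signals with closed-form measure values:
an erf step (|derivative| is a Gaussian bump ⇒ duration = σ, signaling
time = µ exactly), sinusoids and damped sinusoids (known period), and
constants (moment measures undefined — an error, not zero). Seeded
Gaussian noise can be added to stress the estimators.

Two caveats on noisy signals. First, the |derivative| weight rectifies
additive noise: on a dense grid the noise contributes a nearly uniform
weight over the window, biasing signaling time toward the window midpoint
and duration upward, at first order in the noise level (at σ = 0.1 nM,
dt = 0.5 min on a 100 nM step: signaling time 253 vs 200 min, duration 137
vs 30 min). The estimators are therefore consistent as σ → 0 (verified by
Monte-Carlo) but *not* unbiased at finite noise; only AUC is exactly
unbiased (linearity). Applications to noisy experimental series should
smooth before differentiating. Second, the synthetic families emulate the
shapes of model trajectories, not biological variability: passing tests
demonstrate estimator correctness on known ground truth, not robustness to
single-cell measurement noise.

## Scope and limitations

* One deterministic "average cell": no stochastic (Gillespie) variant, no
  cell-to-cell variability, no receptor-level TNF dose response; TNF is
  on/off only.
* β-TrCP paralogues (β-TrCP1/β-TrCP2) are not distinguished, matching
  their reported functional redundancy in this pathway.
* The limit cycle is characterized by simulation only (no periodic-orbit
  continuation or Floquet analysis); periods and envelopes very close to
  the Hopf points, where transients decay slowly, would need longer
  horizons than the default protocol.
* Crosstalk of β-TrCP's other substrates (e.g. β-catenin/Wnt signaling)
  is outside the model.
* Problem sizes of the standard analyses — 630-min responses, 60-point
  measure scans, 200-point branches, 9 limit-cycle points over a
  10,000-min horizon — reproduce every reported quantity on a laptop core
  in seconds to minutes.
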