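# nfkb-btrcp

Quantitative analysis of how the ubiquitin-ligase substrate receptor
**β-TrCP** controls nuclear **NF-κB** dynamics, built on an ODE model of the
canonical TNF → IKK → IκBα/NF-κB/A20 signaling module.

In the canonical pathway, NF-κB is held in the cytoplasm by its inhibitor
IκBα. TNF stimulation activates the IκB kinase (IKK), which phosphorylates
IκBα; β-TrCP then mediates the ubiquitination and proteasomal degradation of
phosphorylated IκBα, releasing NF-κB to the nucleus. Negative feedback through
NF-κB-induced IκBα and A20 expression generates the characteristic damped (or
sustained) nuclear NF-κB oscillations. β-TrCP is a candidate drug target in
inflammation and cancer; this package asks quantitatively what modulating it
does to the nuclear NF-κB response.

## The model

The core is the two-feedback Lipniacki-type model of the module: 15 species
(three IKK forms, cytoplasmic/nuclear NF-κB and IκBα and their complexes,
A20, and the IκBα/A20/control-gene transcripts), 28 mass-action reactions,
14 ODEs plus one conservation relation for total NF-κB. TNF is a binary
input. β-TrCP extends the model as a multiplicative factor on the two
IKK-dependent IκBα degradation reactions (reactions 8 and 10):

    rate₈  = (β-TrCP / 1 nM) · t₁ · [IKKa·IκBα]
    rate₁₀ = (β-TrCP / 1 nM) · t₂ · [IKKa·IκBα·NF-κB]

so at β-TrCP = 1 nM the extension reduces exactly to the base model, and at
β-TrCP = 0 IKK-dependent IκBα degradation is silenced.

On top of the model the package provides:

* **Simulation** — resting steady states (damped Newton on the analytic
  Jacobian, long-relaxation seeded) and stiff TNF step responses over
  630 min with dense 0.5-min output.
* **Measures** — fold-change (max/initial), signal duration (square root of
  the |d[NF-κB]ₙ/dt|-weighted variance of time), signaling time (the
  corresponding mean), area under the curve, first-peak amplitude/timing,
  and prominence-filtered peak counting; plus scans over β-TrCP ∈
  [5×10⁻⁵, 2] nM.
* **Bifurcation analysis** — continuation of the stimulated steady state in
  β-TrCP, eigenvalue stability, bisection-refined Hopf points, and
  limit-cycle envelope/period (detrended DFT with quadratic bin
  interpolation) between them.
* **Perturbation** — time-varying drug profiles (step, exponential decay,
  pulse) acting on β-TrCP abundance or on its IκB-binding rate; the two
  modes are provably equivalent because β-TrCP enters only through the
  multiplicative factor above.

Rate constants are kept in the base model's published units (µM, s); the
public interface uses nM and minutes. Nuclear concentrations are reported as
whole-cell equivalents (per-nucleus concentration divided by the
cytoplasm/nucleus volume ratio kv = 5), the scale on which all results below
are stated. See `docs/methods.md` for the full methods note.

## Worked example

```python
import nfkb_btrcp as nb

params = nb.load_parameter_fixture()          # packaged base-model constants

rest = nb.unstimulated_steady_state(params)
print(f"resting nuclear NF-κB: {rest.nuclear_nfkb(params):.3f} nM")

traj = nb.stimulated_response(params, nb.Stimulus(tnf=1, btrcp_nM=1.0))
rep = nb.measure_report(traj)
print(f"first peak: {rep.first_peak_height:.1f} nM at {rep.first_peak_time:.1f} min")
print(f"fold-change: {rep.fold_change:.1f}, peaks: {rep.n_peaks}")

hopf = nb.find_hopf_points(params)
print("Hopf points (nM):", [round(h.btrcp_nM, 5) for h in hopf])
```

prints

```
resting nuclear NF-κB: 0.459 nM
first peak: 56.0 nM at 23.5 min
fold-change: 121.9, peaks: 5
Hopf points (nM): [0.0055, 0.01567]
```

i.e. TNF drives nuclear NF-κB from a resting 0.46 nM to a ~56 nM first peak
within 90 min, followed by four minor peaks (damped oscillations), a
~122-fold change; and between β-TrCP ≈ 5.5×10⁻³ and 1.6×10⁻² nM the
stimulated steady state is unstable and the oscillations become sustained
limit cycles with periods of roughly 100–112 min.

A CLI wraps the same pipeline for scripted use:

```sh
nfkb-btrcp timecourse scenario.yaml   # trajectories + measures + figure
nfkb-btrcp scan scenario.yaml         # fold-change / duration scan
nfkb-btrcp bifurcation scenario.yaml  # branch, Hopf points, limit cycles
nfkb-btrcp drug scenario.yaml         # drugged vs drug-free comparison
```

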