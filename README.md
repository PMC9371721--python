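# gradientforge

Inverse design of electrochemically generated O₂ and H₂O₂ microgradients on
microwire-array electrodes.

Microbial life is organized by chemical microenvironments — microoxic
niches of ~100 µM O₂ inside oxic surroundings, reactive-oxygen (H₂O₂)
plumes of a few tens of µM — on length scales of 10–100 µm.  A microwire
array coated with an oxygen-reduction catalyst can create such gradients on
demand: under a reductive potential, Pt-coated wires consume dissolved O₂
(4e⁻ ORR) and Au-coated wires additionally release H₂O₂ (2e⁻ ORR).  The
hard problem is inverse: given a desired concentration profile, which
electrode morphology produces it?

`gradientforge` implements the full computational stack for that question,
for experimentalists designing wire-array electrodes and for modelers of
electrochemical microenvironments:

1. **Simulator** — a steady-state reaction–diffusion solver for the
   periodic unit cell of the array.  The morphology is the vector
   **k** = (P, D, L): lattice periodicity, wire diameter, and wire length in
   µm.  Surface kinetics are concentration-dependent Tafel laws per channel,
   `i = −i₀ ([O₂]/C_bulk) exp(−α_c F η n/(RT))` with η = E_appl − 1.23 V,
   which makes both species' problems linear and each solve a few
   milliseconds.  Output is the laterally averaged profile c(z) at 20
   heights, z = 5…100 µm.
2. **Surrogate** — a multilayer perceptron (E_appl, P, D, L) → c(z),
   trained on simulated datasets with a 65/15/20 train/validation/test
   protocol and evaluated by per-profile mean-squared error (AMSE, mM²).
3. **Inverse design** — random search over the morphology block
   P ∈ [1, 100], D ∈ [0.2, 10], L ∈ [1, 150] µm, ranking candidates by the
   similarity score `S = 1 − mean_z |c_pred − c_target| / c_target` over
   seven anchor heights, retaining the top 10,000 and slicing them into
   (P, D) score maps per wire-length band; winners are verified by
   re-simulation, not by the surrogate.

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.

## Worked example

Simulate the microoxic design — a Pt-coated array with
**k** = (46, 6, 20) µm at 0.5 V vs RHE:

```sh
gradientforge simulate --catalyst pt --P 46 --D 6 --L 20 --eappl 0.5 \
    --resolution 0.5 -o profile.csv
```

```python
>>> import gradientforge as gf
>>> o2, _ = gf.simulate(gf.Morphology(46, 6, 20), "pt", 0.5,
...                     gf.SolverSettings(spacing_um=0.5))
>>> print(f"base [O2] = {1e3 * o2.c_mM[0]:.0f} uM")
base [O2] = 138 uM
>>> print(f"depletion = {1e3 * (0.246 - o2.c_mM.min()):.0f} uM")
depletion = 108 uM
```

The array carves a ≈108 µM oxygen depletion out of the 246 µM air-saturated
background, spanning the ≈40 µm from the wire bases to the edge of the
diffusion boundary layer — a microoxic niche in an otherwise oxic medium.

Closing the loop from a target instead of a morphology:

```python
>>> target = gf.TargetProfile.from_profile(o2, E_appl=0.5)   # 7 O2 anchors
>>> model = gf.SurrogateModel.load("model_o2/")               # trained MLP
>>> result = gf.search_morphologies(model, target, n_eval=100_000, seed=3)
>>> best, score = result.top(1)[0]
>>> profile, mse, sim_score = gf.verify_design(best, target, "pt")
```

`search_morphologies` scores ~10⁵ candidates in seconds; `verify_design`
re-runs the full solver on the winner and reports its simulated similarity
score — typically well above 0.9 for attainable targets, through many
distinct morphologies (the score landscape is strongly multimodal).

An end-to-end run (dataset → training → design → verification) is one
command from a YAML config:

```sh
gradientforge pipeline --config run.yaml
```

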