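# brainenergy

Kinetic simulation of brain energy metabolism in a coupled
neuron–astrocyte system, comparing two competing hypotheses about how
the neuron is fuelled:

- **Classical view** — both neurons and astrocytes take up blood
  glucose, run glycolysis, and oxidise pyruvate in their own
  mitochondria.
- **Astrocyte–neuron lactate shuttle (ANLSH)** — the astrocyte
  glycolyses glucose anaerobically to lactate and exports it; the
  neuron imports the lactate, converts it back to pyruvate (LDH1) and
  oxidises it in its mitochondria. The astrocyte mitochondrion is
  switched off entirely.

The package is written for computational/systems biologists who want to
reproduce, probe or extend this comparison: it builds both variants
declaratively from one 94-reaction catalogue, couples an
HIF-1α/prolyl-hydroxylase oxygen-sensing module to the seven
hypoxia-regulated transporters and enzymes (GLUT, MCT, HK, PFK, GAPDH,
PK, LDH), integrates the stiff ODE system under named oxygen/glucose
scenarios, and post-processes ATP plateaus and fold-changes.

## Model

Eight compartments with fixed relative volumes (litres): neuron nucleus
0.033, cytosol 0.33, mitochondrion 0.0855; astrocyte nucleus 0.019,
cytosol 0.19, mitochondrion 0.0475; extracellular space 0.2; capillary
blood 0.095. Species are concentrations in mM; every reaction carries
one of six kinetic-law forms:

| form | rate law |
|---|---|
| passive diffusion | J = γ (C_x − σ C_y) |
| facilitated transport | J = V C_x / (K_m + C_x) |
| Michaelis–Menten | v = V_max S / (K_m + S) |
| bimolecular saturating | J = J_max C_x C_y / (K + C_x C_y) |
| mass action | v = k ∏ C_i |
| uncompetitive inhibition | v = V_max S / (K_m + S (1 + I/K_i)) |

A reaction's rate is referenced to its source compartment; a species in
compartment C receives ±s·J·(V_src/V_C), so amounts are conserved
exactly across membranes. Oxygen sensing follows the standard HIF
scheme: PHase hydroxylates cytosolic HIF-1α at a rate ∝ PHase·O₂·HIF;
surviving HIF translocates to the nucleus and adds a saturating term
V·H/(K+H) to the basal transcription of each regulated gene. Enzyme
capacities scale linearly with the protein pool relative to its
normoxic steady-state level.

Scenarios (blood boundary conditions; O₂ always clamped):
`normoxia` (glucose 4.56 mM initial, O₂ 7 mM), `hypoxia` (glucose
4.56 mM, O₂ 0.35 mM), `starvation` (glucose clamped at 1 mM, O₂ 7 mM).

## Worked example

```python
import brainenergy as be
from brainenergy.analysis import compare_models, summarize_timecourse

params = be.default_parameters()
runs = {(v, "normoxia"): be.run_experiment(v, "normoxia", params=params, t_end=250.0)
        for v in ("classical", "anlsh")}
print(summarize_timecourse(runs[("classical", "normoxia")],
                           ["ATP@Nm", "ATP@Am", "ATP@Nc", "Lac@e"],
                           window=50.0, rel_tol=0.05).to_string())
report = compare_models(runs, window=50.0, rel_tol=0.05)
print(f"neuron mitochondrial ATP fold-change (ANLSH / classical): "
      f"{report.mean_fold_change['ATP@Nm']:.2f}")
```

prints

```
         plateau_mM  attained  attainment_time_min
species
ATP@Nm   148.332106      True                200.0
ATP@Am   164.505289     False                  NaN
ATP@Nc     4.766500      True                 15.0
Lac@e      1.767247     False                  NaN
neuron mitochondrial ATP fold-change (ANLSH / classical): 3.66
```

Under normoxia the classical neuron's mitochondrial ATP settles near
150 mM (glucose is the limiting reactant and is consumed within the
first 50 minutes; the model deliberately has no ATP sinks, so ATP
accumulates to a substrate-limited plateau). Running the
lactate-shuttle variant instead routes all carbon through the neuron's
mitochondria and its ATP plateau rises above 500 mM — a 3–4× advantage
for the neuron, which is the core comparison the package quantifies.
Series keys are `species@compartment` (`Nm` = neuron mitochondrion,
`Ac` = astrocyte cytosol, `e` = extracellular space, `b` = blood).

A command-line interface wraps the same calls:

```sh
brainenergy simulate --model anlsh --scenario hypoxia --t-end 500 --out tc.csv
brainenergy compare --out report.json
brainenergy export-sbml --model classical --out classical.xml
```

Models export to SBML Level 3 (`brainenergy.export_sbml`); re-importing
an exported document reproduces the ODE right-hand side exactly.

The `brainenergy.synthetic` module generates perturbed parameter sets,
noisy observation time courses and hypoxia-vs-normoxia expression
panels, and includes a least-squares estimator that recovers facilitated
transport parameters (V, K_m) from noisy uptake curves.

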