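# Methods

## Scope and model structure

The package implements two multi-compartment kinetic models of coupled
neuron–astrocyte energy metabolism as deterministic ODE systems. Eight
compartments with fixed relative volumes (L): Nn 0.033, Nc 0.33,
Nm 0.0855, An 0.019, Ac 0.19, Am 0.0475, e 0.2, b 0.095. The two
variants — the classical view and the astrocyte–neuron lactate shuttle
(ANLSH) — are selections from one shared catalogue of 94 numbered
reactions; membership is data-driven from the per-variant YAML files,
never hard-coded. The classical model carries reactions 1–92; the
ANLSH model carries 1–14, 16, 18–26, the even numbers 28–48, 50–56,
the even numbers 58–68, 70–71, the odd numbers 73–91, and 93–94.

The catalogue is laid out so that this membership is semantically
coherent:

- 1–14, 16, 18–26, 50–56: shared infrastructure — endothelial glucose
  exchange, O₂/CO₂ diffusion through the extracellular space,
  nucleus–cytosol pore diffusion for the eight non-cofactor cytosolic
  metabolites, astrocytic glucose uptake, and the HIF oxygen-sensor
  reactions.
- 15, 17: neuronal glucose uptake/efflux. Dropped in the ANLSH variant
  ("glucose is taken up by the astrocyte"); the
  `neuron_glucose_uptake` option re-enables them, because whether the
  shuttle permits any neuronal glucose uptake is genuinely open.
- odd 27–49: the neuronal glycolysis block (HK, PFK→GAP, GAPDH,
  BPG→pyruvate, LDH both directions, plasma-membrane monocarboxylate
  transport, creatine kinase). Dropped in the ANLSH variant. The even
  twins 28–48 are the astrocytic copies, which the shuttle keeps.
- odd 57–69 and even 72–92: the astrocyte aerobic block — its gas
  exchange, mitochondrial pyruvate transport, pyruvate dehydrogenase,
  the TCA steps, the malate–aspartate-style NADH shuttle and the lumped
  electron transport chain. All dropped in the ANLSH variant, so no
  reaction is located in Am. The interleaved neuron copies (even 58–68,
  70–71, odd 73–91) are kept.
- 93–94: ANLSH-specific neuron-side shuttle entry — high-affinity MCT2
  lactate uptake (K_m 0.75 mM) and neuron-specific LDH1
  (lactate + NAD⁺ → pyruvate + NADH).

### Pathway lumping

Glycolysis uses the five-species backbone Glc → G6P → 2·GAP → BPG →
pyruvate: hexokinase (uncompetitive product inhibition by G6P), a
lumped PFK/aldolase step consuming the second ATP and yielding two GAP,
GAPDH (NAD⁺ → NADH), and a lumped PGK+PK step producing two ATP per
GAP. Net yield: 2 ATP and 2 NADH per glucose.

The TCA cycle is lumped onto the intermediates AcCoA, α-KG, SucCoA,
Suc, Mal, OxAc: the citrate-synthase entry step condenses
AcCoA + OxAc (+NAD⁺) directly to α-KG + CO₂ + NADH (citrate and
isocitrate are not represented); succinyl-CoA synthetase's GTP is
booked as ATP; succinate dehydrogenase lumps fumarase (Suc + FAD →
Mal + FADH₂). The electron transport chain is two lumped reactions:
NADH + ½O₂ + 3 ADP → NAD⁺ + 3 ATP and FADH₂ + ½O₂ + 2 ADP → FAD +
2 ATP, with the P/O yields exposed as ordinary stoichiometries in the
network config. Cytosolic NADH reaches the mitochondrion through a
lumped redox shuttle (NADH_c + NAD_m ⇌ NAD_c + NADH_m). Reversible
steps (LDH, creatine kinase, SCS, SDH, MDH, transporters) are paired
forward/backward reactions so every rate stays within the six declared
law forms.

There are deliberately **no ATP sinks**: the model compares ATP
*production* capacity, so mitochondrial ATP accumulates to
substrate-limited plateaus far above physiological concentrations.
This is a feature of the study design, not an oversight.

### Kinetic-law conventions

Six forms only (passive diffusion, facilitated transport,
Michaelis–Menten, bimolecular saturating, mass action, uncompetitive
inhibition). The bimolecular form is read with the product-form
denominator J_max·C_x·C_y/(K + C_x·C_y), K in mM², exactly as the
lineage equations print it, although a separable K_x·K_y form is more
conventional; the form is a config choice per reaction, so the
alternative can be expressed by editing the catalogue. Zeroth-order
synthesis (HIF) is expressed as mass action on the constant PHase pool
rather than as an implicit constant. Rates are referenced to the
source/host compartment; the assembler scales cross-compartment
contributions by V_src/V_dst so amounts are conserved exactly — the
concentration-based flux laws alone would not fix this convention.

## Oxygen sensing and gene regulation

Per cell: HIF-1α is synthesised at a constant rate, destroyed by
mass-action hydroxylation ∝ PHase·O₂·HIF (PHase held constant at
0.1 mM — an enzyme, not consumed), translocates to the nucleus
(first-order, amount-conserving across the volume ratio), and decays
there. Each of the seven regulated genes (GLUT, MCT, HK, PFK, GAPDH,
PK, LDH) shares one rate-equation set: nuclear mRNA gains
basal + V·H/(K+H) transcription, is exported and degraded; cytosolic
mRNA is translated; protein decays first-order. All seven genes are
therefore kinetically identical — a stated simplification of the
underlying biology, which the RT-PCR-style synthetic panels emulate
only directionally.

Coupling to metabolism is linear: a regulated reaction's capacity is
base V_max × protein/protein_ref, clipped at zero, with protein_ref the
closed-form steady-state protein at the 7 mM reference O₂ — so
normoxic capacities equal the base values (no double counting). The
sensor constants were calibrated once, analytically, so that the
hypoxic (0.35 mM O₂) steady-state protein is 2–3× the normoxic level
and is approached within ~250 min (protein half-life 35 min); measured
ratio 2.52.

The HIF sensor reactions are part of the numbered catalogue (6,
50–56); the per-gene expression equations form a separate regulation
block shared by both variants. A regression test asserts that the
catalogue-assembled HIF derivatives equal the module's own rate
functions.

## Parameters and provenance

Every kinetic constant lives in `data/parameters.yaml`, keyed by
(reaction number, parameter name) with a unit and a provenance tag from
{supplementary, literature_default, estimated}. No value in the shipped
set is tagged `supplementary`: the published supplementary table was
not available, so the set follows the cited compartmental-metabolism
literature lineage (Aubert–Costalat-style magnitudes: glycolytic V_max
of order 0.1–1 mM min⁻¹, transporter K_m of order 1–8 mM, GLUT3 K_m
2.5 mM < GLUT1 K_m 6–8 mM, MCT2 K_m 0.75 mM) and was calibrated once
against the study's qualitative behaviour: blood and cell glucose
essentially consumed within 50 min of normoxia; classical mitochondrial
ATP plateaus of order 150 mM (neuron) and 140–190 mM (astrocyte);
ANLSH neuron mitochondrial ATP exceeding 500 mM with attainment around
200–370 min; hypoxia slowing ATP accumulation and raising extracellular
lactate. Mitochondrial adenine pools (ADP₀ = 800 mM) are deliberately
non-physiological: with no ATP sinks, the accumulated ATP must fit
inside a conserved pool, and the >500 mM ANLSH plateau dictates the
pool size. Exact plateau reproduction would require the original
supplementary values; with the shipped set, magnitudes are reproduced
at "around" level and all ordering relations hold.

Hypoxia is supply-limited: the blood↔extracellular O₂ conductance
(γ = 0.3 min⁻¹) delivers ample oxygen at 7 mM but caps delivery at
0.35 mM, so mitochondrial NADH accumulates, the TCA cycle backs up,
cytosolic NADH rises and LDH diverts pyruvate to lactate — which is how
the extracellular-lactate increase under hypoxia emerges rather than
being imposed.

### Known divergence: glucose starvation

With the amount-symmetric endothelial GLUT pair (required so that blood
glucose is non-increasing whenever it is not clamped), a 1 mM clamped
blood supply integrated over 250 min delivers more substrate than the
4.56 mM unclamped bolus, so the ANLSH starvation ATP at 250 min
(~650 mM) exceeds the normoxic plateau instead of falling short of it.
The alternative (an asymmetric carrier that washes extracellular
glucose into the perfusate) reproduces a lower starvation plateau but
makes blood glucose non-monotone in the other scenarios. The
monotonicity invariant was kept; the starvation plateau is reported
as-is.

## Simulation

`assemble_odes` validates the model (dangling species, per-reaction
carbon balance from per-species carbon counts, 1:1 conservation of the
NAD/NADH, FAD/FADH₂, ATP/ADP and Cr/PCr pairs within each reaction,
law/parameter completeness) and refuses invalid models. Integration
uses LSODA with rtol 1e-8, atol 1e-10, dense output every minute;
runs are bitwise reproducible at fixed tolerances. Blood O₂ is clamped
for the whole run; blood glucose is clamped only in the starvation
scenario; blood CO₂ is an absorbing pool. Negative concentrations are
never clipped — excursions beyond 1e-9 mM are reported as diagnostics,
because silent clipping would invalidate the conservation tests
(closed-run carbon drift is ~1e-15 relative; halving tolerances moves
plateaus by <0.1%).

Plateaus are detected with a trailing-window criterion: the plateau
value is the mean over the trailing window (default 30 min), attained
at the earliest time after which the trajectory stays within the
relative tolerance (default 1%; the scenario summaries use 5% because
slow lactate recycling leaves a creeping tail) of that value. A series
that never settles is reported not-attained, carrying its final value.

## Synthetic data and the recovery study

The generators stand in for the study's raw observations. Noise is
multiplicative lognormal by default (concentrations and band
intensities are positive); a factor exp(σZ) has median 1 and mean
exp(σ²/2), which the replicate-mean test exploits. Expression panels
normalise to a β-actin-like reference gene and use placeholder
induction ratios of 1.8–2.8× — the underlying experiment reports
direction of effect, not quantified fold-changes, so only direction is
testable. Parameter perturbation uses lognormal factors with a
specified coefficient of variation.

`recover_transport_parameters` fits the integrated facilitated-uptake
model dS/dt = −V·S/(K_m+S) to a noisy closed-pool series. The exact
solution is inverted through the Wright omega function
(S = K_m·ω(ln(S₀/K_m) + (S₀−Vt)/K_m)), which is numerically stable in
both the saturated and the linear regime; the fit minimises log-space
residuals (the correct objective under multiplicative noise) over
log-parameters. When the fitted K_m lies more than 10× above every
observed concentration, the data never left the linear regime, V and
K_m are individually unidentifiable, and the result is flagged with
the still-identifiable ratio V/K_m. At σ = 0.05 with 50 time points the
median relative error over 100 seeds is ≈5–6% for both parameters, and
the median error is monotone in σ over {0.2, 0.1, 0.05, 0}.

## SBML interchange

`export_sbml` writes SBML Level 3 (version 2 core): compartments with
sizes, species with initial concentrations (clamped species as
boundary conditions), reactions with MathML kinetic laws in
substance-extent units (concentration rate × source-compartment
volume, so a generic SBML simulator reproduces the package's volume
bookkeeping) and local parameters. A small annotation namespace
carries the declarative law descriptors and the regulation block; the
importer reads those plus the core elements, which makes the round
trip exact — identical derivatives at any state point, byte-identical
second export. The reader supports exactly the subset the writer
emits; structural validation (id uniqueness, reference resolution,
positive sizes) is built in.

## What the tests do and do not show

The suite checks the rate laws against independent arithmetic oracles,
the assembler against hand-written linear ODEs and matrix-exponential
solutions, conservation laws on full runs, the ordering relations
between variants and oxygen conditions, the regulation module against
its closed-form steady state, and the recovery study's error bounds.
Because every quantitative target depends on a literature-default
parameter set rather than the original supplementary values, agreement
with the published plateau numbers is approximate ("around" level);
the qualitative and ordering results are parameter-robust and are the
ones the acceptance suite asserts. The synthetic data share the
generative assumptions of the model (lognormal noise, identical gene
kinetics), so passing recovery tests demonstrate estimator
correctness, not robustness to real-world model misspecification.

## Problem sizes

Default runs integrate 131 state variables (112 for the ANLSH variant)
over 250 min, extended to 500 min for the lactate-shuttle oxygenation
scenarios; the recovery study uses 50-point series over 100 seeds.
These sizes match the study design while keeping a full suite run in
well under a minute of compute per scenario grid.
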