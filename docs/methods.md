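# Methods

## Model structure and assumptions

The pathway is modelled as an open system of twelve reactions over eight
metabolites.  Phosphatidylcholine (PC) is a clamped boundary species: its
concentration is fixed per strain × treatment condition (the measured
PC C33:2 level) and it is consumed without being depleted.  The five
degradation steps (of 5-HPETE, LTA4, 15-HETE, PGD2 and AA itself) discard
mass; no downstream eicosanoids beyond the modelled set are tracked.
Enzymes are not state variables: each catalysed reaction carries one or
more dimensionless activity ratios u (DDC-vs-control fold changes of the
enzyme's transcript or phosphoprotein) that multiply its V_max term, with
u ≡ 1 in control.  The eight-week treatment is interpreted as a quasi
steady state, so only converged concentration vectors are biologically
interpreted — transients are solver detail.

Rate-law forms:

* `activated_inhibited_mm`:
  `v = V_max · (∏ u_j) · [S] / ((K_m + [S]) · (K_i + [I]))` —
  Michaelis–Menten with exactly linear activator scaling and
  non-competitive product/feedback inhibition.  The flux vanishes at zero
  substrate, scales by c when one activator ratio is scaled by c, and is
  strictly decreasing in the inhibitor.
* `first_order_decay`: `v = k_cat · [S]`.
* `activated_linear` (PGH2 → PGD2): `v = V_max · u · [S]` with V_max
  acting as an effective first-order constant (1/s).  No Michaelis
  constant is published for this step; a saturating variant would require
  inventing one and reproduced the reported behaviour no better, so the
  minimal form was kept.

All internal concentrations are nM.  PC is tabulated in µM and converted
(×1000) on ingestion.

## Resolving the under-determined pieces

The published kinetic-law equations are not machine-readable in the
source material; the forms above are the canonical transcription
consistent with the printed parameter sets.  Three genuinely open points
had to be fixed, and were fixed once, using the printed *results* as the
arbiter:

1. **Catalyst of 15-HPETE → 15-HETE.**  The parameter table names ALOX15,
   but the pathway diagram and the knockdown discussion attribute the
   step to glutathione peroxidase (GPX) — and only with GPX can the
   tabulated GPX activity ratios and the GPX-knockdown prediction have
   any effect.  Default: GPX, with `build_paper_model(r7_catalyst="ALOX15")`
   as the alternative reading.

2. **Double scaling of AA release.**  The initial-values table prints the
   p-ERK RPPA fold change in its PLA2 row, while the R1 rate law lists
   PLA2 and p-ERK as two activators.  Both activators are populated (the
   PLA2 row value and the p-ERK ratio, numerically equal), so R1
   effectively scales with the square of the p-ERK fold change.  The
   single-scaling alternative drives the PWD arachidonic-acid fold change
   below 1, contradicting the reported ≥1.5-fold up-regulation.

3. **PC saturation regime of R1.**  With the printed K_m of 2500 nM and
   PC at 206–269 µM, R1 would be PC-saturated and the predicted ordering
   of AA fold changes across strains would follow the enzyme ratios
   (B6 > PWD > AJ) — the opposite of the reported ordering
   (PWD > B6 > AJ), which instead tracks the per-strain PC ratios.  The
   reported behaviour therefore requires the PC term to transmit, i.e.
   K_m on the µM scale.  Literature Michaelis constants for PLA2 acting
   on phosphatidylcholine substrates sit in the hundreds-of-µM-to-mM
   range, so the constant is interpreted as 2500 µM (stored with an
   explicit unit column; all other constants are used exactly as
   printed).

With these choices the simulation reproduces the reported inequality
results — the ≥1.5-fold up-regulation panels in all three strains, the
≈2-fold PGD2 increase in AJ — but not the two printed point values for
AA (1.35 in B6, 1.2 in AJ): the transcription yields larger AA responses
(≈6.2 and ≈2.3).  Those point values evidently came from a
parameterization or rate-law rendering that is not recoverable from the
printed material (the constants table itself states it was fitted on a
different strain than the text's optimization narrative).  The
discrepancy is reported as-is by the acceptance assertions rather than
absorbed by re-tuning, and the same root cause propagates to two screen
details: the five-enzyme reversion set cannot fully restore 15-HPETE
while GPX stays elevated (at steady state 15-HPETE scales inversely with
the GPX ratio, since the GPX-catalysed step is its only sink), and a
PTGS1 knockdown is compensated by the AA rise it causes, leaving
PGH2/PGD2 inside the unchanged band.

## Numerics

Steady states: LSODA integration from the origin (non-fixed species start
at 0 nM — no invented initial concentrations; a verified property shows
the attractor is independent of the start state to <0.1%) over growing
horizons (1e5 → 3e7 s), each leg followed by a Newton polish
(`scipy.optimize.root`, hybr) of the right-hand side.  A state is
accepted when max |d[x]/dt| ≤ 1e-6 nM/s; negative components are rejected
and non-convergence is reported, never silently returned.  Inside the
calibration loop a fast budget is used (warm-started Newton from the
baseline steady state, one short integration fallback), which was checked
against the strict solver along parameter sweeps.  The adaptive solution
is additionally validated against a fixed-step explicit-Euler oracle
(dt = 1e-3 s over 100 s, agreement within 1%).

Fold-change classification uses the symmetric band: up if ratio ≥ 1.5,
down if ≤ 1/1.5, reflecting the 1.5-fold convention of the underlying
study; the threshold is an argument everywhere it is consumed.

## Calibration

Objective: `f(p) = Σ_{x∈M} (ec_x − sc_x(p))² + (ed_x − sd_x(p))²` over
M = {AA, 5-HPETE, 15-HPETE, 15-HETE, PGD2}, control and DDC of one
training strain (default B6, selectable — the source material names both
B6 and AJ as the training strain in different places).  Non-convergent
candidates receive a large finite penalty so the population search
continues.  The R1 Michaelis constant is literature-sourced and excluded
from fitting by default.

The genetic algorithm works on log10-transformed parameters within
declared bounds (default two decades either side of the published value):
tournament selection (k = 2), uniform crossover (rate 0.7), per-gene
Gaussian mutation in log space (rate 0.1) whose step size anneals
geometrically from 0.5 to 1e-3 over the run, elitism of one, and a 10%
random-immigrant replacement per generation to avoid premature collapse
into secondary basins.  Defaults are population 50 × 500 generations,
mirroring the published optimization settings; everything is
deterministic given the seed.

Because the objective is an unweighted sum of squares over concentrations
spanning four orders of magnitude (≈0.003–13 nM at the published
constants), residuals of the low-abundance species are numerically
invisible until the large-species residuals are almost exactly zero.
Many-parameter blind recovery therefore wanders near-degenerate
compensation valleys, and no optimizer run at a desk budget resolves it.
The shipped recovery experiment uses an identifiable design: one free
V_max per branch (R2, R6, R9), bounds one decade either side, population
30 × 300 generations (~2 minutes), asserting recovery of the measured
metabolites' steady states within 10% in both conditions — on
concentrations, not parameters, since ten observations cannot pin every
constant.

## Synthetic data

A scenario fixes the ground truth: the published constants jittered
log-normally (`exp(N(0, scale))`; scale 0 keeps them exact), the six
published conditions, and the noise model.  Measurement tables draw
log-normal replicates (default 3, matching the experimental design)
median-centred on the model-implied steady states with coefficient of
variation 0.2 by default (a typical MS profiling spread), and report
per-group median and median absolute deviation — matching the convention
of the real profiling tables.  Omics tables are constructed so the
mapping reproduces the scenario's conditions exactly (unit control RPKM,
fold change in the DDC column) and include decoy Gpx isoenzymes with
non-winning p-values to exercise the selection rule.

What the generator deliberately does *not* emulate: count-level sequencing
noise, between-replicate transcript variance, missing values, batch
effects, or any misspecification between the generating model and the
fitted model.  Green calibration tests therefore demonstrate that the
pipeline recovers truth under its own assumptions — not that the model is
identified by real liver data.

## Omics mapping

Gene-level ratios: PTGS1←Ptgs1, ALOX5AP←Alox5ap, PKCD←Prkcd.  GPX uses
the isoenzyme-selection rule: smallest adjusted p-value wins, ties broken
by higher mean expression, then lexicographically (logged).  p-ERK and
p-STAT3 come from RPPA ratios; the PLA2 activity also carries the p-ERK
ratio (the transcript is below 1 RPKM and non-differential, so the
phosphoprotein stands in for the pair — this is exactly what the
published initial-values table prints).  Low-expressed, non-differential
genes (Alox5, Alox15, Ptgds, floor 1 RPKM) map to 1.0.  In the
perturbation screens the "p-ERK" handle therefore reverts or inhibits the
PERK and PLA2 ratios together — they are one measurement — without which
the six-enzyme reversion could not reach the all-normal reference state.

## Known limitations

* The two printed AA point values (1.35, 1.2) are not reproduced; see
  the resolution notes above.
* Only steady states are interpreted; no transient or bifurcation
  analysis, no stochastic kinetics, no thermodynamic constraints.
* The drug screen manipulates activity ratios directly; it models no
  pharmacokinetics or binding of actual compounds.
* SBML exchange covers this model family (the three rate-law forms with
  global `u_*`/`<rid>_<param>` parameters), not arbitrary SBML documents.
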