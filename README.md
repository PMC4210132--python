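# eicokin

Kinetic modelling of arachidonic-acid (AA)/eicosanoid metabolism in the
DDC-fed mouse liver, a model of non-alcoholic steatohepatitis (NASH).

Feeding mice a 3,5-diethoxycarbonyl-1,4-dihydrocollidine (DDC) diet
perturbs the eicosanoid branch of lipid metabolism: mass-spectrometry
profiling shows PGD2, 5-HPETE, 15-HPETE and 15-HETE shifted in treated
livers of the A/J, C57BL/6J and PWD/PhJ strains (AJ, B6, PWD).  `eicokin`
implements the corresponding mechanistic question: can transcriptomics and
phosphoprotein fold changes, used as multiplicative scalings of enzyme
V_max values, quantitatively explain the measured metabolite shifts?

The package is a library first (importable API plus the narrative scripts
under `examples/`), with a thin `eicokin` command-line tool over the same
functions.

## The model

Twelve reactions over eight species in three branches rooted at AA, which
is released from a clamped phosphatidylcholine (PC) pool:

```
            PC --R1--> AA --R12-> (sink)
   5-LOX:   AA --R2--> 5-HPETE --R4--> LTA4        (R3, R5: sinks)
   15-LOX:  AA --R6--> 15-HPETE --R7--> 15-HETE    (R8: sink)
   COX:     AA --R9--> PGH2 --R10--> PGD2          (R11: sink)
```

Catalysed steps follow Michaelis–Menten kinetics with linear activator
scaling and non-competitive product inhibition,

    v = V_max · (∏_j u_j) · [S] / ((K_m + [S]) · (K_i + [I])),

sinks are first order (v = k_cat·[S]), and the PGH2→PGD2 step is first
order with activator scaling.  The dimensionless u_j are DDC/control
fold changes of the catalysing or regulating species — PLA2/p-ERK on R1,
ALOX5/ALOX5AP on R2/R4, ALOX15·PKCD·p-STAT3 on R6, GPX on R7, PTGS1 on
R9, PTGDS on R10 — with u ≡ 1 in every control condition.  Feedback
inhibitors: AA on its own release (R1), product inhibition on R2/R4/R6/R9,
and 15-HETE on R7.

On top of the ODE core the package provides:

* **steady states & fold changes** — stiff integration (LSODA) with a
  Newton polish, DDC/control ratios with a symmetric 1.5-fold
  up/down/unchanged call (`eicokin.simulate`);
* **calibration** — the least-squares objective over the five measured
  metabolites {AA, 5-HPETE, 15-HPETE, 15-HETE, PGD2} in both conditions,
  minimized by a seeded elitist genetic algorithm on log-scaled
  parameters (`eicokin.calibrate`);
* **perturbation screens** — enzyme-reversion analysis (which subsets of
  the six DDC-perturbed activities normalize the state) and 3/6/9-fold
  in-silico knockdowns (`eicokin.perturb`);
* **omics mapping** — expression/RPPA tables to activity ratios,
  including the most-significant-isoenzyme rule (`eicokin.mapping`);
* **synthetic data** — seeded ground-truth scenarios, log-normal noisy
  measurement tables and omics tables for closed-loop testing
  (`eicokin.synth`);
* **I/O** — schema-validated TSV/CSV tables and SBML Level 3 export/import
  (`eicokin.io`).

## Worked example

```
$ python examples/01_steady_states_and_fold_changes.py

AJ  (steady-state residual 6.7e-18 nM/s)
  AA          2.26x  up
  5-HPETE     3.42x  up
  LTA4        5.07x  up
  15-HPETE    8.74x  up
  15-HETE     7.50x  up
  PGH2        2.19x  up
  PGD2        2.19x  up
...
```

Each line is the ratio of the DDC to the control steady-state
concentration of one metabolite in that strain; "up" marks ratios above
the 1.5-fold band.  The AJ panel reproduces the published qualitative
picture — all three branches of the pathway accumulate product under DDC,
with PGD2 roughly doubling — while the absolute AA ratios run higher than
the printed point values (see `docs/methods.md` for the rate-law
ambiguities behind this).

The same computation from the shell:

```
eicokin simulate --strain AJ --condition ddc --out results/
```

Other examples: GA calibration on synthetic data (`02`), the 63-subset
enzyme-reversion screen (`03`), the drug screen (`04`), SBML and omics
I/O (`05`).

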