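# betakin

Kinetic and analytical toolkit for the enzymatic–chemical formation of
betalain pigments from l-DOPA by a bacterial DOPA-extradiol-dioxygenase:

- **`betakin.kinetics`** — Michaelis–Menten and excess-substrate-inhibition
  saturation models, nonlinear least-squares fitting (with standard errors),
  and derived constants (kcat, kcat/Km).
- **`betakin.condensation`** — pseudo-first-order scheme for the spontaneous
  condensation of betalamic acid with l-DOPA into dopaxanthin; slope-based
  and time-course estimators of the second-order rate constant.
- **`betakin.cascade`** — six-species ODE model of the whole cascade
  (l-DOPA → 4,5-/2,3-seco-DOPA → betalamic acid / muscaflavin → dopaxanthin)
  with DOPA-equivalent conservation, lag/peak summaries and whole-model
  fitting by repeated simulation.
- **`betakin.masses`** — monoisotopic exact-mass arithmetic: formula parsing,
  [M+H]+ ions, ppm errors, in-silico trypsin digestion and peptide-mass-
  fingerprint matching.
- **`betakin.purification`** — purification-table arithmetic (total protein,
  total activity, fold, yield) and Beer–Lambert quantification.
- **`betakin.synthetic`** — seeded generators for every input the fitting
  stages consume (saturation curves, condensation endpoints/courses, cascade
  time courses) with multiplicative Gaussian noise.

## CLI

All stages are exposed through one `betakin` command. Examples:

```sh
# exact masses
betakin mass formula C18H18N2O8          # -> [M+H]+ = 391.1136
betakin mass peptide DGIWLGQPR           # -> 1041.55

# synthetic data -> fit round trip
betakin generate saturation --seed 1 --out sat.csv
betakin fit-mm sat.csv --enzyme-conc-uM 10.52

# condensation constant from fixed-time endpoints
betakin generate condensation --seed 1 --noise-cv 0 --t-h 1.5 --out cond.csv
betakin fit-condensation endpoints cond.csv --t-h 1.5 --dopa-mM 3.5

# cascade simulation and curve summaries
betakin simulate --t-end 40 --n 400 --out course.csv
betakin lag course.csv

# tryptic digest against observed masses; purification table arithmetic
betakin digest protein.fasta --missed 1 --observed observed.csv
betakin purification table.csv
```

CSV inputs are comma-separated with a header row; `#` lines carry provenance
(version, seed, input hashes) and are ignored on read.

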