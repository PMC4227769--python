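# flipkin

Transient-kinetic modelling of enzyme-catalyzed nucleotide flipping.

DNA-repair glycosylases such as human alkyladenine DNA glycosylase (AAG)
locate rare damaged bases — here the fluorescent lesion
1,N⁶-ethenoadenine (εA) — by binding duplex DNA nonspecifically, searching,
engaging the lesion in an *initial recognition complex* (IRC), and rotating
the damaged nucleotide 180° into the active site to form the flipped-out
*specific recognition complex* (SRC) from which the N-glycosidic bond is
cleaved.  `flipkin` implements the full desk-scale analysis used to dissect
this mechanism with stopped-flow fluorescence and gel-based pulse-chase
experiments:

* a mass-action kinetic scheme

  ```
  E + D ⇌ ENS → IRC ⇌ SRC → P + E
       k_on/k_off   m·k_search/k_escape   k_flip/k_unflip   k_chem
  ```

  with deterministic (stiff ODE) and stochastic (per-molecule CTMC)
  simulators, an additive multi-protein searching model, and a pulse-chase
  quench mode;
* a synthetic-data module that emulates every experiment class — biphasic
  εA-fluorescence association traces in two sequence contexts (TEC:
  rise-then-quench; AEA: monotonic quench), double-mixing chase recoveries,
  tight-binding titrations, single-turnover excision gels, pulse-chase
  partitioning and competition-inhibition series — with instrument dead
  time and Gaussian noise;
* phase fitting: multistart variable-projection multi-exponential fits
  (`y(t) = y∞ + Σ Aᵢ e^(−kᵢt)`), bimolecular-slope regression
  (`k_1,obs = k_on·[E] + b`), concentration-(in)dependence classification,
  quadratic tight-binding and IC₅₀ fits;
* global fitting of the mechanism ODE across trace ensembles with
  identifiability flagging;
* the analysis layer that turns observables into microscopic constants:
  `k_flip = k_2,obs − k_unflip`, `K_flip = k_flip/k_unflip`, commitment to
  catalysis `C = k_chem/(k_chem + k_unflip)` and its inversion, fold-change
  and nucleotide-excess arithmetic, and a per-variant parameter table with
  provenance (measured / derived / limit).

The package targets transient-kinetics practitioners who want a tested,
reproducible reference implementation of this analysis — and a generator of
realistic synthetic data for validating fitting pipelines.

## Worked example

```python
import numpy as np
from flipkin import (table1_rates, MechanismSpec, MixingExperiment,
                     FluorescenceModel, synthesize_association_trace,
                     fit_exponential_phases, commitment_to_catalysis,
                     fold_change, round_sig)

wt = table1_rates("WT")                       # published rate constants
trace = synthesize_association_trace(         # 300 nM enzyme + 50 nM DNA
    MechanismSpec(wt), FluorescenceModel.tec_default(),
    MixingExperiment("single-mix", E_tot=300e-9, D_tot=50e-9, noise_sd=0.0))
fit = fit_exponential_phases(trace.times, trace.signal, n_phases=2)
print(f"k_1,obs = {fit.rates[0]:.0f} s^-1   k_2,obs = {fit.rates[1]:.2f} s^-1")
print(f"K_flip  = {round_sig(wt.K_flip, 2):.0f}")
print(f"commitment = {100*commitment_to_catalysis(wt.k_chem, wt.k_unflip):.0f}%")
ya = table1_rates("Y162A")
print(f"unflipping fold change (Y162A/WT) = {fold_change(ya.k_unflip, wt.k_unflip, 1)[0]:.0f}")
```

prints

```
k_1,obs = 251 s^-1   k_2,obs = 3.62 s^-1
K_flip  = 2300
commitment = 33%
unflipping fold change (Y162A/WT) = 6000
```

`k_2,obs` is the flipping relaxation (k_flip + k_unflip ≈ 3.6 s⁻¹ for the
wild type); the fast phase is the bimolecular binding/searching phase.
`K_flip = 2300` quantifies the strongly favourable flipping equilibrium,
and a 33% commitment means two thirds of chased complexes release the
lesion before cleaving it.  The Y162A mutant, which lacks the intercalating
tyrosine "plug", unflips 6000-fold faster.

A command-line pipeline wraps the same stages:

```bash
flipkin simulate --config study.yaml      # traces + manifest
flipkin fit --manifest out/manifest.json --mode phases --out fits.json
flipkin report fits.json --outdir report  # parameter table (CSV/JSON/md)
```

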