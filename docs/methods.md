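# Methods

## The kinetic scheme

`flipkin` models multistep lesion recognition by a flipping DNA glycosylase
as a mass-action network over seven species: free enzyme E, free
lesion-containing duplex D, the nonspecific complex ENS, the initial
recognition complex IRC (enzyme engaged at the lesion, base still
intrahelical), the specific recognition complex SRC (base flipped into the
active site), abasic product P, and chase-sequestered enzyme EQ:

```
E + D ⇌ ENS        k_on (M⁻¹s⁻¹), k_off_ns (s⁻¹)
ENS  → IRC          m · k_search (s⁻¹)
IRC  → ENS          k_escape (s⁻¹)
IRC  ⇌ SRC          k_flip, k_unflip (s⁻¹)
SRC  → P + E        k_chem (s⁻¹)
```

Only `k_on`, `k_find = k_search + k_escape`, `k_flip`, `k_unflip` and
`k_chem` are experimentally observable; the split of `k_find` into finding
and leaving, and the nonspecific dissociation rate, are internal
decompositions.  Product rebinding is deliberately absent (single-turnover
conditions).

**Occupancy model.** Under excess protein several enzymes bind one duplex
and search in parallel; the additive model multiplies the ENS → IRC flux by
`m = clip(E_tot/D_tot, 1, 10)` (at most 10 searching proteins per 25mer).
The floor at 1 reflects that every nonspecific complex carries at least the
protein that defines it; with excess DNA the model reduces to
single-protein searching.  This is what makes the two concentration regimes
qualitatively different: with excess protein, searching (`m·k_search`)
outruns bimolecular binding, so the observed first phase is linear in [E]
with slope `k_on` (and a slightly negative intercept from eigenvalue
mixing); with excess DNA a single protein searches, and the first phase is
concentration independent at `k_find`.

**Parameter defaults.** The committed-binding regime requires
`k_off_ns ≪ m·k_search`; the default is `k_off_ns = 1 s⁻¹` (nonspecific
binding at these concentrations is effectively committed to searching).  A
rapid nonspecific pre-equilibrium (`k_off_ns ≫ k_search`) is incompatible
with both observed regimes: it would make the excess-protein first phase
hyperbolic rather than linear and the excess-DNA first phase concentration
dependent.  The `k_find` split is 99:1 in favour of `k_search`: the initial
recognition complex is strongly committed forward.  A larger escape share
would lower the slow relaxation below `k_flip + k_unflip` (the slow
eigenvalue is `k_unflip + k_flip·c/(c+k_escape)` with `c = m·k_search`),
breaking the identities `k_obs = k_flip + k_unflip` and
`k_flip = k_2,obs − k_unflip` at the ~1% level the phase analysis relies
on.  With the 99:1 split both regimes agree with those identities to
better than 1.5%.

**Chase model.** The pulse-chase quench (excess tight-binding inhibitor
DNA) is modelled as instantaneous capture of every enzyme not holding the
flipped lesion: free E, ENS and IRC transfer to the absorbing sink EQ and
their DNA is released.  This is the standard commitment-analysis
assumption — escape from the lesion site and dissociation from nonspecific
DNA are fast in the presence of excess competitor — and it makes the chased
system exactly two-state: SRC partitions between cleavage
(`C = k_chem/(k_chem+k_unflip)`) and unflipping-plus-release, and the
fluorescence recovery rate equals `k_unflip + k_chem`.  Modelling capture
with a finite escape rate instead would allow re-flipping from IRC and
inflate the wild-type commitment from 33% to ~36%, inconsistent with the
partition analysis the pipeline implements.

**Variants.** `table1_rates(variant, context)` provides the published
constants for the wild type and the two intercalating-residue mutants
(Y162F, Y162A), including the context-dependent Y162A flipping rate
(170 s⁻¹ TEC, 66 s⁻¹ AEA).  Y162A binding and searching are too fast to
measure; the presets use k_on = 1e10 M⁻¹s⁻¹ and k_find = 5000 s⁻¹, fast
enough that both phases complete within the instrument dead time, and the
reporting layer stores these only as one-sided limits.

## Numerical integration

Deterministic time courses use a stiff-capable integrator (LSODA, BDF
fallback) at rtol 1e-10 and atol 1e-15 M (scaled with total
concentration).  Rates within one experiment span seven orders of
magnitude (10 s⁻¹ unflipping next to 1.6e-3 s⁻¹), so loose tolerances
visibly violate conservation; at these settings enzyme and DNA totals
drift by less than 1e-12 relative on all tested trajectories (the test
suite enforces 1e-8).  Concentrations more negative than −1e-12·scale
abort integration; smaller negative excursions are clipped to zero for
reporting.

The stochastic simulator draws per-molecule continuous-time Markov jump
chains over {D, ENS, IRC, SRC, P} with pseudo-first-order binding at a
fixed free-enzyme concentration.  It exists as an independent
cross-check of the partition analysis, and agrees with the closed-form
commitment within binomial error.

## Synthetic observables

Fluorescence is a per-species linear signal normalized to free DNA.
Defaults (config-overridable, constrained qualitatively by the observed
trace shapes): TEC {free 1.0, ENS 1.0, IRC 1.6, SRC 0.55} — rise then
quench; AEA {free 1.0, ENS 1.0, IRC 0.9, SRC 0.2 (WT) / 0.4 (mutants)} —
monotonic quench reproducing the 5-fold (WT) and 2–3-fold (mutant)
equilibrium quench.  Product carries coefficient 1.0.  Optional
multiplicative photobleaching `exp(−k_bleach t)` (default off,
0.01 s⁻¹ when enabled) emulates the irreproducible slow third phase.

Dead time defaults to 1.5 ms and simply removes earlier points (no
regridding); Gaussian noise defaults to 0.5% of the free-DNA signal; all
generators are bit-reproducible for a fixed seed.  Acquisition uses a
log-spaced grid (600 points to 3 s by default), matching how stopped-flow
software samples multi-decade kinetics.  Gel-quantified fractions are
quantized to 3 decimals only at the CSV boundary so that in-memory
round-trip tests remain exact.

What the generator does *not* emulate: photophysics (quantum yields, shot
noise), NaOH-cleavage chemistry of the discontinuous assay, sequence-level
energetics, or facilitated-diffusion physics beyond the additive occupancy
model.  Passing round-trip tests therefore demonstrates correctness of the
fitting machinery under the stated noise model, not robustness to every
instrument artifact.

## Fitting

**Multi-exponential fits** use variable projection (offset and amplitudes
solved linearly for any trial rate vector) with rates optimized in log
space, multistarted from 8 log-spaced rate grids per phase count; the best
residual wins.  Rates are reported sorted descending.  Rates within 5% are
merged and flagged rather than reported as separate phases; fits with
amplitude indistinguishable from zero are flagged rate-unidentifiable.
Standard errors come from the full (offset, amplitudes, rates) Jacobian.
The multistart makes fits invariant (to 1e-6) under s ↔ ms rescaling.

**Phase identity.** Phases are labelled by amplitude sign and magnitude:
the principal rise (largest |A| among negative amplitudes) is the
binding/searching phase, the largest positive-amplitude phase slower than
it is the flipping quench.  This matches how the instrument's unresolvable
fast components (small amplitude, partly inside the dead time) are treated
in practice and keeps the phase assignment stable across both
concentration regimes.

**Concentration series.** Bimolecular slopes use (optionally
inverse-variance weighted) linear regression with a free intercept —
negative intercepts are permitted, as observed for extremely fast tight
binding.  Concentration (in)dependence is a slope t-test at α = 0.05; when
independent, the summary rate is the inverse-variance weighted mean.  The
excess-DNA study design uses ≥ 4-fold DNA excess (400–1000 nM DNA vs
100 nM enzyme) so the invisible binding step is faster than searching, and
follows the published protocol of three noisy replicates per concentration
(mean ± SD feeding the t-test).

**Titration and inhibition.** The tight-binding quench model is
`F/F0 = 1 − (1 − 1/q)·f_B` with `f_B` from the standard two-component
quadratic; Kd below D_tot/10 is reported as an upper limit (a titration at
0.4 µM DNA cannot resolve a 5 nM Kd, only bound the stoichiometry).
Competition fits `r = r0/(1 + [N]/IC50)`; a best-fit IC50 above 10× the
highest tested concentration is reported as no inhibition (∞).

**Global fits** integrate the ODE for every candidate parameter vector
across all traces, with per-trace residuals normalized by signal spread,
log-parameterized rates and bounded trust-region least squares.  The
deterministic multistart begins at the supplied starting rates (typically
phase-wise estimates) with seeded log-normal jitters.  Identifiability is
reported two ways: asymptotic relative standard errors (with residual
variance floored at the declared measurement noise) and the RMS of each
parameter's log-space Jacobian column — a parameter whose column RMS is
below 1% of the normalized signal is flagged unidentifiable (this is what
flags `k_unflip` when no chase trace is present, and everything when the
ensemble is flat).

## Analysis conventions

Seconds and molar units internally everywhere; per-minute rates only at
the report boundary (single-turnover `k_chem` is converted min⁻¹ → s⁻¹ by
÷60).  Reported table cells round to two significant figures, half away
from zero; fold changes round at the number of figures used in the printed
comparison (6000- and 50-fold at one figure, 140-fold at two), computed
from the rounded reported constants as the printed comparisons were.
When both a directly fitted unflipping rate and a pulse-chase-implied one
(`k_unflip = k_chem(1−C)/C`) are available, the table reports both and
notes spreads above 15% — for the wild type the direct 1.6e-3 s⁻¹ and the
commitment-implied 1.87e-3 s⁻¹ differ by ~17%, which is surfaced rather
than averaged away.  Zero commitment (the Y162A gel result) yields only a
lower limit on unflipping and is reported as such.

## Problem sizes and tolerances in the test suite

Acceptance-style checks run at desk scale: 10⁵ molecules for
stochastic/analytic partition agreement (3 binomial SE), 600-point traces
for phase fits, four-trace ensembles over 20 seeds for global parameter
recovery (every identifiable constant within 15% in ≥ 90% of seeds at
0.5% noise).  Noiseless round trips are asserted at 1e-6 relative;
recovered second-phase and unflipping rates at 2%; the excess-protein
slope at 10% of 1.1e9 M⁻¹s⁻¹ (the committed-binding regime carries a few
percent of intrinsic eigenvalue-mixing bias) and the excess-DNA summary
rate at 5% of 116 s⁻¹.

## Known limitations

* The k_search/k_escape split and k_off_ns are not separately observable;
  conclusions should be drawn only from the observable combinations.
* The instantaneous-capture chase is an idealization; systems where the
  inhibitor competes slowly with re-flipping need a finite capture rate.
* Global-fit uncertainties are asymptotic (no posterior sampling), and
  model selection across alternative topologies is out of scope.
* The additive occupancy model is a mean-field count of searching
  proteins, not a spatial model of facilitated diffusion.
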