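# Methods

## Competition model

The model tracks well-mixed densities of plasmid-free cells (`N0`), carriers
of the wildtype plasmid (`NW`), of the mutant plasmid (`NM`) and co-infected
cells (`NWM`).  Assumptions: logistic host replication shared through the
total density `T`; a multiplicative plasmid cost `c` on replication; constant
per-capita death `γ`; density-dependent (mass-action) conjugation; no
spontaneous loss from singly infected cells (conjugative plasmids of this
class are highly stable); co-infected cells revert to single carriage only
through segregational loss at replication (probabilities `sW`, `sM`); and
entry exclusion scaling conjugation into plasmid-carrying recipients by
`1 − k`.  Co-infected cells donate either variant with probability 1/2,
giving the force of infection `λi = βi (Ni + NWM/2)`.

### The co-infection displacement term

Two variants of the within-co-infected conjugation step are implemented:

* `displacement_flux=True` (default): a plasmid conjugating into an already
  co-infected cell displaces the resident variant with probability 1/2,
  returning the cell to single carriage of the incoming variant.  This adds
  `+(1−k) NWM λi / 2` to `dNi/dt` and the matching loss to `dNWM/dt`.
* `displacement_flux=False`: the bare four equations with no such flux.

The default matters qualitatively, not just quantitatively.  Without the
displacement term, a mutant with a purely horizontal advantage (`a_H > 1`,
`a_V = 1`) drives the system to a *stable coexistence* — e.g. at
`a_H = 1.2` the wildtype-carrying density settles at ≈ 0.35 and never falls
below the replacement threshold — because the co-infected compartment
recycles both variants symmetrically.  With the displacement term, any
`a_H > 1` or `a_V > 1` leads to replacement in finite time, which is the
regime of interest here: a streamlined variant with any transmission
advantage eventually displaces its full-length competitor.  The term is also
required for structural neutrality to be meaningful at the conjugation level
(both variants face the same displacement risk).

### Parameters and defaults

| parameter | meaning | default | units |
|---|---|---|---|
| `rho` | maximal replication rate | 1 | 1/time |
| `c` | plasmid replication cost | 0.1 | — |
| `gamma` | death rate | 0.1 | 1/time |
| `K` | carrying capacity | 1 | cells/volume |
| `beta_W`, `beta_M` | conjugation rate constants | 1, 1 | volume/cell/time |
| `s_W`, `s_M` | segregational-loss probabilities | 0.1, 0.1 | — |
| `k` | entry-exclusion strength | 0.99 | — |
| `epsilon` | influx of plasmid-free cells | 0 | cells/volume/time |

Time and density units are arbitrary; no unit-conversion layer is provided.
Advantages re-parametrise the mutant: `beta_M = a_H · beta_W`,
`s_W = a_V · s_M`.  Sweep cells where `s_W + s_M > 1` are marked invalid
rather than silently clipped.

Simulations start from the wildtype's single-plasmid equilibrium
`N* = K (1 − γ/((1−c)ρ))` (= 8/9 ≈ 0.89 cells per unit volume at the
defaults) plus a small co-infected inoculum `NWM = 0.01`.

### Replacement criterion

"Replacement" is the first down-crossing of either the absolute
wildtype-carrying density (`NW + NWM`, threshold 0.01 cells per unit volume;
the default) or its relative frequency (threshold 1%; the default for
baseline-parameter sweeps).  Which compartments count as wildtype-carrying
is configurable (`NW` alone is stricter and crosses no later than
`NW + NWM`).  Runs that never cross before `t_max` (default 1e5 time units,
comfortably above every finite time observed on the advantage grids, where
the maximum is ≈ 6.2e4 at the smallest 20×20-grid advantage step) return an
`inf` sentinel and a `censored` flag — the integration cannot distinguish
"never" from "not yet", so censoring is reported rather than asserted
non-replacement.

### Numerics

`scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`, `atol = 1e-10`;
replacement is located by the integrator's event detection (root refinement
on the interpolant), which agrees with an independent dense-output scan
(Radau at `rtol = 1e-10`, grid step 0.1 plus bisection) to ~1e-8 relative.
Densities below `−10·atol` abort the run; smaller negative excursions are
clipped to zero.  Under symmetric parameters the right-hand sides of `NW`
and `NM` are evaluated by identical expressions, so a symmetric initial
state stays symmetric to machine precision — the structural-neutrality
tests exploit this.

### Serial transfer

`simulate_serial_transfer` alternates continuous within-day integration with
instantaneous dilution (default 100-fold every 24 time units).  Optional
immigration mixes plasmid-free cells with the resident culture before
dilution at a configurable ratio (e.g. 95:1 immigrants:residents), assuming
the immigrant culture is at the same density as the resident one.  This mode
mirrors batch-culture experimental designs and is an extension of the
continuous model; it is exercised by tests but not by the headline sweeps.

## Coverage deconvolution

All coordinates are 1-based inclusive.  The default regions on the
99,378 bp reference are backbone = {1–5570, 41387–99378} and
AMR = {6200–15335, 15950–40664}; the gaps between them contain repeated IS
sequence where unique-read depth is unreliable and are excluded from both
means.  Region means are arithmetic means of per-base depth over the
interval unions; dividing by the chromosome mean depth converts depth to
copies per chromosome.  The mixture inversion is exact under the
two-molecule model (every streamlined copy lacks the whole AMR region);
noise that pushes the AMR estimate above the backbone is clamped so that
`n_full + n_streamlined = backbone` always holds.  Clones mixing more than
two molecule types (e.g. partial deletions) are outside the model.

The deletion caller median-smooths the profile (default window 501 bases),
splits smoothed values into two levels by iterated 1-D two-medians, and
thresholds at the level midpoint.  Candidate runs must be at least 5 kb long
(the target deletion is 35.6 kb), and the level separation must exceed twice
the noise scale of the smoothed depth (1.4826 × MAD outside the candidate
runs); on a flat profile the two-medians split of pure noise separates the
levels by only ≈ 1.35 standard deviations, so this guard rejects it.  All
qualifying runs are exposed, longest first.  Calls are invariant to global
depth scaling.  Median filtering preserves step edges, so on noiseless steps
the boundaries are exact; under Poisson noise at ≥ 20× depth they land
within the smoothing window.

## Assay estimators

Transfer efficiency is the end-point estimator `γ = T/(D·R·t)` (mL/cell/h)
using the *measured end-point* donor and recipient densities (a
geometric-mean variant is available but non-default).  It ignores
transconjugant re-conjugation and growth during the assay; the synthetic
oracle quantifies the resulting bias (≈ 2% at the default 1 h, 1e8/1e8
densities, rate 1e-12) rather than correcting it.  Zero transconjugant
colonies are replaced by the density of half a colony at the plating
dilution and flagged as a censored upper bound; the flag propagates to the
estimate.

Maximal growth rate follows the sliding-window log-linear ("easy linear")
procedure: OLS of log(blank-subtracted OD) on time over every window of
`h = 8` consecutive retained readings between 2 and 10 h post-inoculation,
returning the steepest slope with its window and fit diagnostics.  Readings
at or below `blank + 1e-4` are excluded before the log transform and windows
slide over the retained readings.  Picking a maximum over many noisy window
slopes is upward-biased when relative OD noise is large, and the logistic
ceiling biases late windows downward; the estimator is reliable when
relative noise is small through the exponential phase (see below).

## Synthetic data

Generators are deterministic given a seed and return ground truth alongside
the observables; estimator tests consume only the observables.

* **Coverage**: per-base expected depth is `chrom_depth × copies(position)`
  with sharp deletion boundaries at 5,700–41,300 by default (the real
  deletion is IS-bounded and exact, so sharp edges are the realistic
  default; a linear boundary-blur option exists for robustness testing).
  Noise is Poisson, or negative binomial with variance
  `overdispersion × mean` when overdispersion > 1.  Real depth profiles
  additionally show GC/mappability autocorrelation that is not modelled, so
  caller performance on real data may be worse than on these profiles.
* **Allele counts**: binomial draws at a locus, mutant probability equal to
  the streamlined fraction.
* **Conjugation**: mass-action ODE for (D, R, T) with optional exponential
  growth (default 0 over the 1 h assay: freshly diluted cells are still
  lagging) and optional transconjugant conjugation; plate counts are
  Poisson around expected colonies at dilutions chosen to land near 100
  colonies per plate, and densities are back-calculated exactly as from
  real plates.  Single-assay estimates therefore carry ≈ 17% plating CV;
  replicate means are the meaningful comparison.
* **Growth curves**: lagged logistic with inoculum `od0 = 1e-4` (a
  10,000-fold dilution of a unit-OD overnight culture), readings every
  5 min for 24 h.  `noise_sd` is *proportional* photometric noise (sd as a
  fraction of the reading, the way reader accuracy is quoted; default
  0.5%), with an optional additive `noise_floor` (default 0).  Under purely
  proportional noise the log-linear estimator recovers `mu` within 5% in
  ≈ 99% of seeds; with a realistic additive floor of ~0.002–0.005 OD the
  max-window procedure becomes substantially biased near the detection
  limit, so passing recovery tests certify the estimator in the
  proportional-noise regime, not near the reader floor.

## Problem sizes used by the test suite

The advantage heatmap is checked on the full 20×20 grid over
`a_H, a_V ∈ [1, 2]` (≈ 7 s); baseline-parameter effects on 5×5 advantage
grids for two values each of `beta_W` and `k`; estimator recovery on 100
growth-curve seeds and 24 replicate conjugation assays; coverage targets on
the full 99,378-base reference.

## Known limitations

* Deterministic ODE dynamics only: no demographic stochasticity, no more
  than two plasmid variants, no antibiotic selection, no spatial structure.
* The coverage model assumes unique-read depth in, at most, a two-molecule
  mixture; repeat-driven mapping artefacts are excluded by region choice,
  not corrected.
* The transfer-efficiency estimator is the standard end-point formula, not
  a dynamical fit; its biases are characterised, not removed.
* Replacement "no replacement" results are censoring statements at `t_max`,
  not proofs of global coexistence (except where symmetry makes neutrality
  exact).
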