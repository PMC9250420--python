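# Methods

## The problem

Solid-state NMR of the KcsA potassium channel in liposomes captures an
*activated* state (pH 4.0, high [K+]) whose structure is not directly
determined by the experiment. Molecular-dynamics ensembles seeded from
candidate crystal structures — Partially Open (PO, 3FB5-like, ~14 Å inner
gate), Fully Open (FO, 5VK6-like, ~22 Å) and Closed (C) — can be converted
into predicted chemical shifts per nucleus and compared with the measured
shifts. `shiftstate` implements that comparison as a statistical pipeline:
it decides, nucleus by nucleus, whether the simulated PO and FO ensembles
are even distinguishable, and for the nuclei that are, which state better
explains the experimental shifts.

## The model

For each (nucleus, state, prediction-method) the ensemble of per-snapshot
predicted shifts *d* is modelled with a skew-normal likelihood

    L(d | μ, σ, α) = (2/σ) φ(z) Φ(αz),    z = (d − μ)/σ

with φ, Φ the standard normal pdf and cdf. The predicted-shift
distributions from MD snapshots are strikingly non-Gaussian, which is what
motivates the three-parameter family; the prediction-tool error per
snapshot is deliberately not modelled. Priors are weakly informative:

* μ ~ Normal(d̄, 10 ppm), centred on the sample mean of the ensemble,
* σ ~ Half-Cauchy(β = 10 ppm),
* α ~ Normal(0, 10) (dimensionless — skewness carries no units).

The quantity ascribed to the NMR peak position (rapid population-weighted
averaging) is the *distribution mean*

    mean = μ + σ √(2/π) α/√(1+α²),

and the spread is var = σ²(1 − (2/π) α²/(1+α²)). Both are posterior-
distributed; every scalar is summarised by the 94% highest-density interval
(HDI), reported as centre ± distance to the bounds. The HDI was chosen as
the credible-interval flavour because it is the standard summary produced
by arviz and is well defined for the skewed posteriors that arise here; an
equal-tailed variant is available via `credible_interval(..., kind="eti")`.
Each (nucleus, state, method) model is fully independent — no hierarchical
pooling across residues.

Because KcsA is a homotetramer, the four subunits are treated as
independent realisations: the prediction is made on the full tetramer (so
inter-subunit contacts inform the predictor) and the four per-subunit
ensembles are concatenated afterwards, quadrupling the sample per nucleus.
2000 points per ensemble are then subsampled uniformly without replacement
(a seeded, per-nucleus RNG stream; ensembles smaller than 2000 are kept
whole with a warning rather than discarded).

## Sampling the posterior

The posterior over (μ, log σ, α) is sampled with an adaptive random-walk
Metropolis sampler: 4 chains, a joint Gaussian proposal whose covariance is
adapted during warmup (pooled-chain empirical covariance, scaled by
2.38²/3, frozen in the last quarter of warmup) with Robbins–Monro tuning of
a per-chain scalar step toward ~30% acceptance. After warmup, each retained
draw is separated by `thin` internal Metropolis updates (default 4), which
compensates the lower per-step efficiency of a random walk relative to
gradient-based samplers: typical bulk ESS rises from ~150–250 to ~500–800
per 4 × 500 retained draws on n = 2000 ensembles. Defaults are 1000 warmup
+ 1000 retained draws per chain.
Split-R̂ and bulk ESS (arviz) are computed for every fit; a warning is
attached above R̂ = 1.01 or below ESS = 400. Divergences in the HMC sense do
not exist for this sampler; degenerate inputs (< 10 points, constant data)
are refused outright.

Two deliberate numerical choices:

* **Centred sampling.** The data are mean-centred before sampling and the
  location draws are shifted back afterwards. Together with
  state-independent proposal increments this makes the fit numerically
  translation-equivariant: adding a constant to every input shift moves the
  location draws by that constant to ~1e-12, so downstream *difference*
  shifts are immune to referencing offsets not just in expectation but
  numerically. An ensemble sampler with state-dependent moves (e.g. stretch
  moves) would amplify roundoff perturbations chaotically and lose this.
* **Seeding.** Every fit derives its seed deterministically from the run
  seed and the (nucleus, state, method) labels, so whole-pipeline runs are
  exactly reproducible and cacheable.

A maximum-likelihood + parametric-bootstrap fallback (`fit_mle_bootstrap`)
exists for quick smoke runs; it is labelled non-canonical in its output and
is never used by the pipeline.

Calibration of the machinery is checked by simulation: 200 datasets of
n = 2000 from SkewNormal(55, 0.8, 3), fit at 4 × (500 + 500) draws, should
see the 94% HDI of the distribution mean cover the analytic truth in
94 ± 4% of replicates (binomial error at 200). This runs in ~3 minutes on
one CPU and is the primary acceptance quantity of `scripts/acceptance.py`.

## Discrimination filter

A nucleus (per method) *discriminates* PO from FO when both

* |centre of the 94% HDI of mean_FO − mean_PO| > the experimental
  tolerance (0.2 ppm for ¹³C nuclei C/Cα/Cβ, 0.5 ppm for ¹⁵N), and
* |centre of the effect-size HDI| > 0.5 (a medium effect), with
  effect = (mean_FO − mean_PO)/√((var_FO + var_PO)/2).

Criteria act on interval centres only. The pooled standard deviation uses
the **sum** of the variances under the radical; a rendering with a minus
sign circulates but cannot be a standard deviation (it can go negative) and
contradicts the name "pooled". Draws from the two independent posteriors
are paired by index — harmless under independence, and reproducible.

## State assignment

With C as the common reference,

    ΔCS_sim^X = CS_sim^X − CS_sim^C (per draw),  X ∈ {PO, FO}
    ΔCS_exp  = CS_exp^act − CS_exp^deact (a point value; experimental
               shifts carry no modelled uncertainty, only the tolerance band)
    ΔΔCS^X   = |ΔCS_sim^X − ΔCS_exp| (absolute value per draw)

The verdict for a discriminating nucleus compares the HDI centres of
|ΔΔCS^PO| and |ΔΔCS^FO|: smaller centre wins; if both centres sit inside
the tolerance band, or on an exact tie, no state is assigned. All boundary
comparisons in the package are strict, so ties resolve conservatively
(spectator / undetermined). Verdicts are tallied at nucleus level
(fractions of verdicts) and at residue level (majority vote per residue,
ties undetermined). Methods are kept separate through discrimination and
verdicts; a combined per-nucleus verdict (agreement → that state,
disagreement → undetermined) feeds the residue tally.

A nucleus whose experimental shift moves beyond tolerance between
conditions is a *marker*, otherwise a *spectator*. Point-measure baselines
are retained for completeness: absolute-shift RMSE per state, and Gaussian
recentring of the per-group (sim − exp) distributions (MLE normal fit,
centre subtracted; groups under 5 nuclei are passed through).

## Marker classification

Every assigned nucleus is classed from three booleans (|ΔCS| HDI centre vs
tolerance: PO≠C, FO≠C, FO≠PO) plus the marker flag:
A (none distinct), B (FO distinct from both), C (PO distinct from both),
D (both distinct from C but not from each other), E (all distinct);
subtype 1 = spectator, 2 = marker; A is not subdivided. The effect-size
criterion applies only to the FO-vs-PO comparison (where it is defined),
not to these booleans. D-class patterns have FO≠PO false and therefore
can never survive the discrimination filter. The three boolean patterns
matching no class (possible with noisy centres) are mapped to the nearest
regular pattern by Hamming distance — ties broken by preferring candidates
that agree on the FO-vs-PO boolean, then the later letter — and flagged
irregular rather than dropped; the flag is carried into the output table.

## Ensemble curation and structural metrics

Trajectory curation consumes precomputed event data rather than raw
trajectories: `exclude_after_water_entry` truncates at the first
water-in-selectivity-filter frame (a symptom of inactivation);
`stable_gate_window` either applies an explicit window (e.g. 400–1000 ns
for a PO run whose gate needed time to settle) or finds the earliest suffix
whose rolling-mean gate distance stays within a drift bound, requiring a
minimum stable stretch of twice the rolling window so a trailing sliver
never counts. The inner-gate opening itself is the cross-bundle distance:
the mean of the two diagonal Cα–Cα distances at the gate residue (T112),
with the diagonals identified geometrically (the chain pairing maximising
summed distances) because chain-naming conventions vary between PDB
entries; both diagonals are reported since open gates can asymmetrise.
Selectivity-filter occupancy strings (e.g. WKK0KW over six sites) round-trip
through a formatter/parser pair.

## Synthetic data: what it emulates and what it does not

The generator plants per-nucleus, per-state, per-method skew-normal (or
two-component mixture) ensembles parameterised directly by population mean,
sd and skewness, over four exchangeable subunits, and produces experimental
tables from a designated true state (activated = true state's population
mean + Normal noise, deactivated = closed reference's mean + noise). The
experimental noise default is 0.05 ppm — well under both tolerances, so
planted classes survive generation; it is configurable for stress tests.
Scenarios verify *analytically*, before any sampling, that each planted
class is achievable by its own parameters. RNG streams are keyed by the
state's position rather than its label, so relabelling PO↔FO permutes the
generated tables exactly — the basis of the label-symmetry test. An
optional per-subunit parameter override emulates a single deviant subunit
(one chain exploring an extra conformer, as flexible turret residues can).

Preset panels: `spectator_only` (nothing distinguishable), `b1_panel` (FO
displaced by 4× tolerance, experiment unchanged), `e2_panel` /`fo_truth`
(all three states separated by 4× tolerance, sd = 2× tolerance, hence
planted FO-vs-PO effect size 4, truth PO or FO), `bimodal_stress`
(mixtures with a 3-sd gap), `tie_stress` (gaps exactly at tolerance, where
strict comparisons make the outcome an ulp-level coin toss — deliberately
unverified).

What the generator does **not** emulate: frame autocorrelation (frames are
treated as exchangeable, which matches the random-subsampling assumption
but is optimistic about effective sample size for real trajectories),
prediction-tool systematic structure (per-method offsets beyond what the
user plants), realistic residue-specific shift surfaces, and missing
assignments. Passing recovery tests therefore shows the *pipeline logic*
is sound under its own assumptions, not that real MD + predictor output
satisfies those assumptions.

## Problem sizes used in the shipped tests

The unit and end-to-end tests run reduced ensembles (60–100 frames per
subunit, 240–320 subsampled points, 250–300 draws per chain) against
presets whose planted separations are large (≥ 3× tolerance, effect ≥ 2),
so decision margins dwarf the extra Monte-Carlo noise; the calibration
check runs at the full stated conditions (200 × n=2000, 4 × (500+500)).
Production defaults remain 2000 points and 4 × (1000+1000) draws.

## Known limitations

* The sampler is random-walk Metropolis, not NUTS: per-step efficiency is
  lower, which internal thinning compensates at a ~2.5x runtime cost; the
  ESS warning threshold surfaces fits where mixing is still inadequate, and
  the calibration check verifies that HDI endpoints are accurate at the
  achieved ESS.
* Verdicts assign a single dominant state per nucleus; mixed populations /
  state fractions are out of scope.
* No multiple-testing correction is applied — the filter is a per-nucleus
  threshold rule by design.
* Gate-distance values for real PDB entries depend on the deposited
  coordinates; the implementation is validated on exact synthetic geometry
  and rigid-motion invariance.
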