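# Methods

## The generative model

A plate run is a set of wells, each expressing one odorant receptor (OR) or
an empty vector (pCI), read kinetically while an odorant is presented. The
simulator produces each well's raw luminescence as

```
value(t) = G · B · d^c · [1 + E · (1 − exp(−k · max(0, t − t0)))] · ε(t)
```

with cycle index `c` (1-based; the time of cycle `i` is `(i−1) ·
cycle_interval_s`), baseline luminescence `B`, per-cycle multiplicative
drift `d`, rise rate `k`, onset delay `t0`, per-read noise `ε`, and a
static gain `G` combining a per-well transfection-efficiency surrogate and
a per-run (day) gain. The effective drive is

```
E = toxicity_scale · min( Σ_i efficacy_i · occ(c_i), max_i efficacy_i )
```

where the sum runs over dissolved odorants and `occ(c) = c^n / (c^n +
EC50^n)` is Hill occupancy. Capping the mixture drive at the largest
single-ligand efficacy is a generator convention: it prevents unbounded
superposition for mixtures without changing any single-odorant behaviour.

The kinetic form is a single saturating exponential: observed panel traces
rise monotonically to a plateau, so no biphasic or decay term is modeled;
the response reduction seen at undiluted (1e0) exposure is handled by the
scalar toxicity attenuation, not by the kinetics.

**Vapor partitioning.** A vapor dilution `v ∈ (0, 1]` (vol/vol in mineral
oil) maps linearly to a dissolved concentration `c = κ·v` with partition
coefficient `κ` (default 1e-2 mol/L per unit dilution). This is a free
generator parameter, not a physical estimate: no chamber equilibration or
Henry-constant modeling is attempted.

**Esterase conversion.** A Ces1d model is a list of (substrate ester →
product, fraction) conversions applied to the dissolved mixture before
occupancy is computed; total molarity is conserved per conversion (checked
to 1e-12). A receptor tuned to the product gains response under
co-expression, one tuned to the substrate loses it — the sign-level
behaviour the enzyme experiments probe.

**Toxicity.** Vapor above a dilution threshold (default 0.1, i.e. only the
undiluted 1e0 condition on the decade grid) multiplies the drive by a
per-odorant viability floor; presets of 0.25 ("harsh", eugenol-like) and
0.8 ("mild", methyl-benzoate-like) reproduce the qualitative contrast
between strongly and moderately toxic odorants. Whether the 1e0 response
loss is purely viability-driven is not resolvable here; the generator
deliberately conflates viability and any receptor-level loss in one scalar.

**Noise.** All noise is multiplicative log-normal with mean 1: a per-well
gain (CV 0.10), a per-day gain (CV 0.05) and a per-read jitter (CV 0.03).
The first two cancel exactly under the normalization below; the per-read
jitter is what limits replicate reproducibility, and its default was chosen
so that two independently simulated runs of the same odorant correlate at
R² above 0.91 across the 32-unit panel — the regime the assay operates in.
Per-well random streams are keyed by (root seed, condition index, receptor
index, replicate), so adding wells or conditions never perturbs existing
wells and every run is bit-reproducible from its seed.

**Default affinity preset.** The 7-analog panel (acetophenone and six
structural analogs: 4-methyl acetophenone, propiophenone, benzaldehyde,
2-hydroxy acetophenone, methyl salicylate, menthone) draws each analog's
31-receptor efficacy vector as a weighted blend of a shared receptor-tuning
profile (structural similarity) and an analog-specific profile, with blend
weights spread over 0.35–0.95; efficacies below 1 are zeroed, making most
receptors non-responders for any given analog (sparse combinatorial code,
max efficacy 8). EC50 (log-uniform 3e-6–3e-4 mol/L) and Hill slope
(0.8–1.5) are receptor-intrinsic with a ±0.25 log-unit per-analog EC50
jitter. Under these defaults different analogs' panel profiles correlate at
R² ≈ 0.2–0.85 while repeat runs of the same analog correlate above 0.99 —
i.e. analogs are related but separable, which is the premise of the
discrimination analysis.

## Normalization and quantification

Each raw trace is divided by its own cycle-1 value, then by the per-cycle
arithmetic mean of the initially-normalized vector-control wells of the
same run and condition. Cycle 1 of a normalized trace is exactly 1;
normalizing a control well against its own set gives all ones; a common
gain on a trace and its controls cancels. Shared drift (reagent decay,
warm-up) cancels through the control division, which is the only drift
correction applied.

AUC is a plain sum of normalized values over all cycles — no trapezoid or
time weighting. Two modes are provided: `auc_raw` (Σ value) and
`auc_baseline` (Σ (value − 1)), related exactly by `baseline = raw −
n_cycles`. `auc_baseline` is the default because it sends null wells
(vector control) to ≈ 0, which is how panel heat maps are read; since the
two differ by a constant, every correlation- or rank-based downstream
result is identical under either. Peak is the maximum normalized value
(reported baseline-subtracted in matrix mode). On noiseless monotone traces
AUC and peak rank receptors identically, and at the 1e-2 vapor condition
their cell means concord at R² > 0.99.

## Statistics

- **One-way ANOVA** by explicit sum-of-squares decomposition; with 7
  odorants × 3 replicates the dfs are (6, 14) and the 0.05 critical value
  is F = 2.85.
- **Tukey HSD** via the studentized-range distribution
  (`scipy.stats.tukey_hsd`); the differential-activation count for an
  odorant pair is the number of receptors with ANOVA p < α and Tukey
  adjusted p < α for that pair (α = 0.05, gated on the ANOVA).
- **Dunnett onset**: replicate values per reading cycle enter an ANOVA
  across cycles; if significant, each cycle is compared to the baseline
  cycle with Dunnett's many-to-one procedure (`scipy.stats.dunnett`, the
  equi-correlated multivariate-t form, exact for balanced designs; the QMC
  integration is seeded for determinism). The onset is the earliest cycle
  with adjusted p < α and a positive mean shift. True dfs are always
  reported rather than any fixed design values.
- **BH FDR** implemented literally as the step-up rule `adj_(i) = min_{j≥i}
  p_(j)·m/j`, capped at 1. For enzyme comparisons the family is the
  receptor panel within each odorant (matching per-odorant hit counts), not
  all odorants jointly.
- **t-tests** default to Welch; the pooled-variance form is available
  everywhere (`equal_var=True`). The screening direction filter requires
  the odor mean to exceed the control mean, so suppressions are never
  counted as hits.
- **R²** throughout means the squared Pearson correlation, whether from a
  regression fit or computed directly.
- **Hill fitting** (`fit_hill`) optimizes log10(EC50), efficacy and slope
  with bounded least squares; under default noise the EC50 of a responsive
  receptor is recovered within two-fold from a 9-point dose series.

## Discrimination

Trials are replicate-level 32-vectors (no replicate averaging): 3 per
odorant per day. The random forest uses 500 trees, sqrt-feature subsets
(⌊√32⌋ = 5), unlimited depth and majority vote; LDA uses scikit-learn's
SVD solver (pooled within-class covariance; no explicit ridge — the SVD
route is numerically stable at these dimensions). No feature scaling is
applied for either method, and t-SNE (perplexity 10, PCA init, seeded) runs
on raw response vectors. Accuracy is only defined for train/test trial sets
with disjoint day labels; the API refuses overlapping days.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: replicate
and day-to-day variability, same-odorant reproducibility vs cross-analog
similarity, concentration-nested activation (receptors active at a low
dose are a subset of those active at a higher dose, given monotone
occupancy), toxicity attenuation at undiluted exposure, and
esterase-induced gain/loss. It does not emulate plate-position effects,
well-to-well crosstalk, reagent depletion kinetics, receptor environment
(chaperone) variability, plasticware absorption of odorants, or any real
receptor's measured affinities — the affinity preset is a synthetic
stand-in for a combinatorial code, not a reconstruction of published OR
tuning. Tests passing on this generator therefore validate the analysis
machinery and its calibration assumptions, not any claim about particular
receptors.

## Problem sizes and numerical conventions

Simulated sessions use the full 32 × 7 × 3 panel at 20 cycles; summary
statistics average 10 seed pairs (reproducibility) and 20 seeds
(classification), sizes chosen to keep a complete analysis run in the
tens-of-seconds range on one core while leaving Monte-Carlo error well
below the decision margins. Vapor decade dilutions serialize as exact
strings ("1e-2") and all other floats as shortest round-tripping decimals,
making CSV round trips byte-identical. Hierarchical clustering
(average linkage, Euclidean) sorts rows lexicographically before linkage so
equal-distance merges resolve identically on every run; a constant matrix
yields alphabetical order by construction. Heat-map color scales use the
matrix min–max, falling back to [0, 1] for a constant matrix, and the
bounds are recorded in the export metadata.

## Known limitations

The linear vapor→dissolved map ignores volatility differences between
odorants, so absolute dilution scales are not comparable across odorants.
The screening cascade's primary-selection rule (top-k or fold ≥ 2) is
configurable because no single canonical cutoff exists. The Dunnett and
Tukey adjustments assume balanced replicate groups, which the simulator
always produces; unbalanced real data would make the equal-correlation
Dunnett form approximate.
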