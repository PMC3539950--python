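# Methods

This note documents the models, numerical choices and known
limitations behind `probestat`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Generative model

Probe intensities are lognormal-multiplicative with additive optical
background. For gene *g* with true target concentration *e_g* and
probe pair *p* with affinity *φ_p*:

    PM_{g,p} = bg + φ_p · e_g · exp(ε),   ε ~ N(0, σ_tech²)
    MM_{g,p} = bg' + c · φ_p · e_g · exp(ε'),

with backgrounds bg, bg' drawn independently from N(B, σ_B²) (floored
at 10⁻³ to keep intensities positive) and independent technical draws
for PM and MM. The cross-hybridization fraction c < 1 guarantees PM
stochastically dominates MM for expressed targets; for unexpressed
genes (e_g = 0) PM and MM are identically distributed, so PM − MM is
symmetric about zero — exactly the null the detection statistic
assumes. Affinities φ_p are lognormal with unit mean and CV 0.5, drawn
once per chip design and frozen across every chip of an experiment,
because probe effects are sequence properties and chip-invariant in
reality.

Animal-level expression is baseline × condition fold × exp(N(0,
σ_bio²)); the zero-mean-log convention makes the geometric mean across
animals converge to baseline × fold. RNA pooling is the arithmetic
mean of the pooled animals' expression vectors (physical mixing of
equal RNA masses), which shrinks the expression CV by ≈ √k for a pool
of k animals — asserted as the pooling variance law in the tests.

Paired human designs draw one subject-level biological effect per gene
shared by both of a subject's conditions, with chip-level technical
noise on top. This is deliberate: the repeated-measures design exists
precisely because within-subject comparisons remove between-subject
variability, and modelling condition-independent biological draws per
biopsy would erase that structure. Duplicate biopsies share the
subject × condition expression and differ only in technical noise; the
duplicate-biopsy CV therefore measures the technical/sampling
component alone.

### Default parameters

| parameter | default | units / meaning |
|---|---|---|
| background mean B | 100 | scanner units, additive per probe |
| background sd σ_B | 20 | 20 % of B, a realistic optical spread |
| σ_bio | 0.25 | animal-to-animal lognormal scale (~25 % CV) |
| σ_tech | 0.15 | probe-level lognormal scale (~15 % CV) |
| crosshyb c | 0.35 | fraction of specific signal on MM |
| baselines | lognormal, median 300, σ 0.5 | target concentration |
| probe pairs | 11 (human), 16–20 (rat) | per probe set |

With these values expressed genes are called Present ≥ 95 % of the
time and absent genes well under 4 % (both measured in the acceptance
suite). The designated suppressed gene carries fold 0.57 in the rat
inactivity conditions, 0.60 under rat exercise (suppression explicitly
not restored by exercise; no printed value exists for that condition,
so 0.60 is this package's choice), 0.55 in the paired human design
(the PCR-scale effect), and 0.41 / 0.49 / 0.56 across the case-study
conditions. 20 % of null genes are unexpressed, so rendered catalogues
contain a realistic NotDetected stratum.

## Detection

Discrimination scores R_p = (PM_p − MM_p)/(PM_p + MM_p) are tested
against τ = 0.015 by the exact one-sided Wilcoxon signed-rank test.
The null distribution of W⁺ is built by the shift (convolution)
algorithm; values equal to τ are dropped (n reduced), ties among
|R_p − τ| receive midranks and the enumeration then runs over doubled
(hence integral) ranks, still exactly over all 2ⁿ sign assignments.
Call thresholds: Present p ≤ α₁ = 0.04, Marginal p ≤ α₂ = 0.06. τ and
α₂ follow the conventional probe-level detection settings; only α₁ is
dictated by the analysis the package reimplements. All three are
config-exposed.

Because the exact test is discrete and τ > 0 shifts the null
downwards, the Present rate on truly absent genes is conservatively
below α₁ — the acceptance suite measures ≈ 0.016 at defaults.

A normal approximation (tie-corrected variance, continuity correction)
is provided for probe sets beyond the exact regime. The continuity
correction is halved when midrank ties are present, since ties halve
the lattice spacing of W⁺. On continuous inputs with 10 ≤ n ≤ 20 it
agrees with the exact p within 0.01; heavily lattice-tied inputs can
reach ≈ 0.02 disagreement (tested at a 0.025 bound), which is a known
property of tie-corrected normal approximations at small n, not of
this implementation.

Detection runs on un-normalized intensities: the score is a ratio and
therefore invariant to uniform chip scaling.

## Signals and normalization

The per-gene log₂ signal is a one-step Tukey biweight (tuning constant
5, guard 10⁻⁴) of log₂ max(PM_p − MM_p, δ), δ = 1; when the MAD is
zero the median is returned. Global scaling multiplies each chip (on
the linear scale) by target / trimmed-mean with 2 % two-sided trimming
and target 500; normalization is idempotent and collapses chips that
are scalar multiples of each other.

Known bias: flooring PM − MM at δ compresses fold changes for genes
whose weakest probes sink into the background, because the suppressed
condition is floored more often than control. In the paired human
simulation this inflates the measured percent-of-control by a few
points (runs report ≈ 55–60 % for a true 55 %); the same compression
toward unity at low intensities is a well-known property of
background-unsubtracted array signals. The acceptance suite verifies
the true value sits inside the simulation's 95 % interval.

## Pooled differential expression

Each treatment pool is compared with each control pool. Per cell the
fold is 2^(signal_T − signal_C) on normalized signals; the comparison
p-value is a two-sided exact signed-rank test on per-probe differences
of log₂ max(sf·(PM − MM), δ), with each chip's scale factor applied so
the probe-level test sees the same normalization as the fold.
Two-sided was chosen because direction is enforced separately by the
fold filter. The per-gene average p across the grid (arithmetic mean;
geometric mean is a config option) is ranked against
Benjamini–Hochberg step-up thresholds (i/m)·q, q = 0.05, with tied
p-values sharing the better outcome. A gene is differentially
expressed iff it passes the FDR rank test, changes ≥ 1.5-fold in the
same direction in every cell, and is Present on every chip of at least
one side (any/all/either-side is config-exposed).

Note that the mean of several signed-rank p-values is not itself a
p-value; under the null it concentrates near 0.5, so BH applied to it
is conservative. The realized false-discovery proportion on a
5 %-signal mixture stays at or below q (measured in the acceptance
suite).

### Power of the pooled criteria

The conjunction of filters is deliberately conservative, and at the
default noise level it has low power against a 0.57-fold suppression.
Two effects dominate. First, the all-cells fold filter: with pool-level
expression CV σ_bio/√k ≈ 9 % plus signal noise, the probability that
all 9 treatment/control ratios stay below 1/1.5 when the true ratio is
0.57 is only ≈ 0.25–0.5 (the margin log(1.5·0.57) ≈ −0.16 is about
1.5 pooled standard deviations). Second, the averaged-p FDR rank test:
at m = 500 genes the rank-1 BH threshold is q/m = 10⁻⁴, while the mean
of 9 two-sided probe-level p-values is typically ~5·10⁻³ because a
single weak cell dominates an arithmetic mean. Measured end to end,
the suppressed gene is declared DE in ≈ 4 % of replicates at default
noise, while a global null yields essentially zero false positives —
the procedure is safe but weak at this effect size and design, and the
corresponding acceptance test documents this as a failing expectation
rather than hiding it. Recovering such effects reliably would require
either lower biological variability (σ_bio ≲ 0.1), larger pools, a
smaller tested gene universe, or relaxing the all-comparisons
conjunction.

The paired human design, by contrast, recovers the 0.55-fold
suppression readily: subject-level variability cancels in the
within-subject fold, so per-subject folds sit tightly around the truth
and the paired t-test on three subjects is decisive.

## Catalogue classification

Across the chips of an experiment a gene is NotDetected if Present on
none, Strong if Present on all chips with mean detection p ≤ 0.01,
otherwise Moderate. Published detection tables of this kind are not
perfectly consistent at the Strong/Moderate boundary, so the boundary
is config-exposed rather than hard-coded. Detection p-values below a
probe set's attainable exact minimum (0.5ⁿ) cannot arise from a
single-chip exact test; the pipeline flags such values in logs instead
of emulating any undocumented convention.

## PCR arm

Normalized expression is target band density / GAPDH band density per
sample; percent of control is computed per subject and averaged
arithmetically (mean ± SEM), matching the paired design. The paired
t-statistic is computed from its closed form and referred to the t
distribution; all-zero differences return p = 1 (an identity input is
a legitimate null), zero-variance nonzero differences return the
smallest positive float with a warning.

Duplicate CV uses the two-point convention sd = |v₁ − v₂|/√2 per pair,
averaged across pairs. This estimator carries the classic small-sample
sd bias: its expectation is √(2/π) ≈ 0.798 of the true σ, so "recovery
within 20 %" of an injected technical CV is exactly borderline — a
1,000-pair Monte-Carlo draw lands on either side of the 0.8 ratio
depending on the seed. The package reports the estimator as defined
(it is the convention used for inter-biopsy variability reporting)
and the test suite documents the boundary behaviour instead of
correcting the estimator.

## Determinism and provenance

All randomness flows from a single integer seed per run; scenario
construction, truth generation, chip simulation and the PCR simulation
draw from generators derived from it. Every parameter of a run lives
in a flat YAML config (checked by introspection to be complete), and
outputs are written with deterministic formatting, so two runs of the
same config are byte-identical — asserted file-by-file in the tests.
TSVs are read back with exact float round-tripping.

## Limitations

The simulator does not model zone-dependent background, scanner
saturation nonlinearity (only a hard cap), probe-sequence-specific
cross-hybridization, fragmentation/labelling chemistry, or
between-chip spatial artefacts; passing tests therefore say nothing
about those failure modes in real data. The detection and comparison
machinery assumes probe sets of at most 25 pairs (the exact regime);
larger sets would need the provided normal approximation. Annotation
is a static fixture for report rendering only.
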