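# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Precursor discovery

**Cleavage model.** Only dibasic cleavage sites (KK, KR, RK, RR) are
recognised; monobasic and tetrabasic processing is deliberately out of
scope. Any maximal run of ≥2 consecutive K/R downstream of the
signal-peptide boundary is treated as a single cleavage region (so KRR is
one region, not two overlapping motifs). Candidate mature peptides are
the non-empty segments between regions, plus the segment from the signal
boundary to the first region, plus — by default — the segment after the
last region (`include_cterm=True`). Whether a chain-terminal peptide
counts as "properly flanked" is a genuine convention choice; it is
exposed as a toggle because secreted precursors do carry C-terminal
peptides that are observed in practice. A consequence of run merging is
that peptides never contain two consecutive basic residues, though a
lone K/R may survive inside or at the chain-terminal end of a peptide.

**Modifications.** A trailing Gly is consumed as the amidation donor and
contributes −0.98 Da to the peptide's mass shift relative to the mature
core's free acid. A leading Gln/Glu marks the peptide as a potential
pyroglutamate (−17.03 / −18.01 Da); the flag records the donor, since
conversion in vivo is not guaranteed. Half-cystine (−1.01 Da) is
recognised as a modification mass constant but never inferred from
sequence — pairing of cysteines is not predictable from the precursor
alone. Monoisotopic masses come from pyteomics.

**Candidate rule.** `is_candidate = has_signal AND (≥1 detected properly
flanked peptide | detected list supplied; else ≥1 dibasic site)`.
Signal-peptide calls are inputs; the bundled hydrophobic-window heuristic
(`predict_signal_peptide`) exists only so synthetic data can be processed
without an external predictor and is clearly labelled as such.

**Coordinates** are 1-based inclusive everywhere, including serialized
tables.

## Synthetic data

The generators produce data with exactly the statistical structure the
analysis assumes, which is what makes the round-trip and calibration
tests meaningful — and bounds what they show about real data.

* **Proteomes.** Precursor = Met-initiated hydrophobic signal peptide
  (length 15–30) + mature peptides (5–15 aa, alphabet excluding K/R/C)
  alternating with dibasic sites. ~50% of peptides carry an amidation
  donor G; ~20% start with Q/E. Non-amidated peptides are resampled not
  to end in G, so the ground-truth amidation flags coincide with what the
  cleavage rules can infer. Decoys alternate between
  dibasic-sites-without-signal and signal-without-dibasic-sites.
* **Abundances.** Normal on the log10 scale (the scale on which the test
  operates); fold changes are additive log10 shifts of condition 2. The
  technical CV (default 21.63%, the replicate-preparation CV the workflow
  is designed around) maps to the log10 SD via
  σ₁₀ = √(ln(1+CV²))/ln 10. Fragment areas split a peptide's total by a
  fixed per-peptide Dirichlet profile, so summing fragments recovers the
  total exactly; optional second charge states and Met-ox variants split
  the total with fixed weights and are re-summed by aggregation.
* **Dropout.** A replicate whose sampled abundance falls below
  `dropout_threshold` is flagged undetected and its rows carry
  background-level areas near the dataset floor — emulating background
  integration at the expected RT. A threshold between the two condition
  means reproduces the dauer-only on/off pattern.
* **Run effects.** Each run's areas (and its MS1-feature table) are
  multiplied by a log-normal scale factor; median MS1 normalization
  removes it exactly in the zero-noise limit, because the feature
  population is fixed across runs.
* **Bouts.** A two-state alternating-renewal process with exponential
  (memoryless) crawl/nictation durations, truncated at the 90 s window.
  The initial state is drawn from the stationary distribution, which
  together with memorylessness makes the process stationary, so the
  expected nictation ratio equals μ_n/(μ_n+μ_c) exactly. Defaults
  (μ_n = 7.4 s, μ_c = 12.6 s) give a wildtype-like ratio of ≈0.37.

Not emulated: chromatographic peak shapes, isotope envelopes, RT drift
within a run, interference between co-eluting transitions, biological
(inter-culture) variance structure beyond a single CV knob, and any
within-bout behavioral substructure. Passing tests therefore demonstrate
correctness of the estimators and rules under the stated model, not
robustness to instrument artefacts.

## Quantification pipeline

Order of operations is fixed: transition filtering → aggregation →
median MS1 normalization → detection policy and minimum imputation →
log10 → t test. Normalization divides each run by (run MS1 median /
grand median of run medians), preserving overall scale; when no MS1
table is given the per-run peptide-area median is the fallback (with a
warning). The detection policy keeps "all replicates of both conditions"
(quantifiable) and "all replicates of exactly one condition" (on/off);
every partial pattern is dropped. Zero areas among retained peptides are
replaced by the minimum positive value of the retained dataset. The t
test is Student's equal-variance, two-sided (Welch is available via
`equal_var=False`); zero pooled variance yields a flagged degenerate row
with NaN p rather than a fabricated value. No multiple-testing
correction is applied to the headline significance counts, matching the
volcano-style presentation; a Benjamini–Hochberg q column is emitted
additionally. The pipeline is scale-invariant per run by construction.

Per-peptide CVs are computed on linear-scale areas; the summary is the
median across peptides ± SEM of the per-peptide CVs. Note that sample
CVs from few replicates are biased low (the n=4 sample SD underestimates
σ by ≈8%, and the median of a right-skewed CV distribution sits below
its mean), so the acceptance script estimates the design CV from a
30-replicate technical set.

## Power analysis

Each grid cell draws n replicates per condition from
N(mean, sd) / N(mean + log10(fc), sd₂) and applies the same
equal-variance t test as the pipeline; the fold change shifts one
condition only (equivalent for the test to a symmetric split). Each
condition keeps its own SD when two are supplied. The RNG uses one
`SeedSequence` substream per (peptide, effect size, sample size) cell,
so any cell is reproducible in isolation. The closed-form cross-check is
the noncentral-t power with df = 2n−2 and noncentrality
log10(fc)/(sd·√(2/n)).

## PRM scheduling

Concurrency treats RT windows as closed intervals; the maximum overlap
is attained at a window start, so a sweep over starts is exact.
Scheduling is greedy first-fit in ascending RT-center order (ties broken
by peptide id): reproducible, auditable, and within one injection of the
exhaustive optimum on every random instance tested. The unscheduled
model, ceil(n_targets/cap), deliberately ignores instrument cycle-time
constraints, so real unscheduled workflows may need more injections than
it predicts; it is labelled an approximation. RT calibration is an
ordinary least-squares line from library RTs to observed run RTs over
flagged standards.

## Detection statistics

"Sample overlap" is 100 × (analytes detected in all samples)/(maximum
per-sample count). The all/max denominator is the only simple convention
simultaneously consistent with the three published pairs it is validated
against (172/178→97%, 72/114→63%, 259/263→98%); all/mean is available
behind a flag. Percentages are kept unrounded internally and rounded
only for reporting.

## Behavior

The three nictation indices follow the standard formulas
(T_nict/T_total, N_nict/(T_total−T_nict), T_nict/N_nict); the identity
initiation_index × average_duration = ratio/(1−ratio) holds whenever all
terms are defined and is property-tested. Bouts truncated by the
observation window count as one initiation event with their observed
duration. A consequence worth knowing: per-individual bout-level
estimators carry an O(μ/T) finite-window bias (an in-progress bout at
t = 0 is counted as an initiation), so parameter recovery is checked
with pooled ratio-of-sums estimators against their exact renewal-theory
expectations, E[N] = π_n + T/(μ_n+μ_c) and E[T_nict] = T·π_n.

Batch normalization rescales each batch multiplicatively so its
control-group median matches the grand pooled control median (additive
variant behind a flag; ratios clipped to [0,1]). With a single batch
this is the identity; rescaling a whole batch is undone exactly whenever
the grand control median is insensitive to that batch, which holds by
median robustness in multi-batch designs. No data-derived target can
make both the single-batch identity and batch-scale invariance exact
simultaneously; identity was kept exact.

Dunnett's many-to-one comparison uses the one-factor correlation
structure ρ_ij = λ_iλ_j, λ_i = √(n_i/(n_i+n₀)) induced by the shared
control, and evaluates P(max|T_i| ≤ q) by Gauss–Hermite quadrature (96
nodes) over the shared factor and Gauss–Legendre quadrature (96 nodes,
probability scale) over the chi-distributed pooled-SD factor; a seeded
Monte-Carlo mode is available. With a single treatment group the
adjusted p is computed exactly as the two-sided pooled t-test p. The
implementation is cross-checked in the tests against both a seeded
Monte-Carlo simulation of the max-|t| null and SciPy's independent
Dunnett implementation. Statistics are computed on individual worms;
the control's p against itself is 1 by convention.

Track speed is the mean frame-to-frame displacement over Δt, scaled
pixels→μm, with tracks under 30 s excluded and non-monotone timestamps
rejected.

## Problem sizes and tolerances

The test-suite and acceptance-script simulation sizes are chosen to make
each check statistically decisive while staying quick on one CPU: 2000
peptides (4+4 replicates) for the null calibration, 1000 peptides for
fold-change CI coverage, 500 simulations per power cell (binomial SE
< 1 point at the reference cell), 100 peptides for power monotonicity,
1000 random sequences for the cleavage-site oracle, 25–30 random
instances (≤10 targets) for the exhaustive scheduling oracle, and 800
individuals for bout-parameter recovery. Monte-Carlo assertions use
binomial 95% intervals or 3·SE bands with explicitly stated bias
allowances (e.g. the O(μ/T) bout truncation terms).

## Known limitations

* Signal-peptide prediction is out of scope; the bundled heuristic is
  not a substitute for a trained predictor on real proteomes.
* The greedy scheduler is not guaranteed optimal (bin-packing is
  NP-hard); the exhaustive oracle bounds its gap only on small
  instances.
* Detected-peptide matching is exact-substring; isoleucine/leucine
  ambiguity and near-isobaric substitutions are not modelled.
* The quantification model assumes log-normal areas with a common
  within-condition variance; heavy-tailed interference is not simulated.
* Homology/orthology resolution is an upstream input; no alignment is
  performed.
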