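# Methods

This note documents the models and procedures implemented in `rtmut`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and the limitations of validating the pipeline on
synthetic data.

## 1. Replication-timing stratification

The RT profile is a bedGraph of genomic bins with a continuous value;
following the Repli-seq log-ratio convention, **higher value = earlier
replication** (`invert` flips this — the sign convention of an input
profile must be checked by the user). The genome is split at the
**median of the bin values**, bins weighted equally; with fixed-width
bins this coincides with the base-pair-weighted median. Bins at or above
the threshold are early; ties go to early, which is deterministic and
immaterial for continuous RT values. Adjacent same-label bins are merged
into intervals, and every mutation is assigned to the interval containing
its position. Mutations outside RT coverage count toward the ALL state
but neither ERR nor LRR, so the three states are nested and
`|early| + |late| + |unassigned| = |all|` holds per sample.

## 2. Profiles and trinucleotide normalization

SBS-96 channels follow the standard pyrimidine-centric convention
(purine-reference substitutions are reverse-complemented together with
their context); channel index = class·16 + 5'·4 + 3' with classes
ordered C>A, C>G, C>T, T>A, T>C, T>G and bases A,C,G,T. Records whose
context contains N, sits at a chromosome edge, or whose stated reference
allele disagrees with the FASTA are excluded and counted rather than
trusted — profile counts plus exclusions always equal the number of SNVs
supplied.

Because ERR and LRR differ in sequence composition, channel counts are
divided by the frequency of the channel's underlying trinucleotide
*within the analysed region* (region-internal frequencies, computed over
all 3-mer windows lying fully inside the region's intervals) and then
rescaled to sum to one. The unit-sum scale is required for Euclidean
distances between profiles to be comparable; a zero trinucleotide
frequency under a non-zero channel is an error naming the channel.

Indels are classified into a 28-channel scheme used **only for burden
counting**: {DEL, INS} × {C-, T-homopolymer} × run length 1–6+ for 1-bp
events (run length of the reference homopolymer containing a deletion,
or resulting from an insertion; G/A events collapse to C/T by
complement), plus {DEL, INS} × {2–4 bp, 5+ bp} for longer events. Burden
analyses use only the total classifiable count per RT state, so results
are insensitive to the exact within-scheme boundaries.

## 3. Bootstrap spectrum test

Per RT state the control samples define a centroid (element-wise mean of
their normalized spectra) and a pooled 96-channel count vector. The null
distribution of distances is built from `B` bootstrap replicates
(default 10,000, minimum 100): replicates are allocated equally across
controls (remainder round-robin), each replicate draws that control's
mutation count from the pooled channel distribution, is
trinucleotide-normalized exactly like a real profile, and its Euclidean
distance to a reference point is recorded. A sample's raw p-value is the
pseudo-counted exceedance proportion `(k+1)/(B+1)` with ties counted
toward the null — strictly positive, so geometric-mean combination is
always defined, and conservative at the extreme.

### Why the centroid is re-estimated per replicate

The naive construction measures every bootstrap replicate against the
*fixed observed centroid*. Write `Σ` for the per-draw multinomial
covariance of the spectrum, `m` for a sample's mutation count and `n`
for the number of controls. A bootstrap replicate drawn from the pool is
a draw from (essentially) the centroid itself, so its expected squared
distance is `tr(Σ)/m`. An *independent* null sample, however, carries
both its own noise and the centroid's estimation error:
`E‖d‖² = tr(Σ)(1/m + 1/(nm)) = (1 + 1/n)·tr(Σ)/m`. With few controls
this inflation is large relative to the null spread (which scales like
`sqrt(2/k_eff)` for an effective channel count `k_eff ≈ 40–90`): at
`n = 4` the measured false-rejection rate of the naive null for
independent null samples is ≈ 0.39 at a nominal raw α = 0.05
(simulation, 3,000 mutations/sample), and raw p-values are grossly
non-uniform. The naive null is exactly calibrated only for samples
resampled from the pool itself (measured rejection ≈ 0.03–0.07).

`fit_null` therefore defaults to `centroid_mode="resampled"`: for each
bootstrap replicate the whole control cohort is also resampled from the
pool (same per-control sizes) and the replicate's distance is taken to
the centroid of that resampled cohort. This reproduces the sampling
distribution of the observed statistic — an independent sample's
distance to an *estimated* centroid — and restores calibration for
independent null samples (measured rejection ≈ 0.05–0.06; raw p uniform
by KS across cohorts). `centroid_mode="fixed"` retains the literal
fixed-centroid construction for comparison; its pool-drawn calibration
property is kept under test.

### Known size-mismatch caveat

Null replicate sizes follow the *control* mutation counts. A perturbed
sample with a much smaller burden than the controls has larger
multinomial noise than the null accounts for, which inflates its
distance and can flag a spectrum change that is purely a burden deficit.
Interpret spectrum calls for strongly burden-depleted groups together
with the burden table.

### Families and combination

Raw p-values of all perturbation replicates within one RT state form one
BH family. Adjusted values are combined per group by geometric mean
(defined because p > 0); a group is significant when the combined value
is ≤ 0.05. The per-replicate adjusted values are reported alongside, so
any-replicate logic can be applied downstream if preferred.

## 4. Two-stage burden test

Stage 1 screens each group's ALL-state counts against the original
controls with a two-sided Mann-Whitney test. Groups with raw p above the
absorption threshold (default 0.1333, a liberal screen applied to raw
p-values) contribute all their replicates to the expanded control set;
the decision is made once on the ALL state and reused for ERR/LRR.
Because the screen gates "no change in mutation count" and the pipeline
runs separately per assay, the screen-and-expand step is performed per
assay (SBS counts gate SBS tests, indel counts gate indel tests);
`share_expansion=True` reuses the SBS expansion instead. Absorption is
decided per group; with 2–4 replicates against a handful of controls the
screen is noisy (a truly neutral 3-replicate group fails a 4-control
screen ~11% of the time by rank chance alone), so cohorts with more
neutral groups yield more stable expanded sets.

Stage 2 re-tests every group against the expanded set per (RT state ×
assay), always removing the tested group's own replicates first — a
group absorbed at stage 1 is never compared against itself, which would
bias p toward 1. BH families are (state × assay) across groups;
significance is adjusted p ≤ 0.05; direction is MORE/LESS by median
comparison (ties broken by means), reported regardless of significance.

**Mann-Whitney implementation.** The two-sided p-value is the doubled
smaller tail of the exact permutation distribution of U (mid-ranks for
ties, both tails including the observed value), enumerated exhaustively
whenever `C(n+m, min(n,m)) ≤ 50,000` — this covers all the few-replicate
versus expanded-control comparisons the pipeline performs. Beyond that,
the tie-corrected normal approximation with continuity correction is
used (the two branches agree within 0.02 at n = m = 6). The exact branch
is verified against scipy's exhaustive permutation machinery on random
heavily-tied data.

## 5. Classification labels

Per metric (spectrum, SBS counts, indel counts) a group is labelled from
its ERR/LRR significance pattern: exactly early → `ERR`; exactly late →
`LRR`; both → `NA-both` (a genome-wide effect, no RT differentiation);
neither → `NA`. When significant in exactly one state and the other
state's p is at most the marginal threshold (default 0.07), a marginal
flag is set. The heatmap matrix (−log10 corrected/combined p per group ×
metric × state) is a pure function of the result tables and is
re-derivable from them.

## 6. Power simulation

For a condition with observed per-sample burdens in `[b_min, b_max]`,
each of 20 simulated replicate sets draws, per sample slot, a target
burden uniformly from `[b_min, b_max]` and subsamples that many
mutations without replacement from a randomly chosen observed sample of
the condition (donors too small for the target are redrawn). Each set
replaces the condition in the burden table and the *full* two-stage
pipeline — screen, expansion, stage-2 test, BH — is re-run; power is the
fraction of sets significant in ERR or LRR at adjusted p < 0.05 (strict,
deliberately stricter than the main pipeline's ≤). A condition that was
not significant originally but reaches power > 0.5 is flagged
**underpowered**: the observed burden range is compatible with an effect
the replicate structure could not resolve. An alternative reading of
replicate generation — selecting whole observed samples whose burden
lies in range — would concentrate on the observed burden values instead
of interpolating between them; the uniform-target subsampling reading is
implemented because it exercises the full range and is well defined for
singleton conditions.

## 7. Synthetic data generator

The generator emulates the statistical structure of isogenic hiPSC
perturbation screens at desk scale, and its defaults are the conditions
under which the pipeline is validated:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 2 × 500 kb | smallest scale with thousands of sites per trinucleotide per RT class |
| base probabilities | A/T 0.295, C/G 0.205 | human-like 41% GC |
| RT bin width | 10 kb | typical processed Repli-seq resolution |
| RT signal | 5 summed random cosines, wavelengths 5–50 bins | smooth autocorrelated track giving contiguous ERR/LRR blocks |
| controls / replicates | 4 / 2 | a handful of control subclones and 2–4 replicates per condition, as in real screens |
| SBS burden per sample | 3,000 | few-thousand substitutions per subclone genome |
| indel burden | 120 | two orders of magnitude fewer indels than substitutions |
| late/early rate ratio | 2.0 | elevated LRR mutation rate in control cells |
| baseline spectrum | flat floor + C>T peaks at NpCpG + diffuse T>C | deamination-dominated culture spectrum shape |

Placement is **channel-conditional**: a channel is drawn from the
(possibly shifted) spectrum, then a genomic site whose collapsed
trinucleotide matches is chosen uniformly within the target RT class, so
the target spectrum is achieved in expectation regardless of genome
composition and every record's reference allele matches the FASTA by
construction. Class totals are Poisson with expectations proportional to
class bp × class rate; effects multiply the expectation (burden fold)
and/or shift channel mass (spectrum shift `q' = (1−m)q + shift`) only
within their RT restriction. Within a sample, sites are redrawn until
positions are unique. Indels are 1-bp deletions/insertions at random
sites (30% insertions of the site's base, extending its homopolymer).
All randomness flows from one root seed through named substreams (genome
first, then samples in manifest order), so regeneration from the
manifest is byte-identical.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: biological inter-clone overdispersion
beyond Poisson/multinomial noise, clonal substructure and shared
subclonal variants, mappability/callability artifacts, realistic human
genome composition (repeats, CpG islands, isochores), doublet
substitutions, and RT profiles with cell-cycle structure beyond smooth
autocorrelation. In real data the control-only bootstrap is *more*
anti-conservative than here, because real controls are overdispersed
relative to their pooled counts.

## 8. Validation experiments and problem sizes

The acceptance experiments (`rtmut.validation`, run by
`tests/test_acceptance.py` at seed 0 and re-run from scratch by
`scripts/acceptance.py` at the caller's seed) use: a 20-group pure-null
cohort (4 controls, 2 replicates/group, 3,000 mutations/sample,
B = 2,000) for null calibration; twenty 6-sample cohorts with a
0.25-mass late-restricted channel shift (5,000 mutations/sample) for
spectrum recovery; one cohort with 0.4× late and 3× early burden folds
(4 replicates/group, six neutral groups feeding the expanded controls)
for burden recovery; 1,000 random vectors and 200 random tied datasets
for the BH and Mann-Whitney oracles; a constructed strong (4×) and a
heterogeneous moderate condition (replicates at 0.90×, 1.4×, 2.6× the
control burden, eight neutral groups) for the power machinery — the
moderate condition's straggler replicate keeps the original rank test
non-significant while most simulated replicate sets reach significance,
firing the underpowered flag; and one full cohort for the conservation
suite. These sizes keep every experiment to seconds-to-minutes on one
CPU while leaving the measured properties far from their thresholds.

Note that the single-cohort KS uniformity diagnostic retains a
cohort-level random effect (all samples share one estimated centroid and
one null curve), so its p-value varies substantially across seeds even
for a perfectly calibrated test; the many-cohort uniformity property in
the unit suite is the sharper check.

## 9. Other numerical choices and degenerate inputs

- Empty profiles cannot be normalized or tested (error); controls with
  zero mutations abort null fitting naming the sample.
- An RT track with fewer than two distinct values has no meaningful
  median split (error), as does an empty region set for trinucleotide
  counting.
- `B` not divisible by the number of controls: remainder replicates are
  assigned round-robin, preserving equal contribution up to one.
- BH adjustment is the step-up `min_{j≥i} p_(j)·m/j` capped at 1,
  monotone in every raw p.
- MAF/VCF rows with unparseable coordinates or symbolic alleles are
  skipped and counted, never silently dropped; a missing mandatory MAF
  column is an error naming the column.
- Chromosome names are matched after stripping a `chr` prefix across
  FASTA, MAF and bedGraph inputs.
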