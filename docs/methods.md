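# Methods

This note documents the models, conventions and design choices behind
`cnvburden`, in the spirit of the methods documentation of simulation and
statistics packages: what each procedure assumes, which parameters matter,
and what the synthetic-data tests do and do not demonstrate.

## Data model and coordinate conventions

All internal coordinates are 0-based half-open. Formats convert at the
I/O boundary only: BED is read/written as is; VCF `POS` (1-based) becomes
`start = POS − 1` with `INFO/END` taken as the half-open end (so internal
length equals the 1-based inclusive length `END − POS + 1`); the PLINK
six-column CNV layout is emitted 1-based inclusive (`BP1 = start + 1`,
`BP2 = end`) with the `chr` prefix stripped.

Copy-number status is restricted to {0, 1, 3, 4}; 4 means "four or more
copies". Genotypes map as DEL 0/1 → CN 1, DEL 1/1 → CN 0, DUP 0/1 → CN 3,
DUP 1/1 → CN 4. Copy numbers outside the alphabet clamp to 0 or 4 on
ingest; CN 2 (diploid) is rejected — it is not a CNV. A call from a
genotyped VCF counts as passing only when both the site FILTER and the
per-genotype FT field (when present) are PASS; the VCF reader keeps
failing records with `filter_pass=False` rather than dropping them, so
filtering decisions remain visible. Multi-allelic records are split per
ALT before mapping; non-DEL/DUP symbolic ALTs (e.g. `<INV>`) are skipped
and counted.

## Coverage QC

A *repetitive-free region* is a window (default 20 kb) in which every
fully-contained k-mer (default k = 25) occurs exactly once in the entire
reference. Uniqueness is strand-agnostic: a k-mer and its reverse
complement are one object (sequencing reads come from both strands).
k-mers containing ambiguous bases disqualify their window. The
implementation encodes bases 2-bit and hashes windows vectorially; the
test suite checks it against an independent pure-Python hash-table census.

Region placement is deterministic and documented because any qualifying
window is statistically equivalent: the chromosome is partitioned into
`regions_per_chromosome` equal bins, each bin contributes the leftmost
qualifying window starting in it that does not overlap a previous choice,
and a greedy left-to-right scan fills leftover slots. The region count is
best-effort — short or repeat-dense chromosomes yield fewer, and a
chromosome with none has undefined coverage and is excluded from the
sample statistics.

Chromosome coverage is the mean per-base depth over the union of that
chromosome's regions, read from a bedGraph-style depth track (a deliberate
substitution for alignment files: step-function depth is sufficient for
every computation here and keeps the module testable at desk scale).
A chromosome is an outlier when its coverage deviates from the
across-chromosome median by more than `outlier_fraction` (default 0.25,
chosen midway between the euploid expectation of 0 and the ±0.5 deviation
of trisomy/monosomy). The sample mean and standard deviation are computed
over non-outlier chromosomes; the sd is the population form (the
chromosomes are the whole population of interest, not a sample from one).
A sample fails QC iff sd > 0.15 × mean, strict inequality. The verdict is
scale-invariant, and aneuploidy surfaces as an outlier chromosome rather
than a failed sample. Sex chromosomes receive no special treatment;
exclude them from the input if sex composition matters.

## Harmonization

The proximity merge collapses same-type calls whose start positions *and*
end positions each differ by at most `max_breakpoint_distance` (default
100 bp), with single-linkage transitivity — a simple, stated stand-in for
the positional clustering of SV merging tools, not a replica of any of
them. A merged call spans the earliest start to the latest end of its
members, keeps the most extreme copy state (min for DEL, max capped at 4
for DUP), and lists contributing callers.

Consolidation then makes each sample's list non-overlapping: same-type
segments that overlap or are book-ended merge into their union (gap
threshold configurable, default 0); wherever a merged deletion and merged
duplication still overlap, *both whole segments* are removed. Removing
the entire extent rather than the intersection avoids fabricating
breakpoints no caller reported; the intersection-only alternative is
deliberately not offered as a default. Consolidation is idempotent and
never increases the event count.

## Rare-CNV filtering

The frequency filter reimplements `--cnv-freq-exclude-above N
--cnv-overlap 0.5` semantics: for every base, count the cohort events of
any type covering it (the event under test included, so N tolerates
exactly N carriers); exclude an event iff the fraction of its length on
bases with count > N strictly exceeds 0.5. N defaults to
⌊frequency × n_samples⌋ (frequency 0.01), validated against the cohort
sizes 3,800 → 38, 978 → 9, 1,247 → 12 and 1,566 → 15. Counting is
type-agnostic by default. The implementation sweeps
coordinate-compressed breakpoints; tests compare it against an explicit
per-base count-array oracle.

Mask residence is strict: a rare CNV must be 100% covered by the union of
P-class intervals ("reside in" is read as containment, not majority
overlap). Events on chromosomes absent from the mask are excluded and
counted. The pipeline applies mask before frequency by default; the
opposite order is available since the two stages commute only in what
they report, not in which events reach the second stage.

## Burden analysis

Per-sample features per event class (DelDup, Del, Dup): event count,
an indicator of ≥ 1 event (its group mean is the proportion of samples
with an event), total length in kb, and average length in kb — undefined
(NaN) for zero-event samples, which are therefore excluded from
average-length statistics; group means of the average-length feature are
means over samples with at least one event.

The permutation test uses the one-sided statistic mean(cases) −
mean(controls), matching burden-tool convention (and the only direction
consistent with reported p-values of exactly 1 for cells where controls
exceed cases); a two-sided mode exists. When C(n, n_cases) ≤ the
permutation budget, label assignments are enumerated exhaustively and
p = #{assignments with statistic ≥ observed}/#assignments (the identity
assignment bounds p away from 0); otherwise p = (1 + exceedances)/(1 + N)
over N seeded uniform relabelings. Ties at the observed value count as
exceeding (a 10⁻¹² absolute guard absorbs float noise). NaN feature
values are ignored within each relabeled group; a permutation in which a
group has no defined value counts as non-exceeding, and a cell whose
observed statistic is undefined is reported unavailable rather than
tested. Covariates are intentionally not modeled: the test is a marginal
comparison.

The grid crosses {all, rare} × 4 features × {DelDup, Del, Dup} ×
{ALL, AA, Hispanic, NHW} = 96 cells; per-cell generator seeds are spawned
deterministically from the master seed, so the grid is bit-reproducible
and invariant to sample relabeling and row order. Significance uses the
Bonferroni threshold α/96 (0.000521 at 3 significant figures for
α = 0.05). Groups without samples, cases or controls keep their cells in
the output flagged unavailable.

## Concordance

Recall of a primary callset by a secondary one: a primary call is
recalled under "1bp" when any secondary call overlaps it, and under a
fractional criterion f when the *union* of secondary overlap covers at
least f of its length. Union coverage makes the result invariant to
splitting secondary calls into book-ended pieces and explains the
asymmetry of real cross-project comparisons (a short call inside a long
one is fully covered; the converse is not). Matching is type-agnostic by
default, as cross-project checks are usually run on plain intervals;
type-aware matching is a flag. Reciprocal overlap is intentionally not
the default.

## Synthetic data

The generator emulates, per seed: an i.i.d. random reference (optionally
with implanted duplicated blocks so the uniqueness scanner has repeats to
avoid); a pool of mutually non-overlapping CNVs with log-normal lengths
and Beta-distributed allele frequencies; per-sample genotypes drawn
Binomial(2, af); pseudo-callers applying Bernoulli missed calls, rounded
Gaussian breakpoint jitter and book-ended split calls; per-base Poisson
depth with per-chromosome aneuploidy multipliers; a tiled accessibility
mask; and phenotypes with an optional Poisson-distributed private
duplication excess in cases.

Default conditions (chosen once as a desk-scale analogue of a large WGS
cohort): 200 samples / 100 cases on a 700-kb two-chromosome genome; a
120-CNV pool with log-normal lengths of median 1 kb (sd 1 log unit,
capped at 5% of the largest chromosome — WGS CNV callsets are dominated
by small events, and the cap keeps the pool placeable on a small genome);
allele frequencies Beta(0.4, 3.6), skewed rare; three pseudo-callers with
jitter sd 50 bp, 5% missed calls, 5% split calls; 37× mean depth (the
coverage scale of large sequencing efforts); mask classes
P/N/L/H/Z = 89/5.3/1.4/0.6/3.7%; burden effect 0 (null). The worked
power setting injects 16 extra duplications per case — the magnitude of a
reported real-cohort duplication burden — at 200 vs 200 samples.

What the simulation does *not* model: GC bias and mappability-correlated
depth, linkage between CNVs, population structure beyond group labels,
breakpoint-imprecision correlated across callers, and read-level data.
Passing tests therefore demonstrate the pipeline's arithmetic and
statistical behaviour, not caller accuracy on real genomes.

### A note on truth recovery through harmonization

Because a merged call spans the earliest start and latest end of its
members, each merged breakpoint is the extreme of roughly three
independent jitters. P(|min of 3 N(0, σ)| > 2σ) ≈ 6.5%, so the fraction
of truth events recovered with both breakpoints within 2 jitter-sd has a
ceiling near 87% regardless of σ (measured 86.7–88.1% across seeds at
n ≈ 3,000); at 3σ tolerance recovery exceeds 98%. The recovery property
test asserts bounds derived from this analysis (≥ 80% at 2σ, ≥ 93% at
3σ).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the package's
defaults: references up to ~200 kb for k-mer census cross-checks,
cohorts of 200–400 samples, 2,000–4,000 Monte-Carlo permutations per
grid cell (minimum resolvable p = 1/(N + 1); 4,000 permutations resolve
2.5 × 10⁻⁴, below the 96-test Bonferroni threshold), 20 replicates for
the power property and 1,000 replicates for type-I-error calibration
(5v5 exhaustive enumeration, 252 assignments each).

## Known limitations

* The proximity merge is a stated stand-in for dedicated SV merging tools
  and does not claim to replicate their output.
* Frequency filtering approximates PLINK's region semantics per base;
  pathological fragmented-event configurations could differ from PLINK's
  segment bookkeeping.
* The exhaustive permutation path enumerates C(n, k) assignments and is
  only engaged when that count fits the permutation budget.
* Depth input is a step-function track; extracting depth from CRAM/BAM is
  out of scope.
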