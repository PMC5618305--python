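# Methods

`mirloop` quantifies how the nucleotide composition of pre-miRNA *terminal
loops* — the unpaired apical region of the precursor hairpin, the docking
platform for processing regulators such as Lin28 (GGAG element) and KSRP
(AGGGU element) — differs between a set of miRNAs of interest (for example
miRNAs repressed after 17β-estradiol exposure) and the background of all
precursors. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmarks do and
do not demonstrate.

## Secondary structure model

Precursors are folded by **maximum base pairing** over nested structures
(a Nussinov-style dynamic program): among all pseudoknot-free structures
whose pairs are drawn from {AU, UA, GC, CG} plus, by default, the G·U
wobble, and whose hairpin loops contain at least `min_loop = 3` unpaired
bases, the structure with the most pairs is selected. The model has no
thermodynamic parameters; it is deterministic, dependency-free, and
adequate for miRBase-style hairpins, which are strongly self-complementary
so that the maximum-pairing structure is dominated by the single long stem.
When several structures attain the maximum, the traceback resolves ties by
pairing the leftmost position with the **largest** admissible partner
first (outermost pairing first) and preferring pairing over leaving a base
unpaired, which biases tied solutions toward one long hairpin and makes the
output a pure function of the sequence. Users who want thermodynamic
structures can supply Vienna dot-bracket files (e.g. RNAfold output);
supplied structures always override internal folding.

The DP kernel is JIT-compiled with numba; a ~52-nt hairpin folds in
~0.15 ms, so the statistical benchmarks below (hundreds of thousands of
folds) run in seconds to a few minutes.

## Terminal-loop delineation

The terminal loop is found by walking the stem from the outside in. At each
level the directly nested pairs ("branches") are collected; a single branch
is followed through bulges and internal loops; at a genuine multi-branch
point the branch whose closing helix stacks the most pairs is followed
(`longest_stem` policy, logged) or an error is raised (`error_on_multi`).
Descent stops at the innermost pair of the final stem helix; **everything
it encloses is the terminal loop**.

One refinement matters in practice: a maximum-pairing folder will happily
pair two stray complementary bases inside a genuine apical loop, and a
naive "maximal unpaired run" definition would then report a truncated loop.
We therefore classify a helix of **one or two stacked pairs buried under a
much longer stem** (enclosing helix at least `2·depth + 1` pairs) as
incidental intra-loop pairing: it belongs to the loop, not to the stem.
For clean structures this reduces exactly to the textbook hairpin-loop
definition. Consequence: a `TerminalLoop` is guaranteed to be enclosed by
the closing stem pair, but its bases are not guaranteed unpaired in the
folded structure. Loop coordinates are 0-based half-open internally;
1-based closed only in human-readable reports.

Precursors with no extractable loop (structures with no pairs at all) are
excluded from composition with a logged count — silent exclusion would bias
the composition of what remains.

## Composition

k-word counting follows EMBOSS `compseq` semantics: every overlapping
word (step 1) within each sequence, never across record boundaries. A set's
profile pools raw counts, so sequences are weighted by length, matching
what `compseq` does on a multi-FASTA; unweighted per-sequence averaging is
available (`average=True`) as a sensitivity analysis. Sequences shorter
than k contribute nothing and are counted in a warning.

## Enrichment statistic

For a word w, region r (terminal loop or complete stem-loop) and target
set T inside a precursor universe U, the headline quantity is

    E = 100 · (f_T − f_C) / f_C

where f_T is the pooled fraction of w in the targets' region and f_C the
same for a control set of `n_controls = 50` precursors drawn uniformly
without replacement from U \ T. A single control draw makes E
seed-dependent, so by default the control set is redrawn `n_resamples =
1000` times and f_C is the mean control fraction (`n_resamples = 1`
reproduces the single-draw design).

Two uncertainty statements accompany the point estimate:

* **95% interval.** Each resample combines a fresh control draw with a
  bootstrap resample (with replacement) of the target ids; the 2.5/97.5
  percentiles of the per-resample enrichment therefore reflect *both*
  control-sampling and target-sampling noise. An interval built from
  control redraws alone systematically under-covers, because with ~20
  targets the target fraction is the dominant noise source.
* **Permutation p-value** (one-sided, "target enriched"). The target
  fraction is ranked among the fractions of `n_resamples` target-sized
  sets drawn from the **whole** universe, targets included; under the null
  hypothesis that membership in T is unrelated to composition these sets
  are exchangeable with T, so p = (1 + #{f ≥ f_T})/(n_resamples + 1) is
  uniform by construction. Ranking against the target-*excluding* control
  draws instead would be anti-conservative (their spread understates the
  target's own sampling variability; in simulation that variant rejects a
  true null ~15% of the time at nominal 5%). Pooled fractions live on a
  coarse rational lattice, so ties are broken by a seeded jitter many
  orders of magnitude below the lattice spacing — the standard randomised
  construction that keeps the discrete test exact.

Words absent from all controls are reported with an infinity sentinel
rather than dropped, and 0/0 as NaN. No multiple-testing correction is
applied across the 4 (or 16) words of a panel; the counts are reported raw
and readers should treat borderline p-values accordingly.

## Motif analysis

GGAG and AGGGU are matched exactly with overlapping occurrences. Both
per-loop presence rates and total occurrence counts are reported; presence
is the headline (a loop either offers the binding element or it does not),
with a two-sided Fisher exact test on the presence 2×2 table. Paralog
redundancy can be removed by collapsing each miRNA family to its
lexicographically smallest member; if no family map is supplied, families
are inferred from miRBase naming (strip the species prefix, the paralog
number when a digit remains, and the variant letter), and the heuristic is
logged.

## Expression concordance

Differential expression between two conditions uses a two-sided Welch
t-test per gene (pooled-variance optional; one-way ANOVA across more than
two groups), with Benjamini–Hochberg FDR (statsmodels) and a
significance cut of FDR < 0.05. Direction is the sign of the mean
difference on the assumed log scale — no fold-change threshold. Genes with
zero variance everywhere get a NaN p (flagged, never significant). Two
datasets are compared by the case-insensitive overlap of their significant
genes; among common genes we report the percentage with the same direction
and the percentage up in both. Probe-to-gene mapping and normalization are
upstream of this package: inputs are normalized gene-level matrices.

## Synthetic data: what it emulates and what it does not

`generate_hairpin` builds a precursor as 5′ stem arm (uniform bases) +
loop + reverse-complement 3′ arm. Defaults: `stem_len 22`, `loop_len 8`
(typical miRBase dimensions), `gu_fraction 0.1` — each stem pair whose 5′
base is G or U becomes a G·U wobble with probability 0.1 by mutating the
3′ partner, so real stems' imperfection is partially emulated. Loop bases
are i.i.d. from a specified composition: uniform (G = 0.25) for controls
and G = 0.3110 for the canonical biased cohort, programming a relative
loop-G enrichment of 100·(0.3110/0.25 − 1) = +24.4%, with the +10/+100%
variants available for parameter-recovery studies.

The drawn loop bases are **rearranged, never redrawn**: a
composition-preserving permutation is accepted only if (i) the two loop
ends cannot pair each other (otherwise the stem would extend into the
loop) and (ii) two narrow windows flanking the closing pair cannot pair
their flanks (the only configuration in which new pairs outscore, rather
than tie, the designed closing pair under the tie-breaking above).
Rejection sampling over permutations keeps the accepted ordering uniform
among valid ones, so ordering biases are multiplicative and cancel in
target/control ratios: measured on 1000-hairpin cohorts, the realized
pooled G fraction is unbiased, refolding recovers the designed loop
interval in ≥ 99% of hairpins, and measured G and GG enrichments sit at
the programmed +24.4% and (1.244² − 1) = +54.7%. Because loop bases are
(conditionally) independent, dinucleotide enrichment follows from
mononucleotide enrichment by squaring — a built-in cross-check, and the
reason GG enrichments run roughly double the G enrichments.

What the generator does **not** emulate: thermodynamic stem stability,
bulges and internal loops in the stem, length variation among precursors,
phylogenetic correlation between family members, or any dinucleotide
structure in real loops. Passing the synthetic benchmarks therefore shows
that the pipeline measures what was programmed with honest uncertainty —
not that real terminal loops are i.i.d., nor that a particular biological
cohort's enrichment is correct.

`generate_expression` emulates two independent two-condition experiments
(default 5 samples per group, 2000 genes, i.i.d. Gaussian noise σ = 0.5 —
typical replicate-level noise of a normalized log-scale array) sharing 200
differentially expressed genes shifted by ±2; the second experiment keeps
each gene's direction with a programmed probability (default 0.82). At
these defaults a shifted gene is reliably detected (≥ 80% recall at
FDR < 0.05), which makes overlap and concordance recovery well-posed;
microarray noise beyond i.i.d. Gaussian is out of scope.

## Benchmarks run by `scripts/acceptance.py`

With one CPU the script takes about a minute, dominated by the null
calibration. Problem sizes: 200 random sequences (≤ 14 nt) against the
exhaustive folding oracle; 100 random sequences × k ∈ {1..4} against a
regex counting oracle; 1000 null cohorts (20 pseudo-targets in a universe
of 200, 199 permutations each) for test calibration; 100 cohorts at the
programmed +24.4% (20 targets, 500 resamples) for point recovery and
interval coverage; one 1000-target cohort for the GG cross-check; 1000
random p-vectors against the step-up FDR definition; and one paired
expression simulation at programmed 82% concordance.

## Known limitations

* Max-pairing folding is a structural caricature; for real analyses,
  supply RNAfold structures via the dot-bracket override when exact loop
  boundaries matter.
* The enrichment interval is a percentile bootstrap; with fewer than ~10
  targets it becomes ragged and the permutation p-value is the more
  trustworthy statement.
* Multi-branch precursors are resolved by the longest-stem heuristic; the
  affected count is logged and such cases deserve manual inspection.
* Family inference from id naming is a heuristic; supply an explicit
  family map for publication-grade family-collapsed counts.
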