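# mirloop

Terminal-loop composition and enrichment analysis for miRNA precursor
hairpins.

Widespread miRNA repression — after estrogen exposure, after cigarette
smoke, and in many cancers — has been linked to the guanine content of the
precursor's *terminal loop* (TL): the unpaired apical region of the
pre-miRNA hairpin where regulators such as Lin28 (GGAG element) and KSRP
(AGGGU element) dock, and where reactive metabolites can form guanine
adducts that disturb Drosha/Dicer processing. `mirloop` is for
computational biologists who want to test, reproducibly, whether a set of
co-regulated miRNAs has unusual terminal-loop composition: it folds
precursors, delineates their terminal loops, profiles k-word composition,
and quantifies enrichment against randomly drawn control miRNAs with
resampling-based uncertainty — plus motif scanning and a cross-dataset
differential-expression concordance stage.

## The statistic

For a word w (say G, or GG), target set T and precursor universe U, the
package reports the relative enrichment

    E = 100 · (f_T − f_C) / f_C

where f_T is the pooled fraction of w among the targets' terminal loops
(or complete stem-loops) and f_C is the mean of the same fraction over
repeatedly redrawn 50-miRNA control sets from U \ T. Uncertainty comes
from a 95% percentile interval that combines fresh control draws with a
bootstrap of the target set, and a one-sided permutation p-value that
ranks f_T among target-sized sets drawn from the whole universe
(exchangeable under the null, hence exactly calibrated). Folding is
maximum base pairing (Nussinov dynamic program, G·U wobble allowed,
minimum loop 3); a supplied Vienna dot-bracket file always overrides
internal folding. See `docs/methods.md` for the model details and
numerical conventions.

## Worked example

Generate a synthetic cohort with a programmed +24.4% loop-G enrichment
(target loops drawn with G probability 0.3110 against a uniform-composition
universe of 200 hairpins), then run the full analysis:

```
$ mirloop simulate hairpins --n-targets 20 --n-universe 200 --seed 7 --outdir demo
wrote cohort of 200 hairpins to demo

$ mirloop analyze --fasta demo/hairpins.fasta --targets demo/targets.tsv \
      --outdir demo/out --seed 1 --resamples 1000
bundle written to demo/out/bundle.json
config hash c6963a0f931d362c, seed 1
```

The G rows of the mono-nucleotide tables (first columns shown):

```
word  region         target_fraction  control_fraction  relative_enrichment_pct  ci95_low  ci95_high  p_perm
G     terminal_loop  0.3125           0.24771           26.1556                  -9.27518  68.6193    0.045954
G     stem_loop      0.264423         0.25797           2.50164                  -6.20439  11.2881    0.295704
```

Reading: the target terminal loops are 31.25% G versus 24.77% in the
resampled controls — a relative enrichment of +26.2%, whose interval
brackets the programmed +24.4% and whose permutation test is significant
at the 5% level. The complete stem-loops show only +2.5% (p = 0.30): the
stem dilutes a loop-restricted signal about 6.5-fold, so a genuine
terminal-loop effect shows exactly this loop-versus-stem contrast. The
run also writes dinucleotide tables, GGAG/AGGGU motif enrichment (with and
without family collapsing), and a `bundle.json` stamped with the seed and
configuration hash; rerunning the same configuration reproduces every
output byte for byte.

The same subcommands work on real data: a miRBase hairpin FASTA, a
target-id list (one id per line, optional tab-separated family), and
optionally an RNAfold dot-bracket file. `mirloop de` and `mirloop concord`
run the expression stage on gene-level TSV matrices.

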