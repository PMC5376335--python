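# Methods

## Model and assumptions

`contextmmia` ranks candidate miRNA–gene edges for a two-class
(control vs. treated) study by the product of an expression-derived
omics score and a literature-derived context score. The method assumes:

- **Paired samples.** The miRNA and mRNA matrices share the same sample
  columns in the same order; Pearson correlation across samples is
  meaningless otherwise.
- **Repression shows as negative correlation.** A functional
  miRNA–target edge produces anti-correlated log2 expression. Pairs
  with $r \ge 0$ are removed outright, so the method cannot rank
  activating or indirect relationships.
- **Differential expression carries the condition signal.** Both
  endpoints of a relevant edge should differ between classes; the DE
  cutoff is applied *before* pairing, so an edge whose miRNA or gene
  misses the cutoff is never scored.
- **Literature relevance is summarized by non-negative scores.** The
  context score consumes an offline table of (keyword, entity) scores
  plus per-entity self scores; the text-mining system that produces
  such scores is outside the package. Entities absent from the table
  score 0 and simply receive no literature weight — they still rank by
  their omics score whenever any competing entity also lacks signal.

## Pipeline and scores

1. **Differential p-values.** Welch's two-sample t-test per entity on
   log2 values (linear matrices are log2(x + pseudocount) transformed,
   pseudocount 1.0). Welch is the default because it is assumption-light
   for small, possibly unequal-variance groups; any two-class p-value
   function can be substituted through the `test` hook of
   `differential_pvalues`. Zero-variance entities with equal class means
   get p = 1; with unequal means they get the clamp floor. No
   multiple-testing correction is applied by default (selection uses raw
   p-value cutoffs); a Benjamini–Hochberg option exists
   (`fdr_correct=True`).
2. **DE selection.** Strict p < cutoff, default 0.1 for both molecular
   classes; 0.05 is the conventional stricter preset. Strictness at the
   boundary makes `select_de({"a": 0.1}, 0.1)` empty by design.
3. **Differential scores.** diff = −log2(p) with p clamped at 1e−300 so
   underflowed p-values cannot produce infinities. diff_n is min–max
   normalized **within molecular class over the DE-selected set** —
   only selected entities enter downstream scoring, so they are the
   natural normalization population.
4. **Candidate pairs.** Database edges restricted to DE endpoints, in
   deterministic lexicographic order. Multiple database files merge by
   union by default (any support counts); intersection is available.
5. **Correlation filter.** Pearson r of log2 expression pooled over
   *all* samples of both classes — the class contrast itself
   contributes to the anti-correlation signal the score looks for. Pairs
   with undefined correlation (zero variance) are dropped with a logged
   reason rather than given r = 0, so an undefined value can never pass
   the strict r < 0 filter.
6. **Context posteriors.** Likelihood log2(score+1) and prior
   log2(self+1) are min–max normalized over the **denominator set**: the
   miRNAs (resp. genes) that still appear in at least one negatively
   correlated candidate pair. The posterior then ranks exactly the
   entities that compete in the final list. If every
   likelihood × prior product is 0 (no literature signal at all),
   posteriors are set to 0 instead of dividing by zero; all final
   scores are then 0 and the report order degrades to the omics score,
   with a prominent warning.
7. **Ranking.** Score = OS × CS, sorted descending; ties broken by OS
   descending, then (miRNA, gene) lexicographic — a package convention
   chosen to make output byte-reproducible. Ranks are 1-based.

## Numerical choices and degenerate inputs

- **Min–max degenerate case.** When all inputs coincide the normalized
  value is defined as 1.0 (not 0.0) everywhere this normalization is
  used, so a single surviving entity does not annihilate every product
  it enters.
- **p-value clamp** at 1e−300; **correlation clipped** to [−1, 1]
  against floating-point excursions.
- **Report floats** are written at 6 significant digits; writing,
  re-reading and writing again is byte-identical.
- Entity names are canonicalized by trimming, case-folding and
  (configurable) stripping of the `hsa-` species prefix. Arm-level
  naming (miR-155 vs miR-155-5p) is *not* resolved: mismatched names
  fail to match and are logged, which can cost validated-pair hits but
  avoids guessing nomenclature.

## Synthetic study generator

`generate_dataset(SyntheticSpec(...))` emulates the data structure the
method assumes. Defaults: 10 control + 10 treated samples, 30 miRNAs,
200 genes, 15 true interactions, treated-class log2 shift 2.0 for true
miRNAs, repression slope −0.8 linking each true gene to its miRNA,
per-sample noise SD 0.5, 300 decoy database edges, exponential
literature background (mean 5) with an 8× multiplicative boost for
true-pair entities under the matched keyword. Expression is simulated
directly on the log2 scale to decouple the generator from the
pipeline's transform. At these defaults, >90% of true miRNAs pass
p < 0.1 and >90% of true pairs are negatively correlated (checked in
the test suite over 20 seeds), so the generator measurably satisfies
the method's assumptions while leaving room for realistic misses.

What the generator does **not** emulate: probe-level noise models,
correlated gene modules, batch effects, many-to-many targeting,
arm-specific miRNA naming, or document-level literature structure.
Passing recovery tests on this generator shows the scoring machinery
ranks edges with the assumed structure highly; it does not certify
performance on real microarray or sequencing studies.

## Rank evaluation convention

Recovery of injected true pairs is summarized by their median rank as a
fraction of the **candidate universe** (all database edges considered),
with pairs eliminated by filtering counted below every ranked pair.
Filtering is aggressive by construction — in a default study only a few
dozen of the 315 database edges survive, and the true pairs are a large
share of the survivors — so a fraction of the survivors alone would be
dominated by the true pairs themselves and could not distinguish a good
ranker from a bad one. At the defaults the measured median fraction is
about 4% of the universe.

Keyword sensitivity reruns only the context stage (omics scores are
cached), and the matched-vs-mismatched comparison across seeds uses a
one-sided sign test on per-study mean true-pair ranks.

## Known limitations

- The context score depends entirely on the quality and coverage of the
  supplied literature table; a keyword absent from the table silently
  yields an omics-only ranking (with a warning).
- Posteriors compare only the entities surviving the expression filter,
  so a pair's context score changes when unrelated pairs enter or leave
  the analysis — that is inherent to the Bayes normalization, not a
  bug.
- Correlation over ~20 samples is noisy; decoy edges with accidental
  negative correlation do enter the list and are down-weighted only by
  their scores.
- No paired-sample designs, moderated-variance tests, partial
  correlations or transcription-factor adjustment.
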