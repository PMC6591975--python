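# Methods

## The structural model of a Helitron terminus

Helitrons are Class II transposons that replicate by rolling-circle
replication. Their 5′ end is a bare `TC` dinucleotide, weakly conserved and
frequently multiple per element; their 3′ end is the reliable signature and
consists of two parts:

1. a **GC-rich hairpin**: two inverted-repeat arms (the right arm is the
   reverse complement of the left) around a short loop, believed to act as a
   transposition stop signal;
2. a **`CTRR` terminal motif** (in practice almost always `CTAG`) a few bases
   downstream of the hairpin, flanked by the `AT` target-site duplication.

`heliscan` detects this 3′ signature on both strands of arbitrary nucleotide
sequences, attaches upstream `TC` 5′-end candidates, and counts one record
per distinct (sequence, strand, 3′-end position). Counting 3′ termini rather
than full elements sidesteps the ambiguity of multiple 5′ ends and gives the
quantity used throughout the downstream statistics.

### Scan algorithm

The scanner anchors on terminal-motif occurrences (regular-expression scan
with overlapping matches), then searches upstream of each motif for an
admissible hairpin. The motif stringency is tiered by `fuzzy_level`:
`CTAGT` (0), `CTAG` (1, default), `CTRR` (2), `CT..` (3); each level matches
a subset of the next, so candidate sets shrink monotonically with
stringency. The reverse strand is handled by rescanning the reverse
complement and mapping coordinates back; hairpins are strand-symmetric
objects, so a minus-strand hairpin maps to a valid forward-strand hairpin.

A hairpin is admissible when

- the arm length is in `[arm_min, arm_max]` (default 6–20 nt),
- the arm contains at least `⌈arm_gc_min · arm_len⌉` S (G/C) bases
  (default 80 %) and begins and ends with a run of at least `arm_edge_s` S
  bases (default 2),
- the right arm is the exact reverse complement of the left arm,
- the loop is `loop_min`–`loop_max` nt (default 2–10); the lower bound
  exists because a 0–1 nt loop cannot physically close a stem-loop,
- the gap between the right arm and the motif is `spacer_min`–`spacer_max`
  nt (default 2–10),
- the whole matched span is free of `N`.

When several hairpins could license one motif the scanner keeps the nearest
(smallest spacer), then the longest arm, then the shortest loop — the
deterministic analogue of leftmost-longest pattern-engine behaviour. The
standalone `find_hairpins` operation applies the same greedy rule in a
non-overlapping left-to-right scan.

### Calibrating the two free structural constants

The arm stringency of the canonical description ("GC-rich") leaves two
constants genuinely open: how the allowed non-S bases may be placed, and the
minimal loop. We fixed both against the published false-positive protocol:
on i.i.d. random genomes at the measured *A. thaliana* composition
(A:T:G:C = 0.319414:0.319033:0.179905:0.180095, 119,667,750 bp) the
published false-positive rate for this class of scanner is ≈ 5.9 % of the
real-genome count (665). With single-base S boundaries and loops from 0 the
scanner measures ≈ 12.6 %; requiring a 2-base S run at each arm boundary and
a minimal 2-nt loop measures 6.0 ± 0.8 % over 192 Mb of random sequence.
Both constants are exposed (`arm_edge_s`, `loop_min`) and the calibration is
repeatable via `heliscan fpr`.

### 5′ ends and the target site

Every `TC` on the candidate strand that starts upstream of the hairpin and
within `upstream_window` (default 20 kb) of the 3′ end is reported, nearest
first. The target-site flag is informational by default
(`require_target_site=False`): it records whether the base directly 3′ of
the motif is `T` and the base directly 5′ of the nearest `TC` is `A`,
because the `AT` preference is biology rather than part of the structural
definition. Full-length output pairs each 3′ end with its nearest 5′ end
only; all 5′ ends are preserved in the `.5.fa` file.

## Genome statistics

- **Density** = (number of distinct 3′ termini) / (genome size in Mb), with
  N bases included in the size. Density is invariant under splitting a
  genome into more records.
- **Dispersion** uses the sample SD (n−1) by default; `ddof=0` is exposed
  because some published per-species aggregates use the population form.
- **Correlation**: `pearson_bootstrap` reports the product-moment r, its
  t-test p, the Fisher-z interval, and a BCa interval from seeded paired
  resampling (default 1000 replicates, seed 1234, via `scipy.stats.bootstrap`).
  The bootstrap p value is not standard anywhere; here it is the doubled
  one-sided fraction of resampled r values on the far side of zero, capped
  at 1.
- **Sliding windows** (1 Mb window, 500 kb step, last partial window kept)
  count each Helitron by its 3′-end position and each gene by its start —
  representative points rather than interval overlap, the simplest reading
  of local density.
- **LDA** is the classic pooled-covariance discriminant on the two features
  (genome size Mb, density) with class-proportional priors (scikit-learn's
  default behaviour); the pooled within-class scatter is checked for rank 2
  and a degenerate fit raises with advice to jitter. On the bundled 36-row
  feature table (34 training genomes from seven species groups, two de novo
  assemblies) self-prediction plus test prediction recovers 36/36.
- **Median-linkage clustering** (WPGMC, Euclidean) comes from
  `scipy.cluster.hierarchy.linkage(..., method="median")`.
- The **chi-square insertion test** compares observed CDS / intron-UTR /
  intergenic counts with expectations proportional to genomic length
  fractions.

## Random genomes and the false-positive rate

`random_genome` draws bases i.i.d. from the supplied frequencies — the
frequencies, not the base order, are what a composition-matched "shuffle"
preserves. Frequencies measured from an assembly with N content sum to
slightly under 1 and are renormalized proportionally. `estimate_fpr` scans
`n` such genomes (seed `s+i` for genome `i`) and reports
100 × mean count / reference count, the reference being the prediction in
the real genome the composition came from. Only 3′ termini are counted, so
the 5′ search is skipped. The bundled reproduction script uses 6 full-length genomes;
per-genome counts are Poisson-like (mean ≈ 40), so 6 replicates put a ~7 %
relative standard error on the estimate.

## Insertion typing and locus markers

A candidate is typed by its 3′-end position: inside any CDS interval →
`CDS`; inside a gene span but outside CDS → `intron/UTR`; else
`intergenic`. Overlap with a gene on either strand counts as genic, and the
single terminus position (not the uncertain full span) is the
representative point. Cross-ecotype loci are keyed by the nearest gene
starting at or downstream of the 3′ terminus on the forward strand within
500 bp (configurable). This is a coordinate computation, not a sequence
alignment: on assembled genomes the two agree wherever the downstream flank
maps uniquely, and coordinate lookup removes the external aligner; callers
with scaffold-level input can substitute their own
ecotype → marker-set mapping into `build_loc_matrix`. Polymorphic loci
(present in some but not all ecotypes) receive `LOC001…` ids in sorted
marker-gene order.

## Association rules

Transactions are ecotypes; items are locus states (`LOC006=1`, `LOC006=0` —
absence is materialized explicitly so rules about missing insertions are
found) plus one phenotype item. Antecedents of size 1 and 2 with a
phenotype consequent (`maxlen = 3` counting the consequent) are enumerated
exhaustively; support, confidence and lift must *strictly* exceed their
thresholds (defaults 0.1 / 0.8 / 1.1). At the relevant scale (tens of
ecotypes, hundreds of loci) exhaustive enumeration is fast and is itself
the correctness reference an apriori-style pruned search would need.
`paired_rules` extracts loci whose presence and absence both carry a
passing single-item rule.

## Synthetic data

`make_planted_genome` writes cassettes
`A|TC…filler…[arm][loop][revcomp arm][spacer]CTAG|T` into a background of
configurable composition. The default A/T-only background cannot form
GC-rich arms or `CTAG`, so the truth table is provably complete and scanner
recovery can be asserted exactly (precision = recall = 1). This
deliberately does not emulate real genomes: no nested or truncated
elements, no GC-rich background noise, no N runs, no element families.
Passing the planted tests therefore demonstrates correctness of the
detection logic, not real-genome sensitivity; specificity on realistic
composition is covered separately by the random-genome FPR harness.
`make_ecotype_matrix` reproduces requested phenotype margins and per-class
carrier counts exactly, so published rule metrics can be reconstructed from
their margins.

## Problem sizes and numerics

The test suite exercises the scanner against a cubic-time brute-force
enumerator on seeded 2 kb sequences (12 seeds × 2 motif levels), checks
strand symmetry and thread-count byte-equality, and runs the
false-positive harness at 3 full-length (119.7 Mb) genomes; the whole
suite completes in under two minutes on one CPU. Bootstrap intervals are
seeded and deterministic. Coordinates are 0-based half-open internally and
1-based inclusive in all emitted formats. Inputs are uppercased before
scanning; any candidate span containing `N` is discarded.

## Known limitations

- No autonomous/non-autonomous classification (no Rep/helicase homology
  search) and no family clustering of elements.
- The hairpin definition requires exact reverse-complement arms; G·U-style
  wobble pairing and bulged stems are not modelled.
- Marker assignment is coordinate-based and assumes chromosome-scale
  annotation coordinates.
- Full-length records are the nearest-5′ guess; true element boundaries may
  differ when 5′ ends are eroded.
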