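# heliscan

Structural annotation of **Helitron** transposons and whole-genome
Helitron-density analytics.

Helitrons are Class II DNA transposons that move by rolling-circle
replication. Their 5′ ends (`TC`) are poorly conserved and often multiple,
but the 3′ end carries a reliable structural signature: a GC-rich hairpin
(exact inverted-repeat arms of 6–20 nt around a 2–10 nt loop) followed
2–10 nt later by a `CTRR` terminal motif, almost always `CTAG`, inside an
`AT` target site. `heliscan` detects this signature on both strands of any
FASTA input and counts one record per distinct 3′ terminus.

The count of 3′ termini divided by genome size — the **Helitron density**,
in elements per Mb — turns out to be stable across assemblies and ecotypes
of one species while genome size and raw counts vary, which makes the
(genome size, density) plane usable for species classification. The package
therefore pairs the scanner with the analyses that use its output:

- per-genome density, dispersion and seeded BCa-bootstrap correlation;
- false-positive estimation on composition-matched i.i.d. random genomes;
- linear discriminant species classification and median-linkage clustering
  on (genome size, density);
- sliding-window (1 Mb / 500 kb) Helitron-vs-gene density profiles;
- insertion typing (CDS / intron-UTR / intergenic) against GFF3/GTF gene
  annotation with a chi-square randomness test;
- nearest-downstream-gene locus markers, cross-ecotype presence/absence
  matrices, and association-rule mining (support / confidence / lift)
  between insertion polymorphisms and a categorical phenotype such as
  flowering time.

Deterministic synthetic-data generators (planted Helitron cassettes, toy
annotations, ecotype matrices with exact margins) make every analysis
testable offline; see `docs/methods.md` for the model, parameter defaults
and their calibration, and known limitations.

## Worked example

Plant five canonical cassettes (`A|TC…[arm][loop][rc-arm][spacer]CTAG|T`)
in an A/T background and scan:

```python
from heliscan import PlantSpec, make_planted_genome, scan_genome, summarize

rec, truth = make_planted_genome(
    PlantSpec(n_cassettes=5, background_length=8000, seed=11)
)
cands = scan_genome([rec])
print(summarize(cands, [rec]).to_string(index=False))
c = cands[0]
print(c.id, c.strand, c.end3_pos, c.end3_motif,
      c.five_prime_positions, c.target_site_ok)
```

```
 n_sequences  total_bases  n_helitrons  density
           1         8000            5    625.0
synth1H1 + 189 CTAG [41] True
```

All five planted termini are recovered (density 5 / 0.008 Mb = 625 per Mb
on this toy genome). The first candidate is a forward-strand terminus whose
`CTAG` ends at base 189, with one 5′ `TC` at base 41 and intact `AT`
target-site evidence. The same scan from the shell writes the four standard
outputs (3′-end FASTA, 5′-end FASTA, full-length FASTA, GFF3) plus a run
manifest:

```bash
heliscan scan genome.fa -o out        # out.3.txt out.5.fa out.full.fa out.gff3
heliscan classify --train features.tsv --test denovo.tsv
heliscan fpr --seed 1 --n-genomes 3 --length 12000000
heliscan rules matrix.tsv --phenotype-col FT
```

The package bundles two published reference tables
(`heliscan.datasets.load_genome_features()`, 36 genomes from seven species
groups, and `load_ecotypes()`, 18 *A. thaliana* ecotypes with flowering
times) used by the classification and association examples.

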