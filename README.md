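# mitokit

A toolkit for the routine data-preparation and descriptive-statistics
steps of mitochondrial phylogenomics. It is aimed at evolutionary
biologists who assemble complete-mitogenome datasets of protein-coding
genes (PCGs) for tree inference and who report the standard
compositional summaries alongside: strand asymmetry skews and codon
usage. `mitokit` automates three tracks:

* **pipe** — build a codon-aware phylogenomic supermatrix from per-gene
  FASTA files: pre-flight sanity checks, protein-guided retro-alignment
  of each gene (align the translations, then thread the original codons
  back through the protein gap pattern so reading frame is preserved by
  construction), Gblocks-style removal of hypervariable or
  gap-containing regions in whole-codon units, concatenation over the
  shared taxon set, and a PartitionFinder2 configuration seeding one
  partition per gene × codon position (39 charsets for the 13 canonical
  PCGs with all positions, 26 with first+second only).
* **skew** — per-genome compositional statistics over the J- and
  N-strand gene concatenations: AT% (strand independent), AC% (J), GT%
  (N), and the signed skews by codon position

      AT skew = (A − T) / (A + T)        CG skew = (C − G) / (C + G)

* **codon** — amino-acid usage frequencies by strand class (J, N, all)
  and per-genome relative synonymous codon usage,
  RSCU(c) = count(c) · k / Σ_family counts, where k is the synonymous
  family size under the chosen NCBI genetic code.

Tables are tab-separated; figures adapt their level of detail to the
number of genomes (per-genome bars and colour coding up to 20 genomes,
frequency polygons / boxplots above). A deterministic synthetic-data
generator (`mitokit.fixtures`) emulates both input layouts and can
inject sanity violations at recorded locations; it drives the test
suite and the `make-demo` subcommand.

## Worked example

```bash
mitokit make-demo -o demo --taxa 6 --seed 7     # synthetic 13-PCG dataset
mitokit pipe  -i demo/genes.zip   -o out_pipe  --code 5 --positions 3
mitokit skew  -i demo/strands.zip -o out_skew  --code 5
mitokit codon -i demo/strands.zip -o out_codon --code 5
```

`out_pipe/supermatrix.phy` starts with `6 11175` — 6 taxa by 11 175
aligned sites (3 725 codons survived block filtering). The companion
`partitionfinder.cfg` contains 39 charsets such as

```
atp6_pos1 = 1-667\3;
atp6_pos2 = 2-668\3;
atp6_pos3 = 3-669\3;
```

i.e. a stride-3 site sampling per codon position of each gene, ready
for partitioned model selection. `out_skew/base_percentages.tsv` begins

```
genome   at_pct   ac_pct   gt_pct
taxon01  67.8830  43.2692  55.4088
```

— this genome's PCGs are 67.9 % A+T overall, with the J-strand genes
43.3 % A+C and the N-strand genes 55.4 % G+T. The long-format skew
table reports, e.g., `taxon01 J 2 -0.4862 0.1230`: at second codon
positions of J-strand genes, T strongly outnumbers A (AT skew −0.49)
while C slightly outnumbers G. `out_codon/rscu.tsv` rows like
`taxon01 AAA K 83 1.4188` say lysine is encoded by AAA 83 times,
1.42× the uniform-usage expectation within the AAA/AAG family.
Figures land next to the tables (`basecomp.*`, `skews_pos{1,2,3}.*`,
`aafreq.*`, one `rscu_<genome>.*` per genome).

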