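# Methods

## Scope and model of the data

`mitokit` treats a mitogenome dataset as per-gene stacks of coding
nucleotide sequences: one FASTA per protein-coding gene (PCG), headers
being taxon names shared across files. For compositional analyses the
genes additionally carry a strand label, J (majority coding strand) or
N (minority), taken from the input folder layout. Sequences are assumed
to be in coding orientation; no reverse complementing is ever applied.
Translation uses NCBI genetic-code tables (via Biopython's embedded
static tables); the default is table 5, the invertebrate mitochondrial
code (TGA→Trp, AGA/AGG→Ser, ATA→Met). Tables 1, 2, 4, 5, 9, 13, 14 and
all other NCBI nuclear/organellar tables Biopython ships are accepted.

## Sanity rulebook

Four warning classes let the analysis continue: W1 duplicated sequence
strings within a gene; W2 ungapped length deviating from the gene's
mean by strictly more than 2 *sample* (n−1) standard deviations,
skipped for stacks of fewer than 3 sequences where the statistic is
degenerate; W3 internal gaps (stripped); W4 a truncated terminal codon
(1–2 trailing nucleotides removed). Five error classes stop it: E1
malformed archive layout, E2 non-FASTA file, E3 duplicated IDs within a
file, E4 non-IUPAC characters, E5 an internal stop codon. A single
terminal stop codon is not an error; it is stripped before downstream
use (so two trailing stops leave one internal stop and raise E5). The
cleaned dataset therefore differs from the input only by gap removal,
terminal-codon truncation, and terminal-stop stripping, and re-checking
it raises no W3/W4. Sample rather than population SD was chosen as the
conservative option on small gene stacks; length statistics are
per-gene, since lengths are only comparable within a gene.

## Retro-alignment

Each gene stack is translated and multiple-aligned at the protein
level, then the original codons are threaded back through the protein
gap pattern (each residue becomes its source codon, each gap `---`).
This guarantees frame preservation and byte-exact recovery of inputs on
ungapping, both enforced as invariants. The protein MSA is delegated to
MAFFT (FFT-NS-2, `--retree 2 --maxiterate 0`), which is deterministic
for a fixed input; the contract on this stage is deliberately
scheme-agnostic — equal-length rows whose ungapping recovers the
inputs — so any standard progressive aligner would satisfy it.
Identical stacks and singletons short-circuit to the identity.

## Block filtering

Hypervariable regions are removed in whole-codon units by a
re-implementation of Gblocks-style filtering at the codon level.
Column conservation is assessed on whole codons: with n rows, a column
is *conserved* when its modal codon reaches floor(n·f)+1 rows
(f = 0.5 by default, i.e. a strict majority), *highly conserved* at
ceil(0.85·n), *nonconserved* otherwise; a column containing any gap is
its own class. The filter (strict mode): discard gapped columns;
discard runs of more than 8 contiguous nonconserved(+gapped) columns;
trim each surviving block so it starts and ends on a conserved column;
drop blocks shorter than 10 codons. All thresholds are exposed as
`BlockFilterParams` with the defaults above, which mirror the published
Gblocks defaults mapped to codons; `allow_gaps=True` relaxes the gap
rule. Whole-codon (modal codon) conservation rather than per-nucleotide
scoring keeps the procedure frame-safe and simple. The filter may
return an empty alignment; this is logged, not an error.

## Supermatrix and partitions

Filtered gene alignments are concatenated over the sorted union of
taxa, in lexicographic gene order (so input order cannot matter). A
taxon missing from a gene receives an all-gap segment with a logged
warning; a strict flag turns this into an error. Third codon positions
can be physically removed (width becomes 2/3); partitions are then
expressed in the compacted coordinates, since the model-selection tool
needs coordinates valid in the file actually provided. The partition
scheme is one charset per (gene, kept position): stride-3 ranges
`gene_pos1 = 1-669\3` over each gene's span on the full matrix,
stride-2 after third-position removal. 13 genes hence give 39 or 26
starting partitions. Output coordinates are 1-based inclusive
(PHYLIP/PartitionFinder convention); internally everything is 0-based
half-open. The PHYLIP writer uses the relaxed dialect (full taxon
names, whitespace-sanitised); PartitionFinder2 configuration defaults
are `branchlengths=linked, models=all, model_selection=aicc,
search=greedy`, all overridable, as the tool's manual recommends for a
first pass.

## Skew statistics

Genes are padded per gene with trailing gaps to the gene's maximum
length and concatenated per genome (three matrices: all, J-only,
N-only). AT% is computed on the full concatenation, AC% on J, GT% on N,
each as 100·(relevant bases)/(A+C+G+T counted). AT and CG skews,
(A−T)/(A+T) and (C−G)/(C+G), are computed per strand and codon
position. Gaps and ambiguity codes are excluded from every numerator
and denominator — the alternative, fractional allocation of ambiguity
codes, would be arbitrary. Zero denominators yield NaN, flagged as
undefined rather than silently 0. Codon positions are indexed per gene
*before* concatenation, so padding can never shift frames. Terminal
stop codons present in skew-mode input are kept in the counts (the
input contract is raw coding sequence); sanity cleaning can strip them
upstream if desired.

## Codon usage

Codon counts are taken over successive non-overlapping triplets of the
padded concatenation (frame-safe because cleaned gene lengths are
multiples of 3); triplets containing gaps or ambiguity letters are
dropped. Amino-acid frequencies are computed per strand class (J, N,
all) over non-stop codons and sum to 1 per non-empty class. RSCU is
computed on the pooled all-genes counts regardless of strand:
RSCU(c) = count(c)·k/Σ_family counts with k the non-stop family size.
Families never observed are reported NaN, not 0; single-codon families
have RSCU ≡ 1 when observed, a direct consequence of the formula. Stop
codons are excluded from frequencies and RSCU but retained in the raw
count column for transparency.

## Graphics

The level of detail is a pure function of the genome count and a
threshold (default 20, inclusive): at or below it, base-composition
percentages are grouped bars per genome, skew scatters are
colour-coded by genome, and amino-acid frequencies are genome-coloured
grouped bars; above it, percentages become frequency polygons, skew
points are uncoloured, and frequencies become per-amino-acid boxplots.
Strand is always encoded by marker shape (J = circle, N = triangle);
RSCU always gets one stacked-by-codon figure per genome. Defaults are
PNG at 300 dpi plus PDF. Tests of the figures are structural (mode
selection, panel and file counts, non-empty output); pixel comparisons
would be brittle across rendering backends.

## Synthetic data generator

The generator emulates the two input layouts with the 13 canonical
metazoan PCGs at typical lengths (atp8 53 codons … nad5 573; 3 727
codons total) and typical invertebrate strand assignments
(nad1/nad4/nad4l/nad5 on N). Root sequences are drawn codon-wise from
per-position base weights — defaults are AT-rich with T-heavy second
and strongly AT-rich third positions, as in real invertebrate
mitogenomes — with stop codons rejected; taxa then diverge by i.i.d.
per-site mutation (default rate 0.10 per site, a plausible
between-species divergence for a mixed-rate PCG set) with
stop-creating changes rejected, so fixtures are valid by construction.
Optional features: hypervariable windows (per-site rate ≥ 1 replaces
whole codons, guaranteeing nonconserved columns), terminal length
jitter in whole codons (emulating the small annotation-length
differences real datasets show across taxa), and an injection facility
that introduces each sanity violation at a recorded (gene, taxon,
position) so tests can assert a 1:1 match between injections and
report lines. Because divergence is i.i.d. per codon with no indel
process inside genes, the generator does not emulate phylogenetic
correlation, rate heterogeneity among sites, or true insertions;
passing tests therefore demonstrate the correctness of the accounting
and filtering machinery, not alignment accuracy on hard real data.
Archives are written with fixed zip timestamps, so identical seeds give
byte-identical files.

## Numerical and design choices

* All statistics are exact integer-count ratios in double precision;
  the only tolerances in the tests are 1e-12 (accumulated float error)
  and 1e-9 (frequency normalisation).
* Determinism everywhere: lexicographic gene order, sorted taxon
  unions, fixed aligner settings, a single seed for the generator.
* Problem sizes in the test and acceptance runs (18 genomes at full
  gene lengths for the headline dataset; 2–8 taxa with 10–80-codon
  genes for the property sweeps; 1 000 random matrices for the filter
  oracle) keep the full suite in well under a minute while exercising
  every code path at realistic composition.
* Exit codes of the CLI: 0 success, 1 environment/IO, 2 data sanity —
  chosen for scriptability.
* `.zip`, `.tar`, `.tar.gz` archives and plain directories are
  accepted; `.rar`/`.7z` are not, as no portable reader is available as
  a dependency.

## Known limitations

No frameshift or internal-stop auto-correction (errors stop the run by
design); no tree building or model optimisation — the supermatrix and
partition file are inputs to external tools; no NEXUS output; block
filtering is not byte-identical to the original Gblocks binary (its
exact non-default parameters are not part of the contract and are
exposed as options instead).
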