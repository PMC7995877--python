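"""Amino-acid usage frequencies and relative synonymous codon usage.

RSCU of a codon c encoding amino acid a with synonymous family size k
(number of non-stop codons for a under the genetic code in use) is

    RSCU(c) = count(c) * k / sum over the family of counts,

i.e. the observed count divided by the expectation under uniform usage
within the family.  Stop codons are excluded from both amino-acid
frequencies and RSCU; codons containing gaps or ambiguity letters are
dropped from the counts altogether, matching the deletion of
non-conventional translations from ambiguous nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import pandas as pd

from .core import GAP, GeneSet, GeneticCode, load_genetic_code
from .skew_stats import pad_and_concat

__all__ = ["CodonUsageTable", "count_codons", "aa_frequencies", "rscu", "build_usage_table"]

STRAND_CLASSES = ("J", "N", "all")


def count_codons(concat: Mapping[str, str], code: GeneticCode) -> Dict[str, Dict[str, int]]:
    """Per-genome codon counts over successive non-overlapping triplets.

    Triplets containing gaps or ambiguity codes are skipped.  Stop
    codons are counted (they are excluded later by the usage
    statistics, not by the counter).
    """
    out: Dict[str, Dict[str, int]] = {}
    for genome, seq in concat.items():
        counts: Dict[str, int] = {}
        n = len(seq) - len(seq) % 3
        for i in range(0, n, 3):
            codon = seq[i : i + 3]
            if all(b in "ACGT" for b in codon):
                counts[codon] = counts.get(codon, 0) + 1
        out[genome] = counts
    return out


def aa_frequencies(counts: Mapping[str, int], code: GeneticCode) -> Dict[str, float]:
    """Amino-acid frequencies from codon counts (stop codons excluded).

    Returns an empty dict when no non-stop codon was observed.
    """
    totals: Dict[str, float] = {}
    grand = 0
    for codon, n in counts.items():
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        totals[aa] = totals.get(aa, 0) + n
        grand += n
    if not grand:
        return {}
    return {aa: n / grand for aa, n in sorted(totals.items())}


def rscu(counts: Mapping[str, int], code: GeneticCode) -> Dict[str, float]:
    """RSCU per non-stop codon; NaN for families never observed."""
    out: Dict[str, float] = {}
    aas = sorted({aa for aa in code.codon_to_aa.values() if aa != "*"})
    for aa in aas:
        family = code.family(aa)
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            out[c] = counts.get(c, 0) * k / total if total else float("nan")
    return out


@dataclass
class CodonUsageTable:
    """Per-genome usage summary.

    ``aa_freq``: long DataFrame (genome, strand_class, aa, freq);
    ``codon_table``: long DataFrame (genome, codon, aa, count, rscu)
    with counts and RSCU from the all-genes concatenation, pooled over
    both strands.
    """

    aa_freq: pd.DataFrame
    codon_table: pd.DataFrame
    code_id: int = 5

    @property
    def n_genomes(self) -> int:
        return self.codon_table["genome"].nunique()

    def genome_rscu(self, genome: str) -> pd.DataFrame:
        return self.codon_table[self.codon_table["genome"] == genome]

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {"aa_frequencies": self.aa_freq, "rscu": self.codon_table}


def build_usage_table(data: GeneSet, code: GeneticCode | None = None) -> CodonUsageTable:
    """Compute amino-acid frequencies (J / N / all strand classes) and
    RSCU (all genes pooled regardless of strand) for every genome."""
    code = code or load_genetic_code(data.code_id)
    genomes = data.taxa()
    freq_rows = []
    per_class_counts = {}
    for cls in STRAND_CLASSES:
        concat = pad_and_concat(data, cls)
        per_class_counts[cls] = count_codons(concat, code)
        for genome in genomes:
            freqs = aa_frequencies(per_class_counts[cls][genome], code)
            for aa, f in freqs.items():
                freq_rows.append(
                    {"genome": genome, "strand_class": cls, "aa": aa, "freq": f}
                )
    codon_rows = []
    for genome in genomes:
        counts = per_class_counts["all"][genome]
        values = rscu(counts, code)
        for codon in sorted(values):
            codon_rows.append(
                {
                    "genome": genome,
                    "codon": codon,
                    "aa": code.codon_to_aa[codon],
                    "count": counts.get(codon, 0),
                    "rscu": values[codon],
                }
            )
    return CodonUsageTable(
        aa_freq=pd.DataFrame(freq_rows, columns=["genome", "strand_class", "aa", "freq"]),
        codon_table=pd.DataFrame(codon_rows, columns=["genome", "codon", "aa", "count", "rscu"]),
        code_id=code.table_id,
    )
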