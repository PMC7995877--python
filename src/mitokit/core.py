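"""Shared domain types, NCBI genetic codes, and codon translation.

Sequences are nucleotide strings in coding orientation.  Normalisation
uppercases, maps RNA ``U`` to ``T`` and keeps IUPAC ambiguity letters,
which matter downstream: ambiguous codons are dropped from codon-usage
counts and non-IUPAC symbols are a fatal sanity error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

from Bio.Data import CodonTable

__all__ = [
    "IUPAC_NT",
    "GAP",
    "GeneRecord",
    "GeneSet",
    "GeneticCode",
    "FrameError",
    "UnsupportedCodeError",
    "normalize_seq",
    "load_genetic_code",
    "translate",
]

#: IUPAC nucleotide one-letter codes (unambiguous + ambiguity letters).
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

#: Gap character used throughout.
GAP = "-"

_BASES = "TCAG"


class FrameError(ValueError):
    """Sequence length is not a whole number of codons."""


class UnsupportedCodeError(ValueError):
    """Requested NCBI translation-table id is not available."""


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to T.

    Ambiguity letters and gaps are preserved; validation against the
    IUPAC alphabet is the sanity module's job.
    """
    return seq.upper().replace("U", "T")


@dataclass
class GeneRecord:
    """One taxon's coding sequence for one gene.

    ``strand`` is ``"J"`` or ``"N"`` for the two mitochondrial strands
    (majority/minority coding strand in invertebrate nomenclature) or
    ``"unknown"`` when the input layout carries no strand information.
    """

    taxon: str
    gene: str
    seq: str
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon name must be non-empty")
        if not self.seq:
            raise ValueError(f"empty sequence for taxon {self.taxon!r}")
        self.seq = normalize_seq(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass
class GeneSet:
    """Ordered per-gene stacks of taxon-labelled coding sequences.

    Gene iteration order is lexicographic by gene name.  Duplicate taxa
    within a gene are representable (the sanity check reports them as a
    fatal error); uniqueness is guaranteed only after ``assert_clean``.
    """

    genes: Dict[str, List[GeneRecord]] = field(default_factory=dict)
    code_id: int = 5

    def add(self, record: GeneRecord) -> None:
        self.genes.setdefault(record.gene, []).append(record)

    def gene_names(self) -> List[str]:
        return sorted(self.genes)

    def taxa(self) -> List[str]:
        seen = {r.taxon for recs in self.genes.values() for r in recs}
        return sorted(seen)

    def __iter__(self) -> Iterator[tuple[str, List[GeneRecord]]]:
        for name in self.gene_names():
            yield name, self.genes[name]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: 64-codon map plus stop set."""

    table_id: int
    codon_to_aa: Dict[str, str]
    stop_codons: frozenset[str]
    name: str = ""

    def family(self, aa: str) -> List[str]:
        """Synonymous (non-stop) codons encoding ``aa``, in TCAG order."""
        return [c for c, a in self.codon_to_aa.items() if a == aa and a != "*"]


def _all_codons() -> List[str]:
    return ["".join(c) for c in itertools.product(_BASES, repeat=3)]


def load_genetic_code(table_id: int) -> GeneticCode:
    """Load an NCBI translation table (e.g. 5 = invertebrate mitochondrial).

    Raises
    ------
    UnsupportedCodeError
        If ``table_id`` is not an NCBI nuclear/organellar table known to
        Biopython; the message names the supported ids.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    except (KeyError, ValueError) as exc:
        supported = sorted(CodonTable.unambiguous_dna_by_id)
        raise UnsupportedCodeError(
            f"unsupported NCBI genetic-code table id {table_id!r}; "
            f"supported ids: {supported}"
        ) from exc
    mapping = {}
    for codon in _all_codons():
        mapping[codon] = table.forward_table.get(codon, "*")
    stops = frozenset(table.stop_codons)
    assert stops == {c for c, a in mapping.items() if a == "*"}
    return GeneticCode(
        table_id=int(table_id),
        codon_to_aa=mapping,
        stop_codons=stops,
        name=table.names[0] if table.names else "",
    )


def codons(seq: str) -> List[str]:
    """Split a sequence into consecutive triplets; raises FrameError."""
    if len(seq) % 3:
        raise FrameError(
            f"sequence length {len(seq)} is not divisible by 3"
        )
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(seq: str, code: GeneticCode) -> str:
    """Translate a coding nucleotide string, one letter per codon.

    Codons containing a gap character become ``-`` (needed when
    translating aligned rows); codons containing any other non-ACGT
    symbol become the placeholder ``X``; stop codons become ``*``.
    """
    out = []
    for codon in codons(normalize_seq(seq)):
        if GAP in codon:
            out.append(GAP)
        elif any(b not in "ACGT" for b in codon):
            out.append("X")
        else:
            out.append(code.codon_to_aa[codon])
    return "".join(out)
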