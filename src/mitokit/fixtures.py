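"""Deterministic synthetic mitogenome protein-coding-gene datasets.

The generator emulates the tool's two input layouts: a stack of 13
canonical metazoan PCGs per taxon, with typical invertebrate strand
assignments (nad1/nad4/nad4l/nad5 on the minority N strand, the rest on
the majority J strand).  Root sequences per gene are drawn codon-wise
from per-position nucleotide weights (which therefore set the target
compositional skews); taxa diverge from the root by i.i.d. per-site
mutation with stop-creating changes rejected, optionally elevated
inside declared hypervariable windows.  Everything is reproducible from
the seed, including the bytes of the emitted zip archives.

``inject`` introduces sanity-rulebook violations at recorded locations
so tests can assert that exactly the expected code fires exactly there.
"""

from __future__ import annotations

import copy
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GAP, GeneRecord, GeneSet, GeneticCode, load_genetic_code

__all__ = ["CANONICAL_GENES", "FixtureParams", "Injection", "generate", "inject", "write_archives"]

#: The 13 canonical metazoan mitochondrial PCGs with typical lengths
#: (codons) and invertebrate strand assignment.
CANONICAL_GENES: List[Tuple[str, int, str]] = [
    ("atp6", 224, "J"),
    ("atp8", 53, "J"),
    ("cob", 378, "J"),
    ("cox1", 511, "J"),
    ("cox2", 228, "J"),
    ("cox3", 262, "J"),
    ("nad1", 324, "N"),
    ("nad2", 341, "J"),
    ("nad3", 117, "J"),
    ("nad4", 446, "N"),
    ("nad4l", 96, "N"),
    ("nad5", 573, "N"),
    ("nad6", 174, "J"),
]

#: Default per-codon-position base weights (order A, C, G, T): AT-rich
#: overall, T-heavy second positions, strongly AT-rich third positions,
#: as in typical invertebrate mitogenomes.
DEFAULT_BASE_WEIGHTS: Dict[int, Dict[str, float]] = {
    1: {"A": 0.30, "C": 0.15, "G": 0.25, "T": 0.30},
    2: {"A": 0.20, "C": 0.20, "G": 0.15, "T": 0.45},
    3: {"A": 0.40, "C": 0.10, "G": 0.10, "T": 0.40},
}

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureParams:
    n_taxa: int = 18
    genes: Sequence[Tuple[str, int, str]] = field(
        default_factory=lambda: list(CANONICAL_GENES)
    )
    code_id: int = 5
    base_weights: Dict[int, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BASE_WEIGHTS.items()}
    )
    substitution_rate: float = 0.10
    #: per-taxon terminal length variation: up to this many whole codons
    #: are trimmed from a sequence's end, emulating the small gene-length
    #: differences real annotations show across taxa
    length_jitter_codons: int = 0
    # (gene, 0-based codon start, length in codons, per-site rate)
    hypervariable_windows: List[Tuple[str, int, int, float]] = field(
        default_factory=list
    )
    seed: int = 0
    taxon_prefix: str = "taxon"

    def __post_init__(self) -> None:
        for k, w in self.base_weights.items():
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"base weights for position {k} sum to {total}")
        if not self.genes:
            raise ValueError("at least one gene required")


def _draw_codon(rng: np.random.Generator, probs: List[np.ndarray], code: GeneticCode) -> str:
    for _ in range(200):
        codon = "".join(_BASES[rng.choice(4, p=p)] for p in probs)
        if codon not in code.stop_codons:
            return codon
    raise ValueError("cannot draw a stop-free codon from the given base weights")


def _mutate_codon(
    rng: np.random.Generator,
    codon: str,
    rate: float,
    probs: List[np.ndarray],
    code: GeneticCode,
) -> str:
    if rate >= 1.0:
        # full replacement: hypervariable-window regime
        return _draw_codon(rng, probs, code)
    new = list(codon)
    for i in range(3):
        if rng.random() < rate:
            new[i] = _BASES[rng.choice(4, p=probs[i])]
    mutated = "".join(new)
    if mutated in code.stop_codons:
        return codon  # reject stop-creating change
    return mutated


def generate(params: FixtureParams) -> GeneSet:
    """Generate a clean, strand-labelled GeneSet per the parameters."""
    code = load_genetic_code(params.code_id)
    rng = np.random.default_rng(params.seed)
    probs = [
        np.array([params.base_weights[k][b] for b in "ACGT"]) for k in (1, 2, 3)
    ]
    windows: Dict[str, List[Tuple[int, int, float]]] = {}
    for gene, start, length, rate in params.hypervariable_windows:
        windows.setdefault(gene, []).append((start, length, rate))
    taxa = [f"{params.taxon_prefix}{i + 1:02d}" for i in range(params.n_taxa)]
    gs = GeneSet(code_id=params.code_id)
    for gene, n_codons, strand in sorted(params.genes):
        root = [_draw_codon(rng, probs, code) for _ in range(n_codons)]

        def rate_at(j: int) -> float:
            for start, length, rate in windows.get(gene, []):
                if start <= j < start + length:
                    return rate
            return params.substitution_rate

        for taxon in taxa:
            codon_list = [
                _mutate_codon(rng, root[j], rate_at(j), probs, code)
                for j in range(n_codons)
            ]
            if params.length_jitter_codons:
                trim = int(rng.integers(0, params.length_jitter_codons + 1))
                if trim:
                    codon_list = codon_list[:-trim]
            gs.add(
                GeneRecord(
                    taxon=taxon, gene=gene, seq="".join(codon_list), strand=strand
                )
            )
    return gs


_ZIP_DATE = (1980, 1, 1, 0, 0, 0)  # fixed timestamp => byte-identical archives


def _write_zip(path: Path, entries: List[Tuple[str, str]]) -> Path:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, text in sorted(entries):
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, text)
    return path


def _fasta(records: Sequence[GeneRecord]) -> str:
    return "".join(f">{r.taxon}\n{r.seq}\n" for r in records)


def write_archives(gs: GeneSet, outdir) -> Dict[str, Path]:
    """Write the GeneSet as both input layouts (zip archives).

    ``genes.zip`` holds one FASTA per gene at top level; ``strands.zip``
    holds J/ and N/ folders with the per-gene FASTAs of each strand.
    Byte-identical for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flat = [(f"{gene}.fasta", _fasta(records)) for gene, records in gs]
    stranded = []
    for gene, records in gs:
        strands = {r.strand for r in records}
        if strands - {"J", "N"}:
            raise ValueError(f"gene {gene!r} lacks J/N strand labels")
        for strand in sorted(strands):
            recs = [r for r in records if r.strand == strand]
            stranded.append((f"{strand}/{gene}.fasta", _fasta(recs)))
    return {
        "flat": _write_zip(outdir / "genes.zip", flat),
        "strands": _write_zip(outdir / "strands.zip", stranded),
    }


@dataclass(frozen=True)
class Injection:
    """Ledger entry: what was injected and where (for assertions)."""

    kind: str
    expected_code: str
    gene: str
    taxon: str
    detail: str = ""


_KINDS = (
    "internal_stop",
    "non_iupac",
    "duplicate_seq",
    "duplicate_id",
    "length_outlier",
    "internal_gaps",
    "truncated_end",
)


def inject(data: GeneSet, violations: Sequence[str]) -> Tuple[GeneSet, List[Injection]]:
    """Introduce sanity violations at deterministic recorded locations.

    Each violation kind targets a different gene (cycling through the
    sorted gene list) so the resulting report can be matched 1:1 to the
    returned ledger.  The input GeneSet is not modified.
    """
    out = copy.deepcopy(data)
    genes = out.gene_names()
    ledger: List[Injection] = []
    for i, kind in enumerate(violations):
        if kind not in _KINDS:
            raise ValueError(f"unknown violation kind {kind!r}; known: {_KINDS}")
        gene = genes[i % len(genes)]
        records = out.genes[gene]
        rec = records[min(1, len(records) - 1)]
        if kind == "internal_stop":
            k = len(rec.seq) // 6  # a middle codon, never terminal
            rec.seq = rec.seq[: 3 * k] + "TAA" + rec.seq[3 * k + 3 :]
            ledger.append(
                Injection(kind, "E5", gene, rec.taxon, f"codon {k + 1}")
            )
        elif kind == "non_iupac":
            p = len(rec.seq) // 2
            rec.seq = rec.seq[:p] + "?" + rec.seq[p + 1 :]
            ledger.append(Injection(kind, "E4", gene, rec.taxon, f"site {p + 1}"))
        elif kind == "duplicate_seq":
            donor = records[0]
            if donor is rec:
                raise ValueError("duplicate_seq needs at least two records")
            rec.seq = donor.seq
            ledger.append(
                Injection(kind, "W1", gene, rec.taxon, f"copy of {donor.taxon}")
            )
        elif kind == "duplicate_id":
            records.append(
                GeneRecord(taxon=rec.taxon, gene=gene, seq=rec.seq, strand=rec.strand)
            )
            ledger.append(Injection(kind, "E3", gene, rec.taxon))
        elif kind == "length_outlier":
            keep = max(3, len(rec.seq) // 2 // 3 * 3)
            rec.seq = rec.seq[:keep]
            ledger.append(
                Injection(kind, "W2", gene, rec.taxon, f"truncated to {keep} nt")
            )
        elif kind == "internal_gaps":
            p = len(rec.seq) // 2
            rec.seq = rec.seq[:p] + GAP * 2 + rec.seq[p:]
            ledger.append(Injection(kind, "W3", gene, rec.taxon))
        elif kind == "truncated_end":
            rec.seq = rec.seq[:-1]
            ledger.append(Injection(kind, "W4", gene, rec.taxon))
    return out, ledger
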