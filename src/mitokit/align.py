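"""Protein-guided retro-alignment and codon-aware block filtering.

Each gene stack is aligned at the protein level, the original codons are
threaded back through the protein gap pattern (so the nucleotide
alignment preserves reading frame by construction), and hypervariable
or gap-containing regions are discarded in whole-codon units, in the
spirit of Gblocks run with strict settings in codon mode.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from math import ceil, floor
from pathlib import Path
from typing import Dict, List, Sequence

from Bio import SeqIO

from .core import GAP, GeneRecord, GeneticCode, codons, translate

__all__ = [
    "BlockFilterParams",
    "CodonAlignment",
    "align_proteins",
    "backthread",
    "filter_blocks",
    "kept_codon_indices",
    "retroalign_gene",
]


@dataclass
class CodonAlignment:
    """Equal-length, frame-preserving aligned nucleotide matrix."""

    taxa: List[str]
    rows: Dict[str, str]
    gene: str = ""

    def __post_init__(self) -> None:
        widths = {len(self.rows[t]) for t in self.taxa}
        if len(widths) > 1:
            raise ValueError(f"{self.gene}: unequal row lengths {sorted(widths)}")
        if widths and next(iter(widths)) % 3:
            raise ValueError(f"{self.gene}: alignment width not divisible by 3")

    @property
    def width(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    @property
    def n_codons(self) -> int:
        return self.width // 3

    def codon_column(self, j: int) -> List[str]:
        """Codons of column ``j`` (0-based codon index), one per taxon."""
        return [self.rows[t][3 * j : 3 * j + 3] for t in self.taxa]


@dataclass
class BlockFilterParams:
    """Tuning of the Gblocks-style codon-column filter.

    A codon column is *conserved* when its modal codon is shared by more
    than ``min_conserved_fraction`` of the rows (threshold
    ``floor(n * fraction) + 1``, i.e. a strict majority at the default
    0.5), *highly conserved* at ``ceil(n * high_conserved_fraction)``
    rows, and *nonconserved* otherwise.  With ``allow_gaps=False``
    (strict mode) any column containing a gap is discarded outright.
    """

    min_conserved_fraction: float = 0.5
    high_conserved_fraction: float = 0.85
    max_nonconserved_run: int = 8
    min_block_len: int = 10
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        if not 0.5 <= self.min_conserved_fraction <= self.high_conserved_fraction <= 1:
            raise ValueError("require 0.5 <= min_conserved <= high_conserved <= 1")
        if self.min_block_len < 1:
            raise ValueError("min_block_len must be >= 1")


def _find_mafft() -> str:
    exe = shutil.which("mafft")
    if exe is None:
        raise RuntimeError(
            "the 'mafft' executable is required for protein alignment "
            "but was not found on PATH"
        )
    return exe


def align_proteins(translations: Dict[str, str]) -> Dict[str, str]:
    """Multiple-align amino-acid sequences, preserving input key order.

    Uses MAFFT (progressive FFT-NS-2, deterministic for a fixed input).
    Sequences must be stop-free.  A singleton, or a set of identical
    sequences, short-circuits to the identity alignment.
    """
    if not translations:
        raise ValueError("no sequences to align")
    keys = list(translations)
    seqs = [translations[k] for k in keys]
    if len(set(seqs)) == 1:
        return dict(translations)
    exe = _find_mafft()
    with tempfile.TemporaryDirectory(prefix="mitokit_mafft_") as tmp:
        infile = Path(tmp) / "in.faa"
        with infile.open("w") as fh:
            for i, seq in enumerate(seqs):
                fh.write(f">s{i}\n{seq}\n")
        proc = subprocess.run(
            [exe, "--quiet", "--anysymbol", "--amino", "--retree", "2",
             "--maxiterate", "0", str(infile)],
            capture_output=True,
            text=True,
            check=False,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"mafft failed: {proc.stderr.strip()[:500]}")
        aligned = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(_io_from(proc.stdout), "fasta")
        }
    out = {k: aligned[f"s{i}"] for i, k in enumerate(keys)}
    for k in keys:
        if out[k].replace(GAP, "") != translations[k]:
            raise RuntimeError(f"aligner altered sequence for {k!r}")
    return out


def _io_from(text: str):
    import io

    return io.StringIO(text)


def backthread(
    prot_aln: Dict[str, str],
    nts: Dict[str, str],
    code: GeneticCode,
    gene: str = "",
) -> CodonAlignment:
    """Thread source codons through a protein alignment's gap pattern.

    Every protein gap becomes ``---``; every residue is replaced by the
    codon that produced it, so ungapping a row recovers the input
    nucleotides exactly.
    """
    rows = {}
    for taxon, prow in prot_aln.items():
        nt = nts[taxon]
        if translate(nt, code) != prow.replace(GAP, ""):
            raise ValueError(
                f"protein row for {taxon!r} does not match the translation "
                f"of its nucleotide sequence"
            )
        source = codons(nt)
        i = 0
        parts = []
        for aa in prow:
            if aa == GAP:
                parts.append(GAP * 3)
            else:
                parts.append(source[i])
                i += 1
        rows[taxon] = "".join(parts)
    return CodonAlignment(taxa=list(prot_aln), rows=rows, gene=gene)


def classify_codon_columns(
    aln: CodonAlignment, params: BlockFilterParams
) -> List[str]:
    """Per-codon-column status: 'g' gapped, 'n' nonconserved,
    'c' conserved, 'h' highly conserved."""
    n = len(aln.taxa)
    conserved_min = floor(n * params.min_conserved_fraction) + 1
    highly_min = ceil(n * params.high_conserved_fraction)
    status = []
    for j in range(aln.n_codons):
        col = aln.codon_column(j)
        if any(GAP in codon for codon in col):
            status.append("g")
            continue
        modal = Counter(col).most_common(1)[0][1]
        if modal >= max(highly_min, conserved_min):
            status.append("h")
        elif modal >= conserved_min:
            status.append("c")
        else:
            status.append("n")
    return status


def kept_codon_indices(aln: CodonAlignment, params: BlockFilterParams) -> List[int]:
    """0-based codon-column indices surviving the block filter."""
    status = classify_codon_columns(aln, params)
    m = len(status)
    rejected = [False] * m
    # strict mode: gap-containing codon columns are always discarded
    if not params.allow_gaps:
        for j, s in enumerate(status):
            if s == "g":
                rejected[j] = True
    # long nonconserved stretches (gapped columns count as nonconserved)
    j = 0
    while j < m:
        if status[j] in "ng":
            k = j
            while k < m and status[k] in "ng":
                k += 1
            if k - j > params.max_nonconserved_run:
                for idx in range(j, k):
                    rejected[idx] = True
            j = k
        else:
            j += 1
    # trim candidate blocks so they start/end on a conserved codon,
    # then drop blocks shorter than min_block_len
    kept: List[int] = []
    j = 0
    while j < m:
        if rejected[j]:
            j += 1
            continue
        k = j
        while k < m and not rejected[k]:
            k += 1
        block = list(range(j, k))
        while block and status[block[0]] not in "ch":
            block.pop(0)
        while block and status[block[-1]] not in "ch":
            block.pop()
        if len(block) >= params.min_block_len:
            kept.extend(block)
        j = k
    return kept


def filter_blocks(
    aln: CodonAlignment, params: BlockFilterParams | None = None
) -> CodonAlignment:
    """Discard hypervariable/gapped regions in whole-codon units.

    May return an empty (zero-width) alignment when nothing survives.
    """
    params = params or BlockFilterParams()
    kept = kept_codon_indices(aln, params)
    rows = {
        t: "".join(aln.rows[t][3 * j : 3 * j + 3] for j in kept) for t in aln.taxa
    }
    return CodonAlignment(taxa=list(aln.taxa), rows=rows, gene=aln.gene)


def retroalign_gene(
    records: Sequence[GeneRecord],
    code: GeneticCode,
    params: BlockFilterParams | None = None,
    keep_intermediates: bool = False,
):
    """Full per-gene pipeline: translate, align, back-thread, filter.

    Records must already be sanity-cleaned (frame-correct, stop-free).
    A singleton gene passes through unchanged apart from block
    filtering, which on a single gap-free sequence is the identity for
    sequences of at least ``min_block_len`` codons.

    Returns the filtered :class:`CodonAlignment`; with
    ``keep_intermediates=True`` returns ``(protein_alignment,
    pre_filter_alignment, filtered_alignment)``.
    """
    if not records:
        raise ValueError("empty gene stack")
    gene = records[0].gene
    nts = {r.taxon: r.seq for r in records}
    prots = {t: translate(s, code) for t, s in nts.items()}
    for t, p in prots.items():
        if "*" in p:
            raise ValueError(f"{gene}/{t}: stop codon in sequence to align")
    prot_aln = align_proteins(prots)
    pre = backthread(prot_aln, nts, code, gene=gene)
    filtered = filter_blocks(pre, params)
    if keep_intermediates:
        return prot_aln, pre, filtered
    return filtered
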