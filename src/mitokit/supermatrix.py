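"""Concatenation of per-gene codon alignments and partition-scheme
construction (gene × codon position), with optional removal of third
codon positions.

Coordinates are 0-based half-open internally and 1-based inclusive on
output, following the PHYLIP/PartitionFinder convention.  With 13
protein-coding genes this yields 39 starting partitions when all codon
positions are kept and 26 when third positions are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .align import CodonAlignment
from .core import GAP

__all__ = ["Partition", "Supermatrix", "concatenate", "select_positions", "partition_scheme"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Partition:
    """A charset: a stride-sampled 1-based inclusive site range."""

    name: str
    start: int
    end: int
    stride: int = 3

    @property
    def n_sites(self) -> int:
        """Number of sites the stride-sampled range selects."""
        return (self.end - self.start) // self.stride + 1


@dataclass
class Supermatrix:
    taxa: List[str]
    rows: Dict[str, str]
    # (gene, 0-based start, 0-based end-exclusive) in matrix coordinates
    gene_spans: List[Tuple[str, int, int]] = field(default_factory=list)
    positions_kept: Set[int] = field(default_factory=lambda: {1, 2, 3})
    partitions: List[Partition] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    def missing_fraction(self, taxon: str) -> float:
        row = self.rows[taxon]
        return row.count(GAP) / len(row) if row else 0.0


def concatenate(alignments: Sequence[CodonAlignment], strict: bool = False) -> Supermatrix:
    """Concatenate per-gene alignments over the sorted union of taxa.

    Gene order is lexicographic by gene name, so permuting the input
    list cannot change the result.  A taxon absent from a gene receives
    an all-gap filler of that gene's width (a warning is logged), unless
    ``strict=True`` in which case it is an error.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    by_gene = {a.gene: a for a in sorted(alignments, key=lambda a: a.gene)}
    if len(by_gene) != len(alignments):
        raise ValueError("duplicate gene names among alignments")
    taxa = sorted({t for a in alignments for t in a.taxa})
    parts: Dict[str, List[str]] = {t: [] for t in taxa}
    spans: List[Tuple[str, int, int]] = []
    offset = 0
    for gene, aln in by_gene.items():
        for taxon in taxa:
            if taxon in aln.rows:
                parts[taxon].append(aln.rows[taxon])
            elif strict:
                raise ValueError(f"taxon {taxon!r} missing from gene {gene!r}")
            else:
                logger.warning("taxon %r missing from gene %r: gap-filled", taxon, gene)
                parts[taxon].append(GAP * aln.width)
        spans.append((gene, offset, offset + aln.width))
        offset += aln.width
    matrix = Supermatrix(
        taxa=taxa,
        rows={t: "".join(parts[t]) for t in taxa},
        gene_spans=spans,
        positions_kept={1, 2, 3},
    )
    matrix.partitions = partition_scheme(matrix)
    return matrix


def select_positions(matrix: Supermatrix, keep: Set[int]) -> Supermatrix:
    """Restrict the matrix to the given codon positions.

    ``keep={1,2,3}`` is the identity; ``keep={1,2}`` physically removes
    every third site of every codon (width becomes 2/3 of the input) and
    recomputes gene spans and partitions in the compacted coordinates.
    """
    keep = set(keep)
    if keep == {1, 2, 3}:
        return matrix
    if keep != {1, 2}:
        raise ValueError("positions to keep must be {1,2,3} or {1,2}")
    keep_idx = [
        i
        for gene, s, e in matrix.gene_spans
        for i in range(s, e)
        if (i - s) % 3 != 2
    ]
    rows = {t: "".join(matrix.rows[t][i] for i in keep_idx) for t in matrix.taxa}
    spans = []
    offset = 0
    for gene, s, e in matrix.gene_spans:
        width = (e - s) // 3 * 2
        spans.append((gene, offset, offset + width))
        offset += width
    out = Supermatrix(
        taxa=list(matrix.taxa),
        rows=rows,
        gene_spans=spans,
        positions_kept={1, 2},
    )
    out.partitions = partition_scheme(out)
    return out


def partition_scheme(matrix: Supermatrix) -> List[Partition]:
    """One charset per (gene, kept codon position).

    On the full matrix each gene contributes stride-3 charsets for
    positions 1-3; after third-position removal each gene contributes
    stride-2 charsets for positions 1-2 over the compacted coordinates.
    """
    kept = sorted(matrix.positions_kept)
    stride = len(kept)
    parts: List[Partition] = []
    for gene, s, e in matrix.gene_spans:
        for i, pos in enumerate(kept):
            if s == e:  # gene fully filtered away upstream
                continue
            # full-span end with stride sampling, the PartitionFinder
            # convention ("gene_pos1 = 1-300\3" selects 1,4,...,298)
            parts.append(
                Partition(
                    name=f"{gene}_pos{pos}",
                    start=s + i + 1,
                    end=e,
                    stride=stride,
                )
            )
    return parts
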