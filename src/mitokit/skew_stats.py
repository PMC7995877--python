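"""Compositional statistics of mitochondrial protein-coding genes.

Strand asymmetry is summarised by the signed skews

    AT skew = (A - T) / (A + T)        CG skew = (C - G) / (C + G)

computed over the J- and N-strand gene concatenations separately for
first, second, and third codon positions, plus three strand-level
percentages: AT% over all protein-coding genes (strand independent),
AC% over the J-strand concatenation and GT% over the N-strand one.

Gaps and ambiguity codes are excluded from every numerator and
denominator; a zero denominator yields NaN (flagged undefined, never
silently 0).  Codon positions are indexed per gene *before*
concatenation, so the gap padding used to stack genes of unequal taxon
coverage cannot shift reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .core import GAP, GeneSet

__all__ = ["SkewTable", "pad_and_concat", "base_percentages", "codon_position_skews", "build_skew_table"]

STRANDS = ("J", "N")


def _counts(seq: Iterable[str]) -> Dict[str, int]:
    c = {"A": 0, "C": 0, "G": 0, "T": 0}
    for ch in seq:
        if ch in c:
            c[ch] += 1
    return c


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def pad_and_concat(data: GeneSet, strand_filter: str = "all") -> Dict[str, str]:
    """Per-genome concatenation of gene stacks, gap-padded per gene.

    Within each gene, sequences are padded with trailing gaps to the
    gene's maximum length; a genome absent from a gene receives an
    all-gap segment.  Genes are filtered by strand (``"J"``, ``"N"`` or
    ``"all"``) and concatenated in lexicographic gene order.
    """
    if strand_filter not in ("J", "N", "all"):
        raise ValueError(f"strand_filter must be J, N or all, not {strand_filter!r}")
    genomes = data.taxa()
    out: Dict[str, List[str]] = {g: [] for g in genomes}
    for gene, records in data:
        recs = [
            r for r in records if strand_filter == "all" or r.strand == strand_filter
        ]
        if not recs:
            continue
        width = max(len(r.seq) for r in recs)
        by_taxon = {r.taxon: r.seq for r in recs}
        for g in genomes:
            seq = by_taxon.get(g, "")
            out[g].append(seq + GAP * (width - len(seq)))
    return {g: "".join(chunks) for g, chunks in out.items()}


def base_percentages(concat: Dict[str, str], kind: str) -> Dict[str, float]:
    """Percentage of a base pair class per genome over a concatenation.

    ``kind`` is ``"AT"`` (strand independent, full matrix), ``"AC"``
    (J strand) or ``"GT"`` (N strand); gaps/ambiguities are excluded.
    """
    if kind not in ("AT", "AC", "GT"):
        raise ValueError(f"kind must be AT, AC or GT, not {kind!r}")
    out = {}
    for genome, seq in concat.items():
        c = _counts(seq)
        total = sum(c.values())
        out[genome] = _ratio(100.0 * sum(c[b] for b in kind), total)
    return out


def codon_position_skews(
    data: GeneSet, strand: str
) -> Dict[str, Dict[int, Tuple[float, float]]]:
    """AT and CG skew per genome per codon position on one strand.

    For position k in {1,2,3} every k-th codon nucleotide of each gene
    on the strand is pooled per genome; skews use only unambiguous
    A/C/G/T counts.  Returns ``{genome: {k: (at_skew, cg_skew)}}`` with
    NaN where a denominator is zero.
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be J or N, not {strand!r}")
    genomes = data.taxa()
    counts = {
        g: {k: {"A": 0, "C": 0, "G": 0, "T": 0} for k in (1, 2, 3)} for g in genomes
    }
    for gene, records in data:
        for rec in records:
            if rec.strand != strand:
                continue
            seq = rec.seq.replace(GAP, "")
            for k in (1, 2, 3):
                for ch in seq[k - 1 :: 3]:
                    if ch in "ACGT":
                        counts[rec.taxon][k][ch] += 1
    out: Dict[str, Dict[int, Tuple[float, float]]] = {}
    for g in genomes:
        out[g] = {}
        for k in (1, 2, 3):
            c = counts[g][k]
            at = _ratio(c["A"] - c["T"], c["A"] + c["T"])
            cg = _ratio(c["C"] - c["G"], c["C"] + c["G"])
            out[g][k] = (at, cg)
    return out


@dataclass
class SkewTable:
    """Per-genome compositional summary.

    ``percentages``: DataFrame indexed by genome with columns
    ``at_pct``, ``ac_pct``, ``gt_pct``; ``skews``: long-format DataFrame
    with columns genome, strand, position, at_skew, cg_skew.  NaN marks
    undefined values (empty strand class).
    """

    percentages: pd.DataFrame
    skews: pd.DataFrame

    @property
    def n_genomes(self) -> int:
        return len(self.percentages)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "base_percentages": self.percentages.reset_index(names="genome"),
            "codon_position_skews": self.skews,
        }


def build_skew_table(data: GeneSet) -> SkewTable:
    """Assemble the full skew summary for a strand-labelled GeneSet."""
    genomes = data.taxa()
    at = base_percentages(pad_and_concat(data, "all"), "AT")
    ac = base_percentages(pad_and_concat(data, "J"), "AC")
    gt = base_percentages(pad_and_concat(data, "N"), "GT")
    pct = pd.DataFrame(
        {
            "at_pct": [at[g] for g in genomes],
            "ac_pct": [ac[g] for g in genomes],
            "gt_pct": [gt[g] for g in genomes],
        },
        index=pd.Index(genomes, name="genome"),
    )
    rows = []
    for strand in STRANDS:
        skews = codon_position_skews(data, strand)
        for g in genomes:
            for k in (1, 2, 3):
                at_s, cg_s = skews[g][k]
                rows.append(
                    {
                        "genome": g,
                        "strand": strand,
                        "position": k,
                        "at_skew": at_s,
                        "cg_skew": cg_s,
                    }
                )
    return SkewTable(percentages=pct, skews=pd.DataFrame(rows))
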