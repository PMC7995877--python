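"""Pre-flight sanity rulebook for per-gene coding-sequence stacks.

Warnings (analysis continues):

* ``W1`` -- duplicated sequences within a gene file;
* ``W2`` -- a sequence whose ungapped length deviates from the gene's
  mean length by strictly more than 2 sample standard deviations;
* ``W3`` -- internal gap characters (removed automatically);
* ``W4`` -- a truncated terminal codon, i.e. length not divisible by 3
  (1-2 trailing nucleotides removed automatically).

Errors (analysis stops):

* ``E1`` -- malformed archive layout (raised by dataset_io);
* ``E2`` -- a file that is not FASTA (raised by dataset_io);
* ``E3`` -- duplicated sequence IDs within a file;
* ``E4`` -- characters outside the IUPAC nucleotide alphabet;
* ``E5`` -- an internal (non-terminal) stop codon.

A single terminal stop codon is not an error; it is stripped before
downstream use so that retro-alignment sees stop-free sequences.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .core import GAP, IUPAC_NT, GeneRecord, GeneSet, GeneticCode, codons

__all__ = ["Issue", "SanityReport", "SanityError", "check_dataset", "assert_clean"]


@dataclass(frozen=True)
class Issue:
    code: str  # W1..W4 / E1..E5
    gene: str
    taxon: str
    message: str

    def as_line(self) -> str:
        return f"{self.code}\t{self.gene}\t{self.taxon}\t{self.message}"


@dataclass
class SanityReport:
    warnings: List[Issue] = field(default_factory=list)
    errors: List[Issue] = field(default_factory=list)
    cleaned: Optional[GeneSet] = None

    @property
    def ok(self) -> bool:
        return not self.errors

    def lines(self) -> List[str]:
        return [i.as_line() for i in self.errors + self.warnings]


class SanityError(RuntimeError):
    """Aggregated fatal sanity failure; carries the full report."""

    def __init__(self, report: SanityReport):
        self.report = report
        codes = sorted({i.code for i in report.errors})
        detail = "; ".join(i.as_line() for i in report.errors[:10])
        super().__init__(
            f"sanity check failed with {len(report.errors)} error(s) "
            f"({', '.join(codes)}): {detail}"
        )


def _clean_record(
    rec: GeneRecord, code: GeneticCode, report: SanityReport
) -> Optional[str]:
    """Apply E4/W3/W4/E5 to one record; return the cleaned sequence or
    None if a fatal error was recorded."""
    bad = sorted({ch for ch in rec.seq if ch not in IUPAC_NT and ch != GAP})
    if bad:
        report.errors.append(
            Issue("E4", rec.gene, rec.taxon, f"non-IUPAC characters: {''.join(bad)}")
        )
        return None
    seq = rec.seq
    if GAP in seq:
        seq = seq.replace(GAP, "")
        report.warnings.append(
            Issue("W3", rec.gene, rec.taxon, "internal gaps removed")
        )
    if len(seq) % 3:
        drop = len(seq) % 3
        seq = seq[: len(seq) - drop]
        report.warnings.append(
            Issue("W4", rec.gene, rec.taxon, f"truncated end codon ({drop} nt removed)")
        )
    if not seq:
        report.errors.append(Issue("E2", rec.gene, rec.taxon, "empty sequence"))
        return None
    # internal stop scan; a single terminal stop is stripped silently
    triplets = codons(seq)
    if triplets and triplets[-1] in code.stop_codons:
        triplets = triplets[:-1]
        seq = "".join(triplets)
    internal = [
        i + 1
        for i, c in enumerate(triplets)
        if all(b in "ACGT" for b in c) and c in code.stop_codons
    ]
    if internal:
        report.errors.append(
            Issue(
                "E5",
                rec.gene,
                rec.taxon,
                f"internal stop codon at codon {internal[0]} "
                f"(table {code.table_id})",
            )
        )
        return None
    if not seq:
        report.errors.append(Issue("E2", rec.gene, rec.taxon, "empty sequence"))
        return None
    return seq


def check_dataset(data: GeneSet, code: GeneticCode) -> SanityReport:
    """Run the full per-gene rulebook; never raises.

    The returned report's ``cleaned`` GeneSet (present when no fatal
    error fired) differs from the input only by gap removal (W3),
    truncated-terminal-codon removal (W4) and terminal-stop stripping.
    """
    report = SanityReport()
    cleaned = GeneSet(code_id=data.code_id)
    for gene, records in data:
        # E3: duplicate headers within a file
        seen: dict[str, int] = {}
        for rec in records:
            seen[rec.taxon] = seen.get(rec.taxon, 0) + 1
        for taxon, n in seen.items():
            if n > 1:
                report.errors.append(
                    Issue("E3", gene, taxon, f"sequence ID appears {n} times")
                )
        # W1: duplicated sequence strings within the gene
        by_seq: dict[str, str] = {}
        for rec in records:
            key = rec.ungapped
            if key in by_seq and by_seq[key] != rec.taxon:
                report.warnings.append(
                    Issue(
                        "W1",
                        gene,
                        rec.taxon,
                        f"sequence identical to that of {by_seq[key]!r}",
                    )
                )
            else:
                by_seq.setdefault(key, rec.taxon)
        # W2: ungapped length > 2 sample SDs from the gene mean
        lengths = [len(rec.ungapped) for rec in records]
        if len(lengths) >= 3:
            mean = statistics.fmean(lengths)
            sd = statistics.stdev(lengths)
            for rec, ln in zip(records, lengths):
                if abs(ln - mean) > 2 * sd:
                    report.warnings.append(
                        Issue(
                            "W2",
                            gene,
                            rec.taxon,
                            f"length {ln} deviates from gene mean {mean:.1f} "
                            f"by more than 2 SD ({sd:.1f})",
                        )
                    )
        for rec in records:
            seq = _clean_record(rec, code, report)
            if seq is not None:
                cleaned.add(
                    GeneRecord(taxon=rec.taxon, gene=gene, seq=seq, strand=rec.strand)
                )
    if report.ok:
        report.cleaned = cleaned
    return report


def assert_clean(report: SanityReport) -> GeneSet:
    """Return the cleaned GeneSet, or raise an aggregated SanityError."""
    if not report.ok or report.cleaned is None:
        raise SanityError(report)
    return report.cleaned
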