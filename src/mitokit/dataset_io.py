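"""Reading and writing every on-disk format the toolkit touches.

Inputs: FASTA files, either loose in a directory or packed in a
zip/tar/tar.gz archive, in one of two layouts --

* ``flat_genes``: one FASTA per protein-coding gene at the top level
  (``cox1.fasta``, ``cox2.fasta``, ...), used for supermatrix assembly;
* ``strand_folders``: two top-level folders ``J`` and ``N`` holding the
  FASTA files of the genes encoded on each strand, used for skew and
  codon-usage statistics.

Outputs: relaxed PHYLIP, PartitionFinder2 ``.cfg`` configuration files,
and tab-separated tables.
"""

from __future__ import annotations

import io as _io
import re
import tarfile
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd
from Bio import SeqIO

from .core import GeneRecord, GeneSet, normalize_seq

__all__ = [
    "ArchiveLayout",
    "LayoutError",
    "FastaFormatError",
    "read_fasta",
    "load_gene_archive",
    "write_phylip",
    "read_phylip",
    "write_partitionfinder_cfg",
    "write_tables",
]


class LayoutError(ValueError):
    """Archive layout violates the input contract (sanity code E1)."""

    code = "E1"


class FastaFormatError(ValueError):
    """A file is not parseable as FASTA (sanity code E2)."""

    code = "E2"


@dataclass
class ArchiveLayout:
    """Flattened view of an input archive or directory."""

    mode: str  # "flat_genes" | "strand_folders"
    entries: List[Tuple[str, bytes]]  # (relative path, payload)


def read_fasta(source) -> List[Tuple[str, str]]:
    """Parse FASTA into ``(header, sequence)`` pairs.

    ``source`` is a path or a text handle.  Headers are truncated at the
    first whitespace; sequence lines are concatenated and normalized
    (uppercase, U->T).  A file whose first non-blank line does not start
    with ``>`` raises :class:`FastaFormatError`.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        text = Path(source).read_text()
        name = str(source)
    stripped = text.lstrip()
    if not stripped.startswith(">"):
        raise FastaFormatError(f"{name}: not a FASTA file (no leading '>')")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        records.append((rec.id, normalize_seq(str(rec.seq))))
    if not records:
        raise FastaFormatError(f"{name}: no FASTA records found")
    return records


def _iter_archive(path: Path) -> Iterable[Tuple[str, bytes]]:
    """Yield (relative path, payload) for files in a directory/archive."""
    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file():
                yield str(p.relative_to(path)), p.read_bytes()
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                if not info.is_dir():
                    yield info.filename, zf.read(info)
    elif tarfile.is_tarfile(path):
        with tarfile.open(path) as tf:
            for member in sorted(tf.getmembers(), key=lambda m: m.name):
                if member.isfile():
                    handle = tf.extractfile(member)
                    if handle is not None:
                        yield member.name, handle.read()
    else:
        raise LayoutError(
            f"{path}: not a directory, zip, or tar archive "
            "(supported archive types: .zip, .tar, .tar.gz)"
        )


_JUNK = re.compile(r"(^|/)(__MACOSX|\.DS_Store|\._)")


def scan_archive(path, mode: str) -> ArchiveLayout:
    """Flatten an archive/directory and validate it against ``mode``."""
    if mode not in ("flat_genes", "strand_folders"):
        raise ValueError(f"unknown layout mode {mode!r}")
    entries = [
        (name.strip("/"), data)
        for name, data in _iter_archive(Path(path))
        if not _JUNK.search(name)
    ]
    if not entries:
        raise LayoutError(f"{path}: archive is empty")
    if mode == "flat_genes":
        nested = [n for n, _ in entries if "/" in n]
        if nested:
            raise LayoutError(
                f"{path}: a directory is present in the compressed file "
                f"(e.g. {nested[0]!r}); flat per-gene layout expected"
            )
    else:
        tops = {n.split("/", 1)[0] for n, _ in entries}
        loose = [n for n, _ in entries if "/" not in n]
        if loose or tops != {"J", "N"}:
            raise LayoutError(
                f"{path}: strand layout requires exactly two top-level "
                f"folders named J and N (found: {sorted(tops)})"
            )
    return ArchiveLayout(mode=mode, entries=entries)


def load_gene_archive(path, mode: str = "flat_genes", code_id: int = 5) -> GeneSet:
    """Load a per-gene FASTA archive (or directory) into a :class:`GeneSet`.

    Gene name = file stem, lowercased; in ``strand_folders`` mode the
    strand label comes from the enclosing ``J``/``N`` folder.  Gene
    iteration order is lexicographic regardless of archive order.
    """
    layout = scan_archive(path, mode)
    gs = GeneSet(code_id=code_id)
    for name, payload in sorted(layout.entries):
        parts = name.split("/")
        strand = parts[0] if mode == "strand_folders" else "unknown"
        gene = Path(parts[-1]).stem.lower()
        handle = _io.StringIO(payload.decode("utf-8", errors="replace"))
        handle.name = name
        for header, seq in read_fasta(handle):
            gs.add(GeneRecord(taxon=header, gene=gene, seq=seq, strand=strand))
    return gs


def sanitize_name(name: str) -> str:
    """Make a taxon name safe for whitespace-delimited formats."""
    return re.sub(r"\s+", "_", name.strip())


def write_phylip(matrix, path) -> Path:
    """Write a supermatrix as relaxed PHYLIP (full names, one line/taxon)."""
    path = Path(path)
    if not matrix.taxa:
        raise ValueError("cannot write an empty matrix")
    width = len(next(iter(matrix.rows.values())))
    with path.open("w") as fh:
        fh.write(f"{len(matrix.taxa)} {width}\n")
        for taxon in matrix.taxa:
            fh.write(f"{sanitize_name(taxon)} {matrix.rows[taxon]}\n")
    return path


def read_phylip(path) -> Tuple[List[str], Dict[str, str]]:
    """Parse relaxed PHYLIP back into (taxa order, rows). Round-trip aid."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    ntaxa, nsites = (int(tok) for tok in lines[0].split())
    taxa, rows = [], {}
    for line in lines[1 : ntaxa + 1]:
        name, seq = line.split(None, 1)
        seq = seq.replace(" ", "")
        if len(seq) != nsites:
            raise ValueError(f"{path}: row {name} has {len(seq)} != {nsites} sites")
        taxa.append(name)
        rows[name] = seq
    return taxa, rows


_CFG_DEFAULTS = {
    "branchlengths": "linked",
    "models": "all",
    "model_selection": "aicc",
    "search": "greedy",
    "alignment": "supermatrix.phy",
}


def write_partitionfinder_cfg(matrix, path, settings: Mapping[str, str] | None = None) -> Path:
    """Write a PartitionFinder2 configuration seeded with the gene ×
    codon-position starting scheme (one charset per partition).
    """
    if not matrix.partitions:
        raise ValueError("supermatrix has no partitions")
    cfg = dict(_CFG_DEFAULTS)
    cfg.update(settings or {})
    path = Path(path)
    lines = [
        "## ALIGNMENT FILE ##",
        f"alignment = {cfg['alignment']};",
        "",
        "## BRANCHLENGTHS ##",
        f"branchlengths = {cfg['branchlengths']};",
        "",
        "## MODELS OF EVOLUTION ##",
        f"models = {cfg['models']};",
        f"model_selection = {cfg['model_selection']};",
        "",
        "## DATA BLOCKS ##",
        "[data_blocks]",
    ]
    for part in matrix.partitions:
        lines.append(f"{part.name} = {part.start}-{part.end}\\{part.stride};")
    lines += [
        "",
        "## SCHEMES ##",
        "[schemes]",
        f"search = {cfg['search']};",
        "",
    ]
    path.write_text("\n".join(lines))
    return path


def parse_charsets(cfg_path) -> List[Tuple[str, int, int, int]]:
    """Extract ``(name, start, end, stride)`` charset lines from a cfg."""
    out = []
    in_blocks = False
    for line in Path(cfg_path).read_text().splitlines():
        line = line.strip()
        if line.startswith("["):
            in_blocks = line == "[data_blocks]"
            continue
        if in_blocks and "=" in line:
            name, rng = (tok.strip() for tok in line.rstrip(";").split("="))
            m = re.fullmatch(r"(\d+)-(\d+)\\(\d+)", rng)
            if not m:
                raise ValueError(f"unparseable charset line: {line!r}")
            out.append((name, int(m.group(1)), int(m.group(2)), int(m.group(3))))
    return out


def write_tables(results, outdir) -> List[Path]:
    """Write an analysis result's tables as TSV, 4 decimal places.

    ``results`` is any object with a ``tables()`` method returning a
    mapping of file stem -> DataFrame (SkewTable, CodonUsageTable), or
    such a mapping directly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = results.tables() if hasattr(results, "tables") else dict(results)
    written = []
    for stem, frame in frames.items():
        path = outdir / f"{stem}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
        written.append(path)
    return written
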