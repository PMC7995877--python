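"""Retro-alignment and codon-aware block filtering.

The block filter is checked against an independent naive
reimplementation of the column-classification rules (regex-based run
detection over a status string) on randomly generated codon matrices.
"""

import random
import re
from collections import Counter
from math import ceil, floor

import pytest

from mitokit.align import (
    BlockFilterParams,
    CodonAlignment,
    align_proteins,
    backthread,
    classify_codon_columns,
    filter_blocks,
    kept_codon_indices,
    retroalign_gene,
)
from mitokit.core import GAP, GeneRecord, translate
from mitokit.fixtures import FixtureParams, generate


class TestAlignProteins:
    def test_identical_sequences_align_gap_free(self):
        aln = align_proteins({"a": "MKLV", "b": "MKLV", "c": "MKLV"})
        assert aln == {"a": "MKLV", "b": "MKLV", "c": "MKLV"}

    def test_single_insertion(self):
        # one gap opposite the extra residue; any of the three
        # placements satisfies the alignment contract
        aln = align_proteins({"a": "MK", "b": "MAK"})
        assert aln["b"] == "MAK"
        assert aln["a"] in ("M-K", "-MK", "MK-")
        assert len(aln["a"]) == 3 and aln["a"].count("-") == 1

    def test_singleton_identity(self):
        assert align_proteins({"only": "MKL"}) == {"only": "MKL"}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            align_proteins({})

    def test_ungapping_recovers_inputs(self):
        seqs = {"a": "MKLVNPQ", "b": "MKVNPQ", "c": "MKLVNQ"}
        aln = align_proteins(seqs)
        widths = {len(v) for v in aln.values()}
        assert len(widths) == 1
        for k, row in aln.items():
            assert row.replace(GAP, "") == seqs[k]


class TestBackthread:
    def test_gap_becomes_triple_gap(self, code5):
        aln = backthread({"a": "M-K"}, {"a": "ATGAAA"}, code5)
        assert aln.rows["a"] == "ATG---AAA"

    def test_mismatch_names_taxon(self, code5):
        with pytest.raises(ValueError, match="badtaxon"):
            backthread({"badtaxon": "MM"}, {"badtaxon": "ATGAAA"}, code5)

    def test_random_roundtrip(self, code5):
        rng = random.Random(7)
        for _ in range(20):
            nts = {}
            for t in "abcd":
                n = rng.randrange(4, 30)
                seq = []
                while len(seq) < n:
                    codon = "".join(rng.choice("ACGT") for _ in range(3))
                    if codon not in code5.stop_codons:
                        seq.append(codon)
                nts[t] = "".join(seq)
            prot = {t: translate(s, code5) for t, s in nts.items()}
            aln = backthread(align_proteins(prot), nts, code5)
            assert aln.width % 3 == 0
            for t in nts:
                assert aln.rows[t].replace(GAP, "") == nts[t]


def naive_filter(aln, params):
    """Independent oracle: status string + regex run handling."""
    n = len(aln.taxa)
    cons = floor(n * params.min_conserved_fraction) + 1
    high = max(ceil(n * params.high_conserved_fraction), cons)
    status = ""
    for j in range(aln.width // 3):
        col = [aln.rows[t][3 * j: 3 * j + 3] for t in aln.taxa]
        if any("-" in c for c in col):
            status += "g"
        else:
            top = Counter(col).most_common(1)[0][1]
            status += "h" if top >= high else "c" if top >= cons else "n"
    dead = set()
    if not params.allow_gaps:
        dead |= {m.start() for m in re.finditer("g", status)}
    for m in re.finditer("[ng]+", status):
        if m.end() - m.start() > params.max_nonconserved_run:
            dead |= set(range(m.start(), m.end()))
    survivor = "".join("x" if j in dead else status[j] for j in range(len(status)))
    kept = []
    for m in re.finditer("[^x]+", survivor):
        block = m.group(0)
        left = re.search("[ch]", block)
        right = re.search("[ch](?=[^ch]*$)", block)
        if left is None:
            continue
        idx = list(range(m.start() + left.start(), m.start() + right.start() + 1))
        if len(idx) >= params.min_block_len:
            kept.extend(idx)
    return kept


def random_alignment(rng, with_gaps=True):
    n_taxa = rng.randrange(2, 7)
    n_codons = rng.randrange(5, 40)
    base = ["".join(rng.choice("ACGT") for _ in range(3)) for _ in range(n_codons)]
    rows = {}
    for t in range(n_taxa):
        row = []
        for j in range(n_codons):
            r = rng.random()
            if with_gaps and r < 0.05:
                row.append("---")
            elif r < 0.35:
                row.append("".join(rng.choice("ACGT") for _ in range(3)))
            else:
                row.append(base[j])
        rows[f"t{t}"] = "".join(row)
    return CodonAlignment(taxa=sorted(rows), rows=rows, gene="r")


class TestFilterBlocks:
    def test_identical_gapfree_alignment_unchanged(self):
        aln = CodonAlignment(taxa=["a", "b"], rows={"a": "ATG" * 12, "b": "ATG" * 12})
        out = filter_blocks(aln)
        assert out.rows == aln.rows

    def test_gapped_codon_columns_absent_in_strict_mode(self):
        rows = {"a": "ATG" * 20, "b": "ATG" * 9 + "---" + "ATG" * 10}
        out = filter_blocks(CodonAlignment(taxa=["a", "b"], rows=rows))
        assert GAP not in out.rows["b"]
        assert 9 not in kept_codon_indices(
            CodonAlignment(taxa=["a", "b"], rows=rows), BlockFilterParams())

    def test_agrees_with_naive_oracle(self):
        rng = random.Random(2024)
        params = BlockFilterParams()
        for _ in range(300):
            aln = random_alignment(rng)
            assert kept_codon_indices(aln, params) == naive_filter(aln, params)

    def test_agrees_with_naive_oracle_nondefault_params(self):
        rng = random.Random(99)
        params = BlockFilterParams(
            min_conserved_fraction=0.6, high_conserved_fraction=0.9,
            max_nonconserved_run=4, min_block_len=5, allow_gaps=True,
        )
        for _ in range(200):
            aln = random_alignment(rng)
            assert kept_codon_indices(aln, params) == naive_filter(aln, params)

    def test_monotone_and_frame_preserving(self):
        rng = random.Random(5)
        for _ in range(50):
            aln = random_alignment(rng)
            out = filter_blocks(aln)
            assert out.width <= aln.width
            assert out.width % 3 == 0
            assert all(GAP not in row for row in out.rows.values())

    def test_output_rows_are_codon_subsequences_of_input(self):
        rng = random.Random(6)
        aln = random_alignment(rng, with_gaps=False)
        kept = kept_codon_indices(aln, BlockFilterParams(min_block_len=1))
        out = filter_blocks(aln, BlockFilterParams(min_block_len=1))
        for t in aln.taxa:
            source = [aln.rows[t][3 * j: 3 * j + 3] for j in kept]
            assert out.rows[t] == "".join(source)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BlockFilterParams(min_conserved_fraction=0.3)
        with pytest.raises(ValueError):
            BlockFilterParams(min_block_len=0)


class TestRetroalignGene:
    def test_identical_stack_passes_through(self, code5):
        records = [
            GeneRecord(taxon=f"t{i}", gene="cox1", seq="ATGAAACCTTGA"[:9] * 8)
            for i in range(3)
        ]
        aln = retroalign_gene(records, code5)
        assert all(aln.rows[r.taxon] == r.seq for r in records)

    def test_singleton_gene_unchanged(self, code5):
        rec = GeneRecord(taxon="t1", gene="g", seq="ATGAAACCT" * 5)
        aln = retroalign_gene([rec], code5)
        assert aln.rows == {"t1": rec.seq}

    def test_ungapped_rows_recover_inputs_prefilter(self, code5):
        gs = generate(FixtureParams(
            n_taxa=5, seed=9, genes=[("cox1", 40, "J")], substitution_rate=0.15))
        records = gs.genes["cox1"]
        _, pre, post = retroalign_gene(records, code5, keep_intermediates=True)
        for r in records:
            assert pre.rows[r.taxon].replace(GAP, "") == r.seq
        assert post.width % 3 == 0

    def test_empty_stack_raises(self, code5):
        with pytest.raises(ValueError):
            retroalign_gene([], code5)

    def test_hypervariable_window_removed_flanks_survive(self, code5):
        params = FixtureParams(
            n_taxa=8, seed=21, substitution_rate=0.0,
            genes=[("cox1", 60, "J")],
            hypervariable_windows=[("cox1", 25, 12, 1.0)],
        )
        gs = generate(params)
        _, pre, _ = retroalign_gene(gs.genes["cox1"], code5, keep_intermediates=True)
        # identical flanks + equal lengths: alignment must stay gapless,
        # so pre-filter codon columns map 1:1 onto source codon indices
        assert all(GAP not in row for row in pre.rows.values())
        kept = set(kept_codon_indices(pre, BlockFilterParams()))
        window = set(range(25, 37))
        assert kept & window == set()
        assert kept & set(range(0, 25))
        assert kept & set(range(37, 60))
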