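import itertools
import math

import numpy as np
import pytest

from mblsplice import formats_io as fio
from mblsplice import motif_map as mm
from mblsplice import phylo_conservation as pc
from mblsplice.formats_io import AlignmentBlock, GeneModel, MafRow, revcomp
from tests.conftest import random_dna


def make_block(ref_species, chrom, start, rows, src_size=10_000):
    """rows: list of (species, aligned_text); first must be the reference."""
    out = []
    for sp, text in rows:
        size = len(text) - text.count("-")
        out.append(MafRow(sp, chrom if sp == ref_species else f"{sp}_c",
                          start, size, "+", src_size, text))
    return AlignmentBlock(ref_species, out)


class TestFlankWindows:
    def _gene(self, strand="+", intron=600, n_exons=4):
        exons, pos = [], 0
        for _ in range(n_exons):
            exons.append((pos, pos + 100))
            pos += 100 + intron
        return GeneModel("g", "chr", strand, exons)

    def _genome(self, rng, n=6000):
        return {"chr": random_dna(rng, n)}

    def test_four_exon_gene_yields_four_windows(self, rng):
        ws = pc.flank_windows(self._gene(), self._genome(rng))
        assert len(ws) == 4
        assert all(w.end - w.start == 150 for w in ws)
        # two internal exons, each with an upstream and a downstream window
        assert [(w.intron_index, w.side) for w in ws] == [
            (0, "upstream_of_exon"), (1, "downstream_of_exon"),
            (1, "upstream_of_exon"), (2, "downstream_of_exon")]

    def test_two_exon_gene_has_no_internal_exon(self, rng):
        g = GeneModel("g", "chr", "+", [(0, 100), (300, 400)])
        assert pc.flank_windows(g, self._genome(rng)) == []

    def test_short_intron_split_into_non_overlapping_halves(self, rng):
        ws = pc.flank_windows(self._gene(intron=200), self._genome(rng))
        assert all(w.end - w.start == 100 for w in ws)
        shared = [w for w in ws if w.intron_index == 1]
        assert len(shared) == 2
        a, b = sorted(shared, key=lambda w: w.start)
        assert a.end <= b.start

    def test_window_sequences_are_sense_strand(self, rng):
        genome = self._genome(rng)
        for strand in "+-":
            for w in pc.flank_windows(self._gene(strand), genome):
                expected = genome["chr"][w.start:w.end]
                if strand == "-":
                    expected = revcomp(expected)
                assert w.seq == expected

    def test_windows_abut_their_exons(self, rng):
        g = self._gene("+")
        ws = {(w.intron_index, w.side): w for w in pc.flank_windows(g, self._genome(rng))}
        # upstream window of exon 1 ends where exon 1 starts (intron 0 end)
        assert ws[(0, "upstream_of_exon")].end == g.exons[1][0]
        # downstream window of exon 1 starts where intron 1 starts
        assert ws[(1, "downstream_of_exon")].start == g.exons[1][1]


class TestSpanningLength:
    def test_toy_tree_extremes(self, toy_tree):
        span = pc.SpanningLengthCalculator(toy_tree)
        assert span({"R", "A", "B"}) == 4          # whole tree
        assert span({"R", "A"}) == 3               # path R -> A
        assert span({"R"}) == 0
        assert span(set()) == 0

    def test_unknown_species_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            pc.SpanningLengthCalculator(toy_tree)({"R", "Z"})

    def test_adding_a_leaf_never_decreases_length(self, rng):
        tree = fio.read_newick("((A:1,B:2):1,(C:3,(D:1,E:2):1):2);")
        span = pc.SpanningLengthCalculator(tree)
        leaves = ["A", "B", "C", "D", "E"]
        for _ in range(50):
            sub = set(rng.choice(leaves, size=rng.integers(1, 5),
                                 replace=False))
            extra = rng.choice([l for l in leaves if l not in sub])
            assert span(sub | {extra}) >= span(sub)


class TestOccurrenceBranchLength:
    def _window(self, seq, start=1000, strand="+", gene="g"):
        end = start + len(seq)
        return pc.FlankWindow(gene, 0, "downstream_of_exon", "chr",
                              start, end, strand, seq)

    def test_conserved_in_all_species_spans_whole_tree(self, toy_tree):
        seq = "AAGCTTAA"
        w = self._window(seq)
        block = make_block("R", "chr", 1000,
                           [("R", seq), ("A", seq), ("B", seq)])
        occs = pc.occurrence_branch_length(w, "GCTT", [block], toy_tree, "R")
        assert len(occs) == 1
        assert occs[0].conserving_species == {"A", "B"}
        assert occs[0].spanning_branch_length == 4
        assert occs[0].ref_position == 1002

    def test_reference_only_occurrence_scores_zero(self, toy_tree):
        seq = "AAGCTTAA"
        w = self._window(seq)
        block = make_block("R", "chr", 1000,
                           [("R", seq), ("A", "AACCTTAA"), ("B", "AAGCTAAA")])
        occs = pc.occurrence_branch_length(w, "GCTT", [block], toy_tree, "R")
        assert occs[0].conserving_species == frozenset()
        assert occs[0].spanning_branch_length == 0

    def test_single_conserving_species_uses_path_length(self, toy_tree):
        seq = "AAGCTTAA"
        w = self._window(seq)
        block = make_block("R", "chr", 1000,
                           [("R", seq), ("A", seq), ("B", "AAGAATAA")])
        occs = pc.occurrence_branch_length(w, "GCTT", [block], toy_tree, "R")
        assert occs[0].conserving_species == {"A"}
        assert occs[0].spanning_branch_length == 3   # R -> A path

    def test_gap_in_species_breaks_conservation(self, toy_tree):
        w = self._window("AAGCTTAA")
        block = make_block("R", "chr", 1000,
                           [("R", "AAGCTTAA"), ("A", "AAGC-TAA")])
        occs = pc.occurrence_branch_length(w, "GCTT", [block], toy_tree, "R")
        assert occs[0].conserving_species == frozenset()

    def test_occurrence_stitched_across_block_boundary(self, toy_tree):
        seq = "AAGCTTAA"
        w = self._window(seq)
        b1 = make_block("R", "chr", 1000, [("R", "AAGC"), ("A", "AAGC")])
        b2 = make_block("R", "chr", 1004, [("R", "TTAA"), ("A", "TTAA")])
        occs = pc.occurrence_branch_length(w, "GCTT", [b1, b2], toy_tree, "R")
        assert occs[0].conserving_species == {"A"}

    def test_unaligned_window_scores_zero_not_excluded(self, toy_tree):
        w = self._window("AAGCTTAA")
        occs = pc.occurrence_branch_length(w, "GCTT", [], toy_tree, "R")
        assert len(occs) == 1
        assert occs[0].spanning_branch_length == 0

    def test_minus_strand_motif_checked_on_genomic_plus(self, toy_tree):
        # sense GCTT on a minus-strand gene is genomic AAGC
        sense = "TTGCTTCC"
        genomic = revcomp(sense)
        w = self._window(sense, start=1000, strand="-")
        block = make_block("R", "chr", 1000,
                           [("R", genomic), ("A", genomic)])
        occs = pc.occurrence_branch_length(w, "GCTT", [block], toy_tree, "R")
        assert len(occs) == 1
        assert occs[0].conserving_species == {"A"}
        # occurrence at sense offset 2 -> genomic start 1008 - 2 - 4
        assert occs[0].ref_position == 1002

    def test_insertion_gap_in_reference_handled(self, toy_tree):
        # reference row with a gap column (insertion in A): projection must
        # still expose the four reference columns
        w = self._window("AAGCTTAA")
        block = make_block("R", "chr", 1000,
                           [("R", "AAGC-TTAA"), ("A", "AAGCGTTAA")])
        occs = pc.occurrence_branch_length(w, "GCTT", [block], toy_tree, "R")
        assert occs[0].conserving_species == {"A"}


class TestDeltaScores:
    def test_delta_intron_matches_independent_oracle(self, rng, toy_tree):
        # random window and random species rows; oracle recomputes every
        # occurrence's conservation and path length from first principles
        seq = random_dna(rng, 120)
        rows = [("R", seq)]
        for sp in ("A", "B"):
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            mut = rng.random(len(seq)) < 0.25
            arr[mut] = np.frombuffer(random_dna(rng, int(mut.sum())).encode(),
                                     dtype="S1")
            rows.append((sp, arr.tobytes().decode()))
        block = make_block("R", "chr", 500, rows)
        w = pc.FlankWindow("g", 0, "downstream_of_exon", "chr", 500,
                           500 + len(seq), "+", seq)
        targets = mm.TARGET_MOTIFS
        controls = mm.control_motif_union()
        got = pc.delta_intron([w], targets, controls, [block], toy_tree, "R")

        path = {"A": 3.0, "B": 3.0}   # R->X path length in the toy tree
        def oracle_pool(motifs):
            lengths = []
            for m in motifs:
                for i in range(len(seq) - 3):
                    if seq[i:i + 4] != m:
                        continue
                    conserving = {sp for sp, text in rows[1:]
                                  if text[i:i + 4] == m}
                    if not conserving:
                        lengths.append(0.0)
                    elif conserving == {"A", "B"}:
                        lengths.append(4.0)
                    else:
                        lengths.append(path[next(iter(conserving))])
            return lengths

        t, c = oracle_pool(targets), oracle_pool(controls)
        expected = np.mean(t) - np.mean(c)
        assert got == pytest.approx(expected)

    def test_delta_intron_undefined_when_no_target_occurrence(self, toy_tree):
        seq = "A" * 40
        w = pc.FlankWindow("g", 0, "downstream_of_exon", "chr", 0, 40, "+", seq)
        block = make_block("R", "chr", 0, [("R", seq), ("A", seq)])
        d = pc.delta_intron([w], mm.TARGET_MOTIFS, ("AATT",), [block],
                            toy_tree, "R")
        assert math.isnan(d)

    def test_delta_gene_takes_maximum(self):
        assert pc.delta_gene([-0.2, 0.9, 0.1]) == 0.9
        assert pc.delta_gene({0: 0.5}) == 0.5
        assert math.isnan(pc.delta_gene([math.nan, math.nan]))

    def test_delta_gene_monotone_in_added_introns(self):
        base = [0.3, -0.1]
        assert pc.delta_gene(base + [0.8]) >= pc.delta_gene(base)
        assert pc.delta_gene(base + [-0.9]) >= pc.delta_gene(base)
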