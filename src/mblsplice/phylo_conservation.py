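"""Phylogenetic branch-length conservation of MBL/MBNL motifs.

For every internal exon of a gene, the 150 nt of intron immediately
upstream and downstream are scanned for MBNL-binding 4-mers and for
composition-matched control 4-mers.  Each motif occurrence is scored by the
total branch length of the minimal subtree connecting the reference species
to every species whose aligned bases spell the identical motif without
gaps.  The per-intron score delta_intron is the mean branch length of
target occurrences minus the mean of control occurrences; the gene score
delta_gene is the largest delta_intron over the gene's introns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .formats_io import AlignmentBlock, GeneModel, extract_sense, revcomp
from .motif_map import TARGET_MOTIFS, control_motif_union, count_kmer

FLANK_SIZE = 150


@dataclass
class FlankWindow:
    """One intronic flank of an internal exon, on the sense strand."""

    gene_id: str
    intron_index: int           # transcript-order intron the window lies in
    side: str                   # upstream_of_exon | downstream_of_exon
    chrom: str
    start: int                  # genomic, 0-based half-open
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError("window sequence length does not match interval")


@dataclass
class ConservedOccurrence:
    gene_id: str
    intron_index: int
    motif: str
    ref_position: int           # genomic + strand start of the occurrence
    conserving_species: frozenset[str]
    spanning_branch_length: float


@dataclass
class ConservationScore:
    gene_id: str
    delta_intron: dict[int, float]   # intron index -> score (defined only)
    delta_gene: float                # NaN when no intron scored
    best_intron: int | None = None


def flank_windows(gene: GeneModel, genome: Mapping[str, str],
                  size: int = FLANK_SIZE) -> list[FlankWindow]:
    """Intronic windows flanking every internal exon of a gene.

    For internal exon *k* (transcript order) the upstream window covers the
    last ``size`` nt of the preceding intron and the downstream window the
    first ``size`` nt of the following intron.  Introns shorter than
    ``2*size`` are split evenly (floor(intron/2) per window) so the two
    windows of an intron never overlap.  Genes with fewer than three exons
    have no internal exon and yield an empty list.
    """
    exons = gene.exons_transcript_order()
    if len(exons) < 3:
        return []
    # transcript-order introns: intron j lies between exon j and exon j+1
    windows: list[FlankWindow] = []

    def intron_interval(j: int) -> tuple[int, int]:
        a, b = exons[j], exons[j + 1]
        return (a[1], b[0]) if gene.strand == "+" else (b[1], a[0])

    def wsize(j: int) -> int:
        s, e = intron_interval(j)
        ilen = e - s
        return size if ilen >= 2 * size else ilen // 2

    for k in range(1, len(exons) - 1):
        up_j, down_j = k - 1, k
        # upstream window: 3' end of intron k-1 (transcript orientation)
        s, e = intron_interval(up_j)
        w = wsize(up_j)
        if gene.strand == "+":
            interval = (e - w, e)
        else:
            interval = (s, s + w)
        windows.append(FlankWindow(
            gene.gene_id, up_j, "upstream_of_exon", gene.chrom, *interval,
            gene.strand,
            extract_sense(genome, gene.chrom, *interval, gene.strand)))
        # downstream window: 5' start of intron k
        s, e = intron_interval(down_j)
        w = wsize(down_j)
        if gene.strand == "+":
            interval = (s, s + w)
        else:
            interval = (e - w, e)
        windows.append(FlankWindow(
            gene.gene_id, down_j, "downstream_of_exon", gene.chrom, *interval,
            gene.strand,
            extract_sense(genome, gene.chrom, *interval, gene.strand)))
    return windows


# ---------------------------------------------------------------------------
# Spanning branch length on the species tree
# ---------------------------------------------------------------------------

class SpanningLengthCalculator:
    """Total branch length of the minimal subtree connecting a leaf set.

    An edge belongs to the spanning subtree exactly when the selected
    leaves occur both below and above it; precomputing the leaf set under
    every edge makes each query a linear scan over edges, memoised by leaf
    subset.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.leaf_labels = frozenset(
            t.label for t in tree.taxon_namespace if t is not None)
        self._edges: list[tuple[float, frozenset[str]]] = []
        below: dict[int, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = frozenset([node.taxon.label])
            else:
                acc: frozenset[str] = frozenset()
                for ch in node.child_nodes():
                    acc |= below[id(ch)]
                below[id(node)] = acc
            if node is not tree.seed_node and node.edge.length:
                self._edges.append((node.edge.length, below[id(node)]))
        self._cache: dict[frozenset[str], float] = {}

    def __call__(self, leaves: Iterable[str]) -> float:
        s = frozenset(leaves)
        unknown = s - self.leaf_labels
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(s) < 2:
            return 0.0
        if s in self._cache:
            return self._cache[s]
        total = 0.0
        n = len(s)
        for length, under in self._edges:
            k = len(s & under)
            if 0 < k < n:
                total += length
        self._cache[s] = total
        return total


# ---------------------------------------------------------------------------
# Conservation of motif occurrences
# ---------------------------------------------------------------------------

class ReferenceProjection:
    """Aligned characters of every species at reference + strand positions,
    assembled from (possibly several, adjacent) MAF blocks."""

    def __init__(self, blocks: Sequence[AlignmentBlock], chrom: str,
                 start: int, end: int):
        self.start, self.end = start, end
        n = end - start
        self.chars: dict[str, list[str | None]] = {}
        for block in blocks:
            ref = block.ref_row
            if ref.chrom != chrom:
                continue
            b0, b1 = ref.start, ref.start + ref.size
            if b1 <= start or b0 >= end:
                continue
            proj = block.project_to_reference()
            lo, hi = max(b0, start), min(b1, end)
            for sp, chars in proj.items():
                dest = self.chars.setdefault(sp, [None] * n)
                for pos in range(lo, hi):
                    dest[pos - start] = chars[pos - b0]

    def species(self) -> list[str]:
        return sorted(self.chars)

    def slice(self, species: str, gstart: int, gend: int) -> list[str | None]:
        row = self.chars.get(species)
        if row is None:
            return [None] * (gend - gstart)
        return row[gstart - self.start:gend - self.start]


def _scan_occurrences(window: FlankWindow, motif: str,
                      proj: ReferenceProjection,
                      span: SpanningLengthCalculator,
                      reference_species: str) -> list[ConservedOccurrence]:
    genomic_motif = motif if window.strand == "+" else revcomp(motif)
    species = [sp for sp in proj.species() if sp != reference_species]
    out: list[ConservedOccurrence] = []
    k = 4
    off = window.seq.find(motif)
    while off != -1:
        if window.strand == "+":
            gstart = window.start + off
        else:
            gstart = window.end - off - k
        conserving = []
        for sp in species:
            chars = proj.slice(sp, gstart, gstart + k)
            if None not in chars and "".join(chars) == genomic_motif:
                conserving.append(sp)
        leaves = frozenset(conserving)
        length = span(leaves | {reference_species}) if leaves else 0.0
        out.append(ConservedOccurrence(window.gene_id, window.intron_index,
                                       motif, gstart, leaves, length))
        off = window.seq.find(motif, off + 1)
    return out


def occurrence_branch_length(window: FlankWindow, motif: str,
                             alignment_blocks: Sequence[AlignmentBlock],
                             tree: dendropy.Tree | SpanningLengthCalculator,
                             reference_species: str
                             ) -> list[ConservedOccurrence]:
    """Conservation of every occurrence of ``motif`` in one flank window.

    A species conserves an occurrence when all four aligned columns exist
    for it, contain no gap and spell the identical motif.  Occurrences that
    straddle a block boundary are evaluated by stitching adjacent blocks.
    The score is the branch length of the minimal subtree connecting the
    reference and all conserving leaves (0 when no species conserves,
    including reference positions that no block aligns).
    """
    if len(motif) != 4:
        raise ValueError("motifs are 4-mers")
    span = tree if isinstance(tree, SpanningLengthCalculator) \
        else SpanningLengthCalculator(tree)
    proj = ReferenceProjection(alignment_blocks, window.chrom,
                               window.start, window.end)
    return _scan_occurrences(window, motif, proj, span, reference_species)


def delta_intron(windows_of_intron: Sequence[FlankWindow],
                 targets: Sequence[str],
                 controls: Sequence[str],
                 alignment_blocks: Sequence[AlignmentBlock],
                 tree: dendropy.Tree | SpanningLengthCalculator,
                 reference_species: str) -> float:
    """Mean conserved branch length of target occurrences minus the same
    mean over control occurrences, pooled across the intron's windows.
    NaN when either occurrence pool is empty.
    """
    idx = {w.intron_index for w in windows_of_intron}
    if len(idx) != 1:
        raise ValueError("windows must belong to a single intron")
    span = tree if isinstance(tree, SpanningLengthCalculator) \
        else SpanningLengthCalculator(tree)

    projections = [
        ReferenceProjection(alignment_blocks, w.chrom, w.start, w.end)
        for w in windows_of_intron
    ]

    def pool(motifs: Sequence[str]) -> list[float]:
        lengths = []
        for w, proj in zip(windows_of_intron, projections):
            for m in motifs:
                for occ in _scan_occurrences(w, m, proj, span,
                                             reference_species):
                    lengths.append(occ.spanning_branch_length)
        return lengths

    t = pool(targets)
    c = pool(controls)
    if not t or not c:
        return math.nan
    return sum(t) / len(t) - sum(c) / len(c)


def delta_gene(per_intron_scores: Mapping[int, float] | Sequence[float]) -> float:
    """Largest defined per-intron score; NaN when none is defined."""
    values = (per_intron_scores.values()
              if isinstance(per_intron_scores, Mapping) else per_intron_scores)
    defined = [v for v in values if not math.isnan(v)]
    return max(defined) if defined else math.nan


def score_gene(gene: GeneModel, genome: Mapping[str, str],
               alignment_blocks: Sequence[AlignmentBlock],
               tree: dendropy.Tree | SpanningLengthCalculator,
               reference_species: str, *,
               flank: int = FLANK_SIZE,
               targets: Sequence[str] = TARGET_MOTIFS,
               controls: Sequence[str] | None = None) -> ConservationScore:
    """Per-intron and gene-level motif conservation scores for one gene."""
    if controls is None:
        controls = control_motif_union(targets)
    span = tree if isinstance(tree, SpanningLengthCalculator) \
        else SpanningLengthCalculator(tree)
    windows = flank_windows(gene, genome, flank)
    by_intron: dict[int, list[FlankWindow]] = {}
    for w in windows:
        by_intron.setdefault(w.intron_index, []).append(w)
    deltas: dict[int, float] = {}
    for j, ws in sorted(by_intron.items()):
        d = delta_intron(ws, targets, controls, alignment_blocks, span,
                         reference_species)
        if not math.isnan(d):
            deltas[j] = d
    dg = delta_gene(deltas) if deltas else math.nan
    best = max(deltas, key=deltas.get) if deltas else None
    return ConservationScore(gene.gene_id, deltas, dg, best)


def score_genes(genes: Sequence[GeneModel], genome: Mapping[str, str],
                alignment_blocks: Sequence[AlignmentBlock],
                tree: dendropy.Tree, reference_species: str,
                **kwargs) -> pd.DataFrame:
    """delta_gene table for a gene set (one SpanningLengthCalculator reused)."""
    span = SpanningLengthCalculator(tree)
    rows = []
    for g in genes:
        sc = score_gene(g, genome, alignment_blocks, span, reference_species,
                        **kwargs)
        rows.append((g.gene_id, sc.best_intron, sc.delta_gene))
    return pd.DataFrame(rows, columns=["gene_id", "best_intron", "delta_gene"])
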