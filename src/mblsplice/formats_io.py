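"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open on the + strand of the reference
genome; strand-aware sequence extraction reverse-complements at extraction
time so that downstream motif logic always works on the sense (transcribed)
strand.  FASTA, BED12, GFF3, MAF 1.0, Newick and a handful of TSV tables
(junction counts, sample sheets, gene->GO maps) are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A named chromosome/contig sequence over the alphabet {A,C,G,T,N}."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.chrom_name!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"illegal characters {sorted(bad)} in record {self.chrom_name!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``.  Duplicate
    headers, empty files and characters outside {A,C,G,T,N,U} raise
    :class:`FormatError` naming the offending record.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def genome_dict(records: Iterable[GenomeSequence]) -> dict[str, str]:
    return {r.chrom_name: r.sequence for r in records}


# ---------------------------------------------------------------------------
# Gene models (BED12 / GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript: ordered, non-overlapping exons in genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: at least one exon required")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise FormatError(f"{self.gene_id}: exon end {e} <= start {s}")
            if s < prev_end:
                raise FormatError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if not self.transcript_id:
            self.transcript_id = self.gene_id

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Introns in genomic order."""
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """The mature (sense-strand) transcript sequence."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


def extract_sense(genome: Mapping[str, str], chrom: str, start: int, end: int,
                  strand: str) -> str:
    """Sense-strand sequence of a genomic interval (0-based half-open)."""
    seq = genome[chrom][start:end]
    return seq if strand == "+" else revcomp(seq)


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 requires 12 fields")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise FormatError(f"{path}:{ln}: blockSizes/blockStarts mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, strand, exons))
    return genes


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                g.start, g.end, "0,0,0", len(g.exons), sizes, offsets,
            ])) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read transcripts with exon children from GFF3 (1-based -> 0-based)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        exons = [(e.start - 1, e.end) for e in db.children(feat, featuretype="exon")]
        if not exons:
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, exons,
                               transcript_id=feat.id))
    return genes


# ---------------------------------------------------------------------------
# Skipped-exon event annotations
# ---------------------------------------------------------------------------

@dataclass
class SpliceEvent:
    """A cassette exon with its flanking constitutive exons.

    Exon coordinates are genomic (``exon_before`` has the lower coordinate
    regardless of strand); transcript-level orientation is resolved through
    ``strand``.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_before: tuple[int, int]
    skipped_exon: tuple[int, int]
    exon_after: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.exon_before[1] <= self.skipped_exon[0]
                and self.skipped_exon[1] <= self.exon_after[0]):
            raise FormatError(f"{self.event_id}: exons out of genomic order")


_EVENT_COLS = ["event_id", "gene_id", "chrom", "strand",
               "before_start", "before_end", "skip_start", "skip_end",
               "after_start", "after_end"]


def read_events(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns {sorted(missing)}")
    return [
        SpliceEvent(r.event_id, r.gene_id, r.chrom, r.strand,
                    (r.before_start, r.before_end),
                    (r.skip_start, r.skip_end),
                    (r.after_start, r.after_end))
        for r in df.itertuples()
    ]


def write_events(events: Iterable[SpliceEvent], path: str | Path) -> None:
    rows = [[e.event_id, e.gene_id, e.chrom, e.strand,
             *e.exon_before, *e.skipped_exon, *e.exon_after] for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF multiple alignments
# ---------------------------------------------------------------------------

@dataclass
class MafRow:
    species: str
    chrom: str
    start: int          # 0-based on the + strand of the row's source
    size: int           # ungapped length
    strand: str
    src_size: int
    text: str           # aligned text with '-' gaps


@dataclass
class AlignmentBlock:
    """One MAF block with the reference row first and on the + strand."""

    reference_species: str
    rows: list[MafRow]

    @property
    def ncol(self) -> int:
        return len(self.rows[0].text)

    @property
    def ref_row(self) -> MafRow:
        return self.rows[0]

    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def project_to_reference(self) -> dict[str, list[str | None]]:
        """Per species, the aligned character at each ungapped reference
        position (None where the species row has a gap)."""
        ref_text = self.ref_row.text
        cols = [i for i, c in enumerate(ref_text) if c != "-"]
        out: dict[str, list[str | None]] = {}
        for row in self.rows:
            chars: list[str | None] = []
            for i in cols:
                c = row.text[i]
                chars.append(None if c == "-" else c.upper())
            out[row.species] = chars
        return out


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
    else:
        sp, chrom = src, src
    return sp, chrom


def read_maf(path: str | Path, reference_species: str) -> list[AlignmentBlock]:
    """Read MAF 1.0 blocks, normalizing the reference row to the + strand.

    Blocks missing the reference species are skipped with a warning; blocks
    whose reference row is on the - strand are reverse-complemented column
    by column with all row coordinates converted.
    """
    blocks: list[AlignmentBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        ncols = {len(rec.seq) for rec in aln}
        if len(ncols) > 1:
            raise FormatError(f"ragged columns in MAF block of {path}")
        rows = []
        for rec in aln:
            ann = rec.annotations
            sp, chrom = _split_src(rec.id)
            strand = "+" if ann.get("strand", 1) in (1, "+") else "-"
            rows.append(MafRow(sp, chrom, int(ann["start"]), int(ann["size"]),
                               strand, int(ann.get("srcSize", 0)),
                               str(rec.seq).upper()))
        ref = [r for r in rows if r.species == reference_species]
        if not ref:
            logger.warning("MAF block without reference %s skipped",
                           reference_species)
            continue
        ref_row = ref[0]
        if ref_row.strand == "-":
            # reverse-complement every row; '-' passes through translate
            for r in rows:
                r.text = r.text.translate(_COMPLEMENT)[::-1]
                r.start = r.src_size - r.start - r.size
                r.strand = "+" if r.strand == "-" else "-"
        ordered = [ref_row] + [r for r in rows if r is not ref_row]
        blocks.append(AlignmentBlock(reference_species, ordered))
    blocks.sort(key=lambda b: (b.ref_row.chrom, b.ref_row.start))
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    alns = []
    for b in blocks:
        recs = []
        for r in b.rows:
            rec = SeqRecord(Seq(r.text), id=f"{r.species}.{r.chrom}",
                            description="")
            rec.annotations.update({
                "start": r.start, "size": r.size,
                "strand": 1 if r.strand == "+" else -1,
                "srcSize": r.src_size,
            })
            recs.append(rec)
        alns.append(MultipleSeqAlignment(recs))
    AlignIO.write(alns, str(path), "maf")


# ---------------------------------------------------------------------------
# Newick species trees
# ---------------------------------------------------------------------------

def read_newick(path_or_text: str | Path) -> dendropy.Tree:
    """Read a Newick tree; every non-root edge must carry a branch length."""
    text = str(path_or_text)
    if "(" in text:
        tree = dendropy.Tree.get(data=text, schema="newick")
    else:
        tree = dendropy.Tree.get(path=text, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("Newick tree has an edge without branch length")
        if edge.length < 0:
            raise FormatError("negative branch length in species tree")
    return tree

def tree_total_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, suppress_internal_node_labels=True)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """Junction count table: event_id, sample_id, inclusion_reads,
    exclusion_reads, event_type."""
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "sample_id", "inclusion_reads", "exclusion_reads",
                "event_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"count table missing columns {sorted(missing)}")
    if df.duplicated(["event_id", "sample_id"]).any():
        raise FormatError("duplicate (event_id, sample_id) pairs in count table")
    bad = set(df.event_type) - set(EVENT_TYPES)
    if bad:
        raise FormatError(f"unknown event types {sorted(bad)}")
    if (df.inclusion_reads < 0).any() or (df.exclusion_reads < 0).any():
        raise FormatError("negative read counts")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """sample_id -> group mapping (TSV with header sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError("sample sheet needs sample_id and group columns")
    return dict(zip(df.sample_id, df.group))


@dataclass
class GoMap:
    """gene_id -> set of GO category ids, plus optional category names."""

    gene_to_categories: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.category_to_genes: dict[str, set[str]] = {}
        for g, cats in self.gene_to_categories.items():
            for c in cats:
                self.category_to_genes.setdefault(c, set()).add(g)
        empty = [c for c, genes in self.category_to_genes.items() if not genes]
        if empty:
            raise FormatError(f"empty GO categories {empty}")
        for c in self.category_to_genes:
            self.names.setdefault(c, c)

    def categories(self) -> list[str]:
        return sorted(self.category_to_genes)


def read_go_map(path: str | Path) -> GoMap:
    """Two-column TSV ``gene_id<TAB>GO:nnnnnnn`` (optional third = name)."""
    gene_to: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise FormatError(f"{path}:{ln}: expected gene<TAB>category")
            gene_to.setdefault(f[0], set()).add(f[1])
            if len(f) > 2:
                names[f[1]] = f[2]
    return GoMap(gene_to, names)


def write_go_map(gomap: GoMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gomap.gene_to_categories):
            for c in sorted(gomap.gene_to_categories[g]):
                name = gomap.names.get(c, c)
                fh.write(f"{g}\t{c}\t{name}\n")
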