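"""RNA-map motif enrichment around cassette exons.

Muscleblind/MBNL proteins bind YGCY elements; their position relative to a
regulated exon predicts the direction of regulation (downstream-intron
binding correlates with activation, exonic/upstream binding with
repression).  This module extracts the five canonical RNA-map regions
around each skipped exon, counts MBNL-binding 4-mers against
composition-matched control 4-mers, and builds the log2 enrichment matrix
contrasting regulated against unaffected exons.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GenomeSequence, SpliceEvent, extract_sense, genome_dict

logger = logging.getLogger(__name__)

#: MBNL-binding 4-mers (DNA alphabet; GCUU/UGCU at the RNA level)
TARGET_MOTIFS = ("GCTT", "CGCT", "TGCT", "GCGC")

REGION_LABELS = ("up_const_down", "skip_up", "exon", "skip_down",
                 "down_const_up")

_YGCY = re.compile(r"(?=[CT]GC[CT])")


@dataclass
class RegionSet:
    """The five sense-strand RNA-map regions of one skipped-exon event."""

    event_id: str
    exon: str
    up_const_down: str      # intron start after the upstream constitutive exon
    skip_up: str            # intron end just upstream of the skipped exon
    skip_down: str          # intron start just downstream of the skipped exon
    down_const_up: str      # intron end before the downstream constitutive exon

    def region(self, label: str) -> str:
        return getattr(self, label)


def count_kmer(sequence: str, kmer: str) -> int:
    """Overlapping occurrences of ``kmer`` in ``sequence`` (N never matches)."""
    if len(kmer) > len(sequence):
        return 0
    n = 0
    pos = sequence.find(kmer)
    while pos != -1:
        n += 1
        pos = sequence.find(kmer, pos + 1)
    return n


def count_ygcy(sequence: str) -> int:
    """Overlapping YGCY matches (Y = C or T at the DNA level)."""
    return len(_YGCY.findall(sequence))


def at_count(kmer: str) -> int:
    return sum(c in "AT" for c in kmer)


def cg_dinucleotide_count(kmer: str) -> int:
    return sum(kmer[i:i + 2] == "CG" for i in range(len(kmer) - 1))


def matched_controls(kmer: str) -> set[str]:
    """Control 4-mers with the same A+T base count and CG-dinucleotide count
    as ``kmer``, excluding the MBNL target motifs and the query itself."""
    if len(kmer) != 4:
        raise ValueError("controls are defined for 4-mers")
    a, c = at_count(kmer), cg_dinucleotide_count(kmer)
    return {
        "".join(p) for p in itertools.product("ACGT", repeat=4)
        if at_count("".join(p)) == a and cg_dinucleotide_count("".join(p)) == c
    } - set(TARGET_MOTIFS) - {kmer}


def control_motif_union(targets: Sequence[str] = TARGET_MOTIFS) -> tuple[str, ...]:
    """De-duplicated union of the matched control sets of all targets."""
    out: set[str] = set()
    for t in targets:
        out |= matched_controls(t)
    return tuple(sorted(out - set(targets)))


def _split_sizes(intron_len: int, window: int) -> int:
    # short introns are split evenly between their two windows, no overlap
    return window if intron_len >= 2 * window else intron_len // 2


def region_intervals(event: SpliceEvent, window: int = 250
                     ) -> dict[str, tuple[int, int]]:
    """Genomic (+ strand) intervals of the five RNA-map regions of an event.

    Labels are transcript-relative: on the minus strand the transcript-
    upstream intron is the genomic-right one and the "start" of an intron in
    transcript orientation is its genomic end.
    """
    i1 = (event.exon_before[1], event.skipped_exon[0])   # genomic left intron
    i2 = (event.skipped_exon[1], event.exon_after[0])    # genomic right intron
    w1 = _split_sizes(i1[1] - i1[0], window)
    w2 = _split_sizes(i2[1] - i2[0], window)
    left_start = (i1[0], i1[0] + w1)
    left_end = (i1[1] - w1, i1[1])
    right_start = (i2[0], i2[0] + w2)
    right_end = (i2[1] - w2, i2[1])
    if event.strand == "+":
        return {"exon": event.skipped_exon,
                "up_const_down": left_start, "skip_up": left_end,
                "skip_down": right_start, "down_const_up": right_end}
    return {"exon": event.skipped_exon,
            "up_const_down": right_end, "skip_up": right_start,
            "skip_down": left_end, "down_const_up": left_start}


def extract_regions(event: SpliceEvent, genome: Mapping[str, str],
                    window: int = 250) -> RegionSet:
    """Sense-strand sequences of the five RNA-map regions of one event.

    The two windows within each flanking intron shrink to floor(intron/2)
    when the intron is shorter than twice the window, so they never overlap.
    """
    intervals = region_intervals(event, window)
    seqs = {label: extract_sense(genome, event.chrom, s, e, event.strand)
            for label, (s, e) in intervals.items()}
    return RegionSet(event.event_id, **seqs)


def _pooled_frequency(seqs: Iterable[str], motifs: Sequence[str]) -> float:
    """Mean per-motif frequency: for each motif, pooled occurrences across
    all sequences divided by pooled nucleotides; averaged over motifs."""
    seqs = list(seqs)
    total_nt = sum(len(s) for s in seqs)
    if total_nt == 0:
        return math.nan
    freqs = [sum(count_kmer(s, m) for s in seqs) / total_nt for m in motifs]
    return sum(freqs) / len(freqs)


def enrichment_log2(regulated_regions: Sequence[RegionSet],
                    unaffected_regions: Sequence[RegionSet],
                    region_label: str,
                    targets: Sequence[str] = TARGET_MOTIFS,
                    controls: Sequence[str] | None = None) -> float:
    """log2 of (target/control enrichment in regulated exons) over the same
    enrichment in unaffected exons, for one RNA-map region.

    Frequencies are pooled within each event class (total occurrences over
    total nucleotides).  NaN when a control frequency pool is empty.
    """
    if not regulated_regions or not unaffected_regions:
        raise ValueError("both event sets must be non-empty")
    if region_label not in REGION_LABELS:
        raise ValueError(f"unknown region {region_label!r}")
    if controls is None:
        controls = control_motif_union(targets)

    def enrich(regions: Sequence[RegionSet]) -> float:
        seqs = [r.region(region_label) for r in regions]
        t = _pooled_frequency(seqs, targets)
        c = _pooled_frequency(seqs, controls)
        if not c or math.isnan(c) or math.isnan(t):
            return math.nan
        return t / c

    er, eu = enrich(regulated_regions), enrich(unaffected_regions)
    if math.isnan(er) or math.isnan(eu) or er == 0 or eu == 0:
        logger.warning("undefined enrichment cell for region %s", region_label)
        return math.nan
    return math.log2(er / eu)


def enrichment_matrix(regions_by_class: Mapping[str, Sequence[RegionSet]],
                      unaffected_key: str = "unaffected",
                      targets: Sequence[str] = TARGET_MOTIFS) -> pd.DataFrame:
    """Enrichment heat-map: one row per regulated event class (e.g. activated
    events stratified by how many homologs regulate them), one column per
    RNA-map region, each cell the log2 enrichment against unaffected exons."""
    if unaffected_key not in regions_by_class:
        raise ValueError(f"missing {unaffected_key!r} background class")
    controls = control_motif_union(targets)
    background = regions_by_class[unaffected_key]
    rows = {}
    for cls, regions in regions_by_class.items():
        if cls == unaffected_key or not regions:
            continue
        rows[cls] = {
            label: enrichment_log2(regions, background, label, targets, controls)
            for label in REGION_LABELS
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(REGION_LABELS))


def regions_fasta(regions: Iterable[RegionSet]) -> list[GenomeSequence]:
    """Flatten region sets to named records for optional FASTA export."""
    out = []
    for rs in regions:
        for label in REGION_LABELS:
            seq = rs.region(label)
            if seq:
                out.append(GenomeSequence(f"{rs.event_id}|{label}", seq))
    return out
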