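"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a genome of multi-exon
genes each carrying one cassette-exon event; junction read counts for
3 wild-type and 3 double-knockout replicates plus a GFP control line and
five single-replicate homolog-reconstituted lines whose rescue efficacy
varies by homolog; MBNL-binding 4-mers injected into RNA-map regions of
regulated events; multiple alignments over a species tree in which chosen
intronic motifs are held conserved while the rest of the sequence
accumulates per-branch substitutions; and a gene->GO map with one planted
category consisting of the conserved-motif genes.

Everything is driven by one :class:`SimulationConfig` and a single seed;
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (AlignmentBlock, GeneModel, GenomeSequence, GoMap,
                         MafRow, SpliceEvent, read_newick)
from .motif_map import TARGET_MOTIFS, region_intervals
from .phylo_conservation import flank_windows

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: 6-leaf tree emulating a mouse-anchored vertebrate alignment panel
DEFAULT_TREE = ("(((mm:0.08,rn:0.09):0.25,(canFam:0.17,bosTau:0.19):0.22)"
                ":0.28,(monDom:0.36,galGal:0.45):0.22);")

HOMOLOG_GROUPS = ("Hs", "Ci", "Dm", "Ce", "Ta")


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated study."""

    seed: int = 0
    # genome geometry
    n_genes: int = 500
    exons_per_gene: int = 5
    exon_length: int = 150
    intron_length: int = 600
    intergenic_length: int = 200
    chrom_name: str = "chr1"
    # splicing truth
    fraction_regulated: float = 0.1
    fraction_activated: float = 0.5     # among regulated events
    true_delta_psi: float = 0.3
    n_replicates_wt: int = 3
    n_replicates_dko: int = 3
    read_depth: int = 100
    inclusion_junctions: int = 2
    exclusion_junctions: int = 1
    homolog_efficacy: dict[str, float] = field(default_factory=lambda: {
        "Hs": 1.0, "Ci": 0.8, "Dm": 0.6, "Ce": 0.7, "Ta": 0.5})
    # RNA-map motif injection (per regulation class, per region label)
    motif_rates: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "activated": {"skip_down": 3.0},
        "repressed": {"skip_up": 3.0, "exon": 3.0}})
    rna_map_window: int = 250
    # phylogeny / conservation
    tree_newick: str = DEFAULT_TREE
    reference_species: str = "mm"
    substitution_prob: float = 0.3      # per site, per branch
    gap_prob: float = 0.0               # per site, per non-reference species
    n_conserved_genes: int = 30
    conserved_motifs_per_intron: int = 2
    flank_size: int = 150
    # gene ontology
    n_go_categories: int = 50
    go_category_size: int = 30
    planted_category_id: str = "GO:0000001"
    planted_category_name: str = "synthetic planted conserved-motif category"

    def __post_init__(self) -> None:
        for name, v in [("fraction_regulated", self.fraction_regulated),
                        ("fraction_activated", self.fraction_activated),
                        ("substitution_prob", self.substitution_prob),
                        ("gap_prob", self.gap_prob)]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.intron_length < 2:
            raise ValueError("introns must be at least 2 nt")

    def sample_groups(self) -> dict[str, str]:
        groups = {}
        for i in range(self.n_replicates_wt):
            groups[f"WT_{i + 1}"] = "WT"
        for i in range(self.n_replicates_dko):
            groups[f"DKO_{i + 1}"] = "DKO"
        groups["GFP_1"] = "GFP"
        for h in self.homolog_efficacy:
            groups[f"{h}_1"] = h
        return groups


@dataclass
class EventTruth:
    event_id: str
    gene_id: str
    regulation: str             # activated | repressed | unaffected
    true_psi: dict[str, float]  # per group


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    events: list[SpliceEvent]
    truth: list[EventTruth]
    counts: pd.DataFrame
    blocks: list[AlignmentBlock]
    gomap: GoMap
    conserved_genes: set[str]
    sample_groups: dict[str, str]

    @property
    def genome_map(self) -> dict[str, str]:
        return {self.genome.chrom_name: self.genome.sequence}


# ---------------------------------------------------------------------------
# genome & events
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, list[GeneModel], list[SpliceEvent],
                               list[EventTruth]]:
    """Uniform-background genome with one cassette-exon event per gene.

    Returns the mutable genome (byte array, for downstream motif
    injection), gene models, events and per-event regulation truth.
    """
    rng = rng or np.random.default_rng(config.seed)
    if config.exons_per_gene < 3:
        raise ValueError("genes need >= 3 exons to host a cassette exon")
    gene_span = (config.exons_per_gene * config.exon_length
                 + (config.exons_per_gene - 1) * config.intron_length)
    total = config.n_genes * (gene_span + config.intergenic_length)
    genome = _BASES[rng.integers(0, 4, total)].copy()

    genes: list[GeneModel] = []
    events: list[SpliceEvent] = []
    truth: list[EventTruth] = []
    n_reg = round(config.n_genes * config.fraction_regulated)
    reg_ids = rng.choice(config.n_genes, size=n_reg, replace=False)
    classes = np.full(config.n_genes, "unaffected", dtype=object)
    n_act = round(n_reg * config.fraction_activated)
    classes[reg_ids[:n_act]] = "activated"
    classes[reg_ids[n_act:]] = "repressed"

    groups = config.sample_groups()
    mid = config.exons_per_gene // 2
    for i in range(config.n_genes):
        offset = i * (gene_span + config.intergenic_length)
        exons = []
        pos = offset
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_length))
            pos += config.exon_length + config.intron_length
        strand = "+" if i % 2 == 0 else "-"
        gid = f"gene{i:05d}"
        gene = GeneModel(gid, config.chrom_name, strand, exons)
        genes.append(gene)
        event = SpliceEvent(f"ev{i:05d}", gid, config.chrom_name, strand,
                            exons[mid - 1], exons[mid], exons[mid + 1])
        events.append(event)
        truth.append(EventTruth(event.event_id, gid, classes[i],
                                _true_psi(classes[i], config, groups, rng)))
    return genome, genes, events, truth


def _true_psi(regulation: str, config: SimulationConfig,
              groups: Mapping[str, str], rng: np.random.Generator
              ) -> dict[str, float]:
    d = config.true_delta_psi
    if regulation == "unaffected":
        base = rng.uniform(0.1, 0.9)
        psi = {g: base for g in set(groups.values())}
        return psi
    low = rng.uniform(0.15, 0.85 - d)
    high = low + d
    wt, dko = (high, low) if regulation == "activated" else (low, high)
    psi = {"WT": wt, "DKO": dko, "GFP": dko}
    for h, eff in config.homolog_efficacy.items():
        psi[h] = dko + eff * (wt - dko)
    return psi


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def simulate_counts(config: SimulationConfig, truth: Sequence[EventTruth],
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binomial junction reads at the configured depth around true PSI.

    The junction-count weighting of the PSI estimator is inverted when
    drawing reads (an isoform supported by more junctions attracts
    proportionally more reads), so the estimator is unbiased on this data.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    ji, je = config.inclusion_junctions, config.exclusion_junctions
    groups = config.sample_groups()
    rows = []
    for t in truth:
        for sample, group in groups.items():
            psi = t.true_psi[group]
            p_inc = ji * psi / (ji * psi + je * (1 - psi))
            inc = int(rng.binomial(config.read_depth, p_inc))
            rows.append((t.event_id, sample, inc, config.read_depth - inc, "SE"))
    return pd.DataFrame(rows, columns=["event_id", "sample_id",
                                       "inclusion_reads", "exclusion_reads",
                                       "event_type"])


# ---------------------------------------------------------------------------
# motif injection
# ---------------------------------------------------------------------------

def _write_motif(genome: np.ndarray, pos: int, motif: str) -> None:
    genome[pos:pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def inject_motifs(genome: np.ndarray, events: Sequence[SpliceEvent],
                  truth: Sequence[EventTruth], config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Write target 4-mers into RNA-map regions of regulated events.

    For a region with rate multiplier m, the expected number of injected
    occurrences is (m - 1) * region_length * n_targets / 256, i.e. the
    empirical target frequency lands near m times the uniform background.
    Injected positions never overlap each other or exon boundaries (regions
    other than the exon itself are wholly intronic).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    truth_by_event = {t.event_id: t for t in truth}
    k = 4
    for event in events:
        t = truth_by_event[event.event_id]
        rates = config.motif_rates.get(t.regulation, {})
        if not rates:
            continue
        genomic_targets = [m if event.strand == "+" else _revcomp_str(m)
                           for m in TARGET_MOTIFS]
        intervals = region_intervals(event, config.rna_map_window)
        for label, mult in rates.items():
            start, end = intervals[label]
            length = end - start
            lam = max(mult - 1.0, 0.0) * length * len(TARGET_MOTIFS) / 256.0
            n = int(rng.poisson(lam))
            taken: list[tuple[int, int]] = []
            attempts = 0
            while len(taken) < n and attempts < 50 * max(n, 1):
                attempts += 1
                pos = int(rng.integers(start, end - k + 1))
                if any(pos < e and pos + k > s for s, e in taken):
                    continue
                motif = genomic_targets[int(rng.integers(len(genomic_targets)))]
                # require a clean net gain of exactly one occurrence: an
                # injection must neither destroy an existing target nor spell
                # extra ones across its junctions with the flanking sequence
                ws, we = max(start, pos - k + 1), min(end, pos + 2 * k - 1)
                before = genome[ws:we].copy()
                n_before = _count_targets(before, genomic_targets)
                _write_motif(genome, pos, motif)
                if _count_targets(genome[ws:we], genomic_targets) \
                        != n_before + 1:
                    genome[ws:we] = before
                    continue
                taken.append((pos, pos + k))
    return genome


def _count_targets(arr: np.ndarray, motifs: Sequence[str]) -> int:
    """Overlapping occurrences of any motif in a short byte window."""
    s = arr.tobytes().decode()
    return sum(1 for m in motifs for i in range(len(s) - 3) if s[i:i + 4] == m)


def plant_conserved_motifs(genome: np.ndarray, genes: Sequence[GeneModel],
                           chosen: Sequence[str], config: SimulationConfig,
                           rng: np.random.Generator | None = None
                           ) -> list[tuple[int, int]]:
    """Inject target motifs into the intronic flank windows of chosen genes
    and return the genomic intervals to be held conserved in alignments."""
    rng = rng or np.random.default_rng(config.seed + 3)
    genome_map = {config.chrom_name: genome.tobytes().decode()}
    conserved: list[tuple[int, int]] = []
    chosen_set = set(chosen)
    k = 4
    for gene in genes:
        if gene.gene_id not in chosen_set:
            continue
        for w in flank_windows(gene, genome_map, config.flank_size):
            for _ in range(config.conserved_motifs_per_intron):
                pos = int(rng.integers(w.start, w.end - k + 1))
                if any(pos < e and pos + k > s for s, e in conserved):
                    continue
                motif = TARGET_MOTIFS[int(rng.integers(len(TARGET_MOTIFS)))]
                if gene.strand == "-":
                    motif = _revcomp_str(motif)
                _write_motif(genome, pos, motif)
                conserved.append((pos, pos + k))
    return conserved


# ---------------------------------------------------------------------------
# multiple alignments
# ---------------------------------------------------------------------------

def simulate_alignments(genome: np.ndarray, genes: Sequence[GeneModel],
                        config: SimulationConfig,
                        conserved_intervals: Sequence[tuple[int, int]] = (),
                        rng: np.random.Generator | None = None
                        ) -> list[AlignmentBlock]:
    """One MAF block per intronic flank window, evolved along the tree.

    The reference leaf holds the genomic sequence; every edge of the tree
    (rerooted at the reference) substitutes each site independently with the
    configured per-branch probability, except sites inside conserved
    intervals, which are copied unchanged into every species.  An optional
    per-site gap probability punches alignment gaps into non-reference rows.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    tree = read_newick(config.tree_newick)
    ref = config.reference_species
    node = tree.find_node_with_taxon_label(ref)
    if node is None:
        raise ValueError(f"reference {ref!r} not a leaf of the tree")
    tree.reroot_at_node(node)
    genome_map = {config.chrom_name: genome.tobytes().decode()}
    src_size = len(genome)

    conserved_mask_global = np.zeros(src_size, dtype=bool)
    for s, e in conserved_intervals:
        conserved_mask_global[s:e] = True

    blocks: list[AlignmentBlock] = []
    for gene in genes:
        for w in flank_windows(gene, genome_map, config.flank_size):
            n = w.end - w.start
            ref_seq = genome[w.start:w.end].copy()
            keep = conserved_mask_global[w.start:w.end]
            seqs: dict[str, np.ndarray] = {}
            stack = [(tree.seed_node, ref_seq)]
            while stack:
                nd, seq = stack.pop()
                if nd.is_leaf() and nd.taxon.label != ref:
                    seqs[nd.taxon.label] = seq
                for child in nd.child_nodes():
                    child_seq = seq.copy()
                    mut = (rng.random(n) < config.substitution_prob) & ~keep
                    if mut.any():
                        shift = rng.integers(1, 4, int(mut.sum()))
                        codes = np.searchsorted(_BASES, child_seq[mut])
                        child_seq[mut] = _BASES[(codes + shift) % 4]
                    stack.append((child, child_seq))
            rows = [MafRow(ref, w.chrom, w.start, n, "+", src_size,
                           ref_seq.tobytes().decode())]
            for sp in sorted(seqs):
                txt = seqs[sp].astype(object)
                if config.gap_prob > 0:
                    gaps = (rng.random(n) < config.gap_prob) & ~keep
                    txt[gaps] = "-"
                text = "".join(x.decode() if isinstance(x, bytes) else x
                               for x in txt)
                rows.append(MafRow(sp, f"{sp}_chr1", w.start,
                                   n - text.count("-"), "+", src_size, text))
            blocks.append(AlignmentBlock(ref, rows))
    blocks.sort(key=lambda b: (b.ref_row.chrom, b.ref_row.start))
    return blocks


# ---------------------------------------------------------------------------
# gene ontology
# ---------------------------------------------------------------------------

def simulate_go(genes: Sequence[GeneModel], conserved_genes: Sequence[str],
                config: SimulationConfig,
                rng: np.random.Generator | None = None) -> GoMap:
    """Random GO categories plus one planted category holding exactly the
    genes that carry conserved motifs."""
    if config.n_go_categories < 2:
        raise ValueError("need at least two GO categories")
    rng = rng or np.random.default_rng(config.seed + 5)
    ids = [g.gene_id for g in genes]
    gene_to: dict[str, set[str]] = {g: set() for g in ids}
    names = {config.planted_category_id: config.planted_category_name}
    for g in conserved_genes:
        gene_to[g].add(config.planted_category_id)
    size = min(config.go_category_size, len(ids))
    for c in range(1, config.n_go_categories):
        cat = f"GO:{c + 1:07d}"
        names[cat] = f"synthetic category {c + 1}"
        for g in rng.choice(ids, size=size, replace=False):
            gene_to[str(g)].add(cat)
    gene_to = {g: cats for g, cats in gene_to.items() if cats}
    return GoMap(gene_to, names)


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run every generator stage under a single seed."""
    rng = np.random.default_rng(config.seed)
    genome, genes, events, truth = simulate_genome(config, rng)
    inject_motifs(genome, events, truth, config, rng)
    n_cons = min(config.n_conserved_genes, len(genes))
    chosen = sorted(str(g) for g in rng.choice(
        [g.gene_id for g in genes], size=n_cons, replace=False))
    conserved = plant_conserved_motifs(genome, genes, chosen, config, rng)
    blocks = simulate_alignments(genome, genes, config, conserved, rng)
    counts = simulate_counts(config, truth, rng)
    gomap = simulate_go(genes, chosen, config, rng)
    genome_rec = GenomeSequence(config.chrom_name, genome.tobytes().decode())
    return SimulatedData(config, genome_rec, genes, events, truth, counts,
                         blocks, gomap, set(chosen), config.sample_groups())


def truth_table(truth: Sequence[EventTruth]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rec = {"event_id": t.event_id, "gene_id": t.gene_id,
               "regulation": t.regulation}
        rec.update({f"psi_{g}": p for g, p in sorted(t.true_psi.items())})
        rows.append(rec)
    return pd.DataFrame(rows)
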