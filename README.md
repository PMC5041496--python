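# mblsplice

Analysis pipeline for studying how deeply the splicing-regulatory activity
of the Muscleblind (MBL/MBNL) protein family is conserved across metazoans.
MBNL proteins bind YGCY elements (Y = C/U) in pre-mRNA and regulate
alternative splicing position-dependently: binding in the intron downstream
of a cassette exon correlates with activation, binding within the exon or
the upstream intron with repression. Their loss underlies mis-splicing in
myotonic dystrophy.

The package is aimed at computational RNA biologists who want to quantify
splicing regulation from junction read counts, test the RNA-map position
signature of a splicing factor with properly matched background motifs, and
score how deeply candidate binding motifs are conserved across a species
tree — together with a synthetic-data generator that emulates the full
study design (wild-type vs. MBNL1/2 double-knockout replicates plus
homolog-reconstituted lines) so that every stage is testable against known
ground truth, with no downloads.

## What it computes

**Percent spliced in (Ψ).** For a splicing event with inclusion reads *I*
over *j_I* inclusion junctions and exclusion reads *E* over *j_E* exclusion
junctions,

    Ψ = (I/j_I) / (I/j_I + E/j_E)

with a 95% credible interval from the Jeffreys posterior
Beta(I/j_I + ½, E/j_E + ½).

**Regulated-event calls.** An event is *activated* between two conditions
when ΔΨ > 0.1, Bayes factor BF > 5 and monotonicity Z > 1.5 (repression is
symmetric). BF is a conjugate beta-binomial marginal-likelihood ratio of
"independent Ψ per condition" over "one shared Ψ", closed-form in Beta
functions; Z is a Welch statistic on replicate Ψ values with a per-group
variance floor of 10⁻⁴. Single-library homolog comparisons are gated on BF
and ΔΨ only. Reporter-assay arithmetic (background-corrected gel Ψ and
splicing activity relative to HsMBNL1, `(Ψ_homolog − Ψ_mock)/(Ψ_HsMBNL1 −
Ψ_mock)`) is included.

**RNA map.** Around each skipped exon, five regions are extracted on the
sense strand: the exon itself and 250 nt of intron downstream of the
upstream constitutive exon, upstream of the skipped exon, downstream of the
skipped exon, and upstream of the downstream constitutive exon. The
MBNL-binding 4-mers GCTT, CGCT, TGCT, GCGC are counted (overlapping)
against all control 4-mers with identical A+T base count and CG-dinucleotide
count, and each cell of the heat map is

    log2[ (target/control frequency ratio in regulated exons)
        / (target/control frequency ratio in unaffected exons) ]

with frequencies pooled across events (total occurrences / total nt).

**Phylogenetic motif conservation.** In the 150 nt of intron flanking every
internal exon, each motif occurrence is scored by the total branch length of
the minimal subtree connecting the reference species to all species whose
aligned columns spell the identical motif gaplessly (from MAF alignments
and a Newick tree). δ_intron = mean branch length of target-motif
occurrences − mean branch length of matched-control occurrences, pooled
over the intron's two windows; δ_gene = max over the gene's introns.

**GO enrichment.** Per GO category, a two-sided Wilcoxon rank-sum test of
member vs. non-member δ_gene, Benjamini–Hochberg correction, then adjusted
P set to 1 for categories whose members score *lower* than the rest
(enrichment, not depletion, is of interest); categories significant in ≥ 4
organisms form the cross-species intersection.

## Worked example

```python
from mblsplice import synthetic_data as synth, splice_quant as sq
from mblsplice import motif_map as mm, phylo_conservation as pc
from mblsplice import go_enrich as ge, formats_io as fio

cfg = synth.SimulationConfig(seed=7, n_genes=200, n_conserved_genes=15,
                             n_go_categories=20, go_category_size=12)
data = synth.simulate_all(cfg)

calls = sq.call_table(data.counts, data.sample_groups,
                      [("WT-vs-DKO", "WT", "DKO", True),
                       ("Hs-vs-GFP", "Hs", "GFP", False)])
ref = calls[calls.comparison == "WT-vs-DKO"]
print(f"significant WT-vs-DKO events: {int(ref.significant.sum())} of {len(ref)}")
```

prints

```
significant WT-vs-DKO events: 21 of 200
event_id  delta_psi         z           bf direction
 ev00028   0.275732 13.939492 1.257976e+07 activated
 ev00033   0.292379  6.882638 3.474654e+06 activated
 ev00041  -0.311392 -6.494790 1.423367e+08 repressed
```

The generator planted 20 regulated events (10% of 200); 21 calls pass all
three gates, each with the planted direction and a ΔΨ near the simulated
0.3. Continuing with the RNA map and conservation stages:

```python
truth = {t.event_id: t.regulation for t in data.truth}
classes = {"activated": [], "unaffected": []}
for e in data.events:
    if truth[e.event_id] in classes:
        classes[truth[e.event_id]].append(mm.extract_regions(e, data.genome_map))
print("skip_down log2 enrichment (activated vs unaffected):",
      round(mm.enrichment_log2(classes["activated"], classes["unaffected"],
                               "skip_down"), 2))

tree = fio.read_newick(cfg.tree_newick)
scores = pc.score_genes(data.genes, data.genome_map, data.blocks, tree, "mm")
go = ge.go_analysis(dict(zip(scores.gene_id, scores.delta_gene)), data.gomap)
print(go.head(2).to_string(index=False))
```

```
skip_down log2 enrichment (activated vs unaffected): 1.82
  category  n_in        p_raw   p_adjusted  mean_in  mean_out
GO:0000001    15 2.288881e-10 4.577763e-09 1.755497  0.195850
GO:0000004    12 2.104360e-02 2.104360e-01 0.706674  0.287684
```

The downstream-intron cell of the RNA map is strongly positive (targets
were injected there at 3× background for activated exons; log2(3) ≈ 1.58),
and the planted GO category — whose 15 member genes carry fully conserved
target motifs — tops the ranking at adjusted P ≈ 5 × 10⁻⁹ with member mean
δ_gene 1.76 against 0.20 outside.

The same stages are available as a command-line tool:

```sh
mblsplice simulate --seed 7 --out sim/
mblsplice call --counts sim/counts.tsv --samples sim/samples.tsv --out calls.tsv
mblsplice conserve --genome sim/genome.fa --genes sim/genes.bed \
    --maf sim/alignments.maf --tree sim/tree.nwk --reference mm --out scores.tsv
mblsplice run --seed 7 --out results/       # everything, with a manifest
```

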