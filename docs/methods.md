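# Methods

This note records the models implemented by `mblsplice`, the assumptions
behind them, the numerical choices where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## PSI estimation

MISO-style isoform quantification from read alignments is out of scope;
the package instead works from per-event junction read counts and uses an
analytic estimator. A cassette exon is supported by two inclusion
junctions and one exclusion junction, so raw counts are divided by the
junction multiplicity before forming

Ψ = (I/j_I) / (I/j_I + E/j_E).

This preserves the quantities downstream filters act on (ΔΨ, credible
intervals, Bayes factors) while being closed-form and exactly testable.
The 95% interval comes from the Beta(I/j_I + ½, E/j_E + ½) posterior
(Jeffreys prior on the junction-normalized counts); the interval is clipped
to contain the point estimate, which matters only in the degenerate I = 0
or E = 0 cases where the Jeffreys quantiles exclude the boundary. Zero
total coverage yields NaN flagged `no_coverage`, never a silent 0. Junction
multiplicities per event class (SE 2:1, RI 2:1, MXE 2:2, A5SS/A3SS 1:1)
are configuration, not inference.

## Bayes factor

The two-sample Bayes factor compares H1 (each sample has its own Ψ with a
Uniform(0,1) prior) against H0 (one shared Ψ) over binomial likelihoods on
the junction-normalized counts rounded half-up:

BF = B(i₁+1, e₁+1) · B(i₂+1, e₂+1) / B(i₁+i₂+1, e₁+e₂+1),

computed in log space with `betaln`. BF > 1 favours different Ψ. All-zero
counts return BF = 1 with a `no_information` flag. Calibration under the
null (equal Ψ, 50 reads per sample) keeps the BF > 5 rate well below 5%,
and a true ΔΨ of 0.4 at 100 reads is detected in essentially all
simulations; both rates are recomputed by the test suite and the acceptance
script rather than quoted here.

## Monotonicity Z

No closed definition of the replicate-consistency Z-score exists in the
source material, so the package declares one: a Welch-type statistic on
replicate Ψ values,

Z = (mean_A − mean_B) / sqrt(max(var_A, ε)/n_A + max(var_B, ε)/n_B),

with each group's sample variance floored at ε = 10⁻⁴ so that perfectly
reproducible replicates (variance 0, common at high Ψ separation) give a
large finite score instead of infinity. Z is signed and must agree in sign
with ΔΨ for a call. Groups with fewer than two finite values give NaN.

## Regulated-event calls

Activation requires ΔΨ > 0.1 **and** BF > 5 **and** Z > 1.5; repression is
the mirror image. All three thresholds are strict inequalities and
configurable. The homolog-reconstitution comparisons are single library
against single library (no replicates), so those calls use the BF and ΔΨ
gates only — the Z gate applies to the replicated wild-type vs.
double-knockout contrast. Undefined statistics propagate as explicit
`low_coverage` flags and an `unaffected` call. Between-group ΔΨ is the
difference of group mean Ψ; the group BF pools junction-normalized counts
within each group.

## RNA-map regions and enrichment

The five regions are resolved in transcript orientation and extracted on
the sense strand (minus-strand genes are reverse-complemented at extraction
time, so motif logic is strand-free). An intron shorter than twice the
250-nt window is split evenly, floor(intron/2) to each of its two windows,
which therefore never overlap.

Motif counting is overlapping (GCGC occurs twice in GCGCGC) and positions
containing N never match. Control 4-mers for a target are all 4-mers with
the same A+T base count and the same count of CG dinucleotides (3
dinucleotide slots), excluding the four targets and the query; the
conservation and enrichment analyses use the de-duplicated union of the
four targets' control sets (114 4-mers). Frequencies are pooled within an
event class — total occurrences over total nucleotides, motif-averaged —
rather than averaged per event; pooling is robust to the short truncated
regions of small introns, and the choice is declared so results are
reproducible. Cells whose control pool is empty are reported missing, not
zero. Event classes follow the homolog-agreement stratification (regulated
between WT and DKO; additionally regulated by 1–2 or by ≥3 homologs),
activated and repressed separately, always against the unaffected class.

## Branch-length conservation

"Branch length across which a motif is conserved" is formalized as the
total edge length of the minimal spanning subtree connecting the reference
leaf and every conserving leaf — the standard phylogenetic span. It reduces
to the reference-to-X path for a single conserving species, to the whole
tree when all species conserve, and to 0 when none does. An edge belongs to
the spanning subtree exactly when selected leaves lie on both of its sides;
the calculator precomputes per-edge leaf sets and memoises by leaf subset,
and is verified against an independent union-of-pairwise-paths oracle on
random trees.

A species conserves an occurrence only if all four aligned columns exist,
are gap-free, and spell the identical motif — no shifted or compensatory
matches. Species absent from a MAF block are "not aligned", which is
treated as non-conservation (the occurrence still enters the pool with
span 0), not as an exclusion: absence of alignment at this evolutionary
depth is evidence against conservation. Occurrences straddling MAF block
boundaries are evaluated by projecting all overlapping blocks onto
reference coordinates and stitching.

δ_intron pools the two 150-nt windows of an intron (downstream of the
upstream exon, upstream of the downstream exon) as one region, and is the
per-occurrence mean span of targets minus the per-occurrence mean span of
controls (controls pooled per occurrence, not per motif). An intron with an
empty target or control pool is undefined and skipped; δ_gene is the
maximum over defined introns and is undefined only when no intron scored,
in which case the gene is excluded from GO testing rather than scored 0.

## GO enrichment

Member vs. non-member δ_gene values are compared with a two-sided
Mann–Whitney/Wilcoxon rank-sum test: the exact null distribution when
n_in · n_out ≤ 400 and there are no ties, otherwise the tie-corrected
normal approximation. Genes without a defined δ_gene are excluded from both
sides; categories with fewer than 5 scored members are reported untested
(a declared power floor). Benjamini–Hochberg correction is applied across
tested categories, and only then the directional floor: adjusted P is set
to 1 wherever mean_in < mean_out (strict), because only enrichment of
conserved motifs — not depletion — is biologically interesting here. The
cross-species intersection keeps categories with adjusted P < 0.01 in at
least 4 organisms (inclusive) and reports a −log₁₀(P) matrix for display.

## Synthetic data

The generator emulates the study design, not sequencing physics. Defaults:
500 genes of 5 exons (150 nt) and 4 introns (600 nt) on alternating
strands, one cassette-exon event per gene; 10% of events regulated with
true ΔΨ = 0.3 (half activated, half repressed); 3 wild-type and 3
double-knockout replicates, one GFP control library and one library per
homolog; 100 junction reads per event and sample. Homolog rescue efficacy
defaults (Hs 1.0, Ci 0.8, Ce 0.7, Dm 0.6, Ta 0.5) mirror the qualitative
ordering of regulation strength across homologs; they are arbitrary and
configurable. Junction reads are binomial with the junction weighting of
the estimator inverted, so the estimator is unbiased on generated data.

Motif injection writes target 4-mers into chosen RNA-map regions of
regulated events at a rate multiplier over the uniform background
(expected injections = (m−1)·L·4/256). Each injection is accepted only if
it produces a net gain of exactly one target occurrence in its local
window — otherwise junction effects (e.g. GCTT preceded by T also spells
TGCT) would systematically overshoot the nominal multiplier.

Alignments are simulated by rerooting the species tree at the reference
leaf and substituting each site independently with probability 0.3 per
branch (uniform alternative base, no rate heterogeneity, no indels beyond
an optional uniform gap rate), which exercises gap and mismatch handling
without attempting alignment realism. In 30 planted genes, injected
intronic flank motifs are copied unchanged into every species, making them
conserved across the full tree; these genes form the planted GO category
among 49 random ones.

What the generator does **not** emulate: read-level noise and mapping
bias, overdispersion between biological replicates, non-uniform base
composition and repeat structure, indel-rich alignments, correlated motif
clustering, and GO-hierarchy structure (annotations are used as given,
without true-path propagation). Passing recovery tests therefore show that
the statistics detect the planted structure under the declared noise
model, not that they are robust to every artefact of real RNA-seq or real
whole-genome alignments.

## Problem sizes and determinism

The test suite and acceptance script run each recovery analysis at the
scale the design calls for — 500 events (50 regulated) for calling, 500
events per class for the RNA map, 500 genes (30 planted) for conservation
— which keeps the full suite in the tens of seconds. All randomness flows
from explicit `numpy` generator seeds; a fixed seed reproduces
byte-identical generated files and pipeline outputs, and the CLI writes a
manifest (config hash, seed, version) alongside results.
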