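"""Gene Ontology enrichment of motif-conservation scores.

Each GO category's member genes' delta_gene scores are compared against
all non-member genes with a two-sided Wilcoxon rank-sum test; P-values are
Benjamini-Hochberg corrected, then categories whose members score *lower*
than the rest are floored to P = 1 (only enrichment for conserved motifs
is of interest, not depletion).  A cross-species intersection keeps
categories significant in at least a minimum number of organisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .formats_io import GoMap

EXACT_PRODUCT_LIMIT = 400   # exact null distribution up to n_in * n_out pairs
MIN_CATEGORY_GENES = 5


@dataclass
class GoResult:
    category: str
    name: str
    n_in: int
    n_out: int
    p_raw: float
    p_adjusted: float
    mean_in: float
    mean_out: float
    floored: bool = False


def ranksum_enrichment(delta_gene_by_gene: Mapping[str, float],
                       category_members: set[str]
                       ) -> tuple[float, float, float]:
    """Two-sided rank-sum P comparing member against non-member scores.

    Genes without a defined score are excluded from both sides.  The exact
    null distribution is used for small problems without ties; otherwise
    the tie-corrected normal approximation.  Returns (p, mean_in, mean_out).
    """
    inside, outside = [], []
    for gene, d in delta_gene_by_gene.items():
        if d is None or math.isnan(d):
            continue
        (inside if gene in category_members else outside).append(d)
    if not inside or not outside:
        raise ValueError("need defined scores both inside and outside")
    has_ties = len(set(inside + outside)) < len(inside) + len(outside)
    method = ("exact"
              if len(inside) * len(outside) <= EXACT_PRODUCT_LIMIT and not has_ties
              else "asymptotic")
    res = mannwhitneyu(inside, outside, alternative="two-sided", method=method)
    return float(res.pvalue), float(np.mean(inside)), float(np.mean(outside))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def directional_floor(results: Sequence[GoResult]) -> list[GoResult]:
    """Set adjusted P to 1 for categories whose members score strictly lower
    on average than non-members (applied after BH correction)."""
    for r in results:
        if r.mean_in < r.mean_out:
            r.p_adjusted = 1.0
            r.floored = True
    return list(results)


def go_analysis(delta_gene_by_gene: Mapping[str, float], gomap: GoMap,
                min_genes: int = MIN_CATEGORY_GENES) -> pd.DataFrame:
    """Full single-species analysis: rank-sum per category, BH, floor.

    Categories with fewer than ``min_genes`` members holding defined scores
    are reported untested (NaN P-values).
    """
    scored = {g: d for g, d in delta_gene_by_gene.items()
              if d is not None and not math.isnan(d)}
    results: list[GoResult] = []
    untested: list[GoResult] = []
    for cat in gomap.categories():
        members = gomap.category_to_genes[cat] & scored.keys()
        outside_n = len(scored) - len(members)
        name = gomap.names.get(cat, cat)
        if len(members) < min_genes or outside_n < 1:
            untested.append(GoResult(cat, name, len(members), outside_n,
                                     math.nan, math.nan, math.nan, math.nan))
            continue
        p, mi, mo = ranksum_enrichment(scored, gomap.category_to_genes[cat])
        results.append(GoResult(cat, name, len(members), outside_n, p,
                                math.nan, mi, mo))
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
        directional_floor(results)
    rows = results + untested
    return pd.DataFrame(
        [(r.category, r.name, r.n_in, r.n_out, r.p_raw, r.p_adjusted,
          r.mean_in, r.mean_out, r.floored) for r in rows],
        columns=["category", "name", "n_in", "n_out", "p_raw", "p_adjusted",
                 "mean_in", "mean_out", "floored"],
    ).sort_values("p_adjusted", kind="stable").reset_index(drop=True)


def cross_species_intersection(per_species_results: Mapping[str, pd.DataFrame],
                               alpha: float = 0.01, min_species: int = 4
                               ) -> tuple[list[str], pd.DataFrame]:
    """Categories significant (adjusted P < alpha) in >= min_species organisms.

    Returns the retained category list and a -log10(adjusted P) matrix
    (categories x species) for heat-map display.
    """
    if len(per_species_results) < min_species:
        raise ValueError("fewer result sets than min_species")
    support: dict[str, int] = {}
    logp: dict[str, dict[str, float]] = {}
    for sp, df in per_species_results.items():
        for r in df.itertuples():
            p = r.p_adjusted
            if not math.isfinite(p):
                continue
            logp.setdefault(r.category, {})[sp] = -math.log10(max(p, 1e-300))
            if p < alpha:
                support[r.category] = support.get(r.category, 0) + 1
    kept = sorted(c for c, n in support.items() if n >= min_species)
    matrix = pd.DataFrame(
        [[logp.get(c, {}).get(sp, math.nan) for sp in per_species_results]
         for c in kept],
        index=kept, columns=list(per_species_results))
    return kept, matrix
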