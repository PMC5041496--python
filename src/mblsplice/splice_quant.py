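"""Percent-spliced-in (PSI) estimation and regulated-event calling.

PSI is estimated from junction read counts normalized by the number of
junctions supporting each isoform (a cassette exon has two inclusion
junctions and one exclusion junction), with a Jeffreys-prior Beta credible
interval.  Differential regulation between conditions is gated on three
statistics: a conjugate beta-binomial Bayes factor, the between-group PSI
difference, and a monotonicity Z-score on replicate PSI values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import beta as beta_dist
from scipy.stats import binomtest, pearsonr

DEFAULT_THRESHOLDS = {"bf_min": 5.0, "dpsi_min": 0.1, "z_min": 1.5}

#: junctions supporting the inclusion / exclusion isoform, per event type
JUNCTIONS_BY_TYPE = {
    "SE": (2, 1), "RI": (2, 1), "MXE": (2, 2), "A5SS": (1, 1), "A3SS": (1, 1),
}

VARIANCE_FLOOR = 1e-4


@dataclass
class PsiEstimate:
    event_id: str
    sample_id: str
    psi: float
    ci_low: float
    ci_high: float
    inclusion_reads: int
    exclusion_reads: int
    bayes_factor: float | None = None
    no_coverage: bool = False


def estimate_psi(inclusion_reads: int, exclusion_reads: int,
                 n_inclusion_junctions: int = 2, n_exclusion_junctions: int = 1,
                 *, ci_level: float = 0.95,
                 event_id: str = "", sample_id: str = "") -> PsiEstimate:
    """Junction-normalized PSI with a Jeffreys-prior Beta credible interval.

    The point estimate is ``(inc/j_inc) / (inc/j_inc + exc/j_exc)``; the
    interval comes from the Beta(inc_norm + 1/2, exc_norm + 1/2) posterior
    quantiles.  Zero coverage yields an NaN estimate flagged ``no_coverage``.
    """
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("read counts must be non-negative")
    if n_inclusion_junctions < 1 or n_exclusion_junctions < 1:
        raise ValueError("junction counts must be >= 1")
    if inclusion_reads + exclusion_reads == 0:
        return PsiEstimate(event_id, sample_id, math.nan, math.nan, math.nan,
                           0, 0, no_coverage=True)
    i = inclusion_reads / n_inclusion_junctions
    e = exclusion_reads / n_exclusion_junctions
    psi = i / (i + e)
    alpha = 1.0 - ci_level
    lo = beta_dist.ppf(alpha / 2, i + 0.5, e + 0.5)
    hi = beta_dist.ppf(1 - alpha / 2, i + 0.5, e + 0.5)
    return PsiEstimate(event_id, sample_id, psi,
                       min(lo, psi), max(hi, psi),
                       inclusion_reads, exclusion_reads)


def gel_psi(inclusion_intensity: float, exclusion_intensity: float,
            background: float) -> float:
    """Percent exon inclusion from gel band intensities.

    Background-corrected inclusion product over total background-corrected
    splice product.  NaN when both corrected intensities are zero.
    """
    if inclusion_intensity < background or exclusion_intensity < background:
        raise ValueError("band intensities must be >= background")
    inc = inclusion_intensity - background
    exc = exclusion_intensity - background
    if inc + exc == 0:
        return math.nan
    return inc / (inc + exc)


def relative_activity(psi_homolog: float, psi_mock: float,
                      psi_hsmbnl1: float) -> float:
    """Splicing activity of a homolog relative to human MBNL1.

    ``(homolog - mock) / (HsMBNL1 - mock)`` on exon-inclusion fractions; 1
    means parity with HsMBNL1, 0 no activity, negative values the opposite
    direction.  NaN when HsMBNL1 did not move PSI off the mock level.
    """
    denom = psi_hsmbnl1 - psi_mock
    if denom == 0:
        return math.nan
    return (psi_homolog - psi_mock) / denom


class BayesFactorResult(NamedTuple):
    value: float
    no_information: bool = False


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bayes_factor_two_sample(inc1: float, exc1: float, inc2: float, exc2: float
                            ) -> BayesFactorResult:
    """Beta-binomial Bayes factor that two samples have different PSI.

    Marginal likelihoods are closed-form in Beta functions: under H0 a
    single PSI with a Uniform(0,1) prior generates both binomial counts,
    under H1 each sample has its own uniform PSI.  Counts are the
    junction-normalized read counts rounded half-up.  BF > 1 favours
    different PSI.  All-zero counts carry no information and return 1.
    """
    i1, e1 = _round_half_up(inc1), _round_half_up(exc1)
    i2, e2 = _round_half_up(inc2), _round_half_up(exc2)
    if min(i1, e1, i2, e2) < 0:
        raise ValueError("counts must be non-negative")
    if i1 + e1 + i2 + e2 == 0:
        return BayesFactorResult(1.0, no_information=True)
    log_h1 = betaln(i1 + 1, e1 + 1) + betaln(i2 + 1, e2 + 1)
    log_h0 = betaln(i1 + i2 + 1, e1 + e2 + 1)
    return BayesFactorResult(math.exp(log_h1 - log_h0))


def monotonicity_z(group_a_psis: Sequence[float], group_b_psis: Sequence[float],
                   variance_floor: float = VARIANCE_FLOOR) -> float:
    """Welch-type Z separating two replicate groups of PSI values.

    Each group's sample variance is floored at ``variance_floor`` so that
    perfectly reproducible replicates cannot produce an infinite score.
    Positive Z means group A is more included.  NaN when a group has fewer
    than two finite values.
    """
    a = np.asarray([x for x in group_a_psis if math.isfinite(x)], float)
    b = np.asarray([x for x in group_b_psis if math.isfinite(x)], float)
    if len(a) < 2 or len(b) < 2:
        return math.nan
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0.0
    va = max(a.var(ddof=1), variance_floor)
    vb = max(b.var(ddof=1), variance_floor)
    return float((a.mean() - b.mean()) / math.sqrt(va / len(a) + vb / len(b)))


@dataclass
class RegulationCall:
    event_id: str
    comparison: str
    delta_psi: float
    z: float | None
    bayes_factor: float
    direction: str          # activated | repressed | unaffected
    significant: bool
    low_coverage: bool = False


def call_regulation(event_id: str, comparison: str, delta_psi: float,
                    bayes_factor: float, z: float | None = None, *,
                    bf_min: float = 5.0, dpsi_min: float = 0.1,
                    z_min: float = 1.5) -> RegulationCall:
    """Classify one event/comparison as activated, repressed or unaffected.

    Activation requires dPSI > dpsi_min, BF > bf_min and, when a Z score is
    supplied, Z > z_min (the Z is signed and must agree with dPSI);
    repression is symmetric.  Undefined statistics yield an unaffected call
    flagged ``low_coverage``.
    """
    if min(bf_min, dpsi_min, z_min) <= 0:
        raise ValueError("thresholds must be positive")
    undefined = (not math.isfinite(delta_psi)) or (not math.isfinite(bayes_factor)) \
        or (z is not None and not math.isfinite(z))
    if undefined:
        return RegulationCall(event_id, comparison, delta_psi, z, bayes_factor,
                              "unaffected", False, low_coverage=True)
    direction = "unaffected"
    if bayes_factor > bf_min:
        if delta_psi > dpsi_min and (z is None or z > z_min):
            direction = "activated"
        elif delta_psi < -dpsi_min and (z is None or z < -z_min):
            direction = "repressed"
    return RegulationCall(event_id, comparison, delta_psi, z, bayes_factor,
                          direction, direction != "unaffected")


def call_from_groups(event_id: str, comparison: str,
                     psis_a: Sequence[float], psis_b: Sequence[float],
                     counts_a: tuple[float, float], counts_b: tuple[float, float],
                     *, use_z: bool = True, **thresholds) -> RegulationCall:
    """Group-vs-group call: dPSI from group means, BF from pooled
    junction-normalized counts, Z from replicate PSIs (skipped for
    single-sample comparisons with ``use_z=False``)."""
    a = [x for x in psis_a if math.isfinite(x)]
    b = [x for x in psis_b if math.isfinite(x)]
    dpsi = (float(np.mean(a)) - float(np.mean(b))) if a and b else math.nan
    bf = bayes_factor_two_sample(*counts_a, *counts_b).value
    z = monotonicity_z(psis_a, psis_b) if use_z else None
    return call_regulation(event_id, comparison, dpsi, bf, z, **thresholds)


@dataclass
class AgreementSummary:
    event_id: str
    n_homologs_regulating: int
    consistent_fraction: float      # among regulating homologs
    consistent_direction: bool
    per_homolog: dict[str, bool] = field(default_factory=dict)


def homolog_agreement(reference_call: RegulationCall,
                      homolog_calls: Mapping[str, RegulationCall]
                      ) -> AgreementSummary:
    """How many homolog lines regulate an event, and whether their direction
    matches the wild-type-vs-knockout reference."""
    for c in homolog_calls.values():
        if c.event_id != reference_call.event_id:
            raise ValueError("all calls must refer to the same event")
    ref_sign = math.copysign(1.0, reference_call.delta_psi) \
        if reference_call.delta_psi else 0.0
    per: dict[str, bool] = {}
    for name, call in homolog_calls.items():
        if call.significant:
            per[name] = (math.copysign(1.0, call.delta_psi) == ref_sign)
    n = len(per)
    frac = (sum(per.values()) / n) if n else math.nan
    return AgreementSummary(reference_call.event_id, n, frac,
                            bool(per) and all(per.values()), per)


def agreement_table(calls: pd.DataFrame, reference_comparison: str,
                    homolog_comparisons: Sequence[str]) -> pd.DataFrame:
    """Per-event homolog-agreement summary from a calls table."""
    rows = []
    ref = calls[calls.comparison == reference_comparison].set_index("event_id")
    hom = calls[calls.comparison.isin(homolog_comparisons)]
    for event, sub in hom.groupby("event_id", sort=True):
        if event not in ref.index:
            continue
        r = ref.loc[event]
        ref_call = RegulationCall(event, reference_comparison, r.delta_psi,
                                  r.z if math.isfinite(r.z) else None,
                                  r.bf, r.direction, bool(r.significant))
        hom_calls = {
            s.comparison: RegulationCall(event, s.comparison, s.delta_psi,
                                         None, s.bf, s.direction,
                                         bool(s.significant))
            for s in sub.itertuples()
        }
        summary = homolog_agreement(ref_call, hom_calls)
        rows.append((event, r.direction, bool(r.significant),
                     summary.n_homologs_regulating,
                     summary.consistent_fraction,
                     summary.consistent_direction))
    return pd.DataFrame(rows, columns=[
        "event_id", "reference_direction", "reference_significant",
        "n_homologs_regulating", "consistent_fraction", "consistent_direction"])


def direction_bias_test(n_activated: int, n_repressed: int) -> float:
    """Two-sided exact binomial P for activation/repression imbalance."""
    if n_activated < 0 or n_repressed < 0 or n_activated + n_repressed < 1:
        raise ValueError("need non-negative counts summing to >= 1")
    return float(binomtest(n_activated, n_activated + n_repressed, 0.5).pvalue)


@dataclass
class CorrelationResult:
    comparison: str
    r_squared: float
    n_events: int


def rescue_correlation(delta_ref_by_event: Mapping[str, float],
                       delta_homolog_by_event: Mapping[str, float],
                       comparison: str = "") -> CorrelationResult:
    """Squared Pearson correlation of paired per-event dPSI values."""
    shared = [e for e in delta_ref_by_event
              if e in delta_homolog_by_event
              and math.isfinite(delta_ref_by_event[e])
              and math.isfinite(delta_homolog_by_event[e])]
    if len(shared) < 3:
        raise ValueError("need >= 3 paired finite delta-PSI values")
    x = np.array([delta_ref_by_event[e] for e in shared])
    y = np.array([delta_homolog_by_event[e] for e in shared])
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(comparison, math.nan, len(shared))
    r = pearsonr(x, y).statistic
    return CorrelationResult(comparison, float(r * r), len(shared))


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def quantify_table(counts: pd.DataFrame,
                   junctions_by_type: Mapping[str, tuple[int, int]] | None = None
                   ) -> pd.DataFrame:
    """PSI estimates for every (event, sample) row of a count table."""
    junc = dict(JUNCTIONS_BY_TYPE)
    if junctions_by_type:
        junc.update(junctions_by_type)
    rows = []
    for r in counts.itertuples():
        ji, je = junc[r.event_type]
        est = estimate_psi(r.inclusion_reads, r.exclusion_reads, ji, je,
                           event_id=r.event_id, sample_id=r.sample_id)
        rows.append((r.event_id, r.sample_id, r.event_type, est.psi,
                     est.ci_low, est.ci_high, r.inclusion_reads,
                     r.exclusion_reads, est.no_coverage))
    return pd.DataFrame(rows, columns=[
        "event_id", "sample_id", "event_type", "psi", "ci_low", "ci_high",
        "inclusion_reads", "exclusion_reads", "no_coverage"])


def call_table(counts: pd.DataFrame, samples: Mapping[str, str],
               comparisons: Sequence[tuple[str, str, str, bool]],
               *, thresholds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Regulation calls for every event under a list of comparisons.

    ``comparisons`` is a list of (label, group_a, group_b, use_z); per-event
    dPSI is mean(group_a) - mean(group_b).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    junc = JUNCTIONS_BY_TYPE
    psi = quantify_table(counts)
    out = []
    for event, ev_psi in psi.groupby("event_id", sort=True):
        by_group: dict[str, tuple[list[float], tuple[float, float]]] = {}
        for r in ev_psi.itertuples():
            g = samples.get(r.sample_id)
            if g is None:
                continue
            ji, je = junc[r.event_type]
            psis, (inc, exc) = by_group.setdefault(g, ([], (0.0, 0.0)))
            by_group[g] = (psis + [r.psi],
                           (inc + r.inclusion_reads / ji,
                            exc + r.exclusion_reads / je))
        for label, ga, gb, use_z in comparisons:
            if ga not in by_group or gb not in by_group:
                continue
            pa, ca = by_group[ga]
            pb, cb = by_group[gb]
            call = call_from_groups(event, label, pa, pb, ca, cb,
                                    use_z=use_z, **thr)
            out.append((event, label, call.delta_psi,
                        call.z if call.z is not None else math.nan,
                        call.bayes_factor, call.direction, call.significant,
                        call.low_coverage))
    return pd.DataFrame(out, columns=[
        "event_id", "comparison", "delta_psi", "z", "bf", "direction",
        "significant", "low_coverage"])
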