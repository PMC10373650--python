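"""Prognostic biomarker screening from signaling genes.

Signaling genes — the top-5% genes by local sMFE in each sample — are
screened for prognostic value in three steps:

1. split samples at the median survival time into long- and short-survival
   groups (ties go to the long group);
2. a non-differentially-expressed signaling gene is a *candidate* when the
   samples it identifies (those whose signaling set contains it) are
   enriched in one group: n/(n+m) > A or m/(n+m) > A with A = 0.6, where n
   and m count identified samples in the long and short group;
3. each candidate is classified by a Kaplan-Meier log-rank test of
   identified vs unidentified samples: *optimistic* (O-sMFE) if P < 0.05
   and the identified samples survive longer, *pessimistic* (P-sMFE) if
   P < 0.05 and they survive shorter, otherwise unclassified.

"Longer" is operationalized as a positive difference in restricted-mean
survival time over the common follow-up window, which stays defined when
heavy censoring leaves the median survival undefined.

The module also extracts DNB-style *common signaling genes*: genes shared
by the signaling sets of the samples in the critical stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SurvivalRecord

logger = logging.getLogger("smfe")

__all__ = [
    "SurvivalSplit",
    "BiomarkerResult",
    "split_by_median",
    "candidate_biomarkers",
    "classify_biomarker",
    "non_de_genes",
    "common_signaling_genes",
    "screen_biomarkers",
]


@dataclass(frozen=True)
class SurvivalSplit:
    """Samples partitioned at the median survival time."""

    long_group: frozenset[str]
    short_group: frozenset[str]
    median_time: float


@dataclass(frozen=True)
class BiomarkerResult:
    """Classification of one candidate gene.

    ``n_long``/``m_short`` count identified samples from the long/short
    survival groups; ``enrichment`` is max(n, m)/(n + m);
    ``direction_stat`` is the restricted-mean survival difference
    (identified minus unidentified, positive = identified live longer).
    """

    gene: str
    n_long: int
    m_short: int
    enrichment: float
    logrank_p: float
    direction_stat: float
    biomarker_class: str  # "optimistic" | "pessimistic" | "none"


def split_by_median(records: list[SurvivalRecord], ties_to_long: bool = True) -> SurvivalSplit:
    """Split samples into long/short survival groups at the median time.

    The median is taken over all observed times, censored and uncensored
    alike.  Samples exactly at the median join the long group by default.
    """
    if len(records) < 4:
        raise ValueError(f"need >= 4 survival records to split, got {len(records)}")
    times = np.array([r.time for r in records], dtype=float)
    if np.all(times == times[0]):
        raise ValueError("degenerate survival distribution: all times equal")
    median = float(np.median(times))
    long_g, short_g = set(), set()
    for r in records:
        if r.time > median or (ties_to_long and r.time == median):
            long_g.add(r.sample_id)
        else:
            short_g.add(r.sample_id)
    return SurvivalSplit(frozenset(long_g), frozenset(short_g), median)


def candidate_biomarkers(
    signaling_sets: dict[str, set[str]],
    non_de: set[str],
    split: SurvivalSplit,
    A: float = 0.6,
) -> list[tuple[str, int, int]]:
    """Enrichment filter: non-DE signaling genes concentrated in one group.

    Returns ``(gene, n, m)`` triples sorted by gene, where n/m count
    identified samples from the long/short group, for genes with
    n/(n+m) > A or m/(n+m) > A.  Genes identified by no sample with
    survival data are skipped (never a division by zero).
    """
    if not 0.5 <= A < 1.0:
        raise ValueError(f"A must be in [0.5, 1), got {A}")
    seen: dict[str, tuple[int, int]] = {}
    for sample, genes in signaling_sets.items():
        in_long = sample in split.long_group
        in_short = sample in split.short_group
        if not (in_long or in_short):
            continue
        for g in genes:
            if g not in non_de:
                continue
            n, m = seen.get(g, (0, 0))
            seen[g] = (n + int(in_long), m + int(in_short))
    out = []
    for g in sorted(seen):
        n, m = seen[g]
        if n + m == 0:
            continue
        if n / (n + m) > A or m / (n + m) > A:
            out.append((g, n, m))
    return out


def classify_biomarker(
    gene: str,
    identified: set[str],
    records: list[SurvivalRecord],
    alpha: float = 0.05,
) -> BiomarkerResult:
    """Log-rank classification of one candidate gene.

    Identified samples are those whose signaling set contains the gene.
    With log-rank P < alpha, the gene is optimistic when identified
    samples' restricted-mean survival exceeds the unidentified samples',
    pessimistic when it falls short.
    """
    ident = [r for r in records if r.sample_id in identified]
    unident = [r for r in records if r.sample_id not in identified]
    if len(ident) < 2 or len(unident) < 2:
        raise ValueError(
            f"gene {gene!r}: identified ({len(ident)}) and unidentified "
            f"({len(unident)}) groups each need >= 2 records"
        )
    split = split_by_median(records)
    n = len(identified & split.long_group)
    m = len(identified & split.short_group)
    enrichment = max(n, m) / (n + m) if n + m else float("nan")
    t1 = np.array([r.time for r in ident])
    e1 = np.array([r.event for r in ident])
    t0 = np.array([r.time for r in unident])
    e0 = np.array([r.event for r in unident])
    if e1.sum() + e0.sum() == 0:
        logger.warning("gene %r: no events in either group, log-rank undefined", gene)
        return BiomarkerResult(gene, n, m, enrichment, float("nan"), float("nan"), "none")

    p = float(logrank_test(t1, t0, event_observed_A=e1, event_observed_B=e0).p_value)
    tau = float(min(t1.max(), t0.max()))
    km1 = KaplanMeierFitter().fit(t1, e1)
    km0 = KaplanMeierFitter().fit(t0, e0)
    rmst1 = float(restricted_mean_survival_time(km1, t=tau))
    rmst0 = float(restricted_mean_survival_time(km0, t=tau))
    direction = rmst1 - rmst0
    if p < alpha and direction > 0:
        cls = "optimistic"
    elif p < alpha and direction < 0:
        cls = "pessimistic"
    else:
        cls = "none"
    return BiomarkerResult(gene, n, m, enrichment, p, direction, cls)


def non_de_genes(
    tumor: ExpressionMatrix,
    reference: ExpressionMatrix,
    fdr: float = 0.05,
) -> set[str]:
    """Genes *not* differentially expressed between tumor and reference.

    Per-gene two-sample Welch t-test with Benjamini-Hochberg adjustment;
    genes with adjusted P >= fdr are retained.  Genes constant in both
    cohorts (undefined t) count as non-DE with a warning.
    """
    common = [g for g in tumor.gene_ids if g in set(reference.gene_ids)]
    if tumor.shape[1] < 2 or reference.shape[1] < 2:
        raise ValueError("need >= 2 samples per cohort for the DE test")
    a = tumor.data.loc[common].to_numpy()
    b = reference.data.loc[common].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    undefined = ~np.isfinite(pvals)
    if undefined.any():
        logger.warning("%d genes with undefined t statistic treated as non-DE",
                       int(undefined.sum()))
    keep = np.ones(len(common), dtype=bool)
    defined = ~undefined
    if defined.any():
        reject, *_ = multipletests(pvals[defined], alpha=fdr, method="fdr_bh")
        keep[defined] = ~reject
    return {g for g, k in zip(common, keep) if k}


def common_signaling_genes(
    signaling_sets: dict[str, set[str]],
    stage_samples: set[str],
    min_fraction: float = 1.0,
) -> set[str]:
    """Genes shared by the signaling sets of a stage's samples.

    ``min_fraction = 1.0`` is the strict intersection (genes common to
    every set); lower values keep genes present in at least that fraction
    of the sets.
    """
    if not stage_samples:
        raise ValueError("stage_samples is empty")
    sets = [signaling_sets[s] for s in sorted(stage_samples) if s in signaling_sets]
    if not sets:
        return set()
    counts: dict[str, int] = {}
    for s in sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    k = len(sets)
    return {g for g, c in counts.items() if c / k >= min_fraction}


def screen_biomarkers(
    signaling_sets: dict[str, set[str]],
    records: list[SurvivalRecord],
    tumor: ExpressionMatrix,
    reference: ExpressionMatrix,
    A: float = 0.6,
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> list[BiomarkerResult]:
    """Run the full three-step screen and return one result per candidate."""
    split = split_by_median(records)
    non_de = non_de_genes(tumor, reference, fdr)
    candidates = candidate_biomarkers(signaling_sets, non_de, split, A)
    with_survival = {r.sample_id for r in records}
    results = []
    for gene, n, m in candidates:
        identified = {s for s, genes in signaling_sets.items()
                      if gene in genes and s in with_survival}
        try:
            results.append(classify_biomarker(gene, identified, records, alpha))
        except ValueError as exc:
            logger.warning("gene %r not classifiable: %s", gene, exc)
            results.append(BiomarkerResult(gene, n, m, max(n, m) / (n + m),
                                           float("nan"), float("nan"), "none"))
    return results
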