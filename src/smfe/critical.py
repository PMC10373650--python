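"""Stage-wise aggregation of global sMFE and the tipping-point call.

The global score of each case sample is grouped by clinical stage; the
stage with the largest mean score is the candidate critical state.  The
candidate is called significant when a two-sided Welch t-test of its
samples against all other samples pooled gives P < alpha (0.05 by
default).  Because the candidate is chosen as the argmax of the stage
means, the effective size of the call exceeds the nominal alpha as the
number of stages grows; the conservative alternative is the per-pair mode,
which requires the candidate to beat every other stage separately and
reports the largest of those P values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SampleScore
from .io import StageAnnotation

logger = logging.getLogger("smfe")

__all__ = ["StageSeries", "TippingCall", "stage_series", "detect_tipping"]


@dataclass(frozen=True)
class StageSeries:
    """Ordered per-stage global-score lists and their means."""

    labels: tuple[str, ...]
    scores: tuple[tuple[float, ...], ...]
    means: tuple[float, ...]

    def stage_scores(self, label: str) -> np.ndarray:
        return np.asarray(self.scores[self.labels.index(label)], dtype=float)

    @property
    def n_per_stage(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.scores)


@dataclass(frozen=True)
class TippingCall:
    """Result of the critical-state test."""

    candidate: str | None
    p_value: float
    significant: bool


def stage_series(
    scores: list[SampleScore] | dict[str, float],
    annotation: list[StageAnnotation],
) -> StageSeries:
    """Group per-sample global scores by stage, in stage order.

    Samples without an annotation are dropped with a warning; annotated
    samples without a score are likewise dropped.  A sample annotated twice
    is an error.
    """
    if isinstance(scores, dict):
        by_sample = dict(scores)
    else:
        by_sample = {s.sample_id: float(s.global_score) for s in scores}
    seen: set[str] = set()
    for ann in annotation:
        if ann.sample_id in seen:
            raise ValueError(f"sample {ann.sample_id!r} annotated more than once")
        seen.add(ann.sample_id)

    unannotated = set(by_sample) - seen
    if unannotated:
        logger.warning("%d scored samples have no stage annotation; dropped", len(unannotated))
    unscored = seen - set(by_sample)
    if unscored:
        logger.warning("%d annotated samples have no score; dropped", len(unscored))

    order: dict[str, int] = {}
    grouped: dict[str, list[float]] = {}
    for ann in annotation:
        if ann.sample_id not in by_sample:
            continue
        order[ann.stage_label] = ann.stage_order
        grouped.setdefault(ann.stage_label, []).append(by_sample[ann.sample_id])
    if not grouped:
        raise ValueError("no overlap between scored samples and stage annotations")

    labels = tuple(sorted(grouped, key=lambda lab: order[lab]))
    score_lists = tuple(tuple(grouped[lab]) for lab in labels)
    means = tuple(float(np.mean(s)) for s in score_lists)
    for lab, s in zip(labels, score_lists):
        if len(s) < 2:
            logger.warning("stage %r has %d sample(s): not testable as candidate", lab, len(s))
    return StageSeries(labels, score_lists, means)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    # identical constant groups: no evidence of a difference
    if a.std(ddof=0) == 0.0 and b.std(ddof=0) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def detect_tipping(
    series: StageSeries,
    alpha: float = 0.05,
    min_group: int = 2,
    mode: str = "pooled",
) -> TippingCall:
    """Call the tipping point from a stage series.

    The candidate is the stage with the maximal mean global score among
    stages with at least ``min_group`` samples.  ``mode="pooled"`` tests
    candidate vs all other samples pooled (Welch, two-sided);
    ``mode="per_pair"`` tests the candidate against each other stage
    separately and reports the maximum P.  The call is significant only if
    P < alpha *and* the candidate is the argmax — the direction (an
    increase) is enforced by the selection, the test is two-sided.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    eligible = [i for i, s in enumerate(series.scores) if len(s) >= min_group]
    if not eligible:
        raise ValueError("no stage has enough samples to test")
    skipped = [series.labels[i] for i in range(len(series.labels)) if i not in eligible]
    if skipped:
        logger.warning("stages skipped as candidates (fewer than %d samples): %s",
                       min_group, skipped)
    cand_i = max(eligible, key=lambda i: series.means[i])
    cand = np.asarray(series.scores[cand_i], dtype=float)
    others = [np.asarray(s, dtype=float) for i, s in enumerate(series.scores) if i != cand_i]
    rest = np.concatenate(others) if others else np.array([])
    if rest.size < min_group:
        raise ValueError("all samples fall in a single stage; nothing to compare")

    if mode == "pooled":
        p = _welch_p(cand, rest)
    elif mode == "per_pair":
        ps = [_welch_p(cand, o) for o in others if o.size >= min_group]
        if not ps:
            raise ValueError("no other stage has enough samples for per-pair tests")
        p = max(ps)
    else:
        raise ValueError(f"mode must be 'pooled' or 'per_pair', got {mode!r}")

    significant = p < alpha
    label = series.labels[cand_i]
    if significant:
        logger.info("critical state: %s (P = %.3g)", label, p)
    else:
        logger.info("no significant tipping point (best stage %s, P = %.3g)", label, p)
    return TippingCall(candidate=label, p_value=p, significant=significant)
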