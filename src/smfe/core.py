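"""Single-sample Markov flow entropy (sMFE).

The score treats each gene's local network as a tiny Markov chain: the
probability of flow from center gene :math:`g^k` to neighbor :math:`g_i^k`
is its absolute Pearson correlation with the center, normalized by one
(the center's self term) plus the sum over all neighbors,

.. math::

    p_{ki} = \\frac{|\\mathrm{PCC}(g_i^k, g^k)|}
                  {1 + \\sum_{j=1}^{M} |\\mathrm{PCC}(g_j^k, g^k)|}.

The local Markov flow entropy under a cohort of samples is

.. math::

    \\mathrm{MFE}_k = -\\sum_{i=1}^{M} \\bar{x}_k\\, p_{ki}
                      \\log(\\bar{x}_k\\, p_{ki}),

with :math:`\\bar{x}_k` the mean min-max-normalized expression of the
center, natural logarithm, and the convention :math:`0 \\log 0 = 0`.

A single case sample perturbs the reference cohort: the differential score

.. math::

    \\mathrm{sMFE}_k = \\frac{1}{\\log M}
        \\left| \\mathrm{SD}^n_k \\mathrm{MFE}^n_k
              - \\mathrm{SD}^{n+1}_k \\mathrm{MFE}^{n+1}_k \\right|

compares the n reference samples against the n+1 mixed cohort (reference
plus the case sample), weighting each entropy by the population standard
deviation of the center's expression.  The SD is taken on the *raw*
expression by default: the normalizer clips case values into the reference
[0, 1] range, and an SD of clipped values would cap exactly the large
critical-state fluctuation the score exists to detect
(``sd_on="normalized"`` selects the clipped variant).  Near a critical
transition the dominant group of genes fluctuates strongly and becomes
tightly correlated, so one sample drawn from that state shifts both SD and
the correlation structure and the score spikes.  The global score of a
sample is the mean of its top-5% local scores; those genes are its
*signaling genes*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .network import DirectedNetwork, LocalNetwork

logger = logging.getLogger("smfe")

__all__ = [
    "Normalizer",
    "TransitionVector",
    "SampleScore",
    "fit_normalizer",
    "transition_probs",
    "local_mfe",
    "local_smfe",
    "score_sample",
    "score_cohort",
]

EQ6_FORMS = ("product", "literal")
SD_MODES = ("raw", "normalized")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Normalizer:
    """Per-gene min-max normalizer fitted on the reference cohort.

    Case samples are transformed with the *reference* min/max and clipped
    to [0, 1], so the reference-cohort statistics are identical across case
    samples and one extreme case value cannot rescale the cohort.  Genes
    constant in the reference map to 0.
    """

    fit_min: pd.Series
    fit_max: pd.Series

    def transform(self, data: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
        lo = self.fit_min.reindex(data.index if data.ndim == 1 else data.index)
        span = (self.fit_max - self.fit_min).reindex(lo.index)
        if lo.isna().any():
            missing = list(lo.index[lo.isna()])[:5]
            raise KeyError(f"genes not seen during fit: {missing}")
        safe_span = span.replace(0.0, 1.0)
        if data.ndim == 1:
            out = (data - lo) / safe_span
        else:
            out = data.sub(lo, axis=0).div(safe_span, axis=0)
        out = out.clip(0.0, 1.0)
        if data.ndim == 1:
            out[span == 0.0] = 0.0
        else:
            out.loc[span == 0.0, :] = 0.0
        return out


def fit_normalizer(reference: ExpressionMatrix) -> Normalizer:
    """Fit the per-gene [0, 1] normalizer on the reference cohort only."""
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 reference samples to fit the normalizer")
    return Normalizer(reference.data.min(axis=1), reference.data.max(axis=1))


# ---------------------------------------------------------------------------
# transition probabilities and local entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionVector:
    """Flow probabilities from a center gene to its M neighbors.

    ``p`` sums to S/(1+S) < 1 where S is the summed neighbor |PCC|; the
    missing mass is the center's self term (|PCC| = 1 in the denominator).
    """

    center: str
    p: np.ndarray
    S: float


def _abs_pcc_matrix(cohort: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """|Pearson r| for row pairs (a_idx[i], b_idx[i]) of a genes x samples array.

    Pairs where either row has zero variance get 0 (a flat profile carries
    no flow), never NaN.
    """
    centered = cohort - cohort.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    num = np.einsum("ij,ij->i", centered[a_idx], centered[b_idx])
    den = np.sqrt(ss[a_idx] * ss[b_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0.0, num / den, 0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def transition_probs(cohort: pd.DataFrame, local: LocalNetwork) -> TransitionVector:
    """Transition probabilities of a local network under one cohort.

    Parameters
    ----------
    cohort
        Normalized genes x samples matrix containing the center and all
        neighbors; needs >= 2 samples for the correlations to exist.
    """
    if local.m == 0:
        raise ValueError(f"gene {local.center!r} has no neighbors (M = 0)")
    if cohort.shape[1] < 2:
        raise ValueError("cohort needs >= 2 samples to compute correlations")
    genes = [local.center, *local.neighbors]
    sub = cohort.loc[genes].to_numpy(dtype=float)
    m = local.m
    pcc = _abs_pcc_matrix(sub, np.zeros(m, dtype=int), np.arange(1, m + 1))
    s = float(pcc.sum())
    return TransitionVector(local.center, pcc / (1.0 + s), s)


def local_mfe(xbar: float, tv: TransitionVector | np.ndarray) -> float:
    """Local Markov flow entropy -sum u log u with u_i = xbar * p_i.

    Natural logarithm; 0 log 0 = 0; result >= 0 because every u_i < 1.
    """
    p = tv.p if isinstance(tv, TransitionVector) else np.asarray(tv, dtype=float)
    u = xbar * p
    pos = u > 0.0
    return float(-(u[pos] * np.log(u[pos])).sum())


def _weighted_entropy_diff(
    sd_n: float, mfe_n: float, sd_n1: float, mfe_n1: float, m: int, eq6_form: str
) -> float:
    if eq6_form == "product":
        diff = sd_n * mfe_n - sd_n1 * mfe_n1
    elif eq6_form == "literal":
        # the asymmetric form exactly as printed, kept for comparison
        diff = sd_n * mfe_n - sd_n1 + mfe_n1
    else:
        raise ValueError(f"eq6_form must be one of {EQ6_FORMS}, got {eq6_form!r}")
    return abs(diff) / math.log(m)


def local_smfe(
    reference: ExpressionMatrix,
    case_sample: pd.Series,
    local: LocalNetwork,
    eq6_form: str = "product",
    sd_on: str = "raw",
) -> float:
    """Differential sMFE of one gene for one case sample.

    The n-cohort is the reference; the (n+1)-cohort appends the case sample
    under the reference-fitted normalizer.  Requires M >= 2 (the 1/log M
    normalizer needs it).
    """
    if local.m < 2:
        raise ValueError(
            f"gene {local.center!r} is not scoreable: needs >= 2 neighbors, has {local.m}"
        )
    if sd_on not in SD_MODES:
        raise ValueError(f"sd_on must be one of {SD_MODES}, got {sd_on!r}")
    norm = fit_normalizer(reference)
    case_aligned = case_sample.reindex(reference.data.index)
    ref_n = norm.transform(reference.data)
    case_n = norm.transform(case_aligned)
    mixed = pd.concat([ref_n, case_n.rename("__case__")], axis=1)

    tv_n = transition_probs(ref_n, local)
    tv_n1 = transition_probs(mixed, local)
    center_n = ref_n.loc[local.center].to_numpy()
    center_n1 = mixed.loc[local.center].to_numpy()
    mfe_n = local_mfe(float(center_n.mean()), tv_n)
    mfe_n1 = local_mfe(float(center_n1.mean()), tv_n1)
    if sd_on == "raw":
        raw_n = reference.data.loc[local.center].to_numpy(dtype=float)
        raw_n1 = np.append(raw_n, float(case_aligned.loc[local.center]))
        sd_n = float(raw_n.std(ddof=0))
        sd_n1 = float(raw_n1.std(ddof=0))
    else:
        sd_n = float(center_n.std(ddof=0))
        sd_n1 = float(center_n1.std(ddof=0))
    return _weighted_entropy_diff(sd_n, mfe_n, sd_n1, mfe_n1, local.m, eq6_form)


# ---------------------------------------------------------------------------
# whole-sample scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleScore:
    """All per-gene local sMFE values of one case sample plus the global score."""

    sample_id: str
    local_scores: dict[str, float]
    global_score: float
    signaling_genes: tuple[str, ...] = field(default=())


def _select_signaling(
    genes: np.ndarray, scores: np.ndarray, fraction: float
) -> tuple[float, tuple[str, ...]]:
    """Top-Q selection: Q = ceil(fraction * L); ties broken by descending
    score then ascending gene ID (genes are pre-sorted ascending)."""
    L = len(genes)
    q = math.ceil(fraction * L)
    order = np.argsort(-scores, kind="stable")[:q]
    top = scores[order]
    return float(top.mean()), tuple(genes[order])


class _ScoringPlan:
    """Precomputed index arrays and reference-cohort statistics shared by
    every case sample scored against one (network, reference) pair."""

    def __init__(
        self,
        net: DirectedNetwork,
        reference: ExpressionMatrix,
        neighbor_mode: str = "out",
        min_neighbors: int = 2,
    ):
        ref_genes = set(reference.gene_ids)
        missing = net.nodes - ref_genes
        if missing:
            logger.warning(
                "%d network genes absent from the expression matrix; dropped",
                len(missing),
            )
            net = net.subgraph(net.nodes & ref_genes)
        self.net = net
        centers = sorted(
            g for g in net.nodes if len(net.neighbors(g, neighbor_mode)) >= min_neighbors
        )
        if not centers:
            raise ValueError("no scoreable genes: every network gene has fewer than "
                             f"{min_neighbors} neighbors after mapping")
        self.centers = np.array(centers)
        genes_needed = sorted(
            set(centers).union(*(net.neighbors(c, neighbor_mode) for c in centers))
        )
        self.gene_index = {g: i for i, g in enumerate(genes_needed)}
        self.genes_needed = genes_needed

        center_idx, neigh_idx, seg_sizes = [], [], []
        for c in centers:
            nb = net.neighbors(c, neighbor_mode)
            center_idx.extend(self.gene_index[c] for _ in nb)
            neigh_idx.extend(self.gene_index[g] for g in nb)
            seg_sizes.append(len(nb))
        self.center_edge_idx = np.array(center_idx, dtype=int)
        self.neigh_edge_idx = np.array(neigh_idx, dtype=int)
        self.seg_sizes = np.array(seg_sizes, dtype=int)
        self.seg_starts = np.concatenate([[0], np.cumsum(self.seg_sizes)[:-1]])
        self.center_row = np.array([self.gene_index[c] for c in centers], dtype=int)
        self.log_m = np.log(self.seg_sizes.astype(float))

        self.normalizer = fit_normalizer(reference)
        ref_sub = reference.data.loc[genes_needed]
        self.ref_norm = self.normalizer.transform(ref_sub).to_numpy(dtype=float)
        self.ref_index = ref_sub.index
        self.ref_raw_centers = ref_sub.to_numpy(dtype=float)[self.center_row]
        self.sd_n_norm, self.mfe_n = self._cohort_stats(self.ref_norm)
        self.sd_n_raw = self.ref_raw_centers.std(axis=1, ddof=0)

    def _cohort_stats(self, cohort: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-center (population SD, MFE) under one genes x samples cohort."""
        pcc = _abs_pcc_matrix(cohort, self.center_edge_idx, self.neigh_edge_idx)
        s = np.add.reduceat(pcc, self.seg_starts)
        p = pcc / np.repeat(1.0 + s, self.seg_sizes)
        xbar = cohort[self.center_row].mean(axis=1)
        u = np.repeat(xbar, self.seg_sizes) * p
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(u > 0.0, -u * np.log(np.where(u > 0.0, u, 1.0)), 0.0)
        mfe = np.add.reduceat(terms, self.seg_starts)
        sd = cohort[self.center_row].std(axis=1, ddof=0)
        return sd, mfe

    def score_one(
        self,
        sample_id: str,
        case: pd.Series,
        fraction: float,
        eq6_form: str,
        sd_on: str = "raw",
    ) -> SampleScore:
        if sd_on not in SD_MODES:
            raise ValueError(f"sd_on must be one of {SD_MODES}, got {sd_on!r}")
        case_vec = case.reindex(self.ref_index)
        if case_vec.isna().any():
            missing = list(case_vec.index[case_vec.isna()])[:5]
            raise KeyError(f"case sample {sample_id!r} lacks network genes: {missing}")
        case_norm = self.normalizer.transform(case_vec).to_numpy(dtype=float)
        mixed = np.concatenate([self.ref_norm, case_norm[:, None]], axis=1)
        sd_n1_norm, mfe_n1 = self._cohort_stats(mixed)
        if sd_on == "raw":
            case_raw = case_vec.to_numpy(dtype=float)[self.center_row]
            mixed_raw = np.concatenate([self.ref_raw_centers, case_raw[:, None]], axis=1)
            sd_n, sd_n1 = self.sd_n_raw, mixed_raw.std(axis=1, ddof=0)
        else:
            sd_n, sd_n1 = self.sd_n_norm, sd_n1_norm
        if eq6_form == "product":
            diff = sd_n * self.mfe_n - sd_n1 * mfe_n1
        elif eq6_form == "literal":
            diff = sd_n * self.mfe_n - sd_n1 + mfe_n1
        else:
            raise ValueError(f"eq6_form must be one of {EQ6_FORMS}, got {eq6_form!r}")
        local = np.abs(diff) / self.log_m
        global_score, signaling = _select_signaling(self.centers, local, fraction)
        return SampleScore(
            sample_id=sample_id,
            local_scores=dict(zip(self.centers.tolist(), local.tolist())),
            global_score=global_score,
            signaling_genes=signaling,
        )


def score_sample(
    net: DirectedNetwork,
    reference: ExpressionMatrix,
    case_sample: pd.Series,
    fraction: float = 0.05,
    sample_id: str = "case",
    neighbor_mode: str = "out",
    eq6_form: str = "product",
    sd_on: str = "raw",
) -> SampleScore:
    """Score one case sample against the reference cohort.

    Computes local sMFE for every scoreable gene (M >= 2), the global score
    (mean of the Q = ceil(fraction * L) largest local scores) and the
    signaling-gene set (those Q genes).
    """
    plan = _ScoringPlan(net, reference, neighbor_mode)
    return plan.score_one(sample_id, case_sample, fraction, eq6_form, sd_on)


def score_cohort(
    net: DirectedNetwork,
    reference: ExpressionMatrix,
    cases: ExpressionMatrix,
    fraction: float = 0.05,
    neighbor_mode: str = "out",
    eq6_form: str = "product",
    sd_on: str = "raw",
) -> list[SampleScore]:
    """Score every sample of a case cohort.

    The reference-cohort statistics (normalizer, correlations, SD, MFE) are
    computed once and shared, so this is the fast path for whole datasets.
    """
    plan = _ScoringPlan(net, reference, neighbor_mode)
    return [
        plan.score_one(sid, cases.data[sid], fraction, eq6_form, sd_on)
        for sid in cases.sample_ids
    ]
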