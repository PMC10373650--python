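"""Synthetic networks, DNB-structured staged cohorts and linked survival.

The generator realizes the three statistical signatures of a dynamic
network biomarker (DNB) at a designated critical stage: a planted gene
module whose members (i) fluctuate more (SD_in rises), (ii) correlate more
tightly with each other (PCC_in rises), and (iii) decouple from the rest
of the network (PCC_out falls).  Expression is multivariate Gaussian with
a block-structured correlation matrix — the minimal model that hits all
three conditions — shifted to a positive baseline and clipped at zero (a
mild distortion of the target moments at the defaults, where the baseline
sits many SDs above zero).  Stage effects enter only through the
covariance, never the mean, so a differential-expression analysis of the
stages stays flat by design; a ``mean_shift`` knob exists for DE testing.

Survival times are exponential with a proportional-hazard bump for
marker-positive samples plus independent uniform censoring, which is all
the biomarker screen needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, StageAnnotation, SurvivalRecord
from .network import DirectedNetwork

logger = logging.getLogger("smfe")

__all__ = [
    "DnbScenario",
    "make_network",
    "make_dnb_dataset",
    "make_survival",
    "stage_annotations",
    "default_scenario",
]


@dataclass(frozen=True)
class DnbScenario:
    """Parameters of one staged DNB simulation.

    Defaults give a clearly detectable desk-scale critical state: a
    20-gene DNB block in a 200-gene network, four stages of 30 samples
    plus 30 reference samples, SD tripling and within-block correlation
    rising 0.2 -> 0.8 at the critical stage while the block's coupling to
    the rest falls 0.2 -> 0.05.
    """

    n_genes: int = 200
    n_dnb: int = 20
    stages: tuple[str, ...] = ("I", "II", "III", "IV")
    critical_stage: str = "III"
    n_ref: int = 30
    n_per_stage: int = 30
    sd_base: float = 1.0
    sd_crit: float = 3.0
    rho_in_base: float = 0.2
    rho_in_crit: float = 0.8
    rho_out_base: float = 0.2
    rho_out_crit: float = 0.05
    baseline_mean: float = 10.0
    mean_shift: float = 0.0
    dnb_genes: tuple[str, ...] | None = None  # default: highest-out-degree genes
    seed: int = 0

    def __post_init__(self):
        if self.critical_stage not in self.stages:
            raise ValueError(f"critical stage {self.critical_stage!r} not in {self.stages}")
        if not (self.sd_crit > self.sd_base > 0):
            raise ValueError("require sd_crit > sd_base > 0")
        if not (0 <= self.rho_in_base < self.rho_in_crit < 1):
            raise ValueError("require 0 <= rho_in_base < rho_in_crit < 1")
        if self.rho_out_crit > self.rho_out_base:
            raise ValueError("require rho_out_crit <= rho_out_base")


def default_scenario(seed: int = 0, **overrides) -> DnbScenario:
    """The shipped scenario, optionally with field overrides."""
    return replace(DnbScenario(seed=seed), **overrides)


def make_network(
    n_genes: int,
    model: str = "erdos_renyi",
    param: float = 0.05,
    seed: int = 0,
) -> DirectedNetwork:
    """Random directed gene network with deterministic seeding.

    ``erdos_renyi``: each ordered pair is an edge with probability
    ``param``.  ``scale_free``: a Barabási-Albert graph with
    ``m = round(param)`` attachments per node, each undirected edge used in
    both directions, giving the heavy-tailed degree distribution of real
    interactomes.  Isolated nodes are dropped.
    """
    if n_genes < 10:
        raise ValueError(f"need n_genes >= 10, got {n_genes}")
    names = [f"g{i:04d}" for i in range(n_genes)]
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n_genes, param, seed=int(seed), directed=True)
        edges = [(names[u], names[v]) for u, v in g.edges()]
    elif model == "scale_free":
        m = max(1, round(param))
        g = nx.barabasi_albert_graph(n_genes, m, seed=int(seed))
        edges = [(names[u], names[v]) for u, v in g.edges()]
        edges += [(b, a) for a, b in edges]
    else:
        raise ValueError(f"model must be 'erdos_renyi' or 'scale_free', got {model!r}")
    net = DirectedNetwork(edges)
    if net.n_edges == 0:
        raise ValueError(f"{model} with param {param} produced an empty network")
    return net


def _block_correlation(
    n_genes: int, dnb_idx: np.ndarray, rho_in: float, rho_out: float, rho_bg: float
) -> np.ndarray:
    corr = np.full((n_genes, n_genes), rho_bg)
    corr[np.ix_(dnb_idx, dnb_idx)] = rho_in
    mask = np.ones(n_genes, dtype=bool)
    mask[dnb_idx] = False
    out_idx = np.where(mask)[0]
    corr[np.ix_(dnb_idx, out_idx)] = rho_out
    corr[np.ix_(out_idx, dnb_idx)] = rho_out
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_psd(corr: np.ndarray, label: str) -> np.ndarray:
    eig_min = float(np.linalg.eigvalsh(corr).min())
    if eig_min < -1e-8:
        raise ValueError(
            f"covariance for {label} is not positive semi-definite "
            f"(min eigenvalue {eig_min:.3g}); adjust the rho parameters"
        )
    return corr


def _connected_module(net: DirectedNetwork, k: int) -> list[str]:
    """Grow a k-gene connected module by breadth-first expansion from the
    highest-degree node.

    A DNB is an *interconnected* dominant group: the rising within-module
    correlation is only visible to the score if module members sit in each
    other's local networks, so the planted block must form a connected
    subnetwork, not an arbitrary gene subset.
    """
    deg = {g: len(net.out_neighbors(g)) + len(net.in_neighbors(g)) for g in net.nodes}
    seed = max(sorted(net.nodes), key=lambda g: deg[g])
    chosen = [seed]
    seen = {seed}
    queue = [seed]
    while queue and len(chosen) < k:
        g = queue.pop(0)
        both = set(net.out_neighbors(g)) | set(net.in_neighbors(g))
        for nb in sorted(both, key=lambda x: (-deg[x], x)):
            if nb not in seen:
                seen.add(nb)
                chosen.append(nb)
                queue.append(nb)
                if len(chosen) >= k:
                    break
    if len(chosen) < k:
        raise ValueError(
            f"network too fragmented to host a {k}-gene connected module "
            f"(reached {len(chosen)} genes)"
        )
    return chosen


def make_dnb_dataset(
    scenario: DnbScenario,
    net: DirectedNetwork,
) -> tuple[ExpressionMatrix, dict[str, ExpressionMatrix], list[str]]:
    """Draw the reference cohort and one cohort per stage.

    Returns ``(reference, {stage: matrix}, dnb_genes)``.  The DNB block is
    planted on the ``n_dnb`` network genes of highest out-degree (they must
    be scoreable for the signal to be visible), every other gene keeps the
    base parameters at every stage, and only the critical stage switches
    the block to (sd_crit, rho_in_crit, rho_out_crit).
    """
    genes = sorted(net.nodes)
    if len(genes) != scenario.n_genes:
        logger.info("network has %d nodes (scenario n_genes=%d); using network nodes",
                    len(genes), scenario.n_genes)
    n_genes = len(genes)
    if scenario.n_dnb >= n_genes:
        raise ValueError("n_dnb must be smaller than the number of network genes")
    rng = np.random.default_rng(scenario.seed)

    if scenario.dnb_genes is not None:
        missing = set(scenario.dnb_genes) - set(genes)
        if missing:
            raise ValueError(f"dnb_genes absent from the network: {sorted(missing)[:5]}")
        dnb_genes = sorted(scenario.dnb_genes)
    else:
        dnb_genes = sorted(_connected_module(net, scenario.n_dnb))
    dnb_idx = np.array([genes.index(g) for g in dnb_genes])

    sd_vec = np.full(n_genes, scenario.sd_base)
    base_corr = _check_psd(
        _block_correlation(n_genes, dnb_idx, scenario.rho_in_base,
                           scenario.rho_out_base, scenario.rho_out_base),
        "base stages",
    )
    crit_sd = sd_vec.copy()
    crit_sd[dnb_idx] = scenario.sd_crit
    crit_corr = _check_psd(
        _block_correlation(n_genes, dnb_idx, scenario.rho_in_crit,
                           scenario.rho_out_crit, scenario.rho_out_base),
        f"critical stage {scenario.critical_stage!r}",
    )

    def draw(corr: np.ndarray, sds: np.ndarray, n: int, prefix: str, shift: float) -> ExpressionMatrix:
        cov = corr * np.outer(sds, sds)
        x = rng.multivariate_normal(np.zeros(n_genes), cov, size=n, method="cholesky")
        x = np.clip(x.T + scenario.baseline_mean + shift, 0.0, None)
        cols = [f"{prefix}{i:03d}" for i in range(n)]
        return ExpressionMatrix(pd.DataFrame(x, index=genes, columns=cols))

    reference = draw(base_corr, sd_vec, scenario.n_ref, "ref_", 0.0)
    cohorts = {}
    for stage in scenario.stages:
        if stage == scenario.critical_stage:
            cohorts[stage] = draw(crit_corr, crit_sd, scenario.n_per_stage,
                                  f"{stage}_", scenario.mean_shift)
        else:
            cohorts[stage] = draw(base_corr, sd_vec, scenario.n_per_stage, f"{stage}_", 0.0)
    return reference, cohorts, dnb_genes


def stage_annotations(cohorts: dict[str, ExpressionMatrix],
                      stage_order: tuple[str, ...]) -> list[StageAnnotation]:
    """Annotation table matching a simulated stage->cohort map."""
    out = []
    for rank, stage in enumerate(stage_order):
        for sid in cohorts[stage].sample_ids:
            out.append(StageAnnotation(sid, stage, rank))
    return out


def make_survival(
    samples: list[str],
    marker_positive: set[str],
    hazard_ratio: float = 3.0,
    baseline_scale: float = 1000.0,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Exponential survival with a proportional hazard for marked samples.

    Marker-positive samples have their hazard multiplied by
    ``hazard_ratio``; each sample is independently censored with
    probability ``censor_rate`` at a uniform fraction of its event time.
    """
    if hazard_ratio <= 0:
        raise ValueError(f"hazard_ratio must be > 0, got {hazard_ratio}")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    rng = np.random.default_rng(seed)
    records = []
    for sid in samples:
        scale = baseline_scale / (hazard_ratio if sid in marker_positive else 1.0)
        t = float(rng.exponential(scale))
        if rng.random() < censor_rate:
            records.append(SurvivalRecord(sid, float(rng.uniform(0.0, t)), 0))
        else:
            records.append(SurvivalRecord(sid, t, 1))
    return records
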