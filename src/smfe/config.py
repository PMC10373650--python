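"""Run configuration with the method's published default constants.

The defaults are the settings the method is defined with: signaling-gene
fraction 0.05 (top 5% by local sMFE), STRING confidence threshold 0.8,
biomarker enrichment parameter A = 0.6, and significance level 0.05 for
both the tipping-point t-test and the log-rank classification.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # input paths
    expression: str | None = None      # case/tumor expression TSV
    reference: str | None = None       # reference (tumor-adjacent) expression TSV
    network: str | None = None         # edge-list TSV (scored or directed 2-col)
    stages: str | None = None          # sample -> stage table
    survival: str | None = None        # sample, time, event table
    # method constants
    fraction: float = 0.05             # signaling-gene fraction (top 5%)
    score_threshold: float = 0.8       # STRING confidence cut
    A: float = 0.6                     # biomarker enrichment parameter
    alpha: float = 0.05                # significance level (t-test and log-rank)
    de_fdr: float = 0.05               # BH FDR for the non-DE filter
    # switches
    directed: bool = False             # network edge list already oriented
    eq6_form: str = "product"          # differential-score form: product | literal
    sd_on: str = "raw"                 # SD in the differential: raw | normalized
    neighbor_mode: str = "out"         # local-network neighbors: out | in | both
    tipping_mode: str = "pooled"       # candidate test: pooled | per_pair
    time_unit: str = "days"            # survival time unit (metadata only)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Explicit keyword overrides (e.g. CLI flags) take precedence over file
    values, which take precedence over defaults.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
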