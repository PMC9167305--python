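"""Pipeline configuration: defaults, YAML loading and validation.

Bundles the matching-cost weights, aggregation thresholds, refinement and
point-cloud parameters.  The scanline-optimization entries some parameter
tables carry (pi1, pi2, tau_so, tau_s, tau_h) belong to an algorithm this
pipeline does not include; they are accepted and stored untouched so such
tables load as-is, with a warning that they are inert.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cost_volume import CostParams
from .cross_aggregation import AggregationParams
from .pointcloud_volume import FilterParams

__all__ = ["PipelineConfig", "load_config"]

log = logging.getLogger(__name__)

_COST_KEYS = {"lambda_census", "lambda_sd", "lambda_grad", "census_window", "d_min", "d_max"}
_AGG_KEYS = {"tau1", "tau2", "L1", "L2", "iterations", "orientation_schedule"}
_FILTER_KEYS = {"k_neighbors", "sigma_c", "sigma_s", "filter_iterations"}
_PIPE_KEYS = {"eps_subtract", "median_kernel", "seed"}
_INERT_KEYS = {"pi1", "pi2", "tau_so", "tau_s", "tau_h"}


@dataclass
class PipelineConfig:
    """Resolved parameter set for a full run (logged for reproducibility)."""

    cost: CostParams = field(default_factory=CostParams)
    aggregation: AggregationParams = field(default_factory=AggregationParams)
    filter: FilterParams = field(default_factory=FilterParams)
    eps_subtract: float = 1.0
    median_kernel: int = 3
    seed: int = 0
    inert: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eps_subtract < 0:
            raise ValueError("eps_subtract must be >= 0")
        if self.median_kernel % 2 == 0 or self.median_kernel < 3:
            raise ValueError("median_kernel must be odd and >= 3")

    def describe(self) -> dict:
        out = {
            "cost": asdict(self.cost),
            "aggregation": asdict(self.aggregation),
            "filter": asdict(self.filter),
            "eps_subtract": self.eps_subtract,
            "median_kernel": self.median_kernel,
            "seed": self.seed,
        }
        if self.inert:
            out["inert"] = dict(self.inert)
        return out


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a flat YAML mapping plus overrides.

    Unknown keys are rejected; the inert scanline keys are stored with a
    warning.  The defaults are the calibrated experiment values.
    """
    data: dict = {}
    if path is not None:
        with open(Path(path)) as f:
            loaded = yaml.safe_load(f) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    known = _COST_KEYS | _AGG_KEYS | _FILTER_KEYS | _PIPE_KEYS | _INERT_KEYS
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    inert = {k: data[k] for k in _INERT_KEYS if k in data}
    if inert:
        log.warning(
            "config: scanline-optimization keys %s accepted but unused by this pipeline",
            sorted(inert),
        )

    cost_kwargs = {k: data[k] for k in _COST_KEYS if k in data}
    if "census_window" in cost_kwargs:
        cost_kwargs["census_window"] = tuple(cost_kwargs["census_window"])
    agg_kwargs = {k: data[k] for k in _AGG_KEYS if k in data}
    if "orientation_schedule" in agg_kwargs:
        agg_kwargs["orientation_schedule"] = tuple(agg_kwargs["orientation_schedule"])
    filt_kwargs = {k.replace("filter_iterations", "iterations"): data[k]
                   for k in _FILTER_KEYS if k in data}
    cfg = PipelineConfig(
        cost=CostParams(**cost_kwargs),
        aggregation=AggregationParams(**agg_kwargs),
        filter=FilterParams(**filt_kwargs),
        eps_subtract=float(data.get("eps_subtract", 1.0)),
        median_kernel=int(data.get("median_kernel", 3)),
        seed=int(data.get("seed", 0)),
        inert=inert,
    )
    log.info("config resolved: %s", cfg.describe())
    return cfg
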