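"""Pipeline orchestration: method variants, grids, and cross-validated sweeps.

Four method variants share the same upstream computation (bounding box,
atlas selection, majority voting):

* ``MV``      — thresholded majority-vote map (the baseline);
* ``MV-SSLP`` — the vote map refined by label propagation;
* ``RF``      — thresholded per-voxel random-forest probability map;
* ``RF-SSLP`` — the forest map refined by label propagation (the method).

``cross_validated_sweep`` ranks parameter-grid configurations by mean
held-out Dice with leave-one-out folds over subjects, the way the
operating parameters are tuned.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .features import PatchParams
from .io import AtlasPair, LabelVolume, Volume, check_common_grid
from .metrics import MetricsReport, evaluate
from .preprocess import (
    BoundingBox,
    compute_bounding_box,
    majority_vote,
    select_atlases,
)
from .rf_fusion import RFParams, rf_segment
from .sslp import SSLPParams, sslp_refine

__all__ = [
    "METHODS",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "enumerate_grid",
    "cross_validated_sweep",
]

log = logging.getLogger(__name__)

METHODS = ("MV", "MV-SSLP", "RF", "RF-SSLP")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides the images."""

    method: str = "RF-SSLP"
    patch: PatchParams = field(default_factory=PatchParams)
    rf: RFParams = field(default_factory=RFParams)
    sslp: SSLPParams = field(default_factory=SSLPParams)
    n_select: int = 20
    margin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def with_overrides(self, **kv: Any) -> "RunConfig":
        """New config with flat parameter overrides (k, n_tree, n_split,
        T, sigma, beta map onto the nested parameter blocks)."""
        rf_fields = {"k", "n_tree", "n_split"}
        sslp_fields = {"T", "sigma", "beta", "graph"}
        patch_fields = {"r_s", "r"}
        top: dict[str, Any] = {}
        rf: dict[str, Any] = {}
        ss: dict[str, Any] = {}
        pp: dict[str, Any] = {}
        for key, value in kv.items():
            if key in rf_fields:
                rf[key] = value
            elif key in sslp_fields:
                ss[key] = value
            elif key in patch_fields:
                pp[key] = value
            else:
                top[key] = value
        cfg = self
        if rf:
            cfg = replace(cfg, rf=replace(cfg.rf, **rf))
        if ss:
            cfg = replace(cfg, sslp=replace(cfg.sslp, **ss))
        if pp:
            cfg = replace(cfg, patch=replace(cfg.patch, **pp))
        if top:
            cfg = replace(cfg, **top)
        return cfg


@dataclass
class PipelineResult:
    label: LabelVolume
    probability: Volume
    box: BoundingBox
    metrics: MetricsReport | None
    info: dict[str, Any]


def _threshold(prob: Volume) -> LabelVolume:
    return LabelVolume((np.asarray(prob.data) >= 0.5).astype(np.uint8),
                       prob.affine, name="thresholded")


def run_pipeline(
    config: RunConfig,
    target: Volume,
    library: list[AtlasPair],
    truth: LabelVolume | None = None,
) -> PipelineResult:
    """Run one method variant end to end on a target and its atlas library."""
    t0 = time.perf_counter()
    check_common_grid([target] + [a.intensity for a in library])
    # box from the whole library's labels, NMI ranking inside it, then MV
    box = compute_bounding_box([a.label for a in library], margin=config.margin)
    atlases = (
        select_atlases(target, library, box, config.n_select)
        if len(library) > config.n_select
        else list(library)
    )
    partition = majority_vote([a.label for a in atlases], box)
    n_fg = int(partition.unanimous_fg.sum())
    n_bg = int(partition.unanimous_bg.sum())
    n_amb = int(partition.ambiguous.sum())
    assert n_fg + n_bg + n_amb == box.volume
    log.info(
        "box %s (%d voxels): unanimous fg=%d bg=%d ambiguous=%d",
        box.shape, box.volume, n_fg, n_bg, n_amb,
    )

    rf_cfg = replace(config.rf, seed=config.seed)
    if config.method in ("MV", "MV-SSLP"):
        prob = Volume(partition.vote_map, target.affine, name="mv_probability")
    else:
        prob = rf_segment(target, atlases, partition, config.patch, rf_cfg)

    if config.method in ("MV-SSLP", "RF-SSLP"):
        label = sslp_refine(prob, target, box, config.sslp)
    else:
        label = _threshold(prob)

    report = evaluate(truth, label) if truth is not None else None
    info = {
        "method": config.method,
        "n_atlases": len(atlases),
        "box": [*box.lower, *box.upper],
        "unanimous_fg": n_fg,
        "unanimous_bg": n_bg,
        "ambiguous": n_amb,
        "seed": config.seed,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return PipelineResult(label, prob, box, report, info)


def enumerate_grid(grid: dict[str, Iterable[Any]]) -> list[dict[str, Any]]:
    """Cartesian product of candidate parameter values.

    Keys keep their given order and the product is emitted in
    lexicographic order, so enumeration is deterministic.
    """
    keys = list(grid)
    values = [list(grid[k]) for k in keys]
    if any(len(v) == 0 for v in values):
        raise ValueError("every grid list must be non-empty")
    return [dict(zip(keys, combo)) for combo in itertools.product(*values)]


def cross_validated_sweep(
    dataset: list[tuple[Volume, LabelVolume, list[AtlasPair]]],
    grid: dict[str, Iterable[Any]],
    base_config: RunConfig | None = None,
    metric: str = "dice",
) -> pd.DataFrame:
    """Rank grid configurations by mean held-out metric over LOO folds.

    Each subject is held out in turn and segmented with its own atlas
    library under every candidate configuration; a configuration's score
    is its mean held-out metric. Returns a DataFrame sorted by descending
    score with one row per configuration (grid columns + ``mean_<metric>``).
    """
    if len(dataset) < 2:
        raise ValueError("cross-validation needs at least 2 subjects")
    base_config = base_config or RunConfig()
    configs = enumerate_grid(grid)
    rows = []
    for delta in configs:
        cfg = base_config.with_overrides(**delta)
        scores = []
        for target, truth, atlases in dataset:
            result = run_pipeline(cfg, target, atlases, truth)
            assert result.metrics is not None
            scores.append(getattr(result.metrics, metric))
        rows.append({**delta, f"mean_{metric}": float(np.mean(scores))})
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        f"mean_{metric}", ascending=False, kind="stable"
    ).reset_index(drop=True)
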