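"""Before/after-deployment windowing and phase comparison.

After a tracking device is attached to an animal (here: a pre-fledging
bird confined to its nest), fixes from the first days on the nest can be
compared against the surveyed nest position, and the device's
post-deployment accuracy/precision contrasted with its pre-deployment
stationary test. The comparison uses the Kruskal-Wallis test on the
per-observation error samples (per-pair samples for the precision
metrics, which are therefore not independent — read those p-values
descriptively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    MAX_SAMPLED_PAIRS,
    kruskal_wallis,
    pairwise_abs_alt_diffs,
    pairwise_distances,
)
from .fix_io import GeoFix, ReferencePoint
from .geodesy import ErrorRecord

__all__ = [
    "DeploymentRecord",
    "window_after_deployment",
    "compare_phases",
    "PHASE_METRICS",
]

logger = logging.getLogger(__name__)

PHASE_METRICS = (
    "horizontal_accuracy",
    "vertical_accuracy",
    "horizontal_precision",
    "vertical_precision",
)


@dataclass(frozen=True, slots=True)
class DeploymentRecord:
    """Deployment metadata for one device: when and onto which nest."""

    device_id: str
    deployment_time: datetime
    nest_reference: ReferencePoint
    window_days: int = 7

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")


def window_after_deployment(
    fixes: Sequence[GeoFix], rec: DeploymentRecord
) -> list[GeoFix]:
    """Fixes of the deployed device in [t0, t0 + window_days days).

    The window is half-open: a fix exactly at the upper boundary is
    excluded. Retained fixes are relabelled phase="after_deployment".
    Returns an empty list (with a warning) when nothing falls inside.
    """
    t0 = rec.deployment_time
    t1 = t0 + timedelta(days=rec.window_days)
    out = [
        replace(f, phase="after_deployment")
        for f in fixes
        if f.device_id == rec.device_id and t0 <= f.timestamp < t1
    ]
    if not out:
        logger.warning(
            "no fixes for device %s in [%s, %s)", rec.device_id, t0, t1
        )
    return out


def _metric_samples(
    records: Sequence[ErrorRecord],
    metric: str,
    *,
    max_pairs: int,
    seed: int,
) -> Optional[np.ndarray]:
    if metric == "horizontal_accuracy":
        return np.array([r.h_err for r in records])
    if metric == "vertical_accuracy":
        v = [abs(r.v_err) for r in records if r.v_err is not None]
        return np.array(v) if v else None
    fixes = [r.fix for r in records]
    if metric == "horizontal_precision":
        return pairwise_distances(fixes, max_pairs=max_pairs, seed=seed)[0]
    if metric == "vertical_precision":
        if sum(1 for f in fixes if f.alt is not None) < 2:
            return None
        return pairwise_abs_alt_diffs(fixes, max_pairs=max_pairs, seed=seed)[0]
    raise ValueError(f"unknown metric {metric!r}")


def compare_phases(
    before: Sequence[ErrorRecord],
    after: Sequence[ErrorRecord],
    *,
    metrics: Sequence[str] = PHASE_METRICS,
    p_method: str = "chi2",
    max_pairs: int = MAX_SAMPLED_PAIRS,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare accuracy/precision between two deployment phases.

    For each metric the per-observation samples of both phases are
    summarised and compared with a two-group Kruskal-Wallis test
    (df = 1). Vertical metrics are skipped with a warning when either
    phase lacks altitude data. Returns one row per computed metric.
    """
    if len(before) == 0 or len(after) == 0:
        raise ValueError("both phases must be non-empty")
    rows = []
    for metric in metrics:
        xs = _metric_samples(before, metric, max_pairs=max_pairs, seed=seed)
        ys = _metric_samples(after, metric, max_pairs=max_pairs, seed=seed)
        if xs is None or ys is None:
            logger.warning("skipping %s: a phase lacks altitude data", metric)
            continue
        kw = kruskal_wallis([xs, ys], p_method=p_method, seed=seed)
        rows.append(
            {
                "metric": metric,
                "n_before": xs.size,
                "n_after": ys.size,
                "mean_before": xs.mean(),
                "mean_after": ys.mean(),
                "sd_before": float(np.std(xs, ddof=1)) if xs.size > 1 else np.nan,
                "sd_after": float(np.std(ys, ddof=1)) if ys.size > 1 else np.nan,
                "H": kw.H,
                "df": kw.df,
                "p": kw.p,
                "degenerate": kw.degenerate,
            }
        )
    return pd.DataFrame(rows)
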