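"""Quantile screening of fixes by the device's self-reported error.

The device emits a per-fix positional-error estimate (metres at 67%
probability). If that estimate ranks fixes the same way their realised
errors do, discarding the few percent of fixes with the largest estimates
should remove most of the genuinely inaccurate positions (> 10 m error)
at minimal data cost. These routines perform the exclusion and quantify
how well it worked, per removal fraction, axis, and error category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .geodesy import ERROR_CATEGORIES, ErrorRecord, error_category

__all__ = [
    "DEFAULT_FRACTIONS",
    "FilterEfficacy",
    "exclude_top_fraction",
    "filtering_efficacy",
    "efficacy_frame",
]

DEFAULT_FRACTIONS = (0.01, 0.03, 0.05, 0.10)


@dataclass(frozen=True, slots=True)
class FilterEfficacy:
    """Outcome of removing the top ``fraction_removed`` by reported error."""

    group: str
    axis: str
    fraction_removed: float
    n_before: int
    n_after: int
    n_inaccurate_before: int
    n_inaccurate_after: int
    prop_inaccurate_after: float
    pct_inaccurate_eliminated: float  # NaN when nothing was inaccurate
    category_counts_after: dict[str, int]


def _removal_count(q: float, n: int, rounding: str) -> int:
    if rounding == "nearest":  # half away from zero
        return int(math.floor(q * n + 0.5))
    if rounding == "floor":
        return int(math.floor(q * n))
    if rounding == "ceil":
        return int(math.ceil(q * n))
    raise ValueError(f"unknown rounding {rounding!r}")


def exclude_top_fraction(
    records: Sequence[ErrorRecord],
    q: float,
    *,
    rounding: str = "nearest",
) -> list[ErrorRecord]:
    """Drop the ``round(q*n)`` records with the largest reported gps_error.

    Ties at the cutoff are broken deterministically by removing the
    later-timestamped records first, so re-runs are reproducible. Every
    record must carry a gps_error; q must lie in [0, 1).
    """
    if not (0.0 <= q < 1.0):
        raise ValueError(f"q must be in [0, 1), got {q}")
    for r in records:
        if r.fix.gps_error is None:
            raise ValueError(
                f"record {r.fix.device_id} @ {r.fix.timestamp.isoformat()} "
                "has no gps_error; cannot rank"
            )
    n = len(records)
    k = _removal_count(q, n, rounding)
    if k == 0:
        return list(records)
    order = sorted(
        range(n),
        key=lambda i: (records[i].fix.gps_error, records[i].fix.timestamp),
    )
    # ascending (gps_error, time): the tail holds the k largest errors,
    # and within a tie block later timestamps sit later, so they go first
    removed = set(order[n - k:])
    return [r for i, r in enumerate(records) if i not in removed]


def _errors_for_axis(records: Sequence[ErrorRecord], axis: str) -> np.ndarray:
    if axis == "horizontal":
        return np.array([r.h_err for r in records])
    vals = [abs(r.v_err) for r in records if r.v_err is not None]
    return np.array(vals)


def filtering_efficacy(
    records: Sequence[ErrorRecord],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    *,
    threshold: float = 10.0,
    group: str = "",
    rounding: str = "nearest",
    include_baseline: bool = True,
) -> list[FilterEfficacy]:
    """Evaluate top-quantile exclusion at each removal fraction and axis.

    For each fraction q, removes the top q by reported gps_error and
    counts, among the retained fixes, how many still have realised error
    strictly above ``threshold`` per axis, broken down by error category.
    ``pct_inaccurate_eliminated`` is relative to the unfiltered inaccurate
    count on that axis (NaN when no fix was inaccurate to begin with).
    Vertical statistics use altitude-bearing records only.
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    fr = sorted(fractions)
    if include_baseline and (not fr or fr[0] != 0.0):
        fr = [0.0] + fr
    out: list[FilterEfficacy] = []
    base = {ax: _errors_for_axis(records, ax) for ax in ("horizontal", "vertical")}
    for q in fr:
        kept = exclude_top_fraction(records, q, rounding=rounding)
        for axis in ("horizontal", "vertical"):
            errs_before = base[axis]
            if errs_before.size == 0:
                continue
            errs_after = _errors_for_axis(kept, axis)
            n_in_before = int((errs_before > threshold).sum())
            n_in_after = int((errs_after > threshold).sum())
            cats = {c: 0 for c in ERROR_CATEGORIES}
            for e in errs_after:
                cats[error_category(e)] += 1
            if n_in_before > 0:
                pct_elim = (n_in_before - n_in_after) / n_in_before
            else:
                pct_elim = float("nan")
            out.append(
                FilterEfficacy(
                    group=group,
                    axis=axis,
                    fraction_removed=q,
                    n_before=int(errs_before.size),
                    n_after=int(errs_after.size),
                    n_inaccurate_before=n_in_before,
                    n_inaccurate_after=n_in_after,
                    prop_inaccurate_after=(
                        n_in_after / errs_after.size if errs_after.size else 0.0
                    ),
                    pct_inaccurate_eliminated=pct_elim,
                    category_counts_after=cats,
                )
            )
    return out


def efficacy_frame(
    records: Sequence[ErrorRecord],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    *,
    threshold: float = 10.0,
    rounding: str = "nearest",
    group_by: Optional[Callable[[ErrorRecord], str]] = None,
    pooled_label: str = "all",
) -> pd.DataFrame:
    """Efficacy table per group (default: per device) plus pooled.

    One row per group x fraction x axis, in the column layout the
    pipeline writes out.
    """
    if group_by is None:
        group_by = lambda r: r.fix.device_id  # noqa: E731
    groups: dict[str, list[ErrorRecord]] = {}
    for r in records:
        groups.setdefault(group_by(r), []).append(r)
    results: list[FilterEfficacy] = []
    for name in sorted(groups):
        results += filtering_efficacy(
            groups[name], fractions, threshold=threshold, group=name,
            rounding=rounding,
        )
    if len(groups) > 1:
        results += filtering_efficacy(
            records, fractions, threshold=threshold, group=pooled_label,
            rounding=rounding,
        )
    rows = []
    for e in results:
        row = {
            "group": e.group,
            "axis": e.axis,
            "fraction_removed": e.fraction_removed,
            "n_before": e.n_before,
            "n_after": e.n_after,
            "n_inaccurate_after": e.n_inaccurate_after,
            "prop_inaccurate_after": e.prop_inaccurate_after,
            "pct_inaccurate_eliminated": e.pct_inaccurate_eliminated,
        }
        for c in ERROR_CATEGORIES[1:]:
            row[f"n_cat_{c}"] = e.category_counts_after[c]
        rows.append(row)
    return pd.DataFrame(rows)
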