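"""Accuracy/precision summaries and rank-based group comparisons.

Accuracy is closeness of fixes to the surveyed true location; precision
is closeness of fixes to each other, measured over all unordered pairs.
Headline vertical accuracy is the mean of *absolute* vertical errors,
with the signed mean reported separately as the bias — a signed mean
would cancel symmetric errors and cannot serve as an accuracy magnitude.
All standard deviations are sample (n-1) SDs.

Pairwise precision is exact (all n(n-1)/2 pairs) up to ``EXACT_PAIR_LIMIT``
fixes; beyond that a seeded uniform random subsample of pairs is used and
flagged on the returned summary. The pairwise values are not independent
(each fix enters n-1 pairs); the SD across pairs mirrors common reporting
practice and should be read descriptively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fix_io import GeoFix
from .geodesy import ErrorRecord, geodesic_distance

__all__ = [
    "AccuracySummary",
    "PrecisionSummary",
    "KWResult",
    "accuracy_summary",
    "horizontal_precision",
    "vertical_precision",
    "pairwise_distances",
    "pairwise_abs_alt_diffs",
    "fix_acquisition_rate",
    "kruskal_wallis",
    "EXACT_PAIR_LIMIT",
    "MAX_SAMPLED_PAIRS",
]

#: Exact all-pairs computation up to this many fixes; above it, a seeded
#: uniform subsample of MAX_SAMPLED_PAIRS pairs approximates the mean/SD.
EXACT_PAIR_LIMIT = 20_000
MAX_SAMPLED_PAIRS = 20_000_000
_CHUNK = 2_000_000  # pairs per vectorised geodesic chunk


@dataclass(frozen=True, slots=True)
class AccuracySummary:
    group: str
    axis: str  # "horizontal" | "vertical"
    n: int
    mean: float
    sd: float
    prop_below_10m: float
    bias: Optional[float] = None  # mean signed vertical error


@dataclass(frozen=True, slots=True)
class PrecisionSummary:
    group: str
    axis: str
    n_fixes: int
    n_pairs: int  # nominal n(n-1)/2
    mean: float
    sd: float
    n_pairs_evaluated: int = 0
    subsampled: bool = False


@dataclass(frozen=True, slots=True)
class KWResult:
    """Kruskal-Wallis omnibus test (tie-corrected H, df = k-1)."""

    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]
    tie_corrected: bool = True
    degenerate: bool = False
    p_method: str = "chi2"


def accuracy_summary(
    records: Sequence[ErrorRecord],
    axis: str = "horizontal",
    *,
    group: str = "",
    threshold: float = 10.0,
) -> AccuracySummary:
    """Mean/SD accuracy for one group of annotated fixes.

    Horizontal: statistics of the geodesic distance to the reference.
    Vertical: statistics of |signed vertical error|, plus the signed mean
    as ``bias``; records without altitude are excluded from the vertical
    axis. ``prop_below_10m`` is the fraction with error <= ``threshold``
    (an error must strictly exceed the threshold to count as inaccurate).
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"axis must be horizontal|vertical, got {axis!r}")
    if len(records) == 0:
        raise ValueError(f"no records for group {group!r}")
    if axis == "horizontal":
        vals = np.array([r.h_err for r in records])
        bias = None
    else:
        signed = np.array([r.v_err for r in records if r.v_err is not None])
        if signed.size == 0:
            raise ValueError(f"no altitude-bearing records for group {group!r}")
        vals = np.abs(signed)
        bias = float(signed.mean())
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return AccuracySummary(
        group=group,
        axis=axis,
        n=int(vals.size),
        mean=float(vals.mean()),
        sd=sd,
        prop_below_10m=float(np.mean(vals <= threshold)),
        bias=bias,
    )


def _pair_indices(
    n: int, max_pairs: int, seed: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    total = n * (n - 1) // 2
    if n <= EXACT_PAIR_LIMIT and total <= max_pairs:
        i, j = np.triu_indices(n, k=1)
        return i, j, False
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)  # uniform over ordered pairs, i != j
    return np.minimum(i, j), np.maximum(i, j), True


def pairwise_distances(
    fixes: Sequence[GeoFix],
    *,
    max_pairs: int = MAX_SAMPLED_PAIRS,
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """Geodesic distances over unordered fix pairs (possibly subsampled).

    Returns ``(distances, subsampled)``.
    """
    n = len(fixes)
    if n < 2:
        raise ValueError("need at least 2 fixes for pairwise distances")
    lat = np.array([f.lat for f in fixes])
    lon = np.array([f.lon for f in fixes])
    i, j, sub = _pair_indices(n, max_pairs, seed)
    out = np.empty(i.size)
    for s in range(0, i.size, _CHUNK):
        sl = slice(s, min(s + _CHUNK, i.size))
        out[sl] = geodesic_distance(lat[i[sl]], lon[i[sl]], lat[j[sl]], lon[j[sl]])
    return out, sub


def pairwise_abs_alt_diffs(
    fixes: Sequence[GeoFix],
    *,
    max_pairs: int = MAX_SAMPLED_PAIRS,
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """|altitude difference| over unordered pairs of altitude-bearing fixes."""
    alts = np.array([f.alt for f in fixes if f.alt is not None], dtype=float)
    if alts.size < 2:
        raise ValueError("need at least 2 altitude-bearing fixes")
    i, j, sub = _pair_indices(alts.size, max_pairs, seed)
    return np.abs(alts[i] - alts[j]), sub


def horizontal_precision(
    fixes: Sequence[GeoFix],
    *,
    group: str = "",
    max_pairs: int = MAX_SAMPLED_PAIRS,
    seed: int = 0,
) -> PrecisionSummary:
    """Mean/SD of geodesic distance between all unordered fix pairs."""
    d, sub = pairwise_distances(fixes, max_pairs=max_pairs, seed=seed)
    n = len(fixes)
    return PrecisionSummary(
        group=group,
        axis="horizontal",
        n_fixes=n,
        n_pairs=n * (n - 1) // 2,
        mean=float(d.mean()),
        sd=float(np.std(d, ddof=1)) if d.size > 1 else float("nan"),
        n_pairs_evaluated=int(d.size),
        subsampled=sub,
    )


def vertical_precision(
    fixes: Sequence[GeoFix],
    *,
    group: str = "",
    max_pairs: int = MAX_SAMPLED_PAIRS,
    seed: int = 0,
) -> PrecisionSummary:
    """Mean/SD of |altitude difference| between all unordered fix pairs."""
    d, sub = pairwise_abs_alt_diffs(fixes, max_pairs=max_pairs, seed=seed)
    n = sum(1 for f in fixes if f.alt is not None)
    return PrecisionSummary(
        group=group,
        axis="vertical",
        n_fixes=n,
        n_pairs=n * (n - 1) // 2,
        mean=float(d.mean()),
        sd=float(np.std(d, ddof=1)) if d.size > 1 else float("nan"),
        n_pairs_evaluated=int(d.size),
        subsampled=sub,
    )


def fix_acquisition_rate(
    interval: timedelta,
    span: timedelta,
    received: int | Sequence[GeoFix],
) -> float:
    """Fraction of scheduled fixes actually obtained.

    Expected count is ``span // interval`` (a fix per completed interval).
    Rates above 1 (duplicate or burst fixes) are reported as-is with a
    warning rather than capped silently.
    """
    if interval <= timedelta(0) or span <= timedelta(0):
        raise ValueError("interval and span must be positive")
    expected = int(span / interval)
    if expected == 0:
        raise ValueError("span shorter than one interval: zero expected fixes")
    n = received if isinstance(received, int) else len(received)
    rate = n / expected
    if rate > 1.0:
        warnings.warn(
            f"acquisition rate {rate:.3f} > 1: duplicates or burst fixes?",
            stacklevel=2,
        )
    return rate


def summary_table(
    records: Sequence[ErrorRecord],
    *,
    max_pairs: int = MAX_SAMPLED_PAIRS,
    seed: int = 0,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Accuracy/precision summary rows per device x schedule x phase.

    Produces the calibration report's main table: one row per group and
    axis with n, accuracy mean/sd, precision mean/sd, vertical bias and
    the proportion of fixes within the accuracy threshold. Groups with
    every device pooled per schedule/phase are appended (group "all"),
    matching the practice of pooling devices when comparing schedules.
    """

    def group_rows(recs: Sequence[ErrorRecord], device: str) -> list[dict]:
        rows = []
        sched = recs[0].fix.schedule
        phase = recs[0].fix.phase
        fixes = [r.fix for r in recs]
        for axis in ("horizontal", "vertical"):
            try:
                acc = accuracy_summary(recs, axis, group=device, threshold=threshold)
            except ValueError:
                continue  # no altitude data on this axis
            try:
                prec = (
                    horizontal_precision(fixes, max_pairs=max_pairs, seed=seed)
                    if axis == "horizontal"
                    else vertical_precision(fixes, max_pairs=max_pairs, seed=seed)
                )
                prec_mean, prec_sd, n_pairs = prec.mean, prec.sd, prec.n_pairs
            except ValueError:
                prec_mean = prec_sd = float("nan")
                n_pairs = 0
            rows.append(
                {
                    "device": device,
                    "schedule": sched,
                    "phase": phase,
                    "axis": axis,
                    "n": acc.n,
                    "accuracy_mean": acc.mean,
                    "accuracy_sd": acc.sd,
                    "precision_mean": prec_mean,
                    "precision_sd": prec_sd,
                    "n_pairs": n_pairs,
                    "vertical_bias": acc.bias,
                    "prop_within_threshold": acc.prop_below_10m,
                }
            )
        return rows

    if len(records) == 0:
        raise ValueError("no records to summarise")
    by_dev: dict[tuple, list[ErrorRecord]] = {}
    by_pool: dict[tuple, list[ErrorRecord]] = {}
    for r in records:
        by_dev.setdefault(
            (r.fix.device_id, r.fix.schedule, r.fix.phase), []
        ).append(r)
        by_pool.setdefault((r.fix.schedule, r.fix.phase), []).append(r)
    rows: list[dict] = []
    for key in sorted(by_dev):
        rows += group_rows(by_dev[key], key[0])
    for key in sorted(by_pool):
        rows += group_rows(by_pool[key], "all")
    return pd.DataFrame(rows)


def kw_comparisons(
    records: Sequence[ErrorRecord], *, p_method: str = "chi2", seed: int = 0
) -> pd.DataFrame:
    """Kruskal-Wallis accuracy comparisons between devices and schedules.

    Between-device tests run within each schedule/phase (>= 2 devices);
    the between-schedule test pools all devices per schedule. Precision
    comparisons across many groups are omitted here: per-pair samples
    explode combinatorially and the omnibus question is answered by the
    accuracy samples.
    """

    def axis_values(recs: Sequence[ErrorRecord], axis: str) -> np.ndarray:
        if axis == "horizontal":
            return np.array([r.h_err for r in recs])
        return np.array([abs(r.v_err) for r in recs if r.v_err is not None])

    rows = []
    by_sched: dict[tuple, dict[str, list[ErrorRecord]]] = {}
    for r in records:
        by_sched.setdefault((r.fix.schedule, r.fix.phase), {}).setdefault(
            r.fix.device_id, []
        ).append(r)
    for (sched, phase), devs in sorted(by_sched.items()):
        if len(devs) < 2:
            continue
        for axis in ("horizontal", "vertical"):
            groups = [axis_values(v, axis) for _, v in sorted(devs.items())]
            if any(g.size == 0 for g in groups):
                continue
            kw = kruskal_wallis(groups, p_method=p_method, seed=seed)
            rows.append(
                {
                    "comparison": "between_devices",
                    "schedule": sched,
                    "phase": phase,
                    "axis": axis,
                    "k_groups": len(groups),
                    "H": kw.H,
                    "df": kw.df,
                    "p": kw.p,
                }
            )
    scheds: dict[str, list[ErrorRecord]] = {}
    for r in records:
        scheds.setdefault(r.fix.schedule, []).append(r)
    if len(scheds) >= 2:
        for axis in ("horizontal", "vertical"):
            groups = [axis_values(v, axis) for _, v in sorted(scheds.items())]
            if all(g.size > 0 for g in groups):
                kw = kruskal_wallis(groups, p_method=p_method, seed=seed)
                rows.append(
                    {
                        "comparison": "between_schedules",
                        "schedule": "+".join(sorted(scheds)),
                        "phase": "pooled",
                        "axis": axis,
                        "k_groups": len(groups),
                        "H": kw.H,
                        "df": kw.df,
                        "p": kw.p,
                    }
                )
    return pd.DataFrame(rows)


def _h_statistic(values: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled values and group labels."""
    n = values.size
    ranks = stats.rankdata(values)
    ssq = 0.0
    for g in range(k):
        r = ranks[labels == g]
        ssq += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * ssq - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0.0:  # all values identical
        return 0.0
    return h / correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    *,
    p_method: str = "chi2",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> KWResult:
    """Kruskal-Wallis omnibus test across >= 2 groups.

    ``p_method="chi2"`` uses the chi-square approximation with k-1 degrees
    of freedom (tie-corrected H); ``"permutation"`` estimates the p-value
    by Monte-Carlo label permutation of the pooled ranks, which is
    preferable at small sample sizes where the chi-square approximation
    is rough. When every pooled value is identical the statistic is
    degenerate: H = 0, p = 1, flagged.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    sizes = tuple(int(a.size) for a in arrays)
    ntot = sum(sizes)
    if ntot < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KWResult(
            H=0.0, df=df, p=1.0, group_sizes=sizes, degenerate=True,
            p_method=p_method,
        )
    h_obs, p_chi2 = stats.kruskal(*arrays)
    if p_method == "chi2":
        return KWResult(
            H=float(h_obs), df=df, p=float(p_chi2), group_sizes=sizes
        )
    if p_method != "permutation":
        raise ValueError(f"unknown p_method {p_method!r}")
    labels = np.repeat(np.arange(len(arrays)), sizes)
    rng = np.random.default_rng(seed)
    k = len(arrays)
    count = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _h_statistic(pooled, lab, k) >= h_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return KWResult(
        H=float(h_obs), df=df, p=float(p), group_sizes=sizes,
        p_method="permutation",
    )
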