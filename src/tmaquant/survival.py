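"""Survival analytics for dichotomized staining scores.

Implements the product-limit (Kaplan–Meier) estimator, the two-group
log-rank test, a constrained minimum-p cutpoint search over an equidistant
threshold grid, subgroup re-testing at the selected cutpoint, Harrell's
concordance index between an ordinal manual read and a continuous
algorithmic score, and percentile-bootstrap confidence intervals for
per-category medians.

The cutpoint search reports *raw* log-rank p-values together with the
number of tests performed: the minimum p over a grid of K candidate
thresholds is anti-conservative under the null, and downstream consumers
must account for that multiplicity themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from .synthetic import MANUAL_CATEGORIES

__all__ = [
    "KMCurve",
    "CutpointParams",
    "CutpointResult",
    "SubgroupKMResult",
    "BootstrapCI",
    "km_estimate",
    "logrank_test",
    "cutpoint_search",
    "subgroup_km",
    "concordance_index",
    "bootstrap_median_ci",
    "plot_km",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate on the observed time grid.

    ``survival[i]`` is S(t) just after ``times[i]``; S is 1 before the first
    observed time.  ``variance`` is the Greenwood estimate of Var(S(t)).
    """

    times: NDArray[np.float64]
    survival: NDArray[np.float64]
    at_risk: NDArray[np.int64]
    n_events: NDArray[np.int64]
    variance: NDArray[np.float64]

    def survival_at(self, t: ArrayLike) -> NDArray[np.float64]:
        """Step-function evaluation of S at arbitrary times."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    @property
    def median(self) -> float:
        """Smallest observed time with S(t) <= 0.5, or inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")


def km_estimate(times: ArrayLike, events: ArrayLike) -> KMCurve:
    """Kaplan–Meier estimate of the survival function.

    Subjects censored at time t are counted at risk for events at t (the
    standard convention).  Raises on empty input.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("cannot estimate survival from an empty sample")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order].astype(bool)
    grid, start = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - start
    d = np.zeros(grid.size, dtype=np.int64)
    ut, counts = np.unique(t[e], return_counts=True)
    d[np.searchsorted(grid, ut)] = counts

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        gw = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        var = surv**2 * np.cumsum(gw)
    var = np.where(np.isfinite(var), var, 0.0)
    return KMCurve(grid, surv, at_risk.astype(np.int64), d, var)


def _at_risk(sorted_times: NDArray[np.float64], t: NDArray[np.float64]) -> NDArray[np.int64]:
    return sorted_times.size - np.searchsorted(sorted_times, t, side="left")


def logrank_test(
    times: ArrayLike, events: ArrayLike, groups: ArrayLike
) -> tuple[float, float]:
    """Two-group log-rank test.

    Observed-minus-expected events in group 1 with the hypergeometric
    variance, summed over distinct event times; the squared standardized
    statistic is referred to chi-square with 1 df.

    Returns
    -------
    (statistic, p_value)
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {labels.size}")
    in1 = g == labels[0]
    if in1.all() or not in1.any():
        raise ValueError("both groups must be non-empty")

    event_times, d = np.unique(t[e], return_counts=True)
    if event_times.size == 0:
        return 0.0, 1.0

    t_sorted = np.sort(t)
    t1_sorted = np.sort(t[in1])
    n_at = _at_risk(t_sorted, event_times)
    n1_at = _at_risk(t1_sorted, event_times)
    # Events in group 1 at each distinct event time.
    d1 = np.zeros(event_times.size, dtype=np.int64)
    ut1, c1 = np.unique(t[e & in1], return_counts=True)
    d1[np.searchsorted(event_times, ut1)] = c1

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d * n1_at / n_at
        var = d * (n1_at / n_at) * (1.0 - n1_at / n_at) * (n_at - d) / (n_at - 1.0)
    var = np.where(n_at > 1, var, 0.0)

    o_minus_e = float(np.sum(d1 - expected))
    v = float(np.sum(var))
    if v <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class CutpointParams:
    """Grid size and group-size constraint of the cutpoint search.

    ``min_group_fraction`` applies to the smaller risk group: a threshold is
    admissible only if both groups hold at least that fraction of patients.
    """

    n_thresholds: int = 50
    min_group_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        if not 0.0 < self.min_group_fraction < 0.5:
            raise ValueError("min_group_fraction must lie in (0, 0.5)")


@dataclass
class CutpointResult:
    """Outcome of the equidistant-grid minimum-p cutpoint search.

    ``p_value`` entries are raw (uncorrected); ``n_tests`` counts the
    admissible thresholds actually tested, so consumers can reason about
    the selection multiplicity.  ``best_threshold`` is None when no
    threshold satisfies the group-size constraint.
    """

    thresholds: NDArray[np.float64]
    n_high: NDArray[np.int64]
    n_low: NDArray[np.int64]
    admissible: NDArray[np.bool_]
    statistic: NDArray[np.float64]
    p_value: NDArray[np.float64]
    best_index: int | None
    n_tests: int
    n_patients: int
    params: CutpointParams = field(default_factory=CutpointParams)

    @property
    def best_threshold(self) -> float | None:
        return None if self.best_index is None else float(self.thresholds[self.best_index])

    @property
    def best_p(self) -> float | None:
        return None if self.best_index is None else float(self.p_value[self.best_index])

    @property
    def no_admissible(self) -> bool:
        return self.best_index is None

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "n_high": self.n_high.tolist(),
            "n_low": self.n_low.tolist(),
            "admissible": self.admissible.tolist(),
            "statistic": self.statistic.tolist(),
            "p_value": self.p_value.tolist(),
            "best_threshold": self.best_threshold,
            "best_p": self.best_p,
            "n_tests": self.n_tests,
            "n_patients": self.n_patients,
            "n_thresholds": self.params.n_thresholds,
            "min_group_fraction": self.params.min_group_fraction,
        }


def cutpoint_search(
    records: pd.DataFrame, params: CutpointParams = CutpointParams()
) -> CutpointResult:
    """Search K equidistant score thresholds for the minimum log-rank p.

    The grid spans the open interval between the observed score extremes
    (the endpoints would produce an empty group).  At each threshold the
    cohort splits into high (score strictly above) and low; the split is
    admissible only if both groups contain at least ``min_group_fraction``
    of the patients.  The best threshold minimizes the raw log-rank p among
    admissible candidates, ties broken toward the more balanced split and
    then toward the lower threshold.

    A cohort with no admissible threshold yields a result flagged
    ``no_admissible`` rather than an exception.
    """
    scores = records["score"].to_numpy(dtype=float)
    finite = np.isfinite(scores)
    sub = records.loc[finite]
    scores = scores[finite]
    n = scores.size
    if n < int(np.ceil(1.0 / params.min_group_fraction)):
        raise ValueError(
            f"need at least {int(np.ceil(1.0 / params.min_group_fraction))} patients "
            f"with finite scores, got {n}"
        )
    t = sub["time"].to_numpy(dtype=float)
    e = sub["event"].to_numpy()

    k = params.n_thresholds
    lo, hi = scores.min(), scores.max()
    grid = lo + (hi - lo) * np.arange(1, k + 1) / (k + 1)

    n_high = np.array([(scores > thr).sum() for thr in grid], dtype=np.int64)
    n_low = n - n_high
    min_size = params.min_group_fraction * n
    admissible = (n_high >= min_size) & (n_low >= min_size)

    statistic = np.full(k, np.nan)
    p_value = np.full(k, np.nan)
    for i in np.nonzero(admissible)[0]:
        statistic[i], p_value[i] = logrank_test(t, e, scores > grid[i])

    best: int | None = None
    if admissible.any():
        cand = np.nonzero(admissible)[0]
        imbalance = np.abs(n_high - n_low)
        keys = sorted(cand, key=lambda i: (p_value[i], imbalance[i], grid[i]))
        best = int(keys[0])

    return CutpointResult(
        thresholds=grid,
        n_high=n_high,
        n_low=n_low,
        admissible=admissible,
        statistic=statistic,
        p_value=p_value,
        best_index=best,
        n_tests=int(admissible.sum()),
        n_patients=n,
        params=params,
    )


@dataclass(frozen=True)
class SubgroupKMResult:
    """Kaplan–Meier pair and log-rank p for one subgroup at a fixed cutpoint."""

    subgroup: str
    threshold: float
    evaluable: bool
    n_high: int
    n_low: int
    km_high: KMCurve | None = None
    km_low: KMCurve | None = None
    statistic: float | None = None
    p_value: float | None = None


def subgroup_km(
    records: pd.DataFrame, threshold: float, subgroup: str | None = None
) -> SubgroupKMResult:
    """Re-test a previously selected cutpoint within one subgroup.

    Splits the subgroup's patients at ``threshold`` (high = score strictly
    above), estimates Kaplan–Meier curves per risk group and runs the
    log-rank test.  A subgroup lying entirely on one side of the threshold
    is flagged not evaluable.
    """
    sub = records if subgroup is None else records[records["subgroup"] == subgroup]
    name = "all" if subgroup is None else subgroup
    if len(sub) == 0:
        raise ValueError(f"subgroup {name!r} is empty")
    sub = sub[np.isfinite(sub["score"].to_numpy(dtype=float))]
    if len(sub) == 0:
        return SubgroupKMResult(name, threshold, False, 0, 0)
    scores = sub["score"].to_numpy(dtype=float)
    high = scores > threshold
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        return SubgroupKMResult(name, threshold, False, n_high, n_low)
    t = sub["time"].to_numpy(dtype=float)
    e = sub["event"].to_numpy()
    stat, p = logrank_test(t, e, high)
    return SubgroupKMResult(
        name,
        threshold,
        True,
        n_high,
        n_low,
        km_estimate(t[high], e[high]),
        km_estimate(t[~high], e[~high]),
        stat,
        p,
    )


def _manual_to_ordinal(manual: Sequence) -> NDArray[np.float64]:
    arr = np.asarray(manual)
    if arr.dtype.kind in "OUS":
        lookup = {c: i for i, c in enumerate(MANUAL_CATEGORIES)}
        try:
            return np.array([lookup[str(v)] for v in arr], dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"unknown manual category {exc.args[0]!r}; "
                f"allowed: {list(MANUAL_CATEGORIES)}"
            ) from None
    return arr.astype(float)


def concordance_index(manual: Sequence, scores: ArrayLike) -> float:
    """Harrell's concordance between an ordinal manual read and a score.

    Over all patient pairs with *different* manual categories, a pair is
    concordant when the algorithmic scores order the same way; pairs tied
    on the algorithmic score count one half.  Pairs tied on the manual
    category are not comparable and are excluded.

    Invariant under any strictly increasing transform of the score.
    """
    m = _manual_to_ordinal(manual)
    s = np.asarray(scores, dtype=float)
    if m.shape != s.shape:
        raise ValueError("manual categories and scores must be paired")
    if m.size < 2:
        raise ValueError("need at least 2 patients")
    i, j = np.triu_indices(m.size, k=1)
    dm = m[i] - m[j]
    comparable = dm != 0
    if not comparable.any():
        raise ValueError("no comparable pairs: all manual categories identical")
    ds = s[i][comparable] - s[j][comparable]
    dm = dm[comparable]
    concordant = np.sign(ds) == np.sign(dm)
    tied = ds == 0
    return float((concordant.sum() + 0.5 * tied.sum()) / comparable.sum())


def plot_km(curves: Mapping[str, KMCurve], title: str | None = None, path=None):
    """Step-plot one or more Kaplan–Meier curves.

    Returns the matplotlib figure; writes it to ``path`` (PNG/SVG by
    extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, km in curves.items():
        t = np.concatenate([[0.0], km.times])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=f"{name} (n={int(km.at_risk[0])})")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


@dataclass(frozen=True)
class BootstrapCI:
    median: float
    lower: float
    upper: float
    n: int


def bootstrap_median_ci(
    values_by_category: Mapping[str, ArrayLike],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> dict[str, BootstrapCI]:
    """Percentile-bootstrap confidence interval of the median per category.

    Empty categories are skipped with a warning.  Deterministic given
    ``seed``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    q_lo, q_hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    out: dict[str, BootstrapCI] = {}
    for name, vals in values_by_category.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            warnings.warn(f"category {name!r} is empty; skipped", stacklevel=2)
            continue
        resampled = rng.choice(v, size=(n_boot, v.size), replace=True)
        medians = np.median(resampled, axis=1)
        lo, hi = np.percentile(medians, [q_lo, q_hi])
        out[name] = BootstrapCI(float(np.median(v)), float(lo), float(hi), int(v.size))
    return out
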