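"""Cohort-level statistics: box-plot summaries, Wilcoxon signed-rank test
and volume-curvature correlation.

The signed-rank test is exact (full null distribution over sign assignments,
computed by subset-sum convolution) up to n = 25 retained differences, and
uses the tie- and continuity-corrected normal approximation beyond. Because
volume (cm^3) and curvature (1/mm) are incommensurate, the paired
volume-versus-curvature test z-standardises each feature across the cohort
before differencing.
"""
from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PairingError, SampleSizeError, UndefinedStatisticError

EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 10

COHORT_COLUMNS = ("case_id", "source", "volume_cm3", "global_curvature_per_mm")


@dataclass
class CohortSummary:
    """Numbers behind a box plot: location, spread, quartiles, whiskers."""

    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


def summarise(values) -> CohortSummary:
    """Box-plot summary: mean, sample SD, median, quartiles (linear
    interpolation) and Tukey 1.5*IQR whiskers clipped to the data range."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) < 2:
        raise SampleSizeError("summarise needs at least 2 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return CohortSummary(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=len(v),
    )


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w_doubled: int) -> float:
    """Two-sided exact p for the signed-rank statistic, conditional on the
    observed (doubled, hence integer) ranks; null = independent fair signs."""
    total = int(doubled_ranks.sum())
    f = np.zeros(total + 1, dtype=np.float64)
    f[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        f[r:] = f[r:] + f[:-r] if r > 0 else 2.0 * f[r:]
    f /= f.sum()
    lower = f[: w_doubled + 1].sum()
    upper = f[w_doubled:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |d| is ranked with mid-ranks for ties; W
    is the sum of ranks of positive differences. The two-sided p-value is
    exact for n <= 25 retained differences, else a normal approximation with
    continuity and tie corrections.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedStatisticError("all differences are zero; signed-rank undefined")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        p = _exact_signed_rank_p(doubled, int(round(2.0 * w)))
        return w, p
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        raise UndefinedStatisticError("zero variance in signed-rank statistic")
    correction = 0.5 * np.sign(w - mu)
    z = (w - mu - correction) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _t_transform_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Permutation p-value: proportion of y-rank permutations with
    |rho| >= |rho_obs| (full enumeration)."""
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    x_norm = np.sqrt(xc @ xc)
    yc = y_ranks - y_ranks.mean()
    y_norm = np.sqrt(yc @ yc)
    if x_norm == 0 or y_norm == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    hits = 0
    total = 0
    chunk = 100_000
    it = itertools.permutations(yc)
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        rhos = block @ xc / (x_norm * y_norm)
        hits += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
        total += len(block)
    return hits / total


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson: p from the t-distribution transform, df = n - 2. Spearman:
    exact permutation p for n <= 10, else the same t-transform applied to
    the rank correlation.
    """
    xv = np.asarray(x, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if xv.shape != yv.shape or xv.ndim != 1 or len(xv) < 3:
        raise SampleSizeError("correlate needs two equal-length lists with n >= 3")
    n = len(xv)
    if method == "pearson":
        r = _pearson_r(xv, yv)
        return r, _t_transform_p(r, n)
    if method == "spearman":
        xr = sps.rankdata(xv)
        yr = sps.rankdata(yv)
        rho = _pearson_r(xr, yr)
        if n <= EXACT_SPEARMAN_MAX_N:
            return rho, _exact_spearman_p(xr, yr, rho)
        return rho, _t_transform_p(rho, n)
    raise ValueError(f"unknown correlation method {method!r}")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero variance; cannot standardise")
    return (v - v.mean()) / sd


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (case_id, source, volume, curvature) cohort layout."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    for source, group in table.groupby("source"):
        if group["case_id"].duplicated().any():
            raise PairingError(f"duplicate case_ids in source {source!r}")
        if (group["volume_cm3"] <= 0).any():
            raise ValueError(f"non-positive volumes in source {source!r}")
    return table


def analyse_cohort(table: pd.DataFrame) -> dict:
    """Cohort analysis report.

    Per source (truth / predicted): box-plot summaries of volume and
    curvature, Pearson and Spearman volume-vs-curvature correlation, and a
    Wilcoxon signed-rank test on the paired z-standardised (volume,
    curvature) differences. If both sources are present, additional
    signed-rank tests compare truth vs predicted per feature, matched by
    case_id; an all-zero comparison is reported as degenerate rather than
    raising.
    """
    table = validate_cohort_table(table)
    report: dict = {"summaries": {}, "correlations": {}, "wilcoxon": {}}
    for source, group in table.groupby("source"):
        vol = group["volume_cm3"].to_numpy(dtype=float)
        curv = group["global_curvature_per_mm"].to_numpy(dtype=float)
        if len(group) < 3:
            raise SampleSizeError(f"source {source!r} has fewer than 3 cases")
        report["summaries"][source] = {
            "volume_cm3": asdict(summarise(vol)),
            "curvature_per_mm": asdict(summarise(curv)),
        }
        corr = {}
        for method in ("pearson", "spearman"):
            r, p = correlate(vol, curv, method=method)
            corr[method] = {"r": r, "p": p}
        report["correlations"][source] = corr
        w, p = wilcoxon_signed_rank(_zscore(vol) - _zscore(curv))
        report["wilcoxon"][f"{source}_volume_vs_curvature"] = {"W": w, "p": p}

    sources = sorted(table["source"].unique())
    if len(sources) == 2:
        a = table[table["source"] == sources[0]].set_index("case_id")
        b = table[table["source"] == sources[1]].set_index("case_id")
        if set(a.index) != set(b.index):
            raise PairingError("sources do not share the same case_ids")
        b = b.loc[a.index]
        for feature in ("volume_cm3", "global_curvature_per_mm"):
            diffs = a[feature].to_numpy(dtype=float) - b[feature].to_numpy(dtype=float)
            key = f"{sources[0]}_vs_{sources[1]}_{feature}"
            try:
                w, p = wilcoxon_signed_rank(diffs)
                report["wilcoxon"][key] = {"W": w, "p": p}
            except UndefinedStatisticError:
                report["wilcoxon"][key] = {"degenerate": True}
    return report
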