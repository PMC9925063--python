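"""Analysis layer: Welch tests, probability-bin DHW tables, extent and trends.

The probability maps are validated and exploited with a small set of
classical tools: Welch two-sample t-tests (unequal variances and sample
sizes) comparing report cells against all reef cells, mean annual-maximum
DHW per bleaching-probability bin, likely (>66%) / very likely (>90%)
bleaching-extent counts, and OLS trends of annual-mean thermal stress.
No multiple-testing correction is applied by default (the analyses are
exploratory tests of a pre-established hypothesis); a Bonferroni switch
exists for callers who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import CellIndex
from .pipeline import ProbabilityMap

#: probability-bin upper edges, upper-inclusive, matching the printed
#: ranges ">90%", ">66-90%", ">50-66%", ">33-50%", ">10-33%", "<=10%"
BIN_EDGES = (0.10, 0.33, 0.50, 0.66, 0.90)
BIN_LABELS = ("<=10%", ">10-33%", ">33-50%", ">50-66%", ">66-90%", ">90%")

LIKELY_THRESHOLD = 0.66
VERY_LIKELY_THRESHOLD = 0.90


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test (two-sided).

    t = (mean_x - mean_y) / sqrt(s1^2/n1 + s2^2/n2) with
    Welch-Satterthwaite degrees of freedom; sample variances use ddof=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    # threshold absorbs float noise from summing identical values
    if max(v1, v2) < 1e-20:
        raise ValueError("both samples have zero variance; t statistic undefined")
    se2_1, se2_2 = v1 / n1, v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2_1 + se2_2)
    df = (se2_1 + se2_2) ** 2 / (
        (se2_1 ** 2 / (n1 - 1)) + (se2_2 ** 2 / (n2 - 1))
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p,
                       mean_x=float(x.mean()), mean_y=float(y.mean()), n_x=n1, n_y=n2)


def probability_bin(p: float) -> str:
    """Bin label for one probability (boundaries upper-inclusive)."""
    if math.isnan(p):
        raise ValueError("cannot bin a no-data probability")
    for edge, label in zip(BIN_EDGES, BIN_LABELS):
        if p <= edge:
            return label
    return BIN_LABELS[-1]


def bin_by_probability(pmap: ProbabilityMap) -> dict[str, list[CellIndex]]:
    """Partition a map's reef cells over the probability bins.

    No-data cells (NaN) are left out; every finite-probability cell lands
    in exactly one bin.
    """
    out: dict[str, list[CellIndex]] = {label: [] for label in BIN_LABELS}
    for cell, p in pmap.probabilities.items():
        if math.isnan(p):
            continue
        out[probability_bin(p)].append(cell)
    return out


def dhw_by_bin_table(
    maps: Sequence[ProbabilityMap],
    annual_max: pd.DataFrame,
    cells: Sequence[CellIndex],
    years: Optional[Iterable[int]] = None,
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Mean annual-maximum DHW per bleaching-probability bin.

    Pools cell-years over ``years`` (default: all mapped years), assigns
    each to its probability bin, and reports per bin the mean annual-max
    DHW, the pooled count, and whether the bin mean differs from every
    other occupied bin by Welch tests at ``alpha`` (flag column
    ``distinct``).  An "all cells" row leads the table.
    """
    year_set = set(years) if years is not None else {m.year for m in maps}
    cell_pos = {cell: k for k, cell in enumerate(cells)}
    pooled: dict[str, list[float]] = {label: [] for label in BIN_LABELS}
    everything: list[float] = []
    for pmap in maps:
        if pmap.year not in year_set:
            continue
        row = annual_max.loc[pmap.year]
        for cell, p in pmap.probabilities.items():
            if math.isnan(p):
                continue
            dhw = float(row.iloc[cell_pos[cell]])
            pooled[probability_bin(p)].append(dhw)
            everything.append(dhw)

    n_tests = max(1, sum(1 for v in pooled.values() if len(v) >= 2))
    alpha_eff = alpha / (n_tests * (n_tests - 1) / 2) if (bonferroni and n_tests > 1) else alpha
    rows = [{
        "bin": "all cells",
        "mean_dhw": float(np.mean(everything)) if everything else np.nan,
        "n": len(everything), "distinct": False,
    }]
    for label in reversed(BIN_LABELS):  # >90% first, matching the printed order
        vals = pooled[label]
        distinct = False
        if len(vals) >= 2:
            others = [v for lab2, v in pooled.items() if lab2 != label and len(v) >= 2]
            tests = []
            for other in others:
                try:
                    tests.append(welch_t_test(vals, other).p < alpha_eff)
                except ValueError:
                    tests.append(False)
            distinct = bool(tests) and all(tests)
        rows.append({
            "bin": label,
            "mean_dhw": float(np.mean(vals)) if vals else np.nan,
            "n": len(vals), "distinct": distinct,
        })
    return pd.DataFrame(rows)


def extent_summary(
    maps: Sequence[ProbabilityMap],
    cells: Sequence[CellIndex],
    presence_by_year: Optional[dict[int, set[CellIndex]]] = None,
    thresholds: Sequence[float] = (LIKELY_THRESHOLD, VERY_LIKELY_THRESHOLD),
    years: Optional[Iterable[int]] = None,
) -> pd.DataFrame:
    """Cells exceeding each probability threshold at least once in a period.

    Counts and fractions (of all reef cells in scope) per threshold, plus
    the count of cells holding raw presence reports for comparison.
    """
    year_set = set(years) if years is not None else {m.year for m in maps}
    scoped = [m for m in maps if m.year in year_set]
    cell_list = list(cells)
    total = len(cell_list)
    rows = []
    for thr in thresholds:
        hit = {
            cell for m in scoped for cell in cell_list
            if not math.isnan(m.probabilities.get(cell, math.nan)) and m.probabilities[cell] > thr
        }
        rows.append({"threshold": thr, "n_cells": len(hit),
                     "fraction": len(hit) / total if total else np.nan})
    if presence_by_year is not None:
        reported = {c for y, cs in presence_by_year.items() if y in year_set for c in cs if c in set(cell_list)}
        rows.append({"threshold": np.nan, "n_cells": len(reported),
                     "fraction": len(reported) / total if total else np.nan})
    df = pd.DataFrame(rows)
    df["metric"] = [f"prob>{t:g}" for t in thresholds] + (["raw reports"] if presence_by_year is not None else [])
    return df


@dataclass
class TrendResult:
    slope: float        # degC-weeks per year
    intercept: float
    p: float
    stderr: float
    n_years: int


def trend_ols(annual_values: dict[int, float]) -> TrendResult:
    """OLS slope of annual subset-mean DHW on calendar year, two-sided p."""
    years = np.array(sorted(annual_values), dtype=float)
    vals = np.array([annual_values[int(y)] for y in years], dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 years for a trend")
    if np.ptp(years) == 0:
        raise ValueError("constant regressor")
    res = sps.linregress(years, vals)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       p=float(res.pvalue), stderr=float(res.stderr), n_years=len(years))


def dhw_trends_by_subset(
    maps: Sequence[ProbabilityMap],
    annual_max: pd.DataFrame,
    cells: Sequence[CellIndex],
    thresholds: Sequence[float] = (LIKELY_THRESHOLD, VERY_LIKELY_THRESHOLD),
) -> pd.DataFrame:
    """Trend of annual-mean annual-max DHW: all cells vs high-probability cells.

    For each year the subset mean pools the cells whose probability that
    year exceeds the threshold; the "all cells" series averages every reef
    cell.  Years where a subset is empty are skipped for that subset.
    """
    cell_pos = {cell: k for k, cell in enumerate(cells)}
    series: dict[str, dict[int, float]] = {"all cells": {}}
    for thr in thresholds:
        series[f"prob>{thr:g}"] = {}
    for pmap in maps:
        row = annual_max.loc[pmap.year]
        all_vals = [float(row.iloc[cell_pos[c]]) for c in cells]
        series["all cells"][pmap.year] = float(np.mean(all_vals))
        for thr in thresholds:
            sub = [
                float(row.iloc[cell_pos[c]])
                for c, p in pmap.probabilities.items()
                if not math.isnan(p) and p > thr
            ]
            if sub:
                series[f"prob>{thr:g}"][pmap.year] = float(np.mean(sub))
    rows = []
    for name, vals in series.items():
        if len(vals) >= 3:
            tr = trend_ols(vals)
            rows.append({"subset": name, "slope": tr.slope, "p": tr.p,
                         "stderr": tr.stderr, "n_years": tr.n_years})
        else:
            rows.append({"subset": name, "slope": np.nan, "p": np.nan,
                         "stderr": np.nan, "n_years": len(vals)})
    return pd.DataFrame(rows)


def compare_reports_vs_all(pmap: ProbabilityMap, presence: set[CellIndex]) -> WelchResult:
    """Welch test: probabilities at report cells vs at all reef cells."""
    pres = [p for c, p in pmap.probabilities.items() if c in presence and not math.isnan(p)]
    all_cells = [p for p in pmap.probabilities.values() if not math.isnan(p)]
    if len(pres) < 2:
        raise ValueError("need at least 2 presence cells with data")
    return welch_t_test(pres, all_cells)


def rank_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Probability that a positive outranks a negative (Mann-Whitney AUC)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))
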