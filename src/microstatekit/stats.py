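"""Group statistics for microstate parameters.

Independent-samples t-tests (pooled-variance Student test by default,
Welch by flag) for every microstate parameter between the smoker and
control groups, and Spearman rank correlations between the smokers'
microstate features and their smoking characteristics (FTND, cigarettes
per day, pack-years).  No multiple-comparison correction is applied by
default; a Benjamini-Hochberg FDR column is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "independent_t_test",
    "compare_all_parameters",
    "spearman",
    "correlate_with_smoking",
    "PARAMETER_PREFIXES",
]

PARAMETER_PREFIXES = ("duration_", "occurrence_", "coverage_", "t_")


@dataclass
class TTestResult:
    parameter: str
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


@dataclass
class CorrelationResult:
    feature: str
    variable: str
    rho: float
    p: float
    n: int


def _as_summary(x):
    """Accept raw samples or a (mean, sd, n) triple; return (mean, sd, n)."""
    if isinstance(x, (tuple, list)) and len(x) == 3 and np.isscalar(x[2]):
        m, s, n = float(x[0]), float(x[1]), int(x[2])
    else:
        arr = np.asarray(x, dtype=float)
        arr = arr[np.isfinite(arr)]
        n = int(arr.size)
        if n < 2:
            return (float(arr.mean()) if n else float("nan")), float("nan"), n
        m, s = float(arr.mean()), float(arr.std(ddof=1))
    return m, s, n


def independent_t_test(group1, group2, welch: bool = False,
                       parameter: str = "") -> TTestResult:
    """Two-sided independent-samples t-test from samples or summaries.

    Either argument may be raw samples or a ``(mean, sd, n)`` summary
    triple (sd with ddof=1).  The default is the pooled-variance Student
    test with ``df = n1 + n2 - 2``.  A degenerate zero-variance case
    returns t=0, p=1 when the means agree and raises otherwise.
    """
    m1, s1, n1 = _as_summary(group1)
    m2, s2, n2 = _as_summary(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return TTestResult(parameter, 0.0, n1 + n2 - 2, 1.0, m1, s1, n1, m2, s2, n2)
        raise ValueError("zero pooled variance with unequal means")
    res = sstats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
    if welch:
        df = float(res.df) if hasattr(res, "df") else np.nan
    else:
        df = float(n1 + n2 - 2)
    return TTestResult(parameter, float(res.statistic), df, float(res.pvalue),
                       m1, s1, n1, m2, s2, n2)


def compare_all_parameters(table: pd.DataFrame, group_col: str = "group",
                           group1: str = "smoker", group2: str = "control",
                           welch: bool = False, fdr: bool = False) -> pd.DataFrame:
    """One t-test per microstate parameter column.

    Tests every column whose name starts with ``duration_``,
    ``occurrence_``, ``coverage_`` or ``t_`` (the 12 off-diagonal
    transition cells).  Raw two-sided p-values are reported; pass
    ``fdr=True`` to append a Benjamini-Hochberg adjusted column.
    """
    cols = [c for c in table.columns if c.startswith(PARAMETER_PREFIXES)
            and c != "total_seconds"]
    if not cols:
        raise ValueError("no parameter columns found")
    g1 = table[table[group_col] == group1]
    g2 = table[table[group_col] == group2]
    rows = []
    for c in cols:
        r = independent_t_test(g1[c].to_numpy(), g2[c].to_numpy(),
                               welch=welch, parameter=c)
        rows.append({"parameter": c, "t": r.t, "df": r.df, "p": r.p,
                     f"mean_{group1}": r.mean1, f"sd_{group1}": r.sd1,
                     f"mean_{group2}": r.mean2, f"sd_{group2}": r.sd2,
                     "n1": r.n1, "n2": r.n2})
    out = pd.DataFrame(rows)
    if fdr:
        out["p_fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n only)."""
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    n = rx.size
    rs = []
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        rs.append(r)
    rs = np.abs(np.asarray(rs))
    return float(np.mean(rs >= abs(rho_obs) - 1e-12))


def spearman(x, y, method: str = "approx") -> tuple:
    """Spearman rho (mid-rank ties) and two-sided p.

    ``method='approx'`` uses the t-approximation; ``method='exact'``
    enumerates all permutations and is limited to n <= 8.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant variable: Spearman rank correlation undefined")
    rho, p = sstats.spearmanr(x, y)
    if method == "exact":
        if x.size > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        p = _spearman_exact_p(x, y, rho)
    return float(rho), float(p), int(x.size)


def correlate_with_smoking(parameters: pd.DataFrame, clinical: pd.DataFrame,
                           variables: Sequence[str] = ("FTND", "CPD", "pack_years"),
                           features: Optional[Sequence[str]] = None,
                           method: str = "approx") -> pd.DataFrame:
    """Spearman correlations, within the smoker group only.

    ``features`` defaults to all duration/occurrence/coverage columns of
    the parameter table.  Returns a tidy frame (feature, variable, rho,
    p, n).
    """
    merged = parameters.merge(clinical, on="subject_id", suffixes=("", "_clin"))
    gcol = "group" if "group" in merged.columns else "group_clin"
    smokers = merged[merged[gcol] == "smoker"]
    if features is None:
        features = [c for c in parameters.columns
                    if c.startswith(("duration_", "occurrence_", "coverage_"))]
    rows = []
    for v in variables:
        for f in features:
            rho, p, n = spearman(smokers[f], smokers[v], method=method)
            rows.append({"feature": f, "variable": v, "rho": rho, "p": p, "n": n})
    return pd.DataFrame(rows)
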