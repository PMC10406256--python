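"""Histology-dMRI correlation design: Pearson + BH-FDR, grouped by family.

Heterogeneity correlations (hCAD vs each dMRI heterogeneity measure) are
pooled over all (subject, region) points and additionally split by region
class; average correlations (avgCAD vs each dMRI average) are computed
separately within cortical and subcortical regions, because the two classes
show opposite trends that cancel when pooled.  p-values are corrected with
Benjamini-Hochberg within each (family, group) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DMRI_MEASURES = ("FA", "TR", "MSD", "RTOP")


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def linear_fit_with_band(
    x: np.ndarray, y: np.ndarray, level: float = 0.95, x_grid: np.ndarray | None = None
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """OLS line with a pointwise confidence band for the mean response.

    Returns (slope, intercept, x_grid, half_widths) where the band at x0 is
    t_{1-a/2, n-2} * s * sqrt(1/n + (x0 - xbar)^2 / Sxx).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x")
    fit = stats.linregress(x, y)
    n = x.size
    resid = y - (fit.intercept + fit.slope * x)
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if x_grid is None:
        x_grid = np.linspace(x.min(), x.max(), 50)
    tval = stats.t.ppf(0.5 + level / 2.0, n - 2)
    half = tval * np.sqrt(s2 * (1.0 / n + (x_grid - x.mean()) ** 2 / sxx))
    return float(fit.slope), float(fit.intercept), x_grid, half


@dataclass
class CorrelationResult:
    pair: str        # e.g. 'hCAD~hTR' or 'avgCAD~avgMSD'
    family: str      # FDR family the test belongs to
    group: str       # 'all', 'cortical', 'subcortical'
    n: int
    r: float
    p: float
    q: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    wide = table.pivot_table(
        index=["subject", "region", "class"],
        columns="measure",
        values=["average", "heterogeneity"],
        aggfunc="first",
    )
    wide.columns = [
        ("avg" if stat == "average" else "h") + meas for stat, meas in wide.columns
    ]
    return wide.reset_index()


def _one(wide: pd.DataFrame, xcol: str, ycol: str, pair: str, family: str, group: str):
    sub = wide if group == "all" else wide[wide["class"] == group]
    ok = sub[[xcol, ycol]].dropna()
    if len(ok) < 3:
        return None
    r, p = pearson(ok[xcol].to_numpy(), ok[ycol].to_numpy())
    slope, intercept, _, _ = linear_fit_with_band(ok[xcol].to_numpy(), ok[ycol].to_numpy())
    return CorrelationResult(pair, family, group, len(ok), r, p,
                             slope=slope, intercept=intercept)


def run_study_correlations(
    table: pd.DataFrame, fdr_scope: str = "family"
) -> pd.DataFrame:
    """All study correlations with FDR-adjusted q-values.

    ``fdr_scope='family'`` corrects within each (family, group); ``'global'``
    corrects across every test at once.
    """
    dup = table.duplicated(subset=["subject", "region", "measure"])
    if dup.any():
        raise ValueError("summary table violates one-row-per-(subject,region,measure)")
    wide = _pivot(table)
    results: list[CorrelationResult] = []
    for meas in DMRI_MEASURES:
        for group in ("all", "cortical", "subcortical"):
            res = _one(wide, "hCAD", f"h{meas}", f"hCAD~h{meas}",
                       f"heterogeneity_{group}", group)
            if res is not None:
                results.append(res)
        for group in ("cortical", "subcortical"):
            res = _one(wide, "avgCAD", f"avg{meas}", f"avgCAD~avg{meas}",
                       f"average_{group}", group)
            if res is not None:
                results.append(res)

    df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        return df
    if fdr_scope == "global":
        df["q"] = fdr_bh(df["p"].to_numpy())
    elif fdr_scope == "family":
        for fam, idx in df.groupby("family").groups.items():
            df.loc[idx, "q"] = fdr_bh(df.loc[idx, "p"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return df


def volume_effect_check(table: pd.DataFrame, volumes: pd.DataFrame) -> CorrelationResult:
    """Correlation of region volume (voxel count) with average cell density.

    ``volumes`` needs columns (subject, region, volume).  Constant volumes
    make the check untestable and raise a ValueError.
    """
    cad = table[table["measure"] == "CAD"][["subject", "region", "average"]]
    merged = cad.merge(volumes, on=["subject", "region"]).dropna()
    if len(merged) < 3:
        raise ValueError("too few (subject, region) points for the volume check")
    vol = merged["volume"].to_numpy(float)
    if np.ptp(vol) == 0:
        raise ValueError("region volumes are constant: volume effect not testable")
    r, p = pearson(vol, merged["average"].to_numpy())
    return CorrelationResult("volume~avgCAD", "volume_effect", "all", len(merged), r, p)
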