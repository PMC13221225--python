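"""Disease-progression slopes and methylation-clinical Spearman correlation.

The ALS-FRS-R progression slope is the loss of functional-rating points
per month since symptom onset, taking the full score of 48 as the
pre-onset baseline: slope = (48 - score at draw) / months since onset.

Correlations are Spearman rank correlations with average ranks for ties;
p-values come from exact permutation enumeration for n <= 9 complete
pairs and the t approximation otherwise. Ranked gene tables report
unadjusted p (as is conventional for small exploratory panels) plus a
Bonferroni column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALSFRS_MAX = 48
EXACT_MAX_N = 9


def progression_slope(alsfrs_r_at_draw: float, months_from_onset: float) -> float:
    """ALS-FRS-R points lost per month since symptom onset."""
    if months_from_onset <= 0:
        raise ValueError("months_from_onset must be positive")
    if not 0 <= alsfrs_r_at_draw <= ALSFRS_MAX:
        raise ValueError(f"ALS-FRS-R outside [0, {ALSFRS_MAX}]")
    return (ALSFRS_MAX - alsfrs_r_at_draw) / months_from_onset


def add_progression_slopes(sheet: pd.DataFrame) -> pd.DataFrame:
    """Append a ``slope`` column to a sample sheet (NaN where undefined)."""
    out = sheet.copy()
    slopes = []
    for row in sheet.itertuples(index=False):
        score, months = row.alsfrs_r_at_draw, row.months_from_onset
        if pd.isna(score) or pd.isna(months):
            slopes.append(np.nan)
        else:
            slopes.append(progression_slope(float(score), float(months)))
    out["slope"] = slopes
    return out


@dataclass(frozen=True)
class CorrelationRow:
    """Spearman correlation of one gene/region's methylation with a covariate."""

    name: str
    rho: float
    p: float
    n: int
    variable: str


_NULL_RHO_CACHE: dict[int, np.ndarray] = {}


def _null_rho_distribution(n: int) -> np.ndarray:
    """|rho| over all n! rank permutations (cached per n)."""
    if n not in _NULL_RHO_CACHE:
        base = np.arange(1, n + 1, dtype=float)
        perms = np.array(list(permutations(range(n))), dtype=np.int64)
        ranks = base[perms]
        mean = (n + 1) / 2
        denom = np.sum((base - mean) ** 2)
        rhos = ((ranks - mean) @ (base - mean)) / denom
        _NULL_RHO_CACHE[n] = np.abs(rhos)
    return _NULL_RHO_CACHE[n]


def _exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration."""
    null = _null_rho_distribution(n)
    return float(np.mean(null >= abs(rho) - 1e-12))


def correlate_methylation_clinical(
    methylation: pd.Series,
    clinical: pd.Series,
    variable_name: str = "slope",
) -> CorrelationRow:
    """Spearman correlation over complete pairs, NA-safe.

    Requires at least 3 complete pairs; returns NaN rho/p when either
    variable is constant.
    """
    joined = pd.concat([methylation, clinical], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    name = methylation.name if methylation.name is not None else "region"
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("%s: constant variable, correlation undefined", name)
        return CorrelationRow(str(name), float("nan"), float("nan"), n, variable_name)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_MAX_N and not has_ties:
        p = _exact_spearman_pvalue(rho, n)
    else:
        if abs(rho) >= 1.0:
            p = 2.0 * math.factorial(n) ** -1 if not has_ties else 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationRow(str(name), rho, min(p, 1.0), n, variable_name)


def rank_correlated_genes(
    methylation: pd.DataFrame,
    clinical: pd.Series,
    variable_name: str = "slope",
    k: int = 10,
) -> pd.DataFrame:
    """Top-k genes by Spearman correlation with a clinical covariate.

    ``methylation`` is samples x candidate genes/regions (promoter DMC or
    promoter-mean methylation). Rows are ranked by ascending p with ties
    broken by |rho| descending; a Bonferroni-adjusted column is included.
    """
    rows = []
    for name in methylation.columns:
        try:
            row = correlate_methylation_clinical(
                methylation[name], clinical, variable_name
            )
        except ValueError:
            continue
        rows.append(
            {"name": row.name, "rho": row.rho, "p": row.p, "n": row.n}
        )
    table = pd.DataFrame(rows, columns=["name", "rho", "p", "n"])
    table = table.dropna(subset=["p"])
    m = len(table)
    table["p_bonferroni"] = np.minimum(table["p"] * max(m, 1), 1.0)
    table["variable"] = variable_name
    table = table.assign(_abs=table["rho"].abs()).sort_values(
        ["p", "_abs", "name"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_abs")
    if k < len(table):
        table = table.head(k)
    return table.reset_index(drop=True)
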