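"""Differential methylation: per-CpG tests, DMR segmentation and scoring,
promoter-DMR filtering, and z-scored summaries.

Group comparison uses the two-sided Mann-Whitney U test on beta values:
exact enumeration when both groups have at most 8 usable samples, the
tie-corrected normal approximation (with continuity correction) otherwise.
Multiple testing is controlled with Benjamini-Hochberg, adjusted separately
for the CpG-level and region-level families.

DMR discovery is mean-difference binary segmentation: CpGs are first
broken into blocks at gaps exceeding ``max_gap``, the sub-interval with
the largest absolute group-mean difference (subject to a minimum CpG
count) is located in each block, its boundaries are extended while
adjacent CpGs keep at least half the reporting effect size, and accepted
regions are rescored by a Mann-Whitney test on per-sample region means.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import AnnotationSet

logger = logging.getLogger(__name__)

EXACT_MAX_N = 8  # exact MWU enumeration up to this per-group size


def _split_groups(beta: pd.DataFrame, labels: pd.Series) -> Tuple[str, str, np.ndarray, np.ndarray]:
    labels = labels.reindex(beta.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    a, b = uniq
    mask_a = (labels == a).to_numpy()
    counts = (mask_a.sum(), (~mask_a).sum())
    if min(counts) < 2:
        raise ValueError("each group needs n >= 2")
    return a, b, mask_a, ~mask_a


def filter_by_missingness(
    beta: pd.DataFrame, max_missing: float = 0.10
) -> pd.DataFrame:
    """Drop CpG columns whose missing fraction strictly exceeds the cap."""
    frac = beta.isna().mean(axis=0)
    keep = frac.to_numpy() <= max_missing + 1e-12
    if not keep.any():
        logger.warning("all CpG sites removed by missingness filter")
    return beta.loc[:, keep]


def mwu_pvalues(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided Mann-Whitney U on two (samples x sites) blocks.

    Returns (U of the first group, p). NaNs are dropped pairwise per
    column; method selection follows the per-column usable group sizes.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    n_sites = a.shape[1]
    has_nan = np.isnan(a).any() or np.isnan(b).any()
    max_n = max(a.shape[0], b.shape[0])
    if not has_nan:
        method = "exact" if max_n <= EXACT_MAX_N else "asymptotic"
        res = stats.mannwhitneyu(a, b, axis=0, method=method, alternative="two-sided")
        return np.asarray(res.statistic, float), np.clip(np.asarray(res.pvalue, float), 0, 1)

    u = np.full(n_sites, np.nan)
    p = np.full(n_sites, np.nan)
    for j in range(n_sites):
        aj = a[~np.isnan(a[:, j]), j]
        bj = b[~np.isnan(b[:, j]), j]
        if len(aj) < 1 or len(bj) < 1:
            continue
        method = "exact" if max(len(aj), len(bj)) <= EXACT_MAX_N else "asymptotic"
        res = stats.mannwhitneyu(aj, bj, method=method, alternative="two-sided")
        u[j], p[j] = res.statistic, min(float(res.pvalue), 1.0)
    return u, p


def test_dmc(beta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-CpG two-sided Mann-Whitney U with BH adjustment.

    ``beta`` is samples x CpG sites (columns: (chrom, pos) tuples); returns
    one row per testable CpG with group means, delta (group A - group B in
    label order), U, p and q. CpGs where a group is entirely missing are
    skipped and reported with NaN p.
    """
    group_a, group_b, mask_a, mask_b = _split_groups(beta, labels)
    a = beta.to_numpy(dtype=float)[mask_a]
    b = beta.to_numpy(dtype=float)[mask_b]

    ok = (~np.isnan(a)).sum(axis=0) >= 1
    ok &= (~np.isnan(b)).sum(axis=0) >= 1
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("%d CpGs skipped (a group entirely missing)", n_skipped)

    u = np.full(beta.shape[1], np.nan)
    p = np.full(beta.shape[1], np.nan)
    if ok.any():
        u[ok], p[ok] = mwu_pvalues(a[:, ok], b[:, ok])

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(a, axis=0)
        mean_b = np.nanmean(b, axis=0)
    cols = beta.columns
    out = pd.DataFrame(
        {
            "chrom": [c[0] for c in cols],
            "pos": [c[1] for c in cols],
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "delta": mean_a - mean_b,
            "U": u,
            "p": p,
            "q": q,
        }
    )
    out.attrs["groups"] = (group_a, group_b)
    return out


# ---------------------------------------------------------------------------
# DMR segmentation
# ---------------------------------------------------------------------------

def _best_subinterval(d: np.ndarray, min_len: int) -> Tuple[int, int, float]:
    """(a, b, mean) of the min_len+-length window maximizing |mean d[a..b]|."""
    n = len(d)
    cs = np.concatenate([[0.0], np.cumsum(d)])
    best = (0, n - 1, cs[n] / n)
    best_abs = abs(best[2])
    for a in range(0, n - min_len + 1):
        lengths = np.arange(min_len, n - a + 1)
        means = (cs[a + min_len : n + 1] - cs[a]) / lengths
        j = int(np.argmax(np.abs(means)))
        if abs(means[j]) > best_abs:
            best = (a, a + min_len + j - 1, float(means[j]))
            best_abs = abs(means[j])
    return best


def _segment_block(
    d: np.ndarray, lo: int, hi: int, min_cpgs: int, min_delta: float, out: list
) -> None:
    """Recursively harvest candidate DMRs from d[lo..hi] (inclusive)."""
    n = hi - lo + 1
    if n < min_cpgs:
        return
    a, b, mean = _best_subinterval(d[lo : hi + 1], min_cpgs)
    a += lo
    b += lo
    sign = np.sign(mean) if mean != 0 else 1.0
    # boundary extension: absorb flanking CpGs still carrying at least half
    # the reporting effect size in the same direction
    while a - 1 >= lo and sign * d[a - 1] >= min_delta / 2:
        a -= 1
    while b + 1 <= hi and sign * d[b + 1] >= min_delta / 2:
        b += 1
    mean = float(d[a : b + 1].mean())
    if abs(mean) < min_delta:
        return
    out.append((a, b, mean))
    _segment_block(d, lo, a - 1, min_cpgs, min_delta, out)
    _segment_block(d, b + 1, hi, min_cpgs, min_delta, out)


def segment_dmrs(
    beta: pd.DataFrame,
    labels: pd.Series,
    max_gap: int = 300,
    min_cpgs: int = 10,
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """De novo DMR discovery by mean-difference binary segmentation.

    Reported regions are rescored: per-sample mean beta over the region's
    CpGs, Mann-Whitney U across groups, BH over all reported DMRs. Columns
    of ``beta`` must be (chrom, pos) sorted in genome order.
    """
    group_a, group_b, mask_a, mask_b = _split_groups(beta, labels)
    if beta.shape[1] < min_cpgs:
        return _empty_dmr_frame(group_a, group_b)

    values = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        d = np.nanmean(values[mask_a], axis=0) - np.nanmean(values[mask_b], axis=0)
    chroms = np.array([c[0] for c in beta.columns])
    positions = np.array([c[1] for c in beta.columns], dtype=np.int64)

    candidates: list[Tuple[int, int, float]] = []
    start_idx = 0
    for i in range(1, len(positions) + 1):
        boundary = (
            i == len(positions)
            or chroms[i] != chroms[i - 1]
            or positions[i] - positions[i - 1] > max_gap
        )
        if boundary:
            block = []
            _segment_block(d, start_idx, i - 1, min_cpgs, min_delta, block)
            candidates.extend(block)
            start_idx = i

    if not candidates:
        return _empty_dmr_frame(group_a, group_b)

    rows = []
    for a, b, mean in sorted(candidates):
        region_means = np.nanmean(values[:, a : b + 1], axis=1)
        u, p = mwu_pvalues(
            region_means[mask_a, None], region_means[mask_b, None]
        )
        ma = float(np.nanmean(region_means[mask_a]))
        mb = float(np.nanmean(region_means[mask_b]))
        rows.append(
            {
                "chrom": chroms[a],
                "start": int(positions[a]),
                "end": int(positions[b]) + 1,
                "n_cpgs": b - a + 1,
                f"mean_{group_a}": ma,
                f"mean_{group_b}": mb,
                "delta": ma - mb,
                "U": float(u[0]),
                "p": float(p[0]),
                "cpg_start_idx": a,
                "cpg_end_idx": b,
            }
        )
    dmrs = pd.DataFrame(rows)
    dmrs["q"] = multipletests(dmrs["p"], method="fdr_bh")[1]
    dmrs["gene"] = None
    dmrs.attrs["groups"] = (group_a, group_b)
    return dmrs


def _empty_dmr_frame(group_a: str, group_b: str) -> pd.DataFrame:
    out = pd.DataFrame(
        columns=[
            "chrom", "start", "end", "n_cpgs", f"mean_{group_a}",
            f"mean_{group_b}", "delta", "U", "p", "cpg_start_idx",
            "cpg_end_idx", "q", "gene",
        ]
    )
    out.attrs["groups"] = (group_a, group_b)
    return out


def filter_promoter_dmrs(
    dmrs: pd.DataFrame,
    promoters: AnnotationSet,
    min_cpgs: int = 10,
    max_q: float = 1e-5,
    min_abs_delta: float = 0.1,
) -> pd.DataFrame:
    """Stringent promoter-DMR retention filter.

    Keeps DMRs that overlap at least one promoter, carry >= ``min_cpgs``
    CpG sites, have adjusted p < ``max_q`` and |delta| >= ``min_abs_delta``.
    X-chromosome DMRs are excluded (sex-driven differences from
    X-inactivation). Annotates the overlapping promoter gene.
    """
    if len(dmrs) == 0:
        return dmrs.copy()
    keep = []
    genes = []
    for row in dmrs.itertuples(index=True):
        if row.chrom == "chrX":
            continue
        if row.n_cpgs < min_cpgs:
            continue
        if not row.q < max_q:
            continue
        if abs(row.delta) < min_abs_delta - 1e-12:
            continue
        hits = promoters.query(row.chrom, row.start, row.end)
        if not hits:
            continue
        keep.append(row.Index)
        genes.append(hits[0].gene or hits[0].name)
    out = dmrs.loc[keep].copy()
    out["gene"] = genes
    return out


def zscore_promoter_dmcs(
    beta: pd.DataFrame, selected: Optional[Sequence] = None
) -> pd.DataFrame:
    """Z-score betas per CpG across all samples (sample sd, ddof=1).

    Constant CpGs get z = 0 everywhere.
    """
    sub = beta if selected is None else beta.loc[:, list(selected)]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    z = (sub - mean).div(sd.replace(0.0, np.nan), axis=1)
    return z.fillna(0.0).where(~sub.isna(), np.nan)


def top_k_dmcs(dmcs: pd.DataFrame, k: int = 1000) -> pd.DataFrame:
    """Top-k CpGs ranked by ascending q, then p, then |delta| descending.

    Remaining ties break on genome position for a deterministic order.
    """
    if len(dmcs) == 0:
        raise ValueError("no DMC results to rank")
    if k > len(dmcs):
        logger.warning("k=%d exceeds %d available DMCs", k, len(dmcs))
        k = len(dmcs)
    ranked = dmcs.assign(_absd=dmcs["delta"].abs()).sort_values(
        ["q", "p", "_absd", "chrom", "pos"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    return ranked.drop(columns="_absd").head(k).reset_index(drop=True)
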