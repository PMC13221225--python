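"""Fragment-derived epigenetic features: WPS, nucleosome occupancy,
and regional methylation.

The window protection score (WPS) at a base p counts fragments that span
the full window centered on p minus fragments with an endpoint inside the
window; positive peaks mark nucleosome-protected DNA. Conventions (window
size w even, w2 = w // 2, window W = [p - w2, p + w2)):

* spanning:  start <= W.start and end >= W.end;
* endpoint:  not spanning, and (start in W or end - 1 in W).

The two classes are disjoint by construction and tested at the boundaries.
Nucleosome occupancy is raw per-base fragment coverage normalized by the
library-wide mean, averaged over 1 kb windows at TSS/PAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import FeatureMatrix, MethylomeSample
from .regions import AnnotationSet, GenomicRegion

logger = logging.getLogger(__name__)


@dataclass
class WpsTrack:
    """Per-base WPS over one region."""

    region: GenomicRegion
    scores: np.ndarray
    window_size: int

    @property
    def region_mean(self) -> float:
        return float(self.scores.mean())


def compute_wps(
    fragments: pd.DataFrame, region: GenomicRegion, window_size: int = 120
) -> WpsTrack:
    """Window protection score at every base of ``region``.

    Implemented with difference arrays: each fragment contributes +1 over
    its spanning-position run and -1 over its endpoint-position runs, which
    are disjoint closed integer intervals derived from the conventions in
    the module docstring.
    """
    if window_size < 2 or window_size % 2:
        raise ValueError("window_size must be even and >= 2")
    if len(region) < 1:
        raise ValueError("empty region")
    w2 = window_size // 2
    rs, re = region.start, region.end
    m = re - rs
    diff = np.zeros(m + 1, dtype=np.int64)

    if len(fragments):
        frags = fragments[fragments["chrom"] == region.chrom]
    else:
        frags = fragments
    if len(frags) == 0:
        return WpsTrack(region, np.zeros(m, dtype=np.int64), window_size)

    starts = frags["start"].to_numpy(dtype=np.int64)
    ends = frags["end"].to_numpy(dtype=np.int64)
    lengths = ends - starts
    w = window_size

    def _add(lo: np.ndarray, hi: np.ndarray, weight: int) -> None:
        # closed integer position intervals [lo, hi], clipped to the region
        lo = np.clip(lo - rs, 0, m)
        hi = np.clip(hi - rs + 1, 0, m)
        keep = hi > lo
        np.add.at(diff, lo[keep], weight)
        np.add.at(diff, hi[keep], -weight)

    long_enough = lengths >= w
    # spanning run: p in [start + w2, end - w2]
    _add(starts[long_enough] + w2, ends[long_enough] - w2, +1)
    # endpoint runs exclude the spanning boundary positions
    _add(starts[long_enough] - w2 + 1, starts[long_enough] + w2 - 1, -1)
    _add(ends[long_enough] - w2 + 1, ends[long_enough] + w2 - 1, -1)
    # short fragments: both endpoint intervals overlap -> single merged run
    short = ~long_enough
    _add(starts[short] - w2 + 1, ends[short] + w2 - 1, -1)

    scores = np.cumsum(diff[:-1])
    return WpsTrack(region, scores, window_size)


def average_wps_per_region(
    fragments_by_sample: dict,
    regions: AnnotationSet,
    window_size: int = 120,
) -> FeatureMatrix:
    """Mean WPS per target region per sample (modality ``"wps"``)."""
    rows = {}
    for sample_id, frags in fragments_by_sample.items():
        rows[sample_id] = {
            r.name: compute_wps(frags, r, window_size).region_mean
            for r in regions
        }
    values = pd.DataFrame.from_dict(rows, orient="index")
    values = values[[r.name for r in regions]]
    values.index.name = "sample_id"
    return FeatureMatrix(modality="wps", values=values)


def coverage_profile(
    fragments: pd.DataFrame, chrom: str, start: int, end: int
) -> np.ndarray:
    """Per-base count of fragments overlapping each base of [start, end)."""
    m = end - start
    diff = np.zeros(m + 1, dtype=np.int64)
    frags = fragments[fragments["chrom"] == chrom]
    if len(frags):
        lo = np.clip(frags["start"].to_numpy() - start, 0, m)
        hi = np.clip(frags["end"].to_numpy() - start, 0, m)
        keep = hi > lo
        np.add.at(diff, lo[keep], 1)
        np.add.at(diff, hi[keep], -1)
    return np.cumsum(diff[:-1])


def library_mean_coverage(
    fragments: pd.DataFrame, regions: AnnotationSet
) -> float:
    """Library-wide mean per-base coverage over a region universe."""
    span = sum(len(r) for r in regions)
    if span == 0:
        raise ValueError("empty region universe")
    total = 0
    for r in regions:
        total += int(coverage_profile(fragments, r.chrom, r.start, r.end).sum())
    return total / span


def occupancy_profile(
    fragments_by_sample: dict,
    sites: AnnotationSet,
    flank: int = 1000,
    library_mean: Optional[dict] = None,
    universe: Optional[AnnotationSet] = None,
) -> FeatureMatrix:
    """Normalized nucleosome occupancy around TSS/PAS sites.

    The feature for a site is the mean fragment coverage over the ``flank``-
    wide window centered on the site midpoint, divided by the library-wide
    mean per-base coverage. ``library_mean`` maps sample_id to that mean;
    when omitted it is computed over ``universe`` (or the site windows).
    """
    if sites.kind not in ("TSS", "PAS"):
        raise ValueError("sites must be of kind TSS or PAS")
    half = flank // 2
    windows = [
        (r, (r.start + r.end) // 2 - half, (r.start + r.end) // 2 + half)
        for r in sites
    ]
    rows = {}
    for sample_id, frags in fragments_by_sample.items():
        if library_mean is not None:
            lib = library_mean[sample_id]
        else:
            uni = universe
            if uni is None:
                uni = AnnotationSet(
                    kind="target",
                    regions=[
                        GenomicRegion(r.chrom, lo, hi, r.name, "target")
                        for r, lo, hi in windows
                    ],
                )
            lib = library_mean_coverage(frags, uni)
        if lib == 0:
            raise ValueError(f"{sample_id}: library mean coverage is zero")
        rows[sample_id] = {
            r.name: float(
                coverage_profile(frags, r.chrom, lo, hi).mean() / lib
            )
            for r, lo, hi in windows
        }
    values = pd.DataFrame.from_dict(rows, orient="index")
    values = values[[r.name for r in sites]]
    values.index.name = "sample_id"
    return FeatureMatrix(modality="occupancy", values=values)


def regional_methylation(
    samples: Sequence[MethylomeSample],
    regions: AnnotationSet,
) -> FeatureMatrix:
    """Unweighted mean of covered per-CpG betas inside each region.

    Missing when a region contains no covered CpG in that sample. Modality
    tag follows the region kind (CGI -> ``cgi_meth``, DHS -> ``dhs_meth``).
    """
    modality = {"CGI": "cgi_meth", "DHS": "dhs_meth"}.get(regions.kind)
    if modality is None:
        raise ValueError("regions must be of kind CGI or DHS")
    region_list = list(regions)
    rows = {}
    for sample in samples:
        calls = sample.calls
        feats = {}
        by_chrom = {c: sub for c, sub in calls.groupby("chrom", sort=False)}
        for r in region_list:
            sub = by_chrom.get(r.chrom)
            if sub is None:
                feats[r.name] = np.nan
                continue
            pos = sub["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [r.start, r.end])
            betas = sub["beta"].to_numpy()[lo:hi]
            betas = betas[~np.isnan(betas)]
            feats[r.name] = float(betas.mean()) if len(betas) else np.nan
        rows[sample.sample_id] = feats
    values = pd.DataFrame.from_dict(rows, orient="index")
    values = values[[r.name for r in region_list]]
    values.index.name = "sample_id"
    return FeatureMatrix(modality=modality, values=values)
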