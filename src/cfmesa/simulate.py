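"""Synthetic cohorts, fragments, reference atlases, and clinical covariates.

The generators emulate targeted methylome sequencing of serum cfDNA from an
ALS case/control study: per-CpG beta-binomial methylation counts at ~45x
depth, a mono/di-nucleosome fragment-length mixture peaking near 170 bp,
fragment-level methylation haplotypes over a cell-type marker atlas, and
clinical covariates (ALS-FRS-R decline slope, CSF pNfH) rank-coupled to
promoter methylation through a Gaussian copula.

Every generator is deterministic under a fixed seed and returns a truth
table alongside the data so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureMatrix, MethylomeSample, SHEET_COLUMNS
from .regions import AnnotationSet, CpGIndex, GenomicRegion

logger = logging.getLogger(__name__)

#: default cohort sizes for the primary case/control comparison
DEFAULT_N_PER_GROUP = {"sALS": 19, "control": 21}

#: the seven broad tissue categories used to summarize cell types
TISSUE_CATEGORIES = (
    "blood immune cells",
    "connective tissue",
    "epithelium",
    "sex-related tissue",
    "neural tissue",
    "muscle",
    "other",
)

#: default cell types, one per tissue category
DEFAULT_CELL_TYPES = (
    ("monocyte", "blood immune cells"),
    ("fibroblast", "connective tissue"),
    ("colon_epithelial", "epithelium"),
    ("prostate_epithelial", "sex-related tissue"),
    ("neuron", "neural tissue"),
    ("skeletal_myocyte", "muscle"),
    ("adipocyte", "other"),
)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# cohort design and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDMR:
    """A planted group-level methylation difference over a CpG run."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    delta_beta: float
    group: str = "sALS"
    gene: Optional[str] = None

    def __post_init__(self):
        if not -1.0 <= self.delta_beta <= 1.0:
            raise ValueError("delta_beta outside [-1, 1]")
        if self.n_cpgs < 10:
            raise ValueError("planted DMRs must carry >= 10 CpGs")
        if self.start >= self.end:
            raise ValueError("start >= end")

    @property
    def name(self) -> str:
        return self.gene or f"dmr_{self.chrom}_{self.start}"


@dataclass
class CohortDesign:
    """Everything needed to simulate a case/control methylation cohort.

    ``dispersion`` is the beta-binomial concentration: per-sample betas are
    Beta(m*c, (1-m)*c) around the group mean m, giving an inter-sample SD of
    roughly 0.05-0.07 at mid-range betas for the default c = 50.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    n_cpgs: int = 2000
    planted_dmrs: Sequence[PlantedDMR] = ()
    mean_depth: float = 45.0
    dispersion: float = 50.0
    hyper_weight: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        regs = sorted(self.planted_dmrs, key=lambda r: (r.chrom, r.start))
        for a, b in zip(regs, regs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"planted DMRs overlap: {a.name} and {b.name}"
                )


def _baseline_betas(n: int, hyper_weight: float, rng: np.random.Generator) -> np.ndarray:
    """Bimodal genome-like baseline: hypo mode Beta(2,18), hyper Beta(18,2)."""
    hyper = rng.random(n) < hyper_weight
    betas = np.where(hyper, rng.beta(18, 2, size=n), rng.beta(2, 18, size=n))
    return np.clip(betas, 0.02, 0.98)


def _place_cpgs(design: CohortDesign, rng: np.random.Generator):
    """Lay out background CpGs on chr1 and planted CpGs inside their regions.

    Background gaps are 30-180 bp so unplanted runs stay within typical
    DMR-segmentation gap limits; planted CpGs are evenly spaced in their
    declared interval.
    """
    planted_chr1 = [r for r in design.planted_dmrs if r.chrom == "chr1"]
    blocked = [(r.start, r.end) for r in planted_chr1]

    positions = []
    pos = 1000
    while len(positions) < design.n_cpgs:
        pos += int(rng.integers(30, 180))
        if any(s - 5 <= pos < e + 5 for s, e in blocked):
            inside = [e for s, e in blocked if s - 5 <= pos < e + 5]
            pos = max(inside) + 5
            continue
        positions.append(pos)
    chroms = ["chr1"] * len(positions)

    planted_rows = []
    for r in design.planted_dmrs:
        span = r.end - r.start
        cpgs = r.start + np.round(
            (np.arange(r.n_cpgs) + 0.5) * span / r.n_cpgs
        ).astype(int)
        cpgs = np.unique(cpgs)
        if len(cpgs) < r.n_cpgs:
            raise ValueError(f"region {r.name} too short for {r.n_cpgs} CpGs")
        for p in cpgs:
            planted_rows.append((r.chrom, int(p), r))
    return list(zip(chroms, positions)), planted_rows


def generate_cohort(design: CohortDesign):
    """Simulate a cohort of :class:`MethylomeSample` plus a truth table.

    Returns ``(samples, truth)`` where ``truth`` is a dict with ``"dmcs"``
    (one row per planted CpG) and ``"dmrs"`` (one row per planted region).
    """
    rng = _rng(design.seed)
    background, planted = _place_cpgs(design, rng)

    site_rows = [(c, p, None) for c, p in background] + [
        (c, p, r) for c, p, r in planted
    ]
    site_rows.sort(key=lambda t: (t[0] != "chr1", t[0], t[1]))
    chroms = np.array([t[0] for t in site_rows])
    positions = np.array([t[1] for t in site_rows], dtype=np.int64)
    regions = [t[2] for t in site_rows]

    n_sites = len(site_rows)
    base = _baseline_betas(n_sites, design.hyper_weight, rng)
    # planted promoter DMRs sit at intermediate methylation (as real promoter
    # DMRs do), leaving headroom for the planted shift
    planted_mask = np.array([r is not None for r in regions])
    if planted_mask.any():
        base[planted_mask] = np.clip(
            rng.beta(10, 10, size=int(planted_mask.sum())), 0.2, 0.8
        )

    groups = list(design.n_per_group)
    group_means = {g: base.copy() for g in groups}
    clipped = False
    for j, r in enumerate(regions):
        if r is None:
            continue
        if r.group not in group_means:
            raise ValueError(f"planted group {r.group!r} not in design")
        shifted = base[j] + r.delta_beta
        if not 0.02 <= shifted <= 0.98:
            clipped = True
        group_means[r.group][j] = min(max(shifted, 0.02), 0.98)
    if clipped:
        logger.warning("planted deltas clipped to keep group means in [0.02, 0.98]")

    conc = design.dispersion
    samples = []
    for g in groups:
        m = group_means[g]
        for i in range(design.n_per_group[g]):
            depth = rng.poisson(design.mean_depth, size=n_sites)
            if design.missing_rate > 0:
                depth[rng.random(n_sites) < design.missing_rate] = 0
            p = rng.beta(m * conc, (1.0 - m) * conc)
            meth = rng.binomial(depth, p)
            calls = pd.DataFrame(
                {"chrom": chroms, "pos": positions, "meth": meth, "total": depth}
            )
            samples.append(
                MethylomeSample(sample_id=f"{g}_{i + 1:02d}", group=g, calls=calls)
            )

    dmc_rows = [
        {
            "chrom": chroms[j],
            "pos": int(positions[j]),
            "region": r.name,
            "group": r.group,
            "baseline_beta": float(base[j]),
            "delta_beta": r.delta_beta,
        }
        for j, r in enumerate(regions)
        if r is not None
    ]
    dmr_rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "name": r.name,
            "gene": r.gene,
            "n_cpgs": r.n_cpgs,
            "group": r.group,
            "delta_beta": r.delta_beta,
        }
        for r in design.planted_dmrs
    ]
    truth = {
        "dmcs": pd.DataFrame(
            dmc_rows,
            columns=["chrom", "pos", "region", "group", "baseline_beta", "delta_beta"],
        ),
        "dmrs": pd.DataFrame(
            dmr_rows,
            columns=["chrom", "start", "end", "name", "gene", "n_cpgs", "group", "delta_beta"],
        ),
    }
    return samples, truth


# ---------------------------------------------------------------------------
# fragment model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentModel:
    """Two-component cfDNA fragment-length mixture with nucleosome placement.

    Defaults put the mononucleosome peak at 170 bp and a minor
    dinucleosome peak at 330 bp; lengths are truncated to [100, 500] bp.
    """

    mono_len_mean: float = 170.0
    mono_len_sd: float = 10.0
    di_len_mean: float = 330.0
    di_len_sd: float = 15.0
    di_weight: float = 0.15
    nucleosome_spacing: int = 190
    positioning_jitter_sd: float = 20.0
    min_len: int = 100
    max_len: int = 500

    def __post_init__(self):
        if not 0.0 <= self.di_weight <= 1.0:
            raise ValueError("di_weight outside [0, 1]")

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        di = rng.random(n) < self.di_weight
        means = np.where(di, self.di_len_mean, self.mono_len_mean)
        sds = np.where(di, self.di_len_sd, self.mono_len_sd)
        a = (self.min_len - means) / sds
        b = (self.max_len - means) / sds
        q = rng.random(n)
        lengths = stats.truncnorm.ppf(q, a, b, loc=means, scale=sds)
        return np.round(lengths).astype(np.int64)


def _states_from_betas(
    starts: np.ndarray,
    ends: np.ndarray,
    chrom: str,
    cpg_index: CpGIndex,
    beta_at: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    """Draw per-CpG M/U states for each fragment from per-site betas."""
    pos = cpg_index.positions(chrom)
    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, ends)
    out = []
    for i in range(len(starts)):
        idx = np.arange(lo[i], hi[i])
        if len(idx) == 0:
            out.append("")
            continue
        b = beta_at[idx]
        draw = rng.random(len(idx))
        symbols = np.where(np.isnan(b), ".", np.where(draw < b, "M", "U"))
        out.append("".join(symbols))
    return out


def generate_fragments(
    sample: MethylomeSample,
    model: FragmentModel,
    regions: AnnotationSet,
    n_fragments: int,
    seed,
) -> pd.DataFrame:
    """Simulate nucleosome-positioned cfDNA fragments over target regions.

    Fragment centers sit at nucleosome dyads (one every
    ``model.nucleosome_spacing`` bp within each region) plus Gaussian
    jitter; methylation states are Bernoulli draws from the sample's beta
    at each covered CpG. Regions shorter than the maximum fragment length
    are skipped with a warning.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = _rng(seed)

    usable = [r for r in regions if len(r) >= model.max_len]
    skipped = len(regions) - len(usable)
    if skipped:
        logger.warning("%d regions shorter than %d bp skipped", skipped, model.max_len)
    if not usable:
        raise ValueError("no usable regions for fragment generation")

    weights = np.array([len(r) for r in usable], dtype=float)
    weights /= weights.sum()
    region_idx = rng.choice(len(usable), size=n_fragments, p=weights)

    calls = sample.calls
    index_by_chrom: dict[str, CpGIndex] = {}
    betas_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        index_by_chrom[chrom] = CpGIndex({chrom: sub["pos"].to_numpy()})
        betas_by_chrom[chrom] = sub["beta"].to_numpy()

    lengths = model.sample_lengths(n_fragments, rng)
    frames = []
    for ridx in np.unique(region_idx):
        r = usable[ridx]
        mask = region_idx == ridx
        n = int(mask.sum())
        n_dyads = max(1, len(r) // model.nucleosome_spacing)
        dyads = r.start + model.nucleosome_spacing // 2 + (
            rng.integers(0, n_dyads, size=n) * model.nucleosome_spacing
        )
        centers = dyads + np.round(
            rng.normal(0.0, model.positioning_jitter_sd, size=n)
        ).astype(np.int64)
        ln = lengths[mask]
        starts = centers - ln // 2
        ends = starts + ln
        idx = index_by_chrom.get(r.chrom, CpGIndex({}))
        beta_at = betas_by_chrom.get(r.chrom, np.empty(0))
        states = _states_from_betas(starts, ends, r.chrom, idx, beta_at, rng)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": r.chrom,
                    "start": starts,
                    "end": ends,
                    "cpg_states": states,
                    "sample_id": sample.sample_id,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# reference atlas
# ---------------------------------------------------------------------------

@dataclass
class ReferenceAtlas:
    """Cell-type x marker U-fraction matrix with a 7-category grouping."""

    cell_types: list
    markers: AnnotationSet
    u_fractions: pd.DataFrame  # cell types x marker names
    grouping: dict

    def __post_init__(self):
        if self.u_fractions.isna().any().any():
            raise ValueError("atlas U-fractions must have no missing entries")
        unmapped = set(self.cell_types) - set(self.grouping)
        if unmapped:
            raise ValueError(f"cell types without category: {sorted(unmapped)}")
        bad = set(self.grouping.values()) - set(TISSUE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown tissue categories: {sorted(bad)}")

    @property
    def marker_names(self) -> list:
        return list(self.u_fractions.columns)


def generate_atlas(
    n_cell_types: int = 7,
    n_markers_per_type: int = 25,
    u_high: float = 0.8,
    u_low: float = 0.05,
    n_samples_per_type: int = 3,
    n_fragments_per_marker: int = 120,
    model: FragmentModel = FragmentModel(),
    flip_error: float = 0.03,
    seed: int = 0,
):
    """Build a synthetic marker atlas plus per-cell-type fragment samples.

    Each cell type owns ``n_markers_per_type`` marker regions where its
    fragments are mostly unmethylated (expected U-fraction ``u_high``);
    at all other markers its U-fraction is ``u_low``. Fragments carry a
    molecule-level methylation haplotype (all-M or all-U with a small
    per-CpG read error), mirroring the bimodality that makes fragment-level
    deconvolution identifiable.

    Returns ``(atlas, cpg_index, fragments_by_type)`` where
    ``fragments_by_type[cell_type]`` is a list of per-sample fragment
    DataFrames.
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_markers_per_type < 1:
        raise ValueError("n_markers_per_type must be >= 1")
    if not u_high > u_low:
        raise ValueError(
            "u_high must exceed u_low, otherwise the deconvolution "
            "problem is unidentifiable"
        )
    rng = _rng(seed)

    cell_types = []
    grouping = {}
    for i in range(n_cell_types):
        base_name, category = DEFAULT_CELL_TYPES[i % len(DEFAULT_CELL_TYPES)]
        name = base_name if i < len(DEFAULT_CELL_TYPES) else f"{base_name}_{i}"
        cell_types.append(name)
        grouping[name] = category

    marker_len = 240
    marker_gap = 2000
    n_cpgs_per_marker = 6
    markers = AnnotationSet(kind="marker")
    cpg_positions = []
    owner = []
    offset = 10_000
    for t, ctype in enumerate(cell_types):
        for m in range(n_markers_per_type):
            start = offset
            offset += marker_len + marker_gap
            name = f"{ctype}.m{m + 1:02d}"
            markers.add(GenomicRegion("chr1", start, start + marker_len, name, "marker"))
            step = marker_len // (n_cpgs_per_marker + 1)
            cpg_positions.extend(start + step * (k + 1) for k in range(n_cpgs_per_marker))
            owner.append(ctype)
    cpg_index = CpGIndex({"chr1": cpg_positions})

    marker_names = [r.name for r in markers]
    u = np.full((n_cell_types, len(marker_names)), u_low)
    for j, own in enumerate(owner):
        u[cell_types.index(own), j] = u_high
    u_fractions = pd.DataFrame(u, index=cell_types, columns=marker_names)

    marker_list = list(markers)
    fragments_by_type = {}
    for ctype in cell_types:
        sample_frames = []
        for s in range(n_samples_per_type):
            frame = _atlas_sample_fragments(
                f"{ctype}_s{s + 1}",
                marker_list,
                u_fractions.loc[ctype].to_numpy(),
                cpg_index,
                n_fragments_per_marker,
                model,
                flip_error,
                rng,
            )
            sample_frames.append(frame)
        fragments_by_type[ctype] = sample_frames

    atlas = ReferenceAtlas(
        cell_types=cell_types,
        markers=markers,
        u_fractions=u_fractions,
        grouping=grouping,
    )
    return atlas, cpg_index, fragments_by_type


def _atlas_sample_fragments(
    sample_id: str,
    marker_list: list[GenomicRegion],
    u_row: np.ndarray,
    cpg_index: CpGIndex,
    n_per_marker: int,
    model: FragmentModel,
    flip_error: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_total = n_per_marker * len(marker_list)
    lengths = model.sample_lengths(n_total, rng)
    rows = {"start": [], "end": [], "cpg_states": []}
    k = 0
    pos_all = cpg_index.positions("chr1")
    for j, marker in enumerate(marker_list):
        center = (marker.start + marker.end) // 2
        ln = lengths[k : k + n_per_marker]
        centers = center + np.round(rng.normal(0, 15, size=n_per_marker)).astype(int)
        starts = centers - ln // 2
        ends = starts + ln
        unmeth = rng.random(n_per_marker) < u_row[j]
        lo = np.searchsorted(pos_all, starts)
        hi = np.searchsorted(pos_all, ends)
        flips = rng.random((n_per_marker, 12)) < flip_error
        for i in range(n_per_marker):
            n_cpg = hi[i] - lo[i]
            base = "U" if unmeth[i] else "M"
            other = "M" if unmeth[i] else "U"
            states = "".join(
                other if flips[i, c % 12] else base for c in range(n_cpg)
            )
            rows["cpg_states"].append(states)
        rows["start"].extend(starts)
        rows["end"].extend(ends)
        k += n_per_marker
    out = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.asarray(rows["start"]),
            "end": np.asarray(rows["end"]),
            "cpg_states": rows["cpg_states"],
            "sample_id": sample_id,
        }
    )
    return out.sort_values("start", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# spike-in mixtures
# ---------------------------------------------------------------------------

def spike_in_mixture(
    background_fragments: pd.DataFrame,
    target_fragments: pd.DataFrame,
    fraction: float,
    total_n: int,
    seed,
) -> pd.DataFrame:
    """Mix target into background fragments at an exact fraction.

    Draws ``round(fraction * total_n)`` target fragments and the remainder
    from background, both without replacement. The returned frame carries an
    ``origin`` column ("target"/"background") for truth checking.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    rng = _rng(seed)
    n_target = int(round(fraction * total_n))
    n_background = total_n - n_target
    if n_target > len(target_fragments):
        raise ValueError(
            f"target pool exhausted: need {n_target}, have {len(target_fragments)}"
        )
    if n_background > len(background_fragments):
        raise ValueError(
            f"background pool exhausted: need {n_background}, "
            f"have {len(background_fragments)}"
        )
    t_idx = rng.choice(len(target_fragments), size=n_target, replace=False)
    b_idx = rng.choice(len(background_fragments), size=n_background, replace=False)
    target = target_fragments.iloc[t_idx].copy()
    target["origin"] = "target"
    background = background_fragments.iloc[b_idx].copy()
    background["origin"] = "background"
    return pd.concat([background, target], ignore_index=True)


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalCoupling:
    """Target Spearman coupling between promoter methylation and clinical course."""

    gene: str
    rho_slope: float = 0.8
    rho_pnfh: float = 0.5
    noise: float = 1.0
    slope_log_mean: float = math.log(0.7)
    slope_log_sd: float = 0.6
    months_log_mean: float = math.log(12.0)
    months_log_sd: float = 0.4
    pnfh_log_median: float = math.log(2500.0)
    pnfh_log_sd: float = 0.5

    def __post_init__(self):
        for rho in (self.rho_slope, self.rho_pnfh):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("|rho| must be <= 1")
        if self.noise == 0 and (abs(self.rho_slope) not in (0.0, 1.0)):
            raise ValueError("|rho| < 1 requires noise > 0")


def _copula_latent(
    meth: np.ndarray, rho: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent normal rank-coupled to `meth`, calibrated to Spearman rho.

    The noise component is orthogonalized against the methylation normal
    scores in-sample, so the realized sample correlation concentrates on
    the target instead of wandering with the finite-sample noise draw.
    """
    n = len(meth)
    ranks = stats.rankdata(meth)
    z = stats.norm.ppf(ranks / (n + 1))
    z = (z - z.mean()) / z.std()
    # Pearson r giving Spearman rho for a bivariate Gaussian copula
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    eps = rng.standard_normal(n)
    eps = eps - (eps @ z) / (z @ z) * z
    sd = eps.std()
    if sd > 0:
        eps = eps / sd
    return r * z + noise * math.sqrt(max(0.0, 1.0 - r * r)) * eps


def generate_clinical(
    sample_ids: Sequence[str],
    groups: Sequence[str],
    promoter_methylation: pd.Series,
    coupling: ClinicalCoupling,
    seed,
    cohort_tag: str = "discovery",
) -> pd.DataFrame:
    """Generate sample-sheet rows with methylation-coupled clinical course.

    The ALS-FRS-R decline slope (points lost per month since symptom onset)
    is a monotone transform of a latent normal rank-coupled to the supplied
    promoter methylation; the score at draw and months since onset are then
    back-solved so that (48 - score) / months reproduces the slope exactly.
    CSF pNfH is log-normal, coupled analogously. Non-ALS rows (controls,
    presymptomatic carriers) get missing clinical values.
    """
    rng = _rng(seed)
    sample_ids = list(sample_ids)
    groups = list(groups)
    meth = promoter_methylation.reindex(sample_ids).to_numpy(dtype=float)
    is_als = np.array([g in ("sALS", "C9-ALS") for g in groups])

    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "alsfrs_r_at_draw": np.nan,
            "months_from_onset": np.nan,
            "pnfh_csf": np.nan,
            "cohort_tag": cohort_tag,
        }
    )
    idx = np.flatnonzero(is_als & ~np.isnan(meth))
    if len(idx) == 0:
        return sheet[SHEET_COLUMNS]

    z_slope = _copula_latent(meth[idx], coupling.rho_slope, coupling.noise, rng)
    slope = np.exp(coupling.slope_log_mean + coupling.slope_log_sd * z_slope)

    months = np.exp(
        coupling.months_log_mean
        + coupling.months_log_sd * rng.standard_normal(len(idx))
    )
    score = np.clip(np.round(48.0 - slope * months), 0, 48).astype(int)
    # keep the slope identity exact after integer rounding of the score
    months = np.where(slope > 0, (48.0 - score) / np.maximum(slope, 1e-12), months)

    z_pnfh = _copula_latent(meth[idx], coupling.rho_pnfh, coupling.noise, rng)
    pnfh = np.exp(coupling.pnfh_log_median + coupling.pnfh_log_sd * z_pnfh)

    if len(idx) >= 3 and len(np.unique(slope)) > 1:
        realized = stats.spearmanr(meth[idx], slope).statistic
        if abs(realized - coupling.rho_slope) > 0.35:
            logger.warning(
                "realized Spearman %.2f far from target %.2f at n=%d",
                realized, coupling.rho_slope, len(idx),
            )

    sheet.loc[sheet.index[idx], "alsfrs_r_at_draw"] = score
    sheet.loc[sheet.index[idx], "months_from_onset"] = months
    sheet.loc[sheet.index[idx], "pnfh_csf"] = pnfh
    return sheet[SHEET_COLUMNS]


# ---------------------------------------------------------------------------
# multimodal feature datasets (for classifier studies)
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_COUNTS = {"cgi_meth": 200, "dhs_meth": 200, "occupancy": 60, "wps": 60}


def generate_multimodal_dataset(
    n_per_group: Mapping[str, int] | None = None,
    n_features: Mapping[str, int] | None = None,
    n_informative: Mapping[str, int] | None = None,
    delta_beta: float = 0.15,
    shift_sd: float = 1.0,
    dispersion: float = 50.0,
    seed: int = 0,
    scheme_seed: Optional[int] = None,
):
    """Four aligned feature matrices with an optional planted group signal.

    Methylation modalities (cgi_meth, dhs_meth) are beta-distributed around
    feature-specific baselines, with case-group means shifted by
    ``delta_beta`` (random sign) in the informative features. Fragmentomic
    modalities (occupancy, wps) are Gaussian with case shifts of
    ``shift_sd`` standard deviations. Returns ``(matrices, labels, truth)``
    with ``matrices`` a dict of :class:`FeatureMatrix`.

    ``scheme_seed`` fixes the feature scheme (baselines and shift signs)
    independently of the sampling noise, so two cohorts drawn with the same
    scheme but different ``seed`` come from the same generative process.
    """
    n_per_group = dict(n_per_group or DEFAULT_N_PER_GROUP)
    n_features = dict(DEFAULT_FEATURE_COUNTS, **(n_features or {}))
    n_informative = {m: 0 for m in n_features} | dict(n_informative or {})
    rng = _rng(seed)
    scheme_rng = np.random.default_rng(seed if scheme_seed is None else scheme_seed)

    sample_ids, labels = [], []
    for g, n in n_per_group.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1:02d}")
            labels.append(g)
    labels = pd.Series(labels, index=sample_ids, name="group")
    case_group = [g for g in n_per_group if g != "control"][0]
    is_case = (labels == case_group).to_numpy()
    n_samples = len(sample_ids)

    matrices = {}
    truth = {}
    for modality, p in n_features.items():
        k = n_informative[modality]
        if k > p:
            raise ValueError(f"{modality}: n_informative > n_features")
        informative = np.arange(k)  # leading features carry the signal
        if modality in ("cgi_meth", "dhs_meth"):
            base = scheme_rng.uniform(0.25, 0.75, size=p)
            sign = scheme_rng.choice([-1.0, 1.0], size=p)
            mean = np.tile(base, (n_samples, 1))
            mean[np.ix_(is_case, informative)] += (
                sign[informative] * delta_beta
            )
            mean = np.clip(mean, 0.02, 0.98)
            values = rng.beta(mean * dispersion, (1 - mean) * dispersion)
        else:
            center = 1.0 if modality == "occupancy" else 0.0
            scale = 0.2 if modality == "occupancy" else 1.0
            sign = scheme_rng.choice([-1.0, 1.0], size=p)
            mean = np.full((n_samples, p), center)
            mean[np.ix_(is_case, informative)] += (
                sign[informative] * shift_sd * scale
            )
            values = rng.normal(mean, scale)
        cols = [f"{modality}_f{j + 1:04d}" for j in range(p)]
        matrices[modality] = FeatureMatrix(
            modality=modality,
            values=pd.DataFrame(values, index=sample_ids, columns=cols),
        )
        truth[modality] = [cols[j] for j in informative]
    return matrices, labels, truth
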