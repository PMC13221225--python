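"""Fragment-level tissue-of-origin deconvolution.

Each cfDNA fragment with at least ``min_cpgs`` observed CpGs is classified
as mostly Unmethylated (U), miXed (X), or mostly Methylated (M) by its
methylated fraction. Per-marker U-fractions — U / (U + X + M) among
informative fragments — form the sample vector b, which is decomposed
over a cell-type reference atlas A by nonnegative least squares and
normalized to proportions. Cell-type proportions are then summed into
seven broad tissue categories.

The leave-one-out spike-in simulation validates recovery: a held-out
target-cell-type sample is mixed into background fragments at known
fractions, the reference is rebuilt without that sample, and the estimated
target proportion is compared with the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .regions import AnnotationSet
from .simulate import ReferenceAtlas

logger = logging.getLogger(__name__)

MIN_CPGS = 3
U_MAX = 0.25
M_MIN = 0.75

LABELS = ("U", "X", "M", "uninformative")


def classify_fragment(
    fragment, min_cpgs: int = MIN_CPGS, u_max: float = U_MAX, m_min: float = M_MIN
) -> str:
    """U/X/M label for one fragment (or a raw state string)."""
    states = fragment.cpg_states if hasattr(fragment, "cpg_states") else fragment
    k = sum(1 for s in states if s != ".")
    if k < min_cpgs:
        return "uninformative"
    f = sum(1 for s in states if s == "M") / k
    if f <= u_max:
        return "U"
    if f >= m_min:
        return "M"
    return "X"


def classify_fragments(
    fragments: pd.DataFrame,
    min_cpgs: int = MIN_CPGS,
    u_max: float = U_MAX,
    m_min: float = M_MIN,
) -> np.ndarray:
    """Vectorized U/X/M labels (int codes into :data:`LABELS`)."""
    states = fragments["cpg_states"].to_numpy()
    k = np.array([len(s) - s.count(".") for s in states])
    m = np.array([s.count("M") for s in states])
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(k > 0, m / np.maximum(k, 1), np.nan)
    codes = np.full(len(states), 3, dtype=np.int8)  # uninformative
    informative = k >= min_cpgs
    codes[informative & (f <= u_max)] = 0
    codes[informative & (f >= m_min)] = 2
    codes[informative & (f > u_max) & (f < m_min)] = 1
    return codes


def assign_markers(fragments: pd.DataFrame, markers: AnnotationSet) -> list:
    """Marker name lists per fragment (>= 1 bp overlap; possibly several)."""
    out = []
    for row in fragments.itertuples(index=False):
        hits = markers.query(row.chrom, row.start, row.end)
        out.append([h.name for h in hits])
    return out


def compute_u_fractions(
    fragments: pd.DataFrame,
    markers: AnnotationSet,
    min_cpgs: int = MIN_CPGS,
    u_max: float = U_MAX,
    m_min: float = M_MIN,
) -> pd.Series:
    """Per-marker U / (U + X + M) among informative fragments; NaN if none.

    A fragment overlapping several markers is counted in each.
    """
    marker_names = [r.name for r in markers]
    codes = classify_fragments(fragments, min_cpgs, u_max, m_min)
    u_counts = dict.fromkeys(marker_names, 0)
    inf_counts = dict.fromkeys(marker_names, 0)
    for code, names in zip(codes, assign_markers(fragments, markers)):
        if code == 3:
            continue
        for name in names:
            inf_counts[name] += 1
            if code == 0:
                u_counts[name] += 1
    frac = {
        name: (u_counts[name] / inf_counts[name]) if inf_counts[name] else np.nan
        for name in marker_names
    }
    return pd.Series(frac, name="u_fraction")


def build_reference(
    fragments_by_type: Mapping[str, Sequence[pd.DataFrame]],
    markers: AnnotationSet,
    grouping: Mapping[str, str],
    **classify_kwargs,
) -> ReferenceAtlas:
    """Mean per-type U-fraction atlas from per-sample fragment sets.

    Markers with a missing U-fraction in any cell type are dropped (logged).
    """
    rows = {}
    for ctype, sample_frames in fragments_by_type.items():
        if len(sample_frames) == 0:
            raise ValueError(f"cell type {ctype!r} has no samples")
        vectors = [
            compute_u_fractions(frags, markers, **classify_kwargs)
            for frags in sample_frames
        ]
        mean_vec = pd.concat(vectors, axis=1).mean(axis=1)
        if mean_vec.isna().all():
            raise ValueError(
                f"cell type {ctype!r} has no informative fragments at any marker"
            )
        rows[ctype] = mean_vec
    u = pd.DataFrame(rows).T
    bad = u.columns[u.isna().any(axis=0)]
    if len(bad):
        logger.warning("dropping %d markers with missing U-fractions", len(bad))
        u = u.drop(columns=bad)
    kept = set(u.columns)
    marker_set = AnnotationSet(
        kind="marker", regions=[r for r in markers if r.name in kept]
    )
    return ReferenceAtlas(
        cell_types=list(u.index),
        markers=marker_set,
        u_fractions=u,
        grouping=dict(grouping),
    )


@dataclass
class DeconvolutionResult:
    """Normalized cell-type proportions for one sample."""

    sample_id: str
    proportions: pd.Series  # per cell type, >= 0, sums to 1
    category_proportions: pd.Series
    markers_used: int
    residual: float

    def __post_init__(self):
        if (self.proportions < -1e-12).any():
            raise ValueError("negative proportions")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions do not sum to 1")


class UXMDeconvolver:
    """Nonnegative least-squares mixture solver over a reference atlas.

    Parameters follow scikit-learn conventions: construct with the atlas,
    call :meth:`fit` (validates the reference), then :meth:`transform` with
    per-marker U-fraction vectors (or fragment DataFrames via
    :meth:`deconvolute_fragments`).
    """

    def __init__(self, atlas: ReferenceAtlas):
        self.atlas = atlas

    def fit(self, X=None, y=None) -> "UXMDeconvolver":
        u = self.atlas.u_fractions
        self.matrix_ = u.to_numpy(dtype=float).T  # markers x cell types
        self.marker_names_ = list(u.columns)
        self.cell_types_ = list(u.index)
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"atlas": self.atlas}

    def set_params(self, **params) -> "UXMDeconvolver":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def deconvolute(self, b: pd.Series, sample_id: str = "sample") -> DeconvolutionResult:
        """Solve min ||A x - b||_2, x >= 0, then normalize x to proportions.

        Markers with missing U-fraction in ``b`` are dropped from both sides;
        at least as many markers as cell types must remain, and the retained
        reference must be full rank.
        """
        if not hasattr(self, "matrix_"):
            self.fit()
        b = b.reindex(self.marker_names_)
        keep = ~b.isna().to_numpy()
        A = self.matrix_[keep]
        if A.shape[0] < len(self.cell_types_):
            raise ValueError(
                f"only {A.shape[0]} usable markers for {len(self.cell_types_)} cell types"
            )
        if np.linalg.matrix_rank(A) < len(self.cell_types_):
            degenerate = _degenerate_types(A, self.cell_types_)
            raise ValueError(
                f"reference rank-deficient after marker dropping; "
                f"degenerate cell types: {degenerate}"
            )
        x, residual = nnls(A, b.to_numpy(dtype=float)[keep])
        total = x.sum()
        if total <= 0:
            raise ValueError("all-zero NNLS solution")
        props = pd.Series(x / total, index=self.cell_types_, name=sample_id)
        cats = props.groupby(self.atlas.grouping).sum()
        return DeconvolutionResult(
            sample_id=sample_id,
            proportions=props,
            category_proportions=cats,
            markers_used=int(keep.sum()),
            residual=float(residual),
        )

    def deconvolute_fragments(
        self, fragments: pd.DataFrame, sample_id: str = "sample", **classify_kwargs
    ) -> DeconvolutionResult:
        b = compute_u_fractions(fragments, self.atlas.markers, **classify_kwargs)
        return self.deconvolute(b, sample_id=sample_id)


def _degenerate_types(A: np.ndarray, cell_types: Sequence[str]) -> list:
    """Cell types whose reference columns are linearly dependent."""
    degenerate = []
    for j in range(A.shape[1]):
        others = np.delete(A, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(A):
            degenerate.append(cell_types[j])
    return degenerate


def deconvolute(b: pd.Series, atlas: ReferenceAtlas, sample_id: str = "sample") -> DeconvolutionResult:
    """Functional wrapper over :class:`UXMDeconvolver`."""
    return UXMDeconvolver(atlas).fit().deconvolute(b, sample_id=sample_id)


# ---------------------------------------------------------------------------
# leave-one-out spike-in simulation
# ---------------------------------------------------------------------------

def _precompute_marker_profile(
    fragments: pd.DataFrame, markers: AnnotationSet, **classify_kwargs
):
    """(fragment idx, marker idx, is_U, n_markers, pool size) for resampling."""
    marker_names = [r.name for r in markers]
    name_to_idx = {n: i for i, n in enumerate(marker_names)}
    codes = classify_fragments(fragments, **classify_kwargs)
    assignments = assign_markers(fragments, markers)
    frag_idx, marker_idx, is_u = [], [], []
    for i, (code, names) in enumerate(zip(codes, assignments)):
        if code == 3:
            continue
        for name in names:
            frag_idx.append(i)
            marker_idx.append(name_to_idx[name])
            is_u.append(code == 0)
    return (
        np.asarray(frag_idx, dtype=np.int64),
        np.asarray(marker_idx, dtype=np.int64),
        np.asarray(is_u, dtype=bool),
        len(marker_names),
        len(fragments),
    )


def _subset_counts(profile, subset: np.ndarray):
    """(informative count, U count) per marker for a fragment subset."""
    frag_idx, marker_idx, is_u, n_markers, n_frags = profile
    chosen = np.zeros(n_frags, dtype=bool)
    chosen[subset] = True
    mask = chosen[frag_idx] if len(frag_idx) else np.zeros(0, dtype=bool)
    inf = np.bincount(marker_idx[mask], minlength=n_markers).astype(float)
    u = np.bincount(marker_idx[mask & is_u], minlength=n_markers).astype(float)
    return inf, u


def run_mixture_simulation(
    fragments_by_type: Mapping[str, Sequence[pd.DataFrame]],
    markers: AnnotationSet,
    grouping: Mapping[str, str],
    target_type: str,
    background_fragments: pd.DataFrame,
    fractions: Sequence[float] = (0.0, 0.025, 0.05, 0.075, 0.10),
    n_reps: int = 50,
    total_n: int = 20_000,
    seed: int = 0,
    **classify_kwargs,
) -> pd.DataFrame:
    """Leave-one-out in-silico spike-in validation of deconvolution.

    For each replicate: hold out one target-type sample (cycled), rebuild
    the reference atlas without it, spike its fragments into the background
    at the given fraction, deconvolute the mixture, and record the estimated
    target-type proportion. Returns the per-replicate recovery table.
    """
    target_samples = fragments_by_type.get(target_type, [])
    if len(target_samples) < 2:
        raise ValueError(
            f"need >= 2 samples of {target_type!r} for leave-one-out rebuilding"
        )
    rng = np.random.default_rng(seed)
    marker_names = [r.name for r in markers]

    # per-sample U-fraction vectors, computed once and reused for every
    # leave-one-out reference rebuild
    vectors_by_type = {
        t: [compute_u_fractions(f, markers, **classify_kwargs) for f in frames]
        for t, frames in fragments_by_type.items()
    }

    atlases = []
    for held_out in range(len(target_samples)):
        rows_u = {}
        for t, vectors in vectors_by_type.items():
            kept = [
                v for i, v in enumerate(vectors)
                if not (t == target_type and i == held_out)
            ]
            rows_u[t] = pd.concat(kept, axis=1).mean(axis=1)
        u = pd.DataFrame(rows_u).T
        u = u.drop(columns=u.columns[u.isna().any(axis=0)])
        kept_names = set(u.columns)
        atlases.append(
            ReferenceAtlas(
                cell_types=list(u.index),
                markers=AnnotationSet(
                    kind="marker", regions=[r for r in markers if r.name in kept_names]
                ),
                u_fractions=u,
                grouping=dict(grouping),
            )
        )

    bg_profile = _precompute_marker_profile(background_fragments, markers, **classify_kwargs)
    target_profiles = [
        _precompute_marker_profile(f, markers, **classify_kwargs)
        for f in target_samples
    ]

    rows = []
    for fraction in fractions:
        n_target = int(round(fraction * total_n))
        n_background = total_n - n_target
        if n_background > len(background_fragments):
            raise ValueError("background pool exhausted")
        for rep in range(n_reps):
            held_out = rep % len(target_samples)
            tgt_frags = target_samples[held_out]
            if n_target > len(tgt_frags):
                raise ValueError("target pool exhausted")
            t_subset = rng.choice(len(tgt_frags), size=n_target, replace=False)
            b_subset = rng.choice(
                len(background_fragments), size=n_background, replace=False
            )
            inf_t, u_t = _subset_counts(target_profiles[held_out], t_subset)
            inf_b, u_b = _subset_counts(bg_profile, b_subset)
            inf, u = inf_t + inf_b, u_t + u_b
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(inf > 0, u / np.maximum(inf, 1), np.nan)
            b_mix = pd.Series(frac, index=marker_names)
            result = UXMDeconvolver(atlases[held_out]).fit().deconvolute(
                b_mix, sample_id=f"mix_f{fraction}_r{rep}"
            )
            rows.append(
                {
                    "fraction": fraction,
                    "rep": rep,
                    "held_out": held_out,
                    "estimated": float(result.proportions[target_type]),
                    "estimated_category": float(
                        result.category_proportions[grouping[target_type]]
                    ),
                }
            )
    return pd.DataFrame(rows)


def summarize_mixture_simulation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd of the estimated fraction at each true fraction."""
    return (
        table.groupby("fraction")["estimated"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
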