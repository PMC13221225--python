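"""Readers and writers for every on-disk artifact of the pipeline.

Formats (all plain text, tab separated, 0-based half-open coordinates):

* methylation calls — MethylDackel-style bedGraph:
  ``chrom  start  end  percent  meth  unmeth`` (``dialect="percent"``),
  or the same with a beta in [0,1] in column 4 (``dialect="beta"``);
* fragments — PAT-like TSV in genomic coordinates:
  ``chrom  start  end  states  sample_id`` with states over {M, U, .};
* regions — BED3+name (optional 5th column: gene symbol);
* feature matrices — TSV, samples x features, ``NA`` for missing, with a
  ``#modality: <tag>`` header comment;
* sample sheets — TSV with group labels and optional clinical covariates.

Readers validate rather than coerce: malformed rows raise ``ParseError``
naming the offending line, impossible counts raise ``ValidationError``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import (
    AnnotationSet,
    CpGIndex,
    GenomicRegion,
    chrom_sort_key,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

GROUPS = ("sALS", "C9-ALS", "C9-carrier", "control")

FRAGMENT_MIN_LEN = 50
FRAGMENT_MAX_LEN = 1000

CALL_COLUMNS = ["chrom", "pos", "meth", "total", "beta"]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "cpg_states", "sample_id"]


class ParseError(ValueError):
    """A row could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """Parsed content violates an invariant of the format."""


@dataclass(frozen=True)
class CpGCall:
    """One CpG cytosine's methylation evidence in one sample."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self):
        if self.meth_reads < 0 or self.total_reads < 0:
            raise ValidationError("negative read counts")
        if self.meth_reads > self.total_reads:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: meth {self.meth_reads} > "
                f"total {self.total_reads}"
            )

    @property
    def beta(self) -> float:
        """Methylated fraction; NaN when the site is uncovered."""
        if self.total_reads == 0:
            return float("nan")
        return self.meth_reads / self.total_reads


@dataclass
class MethylomeSample:
    """One participant's ordered CpG calls.

    ``calls`` is a DataFrame with columns chrom, pos, meth, total, beta,
    sorted by (chrom, pos) and free of duplicate sites.
    """

    sample_id: str
    group: str
    calls: pd.DataFrame

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"group {self.group!r} not in {sorted(GROUPS)}"
            )
        self.calls = _validate_calls(self.calls)

    @property
    def mean_depth(self) -> float:
        if len(self.calls) == 0:
            return float("nan")
        return float(self.calls["total"].mean())

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    calls = calls.copy()
    missing = [c for c in ("chrom", "pos", "meth", "total") if c not in calls]
    if missing:
        raise ValidationError(f"calls missing columns {missing}")
    if (calls["meth"] > calls["total"]).any():
        bad = calls.index[calls["meth"] > calls["total"]][0]
        raise ValidationError(f"meth > total at row {bad}")
    calls["chrom"] = calls["chrom"].map(normalize_chrom)
    order = calls["chrom"].map(chrom_sort_key)
    if not (order.is_monotonic_increasing and calls.groupby("chrom", sort=False)["pos"].apply(
        lambda s: s.is_monotonic_increasing
    ).all()):
        logger.warning("methylation calls not sorted; sorting")
        calls = calls.sort_values(
            ["pos"], kind="mergesort"
        ).sort_values("chrom", key=lambda s: s.map(chrom_sort_key), kind="mergesort")
    if calls.duplicated(["chrom", "pos"]).any():
        raise ValidationError("duplicate (chrom, pos) in calls")
    with np.errstate(invalid="ignore", divide="ignore"):
        calls["beta"] = np.where(
            calls["total"] > 0, calls["meth"] / calls["total"], np.nan
        )
    return calls.reset_index(drop=True)[CALL_COLUMNS]


@dataclass(frozen=True)
class FragmentRecord:
    """A cfDNA fragment with per-CpG methylation states in genomic order."""

    chrom: str
    start: int
    end: int
    cpg_states: str
    sample_id: str

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        length = self.end - self.start
        if not FRAGMENT_MIN_LEN <= length <= FRAGMENT_MAX_LEN:
            raise ValidationError(
                f"fragment length {length} outside "
                f"[{FRAGMENT_MIN_LEN}, {FRAGMENT_MAX_LEN}]"
            )
        if set(self.cpg_states) - set("MU."):
            raise ValidationError(
                f"states {self.cpg_states!r} not over alphabet {{M, U, .}}"
            )


# ---------------------------------------------------------------------------
# methylation calls (bedGraph dialects)
# ---------------------------------------------------------------------------

def read_methylation_calls(
    path,
    dialect: str = "percent",
    sample_id: Optional[str] = None,
    group: str = "control",
) -> MethylomeSample:
    """Read a per-CpG methylation call file into a :class:`MethylomeSample`.

    ``dialect="percent"`` expects column 4 in 0-100 (MethylDackel bedGraph);
    ``dialect="beta"`` expects it in [0, 1]. The value column is only used
    for cross-checking — betas are always recomputed from the counts.
    """
    if dialect not in ("percent", "beta"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
                meth, unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end != start + 1:
                raise ParseError(
                    f"{path}:{lineno}: CpG rows must have end = start + 1"
                )
            scale = 100.0 if dialect == "percent" else 1.0
            total = meth + unmeth
            if total > 0 and abs(value / scale - meth / total) > 1e-6:
                raise ValidationError(
                    f"{path}:{lineno}: value column inconsistent with counts"
                )
            rows.append((chrom, start, meth, total))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    if sample_id is None:
        sample_id = str(path)
    return MethylomeSample(sample_id=sample_id, group=group, calls=calls)


def write_methylation_calls(
    sample: MethylomeSample, path, dialect: str = "percent"
) -> None:
    scale = 100.0 if dialect == "percent" else 1.0
    with open(path, "w") as fh:
        for row in sample.calls.itertuples(index=False):
            total = int(row.total)
            meth = int(row.meth)
            value = scale * meth / total if total else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{value:g}"
                f"\t{meth}\t{total - meth}\n"
            )


# ---------------------------------------------------------------------------
# fragments (PAT-like genomic-coordinate TSV)
# ---------------------------------------------------------------------------

def read_fragment_records(
    path, cpg_index: Optional[CpGIndex] = None
) -> pd.DataFrame:
    """Read fragments into a DataFrame (chrom, start, end, cpg_states, sample_id).

    When ``cpg_index`` is given, each record's state-string length is checked
    against the number of reference CpGs it overlaps.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                chrom, start, end, states, sid = (
                    fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            # constructor enforces alphabet and length bounds
            FragmentRecord(chrom, start, end, states, sid)
            rows.append((normalize_chrom(chrom), start, end, states, sid))
    frags = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if cpg_index is not None:
        validate_fragments(frags, cpg_index)
    return frags


def validate_fragments(fragments: pd.DataFrame, cpg_index: CpGIndex) -> None:
    """Check every state string against the reference CpG index."""
    for row in fragments.itertuples(index=True):
        expected = cpg_index.count_in(row.chrom, row.start, row.end)
        if len(row.cpg_states) != expected:
            raise ValidationError(
                f"fragment {row.chrom}:{row.start}-{row.end} ({row.sample_id}): "
                f"{len(row.cpg_states)} states but {expected} reference CpGs"
            )


def write_fragment_records(fragments: pd.DataFrame, path) -> None:
    fragments.to_csv(
        path, sep="\t", header=False, index=False,
        columns=FRAGMENT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def read_bed_regions(path, kind: str) -> AnnotationSet:
    """Read a BED3+ file as an :class:`AnnotationSet` of one region kind."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else f"{kind}_{lineno}"
            gene = fields[4] if len(fields) > 4 else None
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            regions.append(GenomicRegion(chrom, start, end, name, kind, gene))
    return AnnotationSet(kind=kind, regions=regions)


def write_bed_regions(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for r in annotation:
            gene = f"\t{r.gene}" if r.gene is not None else ""
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}{gene}\n")


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

MODALITIES = ("cgi_meth", "dhs_meth", "occupancy", "wps")


@dataclass
class FeatureMatrix:
    """Samples x features values for one modality; missing cells are NaN."""

    modality: str
    values: pd.DataFrame

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample ids")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#modality: {matrix.modality}\n")
        matrix.values.to_csv(
            fh, sep="\t", na_rep="NA", index_label="sample_id",
            float_format="%.17g",
        )


def read_feature_matrix(path) -> FeatureMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#modality:"):
            raise ParseError(f"{path}: missing '#modality:' header comment")
        modality = first.split(":", 1)[1].strip()
        values = pd.read_csv(
            fh, sep="\t", index_col="sample_id", na_values=["NA"],
            float_precision="round_trip",
        )
    if values.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate feature ids")
    return FeatureMatrix(modality=modality, values=values)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = [
    "sample_id", "group", "alsfrs_r_at_draw", "months_from_onset",
    "pnfh_csf", "cohort_tag",
]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet; sample_ids must be unique, groups valid."""
    sheet = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in ("sample_id", "group") if c not in sheet]
    if missing:
        raise ValidationError(f"sample sheet missing columns {missing}")
    for col in SHEET_COLUMNS:
        if col not in sheet:
            sheet[col] = np.nan
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    bad = set(sheet["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}")
    score = sheet["alsfrs_r_at_draw"].dropna()
    if ((score < 0) | (score > 48)).any():
        raise ValidationError("ALS-FRS-R outside [0, 48]")
    months = sheet["months_from_onset"].dropna()
    if (months <= 0).any():
        raise ValidationError("months_from_onset must be positive")
    return sheet[SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", na_rep="NA", index=False, columns=SHEET_COLUMNS)


# ---------------------------------------------------------------------------
# cohort helpers
# ---------------------------------------------------------------------------

def beta_matrix(samples: Sequence[MethylomeSample]) -> pd.DataFrame:
    """Stack samples into a (samples x CpG sites) beta-value matrix.

    Columns are a MultiIndex of (chrom, pos) in genome order; sites missing
    in a sample are NaN.
    """
    series = {}
    for s in samples:
        series[s.sample_id] = s.calls.set_index(["chrom", "pos"])["beta"]
    mat = pd.DataFrame(series).T
    cols = sorted(mat.columns, key=lambda cp: (chrom_sort_key(cp[0]), cp[1]))
    mat = mat[cols]
    mat.columns = pd.MultiIndex.from_tuples(cols, names=["chrom", "pos"])
    mat.index.name = "sample_id"
    return mat
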