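"""Enhancer activity matrices: construction, normalization, imputation.

Activity is H3K27Ac ChIP-seq coverage summarized over unified enhancer
regions.  The processing chain is raw counts (per sample) -> aggregated (per
cell line) -> RLE-normalized (median-of-ratios size factors computed over the
genome-wide enhancer set) -> zero-imputed -> log2, with a mask of the
pre-imputation zeros carried along so they can be excluded from global model
fits downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import CEtoSEMap, UnifiedRegion

logger = logging.getLogger(__name__)

STAGES = ("raw", "aggregated", "normalized", "imputed", "log2")

__all__ = [
    "ActivityMatrix",
    "SampleSheet",
    "summarize_coverage",
    "aggregate_replicates",
    "rle_normalize",
    "impute_zeros",
    "log2_transform",
    "se_contribution_filter",
    "per_kb_activity",
    "read_bedgraph",
]


class SampleSheet:
    """Sample -> cell line -> cancer type design table.

    Replicate structure is implied: samples sharing a cell line are
    replicates.  Every sample_id must be unique and every cell line must map
    to exactly one cancer type.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"sample_id", "cell_line", "cancer_type"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        df = df.loc[:, ["sample_id", "cell_line", "cancer_type"]].copy()
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        per_cell = df.groupby("cell_line")["cancer_type"].nunique()
        bad = per_cell[per_cell > 1]
        if len(bad):
            raise ValueError(
                f"cell lines with >1 cancer type: {bad.index.tolist()}")
        self.df = df

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.df["cell_line"]))

    @property
    def cancer_types(self) -> list[str]:
        return list(dict.fromkeys(self.df["cancer_type"]))

    def sample_to_cell(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["cell_line"]))

    def cell_to_cancer(self) -> dict[str, str]:
        return dict(zip(self.df["cell_line"], self.df["cancer_type"]))

    def cells_of_cancer(self, cancer: str) -> list[str]:
        sub = self.df[self.df["cancer_type"] == cancer]
        return list(dict.fromkeys(sub["cell_line"]))


@dataclass
class ActivityMatrix:
    """Regions x columns activity with processing-stage bookkeeping.

    ``values`` rows are region uids, columns sample or cell-line ids.
    ``zero_mask`` marks pre-imputation zeros (set at imputation); it shares
    the frame's shape.  ``size_factors`` are per-column positive scalars,
    present from the normalized stage onward.
    """

    values: pd.DataFrame
    stage: str = "raw"
    zero_mask: pd.DataFrame | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage != "log2" and (self.values.values < 0).any():
            raise ValueError(f"negative values in {self.stage} matrix")
        if self.stage in ("imputed",) and (self.values.values <= 0).any():
            raise ValueError("imputed matrix must be strictly positive")
        if self.zero_mask is not None and self.zero_mask.shape != self.values.shape:
            raise ValueError("zero_mask shape mismatch")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def regions(self) -> pd.Index:
        return self.values.index

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="region_id")

    @classmethod
    def from_tsv(cls, path, stage: str = "raw") -> "ActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        return cls(df.astype(float), stage=stage)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph coverage track (chrom, start, end, depth)."""
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end", "value"],
                       dtype={0: str, 1: int, 2: int, 3: float})


def _track_coverage(track: pd.DataFrame, region: UnifiedRegion) -> float:
    sub = track[track["chrom"] == region.chrom]
    if sub.empty:
        return 0.0
    overlap = (np.minimum(sub["end"].to_numpy(), region.end)
               - np.maximum(sub["start"].to_numpy(), region.start))
    overlap = np.clip(overlap, 0, None)
    return float((overlap * sub["value"].to_numpy()).sum())


def summarize_coverage(
    regions: Sequence[UnifiedRegion],
    tracks: Mapping[str, pd.DataFrame],
) -> ActivityMatrix:
    """Total per-base coverage of each track within each unified region.

    ``tracks`` maps sample id to a bedGraph frame (:func:`read_bedgraph`).
    A region on a chromosome absent from a track contributes 0 with a
    logged warning.
    """
    uids = [r.uid or f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    data = np.zeros((len(regions), len(tracks)))
    for j, (sample, track) in enumerate(tracks.items()):
        chroms = set(track["chrom"])
        for i, region in enumerate(regions):
            if region.chrom not in chroms:
                logger.warning("chromosome %s absent from track %s; 0 assigned",
                               region.chrom, sample)
                continue
            data[i, j] = _track_coverage(track, region)
    return ActivityMatrix(
        pd.DataFrame(data, index=uids, columns=list(tracks)), stage="raw")


def aggregate_replicates(
    m: ActivityMatrix, sheet: SampleSheet, how: str = "sum"
) -> ActivityMatrix:
    """Collapse replicate sample columns into one column per cell line.

    ``how`` is ``sum`` (default — preserves count semantics for the
    downstream median-of-ratios normalization) or ``mean``.
    """
    if m.stage != "raw":
        raise ValueError(f"expected raw matrix, got {m.stage}")
    mapping = sheet.sample_to_cell()
    unknown = [c for c in m.columns if c not in mapping]
    if unknown:
        raise ValueError(f"matrix columns absent from sample sheet: {unknown}")
    grouped = m.values.T.groupby([mapping[c] for c in m.columns], sort=False)
    agg = grouped.sum().T if how == "sum" else grouped.mean().T
    # stable, sheet-defined cell line order
    agg = agg.loc[:, [c for c in sheet.cell_lines if c in agg.columns]]
    return ActivityMatrix(agg, stage="aggregated")


def rle_normalize(m: ActivityMatrix) -> ActivityMatrix:
    """Median-of-ratios (RLE) depth normalization.

    For each all-positive row the geometric mean across columns is a
    pseudo-reference; a column's size factor is the median of its ratios to
    that reference, and every value (including zeros and zero-containing
    rows) is divided by its column's size factor.  Rows containing a zero are
    excluded from the size-factor computation only.  Scaling the columns by
    per-column depths changes the size factors proportionally and the
    normalized matrix only by a common constant (the geometric mean of the
    depths), so all cross-column comparisons are depth-free.
    """
    if m.stage not in ("raw", "aggregated"):
        raise ValueError(f"expected count-stage matrix, got {m.stage}")
    vals = m.values.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no all-positive row; size factors undefined")
    ref = vals[positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    size_factors = np.median(ref / geomean[:, None], axis=0)
    normalized = m.values / size_factors
    return ActivityMatrix(
        normalized, stage="normalized",
        size_factors=pd.Series(size_factors, index=m.columns,
                               name="size_factor"))


def impute_zeros(m: ActivityMatrix) -> ActivityMatrix:
    """Replace zeros with half the column's minimum positive value.

    The pre-imputation zero positions are recorded in ``zero_mask`` so
    downstream global model fits can exclude them.  A column with no
    positive value is rejected (no minimum exists).
    """
    if m.stage != "normalized":
        raise ValueError(f"expected normalized matrix, got {m.stage}")
    vals = m.values.copy()
    zero_mask = vals == 0
    for col in vals.columns:
        column = vals[col]
        positives = column[column > 0]
        if positives.empty:
            raise ValueError(f"column {col!r} is entirely zero; cannot impute")
        if zero_mask[col].any():
            vals.loc[zero_mask[col], col] = 0.5 * positives.min()
    return ActivityMatrix(vals, stage="imputed", zero_mask=zero_mask,
                          size_factors=m.size_factors)


def log2_transform(m: ActivityMatrix) -> ActivityMatrix:
    """log2 of an imputed (strictly positive) matrix; no pseudocount."""
    if m.stage != "imputed":
        raise ValueError(f"expected imputed matrix, got {m.stage}")
    return ActivityMatrix(np.log2(m.values), stage="log2",
                          zero_mask=m.zero_mask, size_factors=m.size_factors)


def se_contribution_filter(
    ce_matrix: ActivityMatrix,
    ce_to_se: CEtoSEMap,
    threshold: float = 0.03,
) -> tuple[pd.DataFrame, list[str]]:
    """Flag CE occurrences contributing more than ``threshold`` of SE activity.

    The SE total in a cell line is the sum of its member CEs' activities
    there.  Returns the boolean pass mask (CE x cell line; strictly greater
    than the threshold; False wherever the SE total is 0) and the list of
    CEs passing in at least one cell line.
    """
    unmapped = [ce for ce in ce_matrix.regions if ce_to_se.se_of(ce) is None]
    if unmapped:
        raise ValueError(f"CE rows without SE assignment: {unmapped[:5]}...")
    se_ids = pd.Series({ce: ce_to_se.se_of(ce) for ce in ce_matrix.regions})
    se_totals = ce_matrix.values.groupby(se_ids).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = ce_matrix.values / se_totals
    mask = (ratio > threshold) & (se_totals > 0)
    retained = mask.index[mask.any(axis=1)].tolist()
    return mask, retained


def per_kb_activity(signal, width):
    """Per-kilobase activity: signal / width * 1000 (width in bp, > 0)."""
    width_arr = np.asarray(width, dtype=float)
    if (width_arr <= 0).any():
        raise ValueError("width must be positive")
    out = np.asarray(signal, dtype=float) / width_arr * 1000.0
    return out.item() if out.ndim == 0 else out
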