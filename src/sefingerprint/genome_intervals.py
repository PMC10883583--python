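"""Interval algebra for unifying super-enhancer (SE) and constituent-enhancer
(CE) calls across samples.

SEs and CEs are called per sample upstream (peak calling + SE stitching); to
compare activities across a cell panel the per-sample calls must first be
collapsed into a single unified candidate list.  Two regions of the same
class are considered the same element when they overlap by at least a given
fraction of width (default 25%), and merging is transitive so that the
unified list is a partition of the input calls.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGION_CLASSES = {"SE", "CE", "enhancer", "promoter", "blacklist"}

__all__ = [
    "GenomicRegion",
    "UnifiedRegion",
    "CEtoSEMap",
    "overlap_fraction",
    "merge_regions",
    "filter_excluded",
    "assign_ce_to_se",
    "promoter_windows",
    "read_bed",
    "write_unified_bed",
    "read_unified_bed",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval with optional sample provenance.

    ``start``/``end`` are 0-based half-open; ``width = end - start`` must be
    positive.  ``region_class`` is one of SE, CE, enhancer, promoter,
    blacklist.
    """

    chrom: str
    start: int
    end: int
    sample_id: str | None = None
    region_class: str = "enhancer"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def intersection_width(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class UnifiedRegion:
    """A merged cross-sample region; spans the union of its member intervals."""

    chrom: str
    start: int
    end: int
    members: tuple[GenomicRegion, ...]
    region_class: str
    uid: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("UnifiedRegion requires at least one member")
        if self.start != min(m.start for m in self.members):
            raise ValueError("start must equal min of member starts")
        if self.end != max(m.end for m in self.members):
            raise ValueError("end must equal max of member ends")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def n_members(self) -> int:
        return len(self.members)

    def as_region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end,
                             region_class=self.region_class)


@dataclass
class CEtoSEMap:
    """Assignment of unified CEs to their parent unified SE.

    ``mapping`` is CE uid -> SE uid; CEs overlapping no SE are listed in
    ``unassigned``.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def se_of(self, ce_uid: str) -> str | None:
        return self.mapping.get(ce_uid)

    def ces_of(self, se_uid: str) -> list[str]:
        return [ce for ce, se in self.mapping.items() if se == se_uid]


def overlap_fraction(
    a: GenomicRegion, b: GenomicRegion, denominator: str = "smaller"
) -> float:
    """Fractional width overlap between two regions.

    ``denominator`` selects the reference width: ``smaller`` (intersection
    over the smaller region's width, the default), ``either`` (the larger of
    the two per-region fractions, numerically identical to ``smaller``) or
    ``reciprocal`` (the smaller of the two per-region fractions, i.e. both
    regions must individually reach the cutoff).
    """
    inter = a.intersection_width(b)
    if inter == 0:
        return 0.0
    fa = inter / a.width
    fb = inter / b.width
    if denominator == "smaller":
        return inter / min(a.width, b.width)
    if denominator == "either":
        return max(fa, fb)
    if denominator == "reciprocal":
        return min(fa, fb)
    raise ValueError(f"unknown denominator mode {denominator!r}")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_regions(
    regions: Sequence[GenomicRegion],
    min_overlap: float = 0.25,
    denominator: str = "smaller",
    uid_prefix: str | None = None,
) -> list[UnifiedRegion]:
    """Transitively merge regions whose pairwise overlap reaches ``min_overlap``.

    Any two input regions with ``overlap_fraction >= min_overlap`` (and a
    strictly positive intersection — abutting or disjoint regions never
    merge, even at cutoff 0) end up in the same unified region; merging is
    the transitive closure of that relation, so the output is a partition of
    the input and independent of input order.  Output is sorted by
    (chrom, start, end) and assigned uids ``<class>_<i:05d>``.
    """
    if not 0.0 <= min_overlap <= 1.0:
        raise ValueError("min_overlap must be in [0, 1]")
    if not regions:
        return []
    classes = {r.region_class for r in regions}
    if len(classes) > 1:
        raise ValueError(f"regions must share a region_class, got {classes}")
    region_class = classes.pop()

    order = sorted(range(len(regions)),
                   key=lambda i: (regions[i].chrom, regions[i].start,
                                  regions[i].end, regions[i].sample_id or ""))
    uf = _UnionFind(len(regions))
    # sweep: compare each region against still-open regions on its chromosome
    active: list[int] = []
    prev_chrom: str | None = None
    for idx in order:
        r = regions[idx]
        if r.chrom != prev_chrom:
            active = []
            prev_chrom = r.chrom
        active = [j for j in active if regions[j].end > r.start]
        for j in active:
            if overlap_fraction(r, regions[j], denominator) >= min_overlap:
                uf.union(idx, j)
        active.append(idx)

    groups: dict[int, list[GenomicRegion]] = {}
    for i in order:
        groups.setdefault(uf.find(i), []).append(regions[i])

    unified = [
        UnifiedRegion(
            chrom=members[0].chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            members=tuple(members),
            region_class=region_class,
        )
        for members in groups.values()
    ]
    unified.sort(key=lambda u: (u.chrom, u.start, u.end))
    prefix = uid_prefix if uid_prefix is not None else region_class
    return [
        UnifiedRegion(u.chrom, u.start, u.end, u.members, u.region_class,
                      uid=f"{prefix}_{i:05d}")
        for i, u in enumerate(unified)
    ]


def _overlaps_any(peak: GenomicRegion,
                  by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if peak.chrom not in by_chrom:
        return False
    starts, max_ends = by_chrom[peak.chrom]
    # intervals starting before peak.end; max prefix end must exceed peak.start
    k = int(np.searchsorted(starts, peak.end, side="left"))
    return k > 0 and max_ends[k - 1] > peak.start


def _index_regions(regions: Iterable[GenomicRegion]
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        per.setdefault(r.chrom, []).append((r.start, r.end))
    out = {}
    for chrom, ivs in per.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        out[chrom] = (starts, ends)
    return out


def filter_excluded(
    peaks: Sequence[GenomicRegion],
    promoters: Sequence[GenomicRegion] = (),
    blacklist: Sequence[GenomicRegion] = (),
) -> list[GenomicRegion]:
    """Drop peaks sharing any base with a promoter window or blacklist region.

    Promoter windows around each TSS span upstream 3 kb to downstream 1 kb
    (see :func:`promoter_windows`).  Intersection is strict: a peak exactly
    abutting an excluded region (no shared base under half-open coordinates)
    is retained.
    """
    excluded = _index_regions(list(promoters) + list(blacklist))
    return [p for p in peaks if not _overlaps_any(p, excluded)]


def promoter_windows(
    tss: pd.DataFrame, upstream: int = 3000, downstream: int = 1000
) -> list[GenomicRegion]:
    """Build promoter exclusion windows from a TSS table.

    ``tss`` needs columns ``chrom``, ``tss`` and ``strand``; on the + strand
    the window is [TSS-upstream, TSS+downstream), mirrored on the - strand.
    Windows are clipped at position 0.
    """
    out = []
    for row in tss.itertuples(index=False):
        if row.strand == "-":
            start, end = row.tss - downstream, row.tss + upstream
        else:
            start, end = row.tss - upstream, row.tss + downstream
        out.append(GenomicRegion(row.chrom, max(0, start), end,
                                 region_class="promoter"))
    return out


def assign_ce_to_se(
    ces: Sequence[UnifiedRegion], ses: Sequence[UnifiedRegion]
) -> CEtoSEMap:
    """Assign each unified CE to the unified SE sharing the most bases.

    Ties go to the SE with the smaller start (then smaller uid) so the
    assignment is deterministic; CEs intersecting no SE are flagged
    unassigned.
    """
    ses_by_chrom: dict[str, list[UnifiedRegion]] = {}
    for se in ses:
        ses_by_chrom.setdefault(se.chrom, []).append(se)
    for lst in ses_by_chrom.values():
        lst.sort(key=lambda s: (s.start, s.end))

    result = CEtoSEMap()
    for ce in ces:
        if ce.uid is None:
            raise ValueError("unified CEs must carry uids before assignment")
        best: tuple[int, int, str] | None = None  # (-inter, start, uid)
        for se in ses_by_chrom.get(ce.chrom, []):
            if se.start >= ce.end:
                break
            inter = max(0, min(ce.end, se.end) - max(ce.start, se.start))
            if inter > 0:
                key = (-inter, se.start, se.uid or "")
                if best is None or key < best:
                    best = key
        if best is None:
            result.unassigned.append(ce.uid)
        else:
            result.mapping[ce.uid] = best[2]
    return result


# ---------------------------------------------------------------------------
# BED I/O

def read_bed(path, region_class: str = "enhancer",
             sample_id: str | None = None) -> list[GenomicRegion]:
    """Read BED3/BED6 into regions (extra columns beyond the first three are
    ignored; strand is irrelevant for unstranded H3K27Ac intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str, 1: int, 2: int})
    return [GenomicRegion(r.chrom, r.start, r.end, sample_id=sample_id,
                          region_class=region_class)
            for r in df.itertuples(index=False)]


def write_unified_bed(path, unified: Sequence[UnifiedRegion]) -> None:
    """Write unified regions as BED6; the name field encodes uid and member
    count as ``<uid>;n=<members>``."""
    rows = [(u.chrom, u.start, u.end, f"{u.uid};n={u.n_members}", 0, ".")
            for u in unified]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_unified_bed(path, region_class: str) -> list[UnifiedRegion]:
    """Inverse of :func:`write_unified_bed` (membership collapses to the
    merged span; original member intervals are not recoverable from BED)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"],
                     dtype={0: str, 1: int, 2: int, 3: str})
    out = []
    for r in df.itertuples(index=False):
        uid = r.name.split(";")[0]
        g = GenomicRegion(r.chrom, r.start, r.end, region_class=region_class)
        out.append(UnifiedRegion(r.chrom, r.start, r.end, (g,), region_class,
                                 uid=uid))
    return out
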