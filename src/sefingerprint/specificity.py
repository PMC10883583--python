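"""Cell- and cancer-specific constituent enhancers from binary state calls.

A CE's active prevalence is the fraction of cell lines in which it is called
active.  CEs whose active (or inactive) prevalence falls below a threshold
are cell-specific; the threshold is chosen by scanning candidate cutoffs
0..0.5, clustering the cell lines on the CEs selected at each cutoff, and
comparing the clustering to the known cancer types with the variation of
information (VI) distance — the selected cutoff sits at the inflection point
where the min-max-scaled, smoothed VI-vs-cutoff curve has slope -1.
Cell-specific CEs shared by at least two cell lines of one cancer type (or
by the sole cell line of a singleton cancer) become cancer-specific, and SEs
containing them are the cancer-specific "fingerprint" SEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import savgol_filter

from .activity_matrix import ActivityMatrix, SampleSheet
from .genome_intervals import CEtoSEMap

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceProfile",
    "SpecificityCall",
    "ThresholdScan",
    "compute_prevalence",
    "variation_of_information",
    "cluster_cells",
    "select_threshold",
    "select_from_curve",
    "call_cell_specific",
    "call_cancer_specific",
    "summarize_cancer_specific_se",
]

SLOPE_TOL = 1e-6


def compute_prevalence(states: pd.DataFrame) -> pd.DataFrame:
    """Per-CE active and inactive prevalence across cell lines.

    ``states`` is the boolean CE x cell-line frame; the two prevalences sum
    to 1 by construction.
    """
    active = states.astype(bool).mean(axis=1)
    return pd.DataFrame({
        "active_prevalence": active,
        "inactive_prevalence": 1.0 - active,
    })


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def variation_of_information(labels_a, labels_b) -> float:
    """VI distance between two partitions of the same items (natural log).

    VI = H(A) + H(B) - 2 I(A;B), computed from the contingency table; it is
    0 iff the partitions agree up to label renaming, symmetric, and a metric
    on the space of partitions.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D label vectors of equal length")
    if len(a) == 0:
        raise ValueError("empty partitions")
    cont = pd.crosstab(a, b).to_numpy(dtype=float)
    n = cont.sum()
    h_a = _entropy(cont.sum(axis=1))
    h_b = _entropy(cont.sum(axis=0))
    p = cont[cont > 0] / n
    pa = (cont.sum(axis=1) / n)[:, None]
    pb = (cont.sum(axis=0) / n)[None, :]
    outer = np.broadcast_to(pa * pb, cont.shape)[cont > 0]
    mi = float((p * np.log(p / outer)).sum())
    return max(0.0, h_a + h_b - 2.0 * mi)


def cluster_cells(m: ActivityMatrix | pd.DataFrame, k: int,
                  method: str = "ward", metric: str = "euclidean"
                  ) -> np.ndarray:
    """Agglomerative clustering of cell lines on the selected CEs' activities.

    Observations are the matrix columns (cell lines), features the CE rows;
    Ward linkage on Euclidean distance by default, tree cut into ``k``
    groups.  With zero CE rows every cell line falls into one cluster.
    """
    values = m.values if isinstance(m, ActivityMatrix) else m
    n_cells = values.shape[1]
    if k < 1 or k > n_cells:
        raise ValueError(f"k={k} outside [1, {n_cells}]")
    if values.shape[0] == 0 or k == 1:
        return np.ones(n_cells, dtype=int)
    if k == n_cells:
        return np.arange(1, n_cells + 1)
    Z = linkage(values.to_numpy(dtype=float).T, method=method, metric=metric)
    return fcluster(Z, t=k, criterion="maxclust")


@dataclass
class ThresholdScan:
    """Result of the VI-vs-prevalence-cutoff scan.

    ``table`` has one row per candidate cutoff with the number of selected
    CEs, the raw VI, and the min-max-scaled smoothed curve and its slope.
    ``selected`` is the chosen prevalence threshold; ``fallback_used`` marks
    that the slope never reached -1 and the closest-to-ideal-corner rule
    fired instead.
    """

    table: pd.DataFrame
    selected: float
    fallback_used: bool = False

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def select_threshold(
    profiles: pd.DataFrame,
    m: ActivityMatrix | pd.DataFrame,
    true_labels,
    grid_start: float = 0.0,
    grid_stop: float = 0.5,
    grid_step: float = 0.01,
    smooth_window: int = 11,
    method: str = "ward",
    metric: str = "euclidean",
) -> ThresholdScan:
    """Choose the prevalence threshold at the VI curve's inflection point.

    For each candidate cutoff the CEs with active prevalence strictly below
    it are selected, the cell lines are clustered on their log2 activities,
    and the clustering is scored against the true cancer-type labels by VI
    (a cutoff selecting zero CEs scores the single-cluster VI, i.e. maximal
    uninformativeness).  Cutoffs and VI are min-max scaled to [0, 1], the VI
    curve is smoothed by a local quadratic (Savitzky-Golay, window
    ``smooth_window`` grid points) and the threshold is the cutoff where
    the smoothed slope climbs back through -1 after the curve's dominant
    descent (the knee of the curve).  If the slope never reaches -1, the
    cutoff minimizing scaled VI + scaled cutoff (closest to the ideal
    low-VI/low-cutoff corner) is used with a warning.
    """
    values = m.values if isinstance(m, ActivityMatrix) else m
    labels = np.asarray(true_labels)
    if len(labels) != values.shape[1]:
        raise ValueError("one true label per matrix column is required")
    k = len(np.unique(labels))

    n_steps = int(round((grid_stop - grid_start) / grid_step))
    grid = grid_start + grid_step * np.arange(n_steps + 1)
    single = np.ones(len(labels), dtype=int)
    vi_single = variation_of_information(single, labels)

    n_selected = np.zeros(len(grid), dtype=int)
    vi = np.zeros(len(grid))
    for i, cutoff in enumerate(grid):
        sel = profiles.index[profiles["active_prevalence"] < cutoff]
        n_selected[i] = len(sel)
        if len(sel) == 0:
            vi[i] = vi_single
        else:
            part = cluster_cells(values.loc[sel], k, method=method,
                                 metric=metric)
            vi[i] = variation_of_information(part, labels)

    scan = select_from_curve(grid, vi, smooth_window=smooth_window)
    scan.table.insert(1, "n_selected", n_selected)
    return scan


def select_from_curve(grid: np.ndarray, vi: np.ndarray,
                      smooth_window: int = 11) -> ThresholdScan:
    """Apply the inflection-point rule to a precomputed VI-vs-cutoff curve.

    Both axes are min-max scaled to [0, 1]; the scaled VI is smoothed by a
    local quadratic (Savitzky-Golay); the threshold is the last cutoff of
    the contiguous slope<=-1 run containing the curve's steepest point —
    the knee where the dominant descent levels off.  A curve whose slope
    never reaches -1 falls back to the cutoff minimizing scaled VI +
    scaled cutoff.
    """
    grid = np.asarray(grid, dtype=float)
    vi = np.asarray(vi, dtype=float)
    x_scaled = _minmax(grid)
    vi_scaled = _minmax(vi)
    window = min(smooth_window, len(grid) if len(grid) % 2 else len(grid) - 1)
    smoothed = savgol_filter(vi_scaled, window_length=window, polyorder=2)
    slope = np.gradient(smoothed, x_scaled)

    steep = slope <= -1.0 + SLOPE_TOL
    fallback = False
    if steep.any():
        # the knee is where the slope climbs back through -1 after the
        # dominant descent; isolated steep wiggles before or after the main
        # drop are ignored by anchoring on the steepest point of the curve
        anchor = int(np.argmin(slope))
        last = anchor
        while last + 1 < len(grid) and steep[last + 1]:
            last += 1
        selected = float(grid[last])
    else:
        logger.warning("VI slope never reached -1; corner-rule fallback used")
        fallback = True
        selected = float(grid[int(np.argmin(vi_scaled + x_scaled))])

    table = pd.DataFrame({
        "cutoff": grid,
        "vi": vi,
        "vi_scaled": vi_scaled,
        "vi_smoothed": smoothed,
        "slope": slope,
    })
    return ThresholdScan(table=table, selected=selected, fallback_used=fallback)


@dataclass
class SpecificityCall:
    """A cell-specific CE call: the CE, its mode and the minority cell lines.

    ``mode`` is ``specific_active`` (rarely active; ``cells`` are the active
    lines) or ``specific_inactive`` (rarely inactive; ``cells`` are the
    inactive lines).  ``cancers`` is filled by :func:`call_cancer_specific`.
    """

    ce_id: str
    mode: str
    cells: tuple[str, ...]
    cancers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("specific_active", "specific_inactive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.cells:
            raise ValueError("a specificity call requires >=1 carrying cell")


def call_cell_specific(
    profiles: pd.DataFrame,
    states: pd.DataFrame,
    threshold: float,
) -> list[SpecificityCall]:
    """Cell-specific CE calls at a prevalence threshold (strict inequality).

    A CE with active prevalence < threshold is specific_active, carrying its
    active cell lines; one with inactive prevalence < threshold is
    specific_inactive, carrying its inactive lines.  CEs at prevalence 0
    have no carrying cells (the uniformly active/inactive classes) and are
    not called.
    """
    calls: list[SpecificityCall] = []
    states = states.astype(bool)
    for ce, row in profiles.iterrows():
        if 0.0 < row["active_prevalence"] < threshold:
            cells = tuple(states.columns[states.loc[ce]])
            calls.append(SpecificityCall(ce, "specific_active", cells))
        if 0.0 < row["inactive_prevalence"] < threshold:
            cells = tuple(states.columns[~states.loc[ce]])
            calls.append(SpecificityCall(ce, "specific_inactive", cells))
    return calls


def call_cancer_specific(
    calls: list[SpecificityCall], sheet: SampleSheet
) -> pd.DataFrame:
    """Promote cell-specific calls to cancer-specific calls.

    A cancer type is attached to a call when at least two of its cell lines
    carry the state — or, for cancers represented by a single cell line in
    the panel, when that one line carries it.  Calls attaching no cancer are
    dropped (they remain in the cell-specific table).  Returns one row per
    (CE, mode, cancer).
    """
    cancer_cells = {c: set(sheet.cells_of_cancer(c))
                    for c in sheet.cancer_types}
    rows = []
    for call in calls:
        cellset = set(call.cells)
        for cancer, panel_cells in cancer_cells.items():
            hit = len(panel_cells & cellset)
            if hit >= 2 or (len(panel_cells) == 1 and hit == 1):
                rows.append({
                    "ce_id": call.ce_id,
                    "mode": call.mode,
                    "cancer_type": cancer,
                    "cells": ",".join(sorted(panel_cells & cellset)),
                })
    return pd.DataFrame(rows, columns=["ce_id", "mode", "cancer_type", "cells"])


def summarize_cancer_specific_se(
    cancer_ces: pd.DataFrame,
    ce_to_se: CEtoSEMap,
    all_se_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Summarize SEs containing cancer-specific CEs ("fingerprint" SEs).

    Each SE is listed once per cancer it is specific to, with its
    specific-active and specific-inactive member CEs, and carries an overall
    category: ``both`` (has active- and inactive-specific CEs, possibly for
    different cancers), ``active_only``, ``inactive_only`` or ``none``.
    Passing ``all_se_ids`` adds ``none`` rows for SEs without specific CEs.
    CEs lacking an SE assignment are excluded with a warning.
    """
    per_se_modes: dict[str, set[str]] = {}
    per_se_cancer: dict[tuple[str, str], dict[str, set[str]]] = {}
    for row in cancer_ces.itertuples(index=False):
        se = ce_to_se.se_of(row.ce_id)
        if se is None:
            logger.warning("cancer-specific CE %s has no SE; excluded",
                           row.ce_id)
            continue
        per_se_modes.setdefault(se, set()).add(row.mode)
        slot = per_se_cancer.setdefault((se, row.cancer_type),
                                        {"specific_active": set(),
                                         "specific_inactive": set()})
        slot[row.mode].add(row.ce_id)

    def category(modes: set[str]) -> str:
        if modes == {"specific_active", "specific_inactive"}:
            return "both"
        if modes == {"specific_active"}:
            return "active_only"
        if modes == {"specific_inactive"}:
            return "inactive_only"
        return "none"

    rows = []
    for (se, cancer), slot in sorted(per_se_cancer.items()):
        rows.append({
            "se_id": se,
            "cancer_type": cancer,
            "category": category(per_se_modes[se]),
            "specific_active_ces": ",".join(sorted(slot["specific_active"])),
            "specific_inactive_ces": ",".join(sorted(slot["specific_inactive"])),
        })
    if all_se_ids is not None:
        covered = {r["se_id"] for r in rows}
        for se in all_se_ids:
            if se not in covered:
                rows.append({"se_id": se, "cancer_type": "",
                             "category": "none",
                             "specific_active_ces": "",
                             "specific_inactive_ces": ""})
    return pd.DataFrame(rows, columns=["se_id", "cancer_type", "category",
                                       "specific_active_ces",
                                       "specific_inactive_ces"])
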