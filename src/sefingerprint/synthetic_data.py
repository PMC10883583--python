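"""Synthetic datasets with the structure the fingerprinting pipeline assumes.

The generator emulates a cancer cell panel profiled by H3K27Ac ChIP-seq:
non-overlapping super-enhancers containing nested constituent enhancers,
per-sample boundary jitter (so cross-sample unification is non-trivial),
bimodal log2-scale activities with active/inactive components, planted
cancer-specific CEs at a controlled prevalence, uniformly active/inactive
CEs, a background of non-SE enhancers for depth normalization, per-sample
sequencing-depth factors, replicate noise and excess zeros among inactive
occurrences.  Everything is a pure function of the configuration (which
includes the seed), and ground truth is emitted alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity_matrix import SampleSheet
from .genome_intervals import CEtoSEMap, GenomicRegion

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedRegions",
    "SimulatedDataset",
    "simulate_regions",
    "simulate_activity",
    "simulate_dataset",
    "simulate_log2_matrix",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults give 10 cancers x 3 cell lines x 2
    replicates, 200 SEs of 5 CEs each, and planted specific CEs at ~0.15
    active prevalence against a 0.5-prevalence background."""

    n_cancers: int = 10
    cells_per_cancer: int = 3
    replicates_per_cell: int = 2
    n_ses: int = 200
    ces_per_se: int = 5
    n_other_enhancers: int = 500
    mu_active: float = 9.0
    mu_inactive: float = 3.0
    sd_active: float = 1.0
    sd_inactive: float = 1.0
    fraction_specific: float = 0.15
    planted_specific_prevalence: float = 0.15
    background_active_rate: float = 0.5
    fraction_all_active: float = 0.01
    fraction_all_inactive: float = 0.01
    other_active_rate: float = 0.7
    replicate_sd: float = 0.25
    depth_low: float = 0.5
    depth_high: float = 2.0
    zero_rate: float = 0.05
    jitter_frac: float = 0.05
    n_chroms: int = 5
    count_mode: str = "round"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_active <= self.mu_inactive:
            raise ValueError("mu_active must exceed mu_inactive")
        for name in ("n_cancers", "cells_per_cancer", "replicates_per_cell",
                     "n_ses", "ces_per_se"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fraction_specific", "planted_specific_prevalence",
                     "background_active_rate", "zero_rate",
                     "fraction_all_active", "fraction_all_inactive",
                     "other_active_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.count_mode not in ("round", "poisson"):
            raise ValueError("count_mode must be 'round' or 'poisson'")

    @property
    def n_cells(self) -> int:
        return self.n_cancers * self.cells_per_cancer

    @property
    def n_samples(self) -> int:
        return self.n_cells * self.replicates_per_cell

    @property
    def n_ces(self) -> int:
        return self.n_ses * self.ces_per_se


@dataclass
class GroundTruth:
    """True per-CE states and planted specificity labels.

    ``states``: boolean CE x cell-line frame.  ``specificity``: per-CE label,
    ``none`` or ``specific_active:<cancer>`` / ``specific_inactive:<cancer>``.
    ``depth_factors``: the per-sample scale actually applied (RLE should
    recover these up to a common constant).
    """

    states: pd.DataFrame
    specificity: pd.Series
    depth_factors: pd.Series


@dataclass
class SimulatedRegions:
    se_table: pd.DataFrame
    ce_table: pd.DataFrame
    sample_ses: dict[str, list[GenomicRegion]]
    sample_ces: dict[str, list[GenomicRegion]]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sheet: SampleSheet
    regions: SimulatedRegions
    counts: pd.DataFrame  # CE + background-enhancer rows x sample columns
    ce_ids: list[str]
    ce_to_se: CEtoSEMap
    truth: GroundTruth


def _make_sheet(cfg: SimulationConfig) -> SampleSheet:
    rows = []
    for c in range(cfg.n_cancers):
        cancer = f"cancer_{c + 1:02d}"
        for i in range(cfg.cells_per_cancer):
            cell = f"{cancer}_cell{i + 1}"
            for r in range(cfg.replicates_per_cell):
                rows.append({"sample_id": f"{cell}_rep{r + 1}",
                             "cell_line": cell, "cancer_type": cancer})
    return SampleSheet(pd.DataFrame(rows))


def simulate_regions(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None
                     ) -> SimulatedRegions:
    """Lay out non-overlapping SEs with nested CEs and jitter them per sample.

    Boundary jitter is uniform within ±``jitter_frac`` of the region width
    on each side; at the default 5% every per-sample pair of calls for the
    same element overlaps well above the 25% merge cutoff, so unification
    recovers exactly the planted elements.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sheet = _make_sheet(cfg)
    se_rows, ce_rows = [], []
    ses_per_chrom = -(-cfg.n_ses // cfg.n_chroms)
    se_idx = ce_idx = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        pos = 10_000
        for _ in range(ses_per_chrom):
            if se_idx >= cfg.n_ses:
                break
            pos += int(rng.integers(20_000, 100_000))  # inter-SE gap
            se_start = pos
            ce_local = []
            for _ in range(cfg.ces_per_se):
                pos += int(rng.integers(500, 2_000))  # intra-SE gap
                width = int(rng.integers(1_000, 3_000))
                ce_local.append((pos, pos + width))
                pos += width
            se_end = pos
            se_rows.append({"se_id": f"SE_{se_idx:05d}", "chrom": chrom,
                            "start": se_start, "end": se_end})
            for s, e in ce_local:
                ce_rows.append({"ce_id": f"CE_{ce_idx:05d}",
                                "se_id": f"SE_{se_idx:05d}",
                                "chrom": chrom, "start": s, "end": e})
                ce_idx += 1
            se_idx += 1
    se_table = pd.DataFrame(se_rows)
    ce_table = pd.DataFrame(ce_rows)

    def jittered(start: int, end: int) -> tuple[int, int]:
        width = end - start
        j = cfg.jitter_frac * width
        s = start + int(round(rng.uniform(-j, j)))
        e = end + int(round(rng.uniform(-j, j)))
        if e <= s:
            e = s + 1
        return max(0, s), e

    sample_ses: dict[str, list[GenomicRegion]] = {}
    sample_ces: dict[str, list[GenomicRegion]] = {}
    for sample in sheet.samples:
        ses = []
        for row in se_table.itertuples(index=False):
            s, e = jittered(row.start, row.end)
            ses.append(GenomicRegion(row.chrom, s, e, sample_id=sample,
                                     region_class="SE"))
        ces = []
        for row in ce_table.itertuples(index=False):
            s, e = jittered(row.start, row.end)
            ces.append(GenomicRegion(row.chrom, s, e, sample_id=sample,
                                     region_class="CE"))
        sample_ses[sample] = ses
        sample_ces[sample] = ces
    return SimulatedRegions(se_table, ce_table, sample_ses, sample_ces)


def _plant_states(cfg: SimulationConfig, sheet: SampleSheet,
                  rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, pd.Series]:
    cells = sheet.cell_lines
    n_cells = len(cells)
    cancers = sheet.cancer_types
    cell_idx_of_cancer = {c: [cells.index(x) for x in sheet.cells_of_cancer(c)]
                          for c in cancers}
    ce_ids = [f"CE_{i:05d}" for i in range(cfg.n_ces)]

    n_spec = int(round(cfg.fraction_specific * cfg.n_ces))
    n_all_a = int(round(cfg.fraction_all_active * cfg.n_ces))
    n_all_i = int(round(cfg.fraction_all_inactive * cfg.n_ces))
    perm = rng.permutation(cfg.n_ces)
    spec_idx = perm[:n_spec]
    all_a_idx = perm[n_spec:n_spec + n_all_a]
    all_i_idx = perm[n_spec + n_all_a:n_spec + n_all_a + n_all_i]

    states = rng.random((cfg.n_ces, n_cells)) < cfg.background_active_rate
    specificity = pd.Series("none", index=ce_ids, dtype=object)

    # round half up so a design aiming at prevalence p never undershoots it
    n_minority = max(cfg.cells_per_cancer,
                     int(np.floor(cfg.planted_specific_prevalence * n_cells
                                  + 0.5)))
    for j, ce in enumerate(spec_idx):
        cancer = cancers[j % len(cancers)]
        own = cell_idx_of_cancer[cancer]
        minority = list(own)
        n_extra = n_minority - len(own)
        if n_extra > 0:
            # one extra cell from each of n_extra distinct other cancers, so
            # the extras can never satisfy the >=2-cell-line rule elsewhere
            others = [c for c in cancers if c != cancer]
            picked = rng.choice(len(others), size=n_extra, replace=False)
            for p in picked:
                minority.append(int(rng.choice(cell_idx_of_cancer[others[p]])))
        active_mode = j % 2 == 0
        row = np.zeros(n_cells, dtype=bool) if active_mode \
            else np.ones(n_cells, dtype=bool)
        row[minority] = active_mode
        states[ce] = row
        mode = "specific_active" if active_mode else "specific_inactive"
        specificity.iloc[ce] = f"{mode}:{cancer}"
    states[all_a_idx] = True
    states[all_i_idx] = False
    return (pd.DataFrame(states, index=ce_ids, columns=cells), specificity)


def _draw_counts(cfg: SimulationConfig, states: np.ndarray,
                 sheet: SampleSheet, depth: pd.Series,
                 rng: np.random.Generator, ids: list[str],
                 allow_zeros: bool) -> pd.DataFrame:
    cells = sheet.cell_lines
    n_rows, n_cells = states.shape
    mu = np.where(states, cfg.mu_active, cfg.mu_inactive)
    sd = np.where(states, cfg.sd_active, cfg.sd_inactive)
    log2_cell = rng.normal(mu, sd)
    zero_here = np.zeros_like(states, dtype=bool)
    if allow_zeros and cfg.zero_rate > 0:
        zero_here = (~states) & (rng.random(states.shape) < cfg.zero_rate)
    cols = {}
    sample_cell = sheet.sample_to_cell()
    for sample in sheet.samples:
        ci = cells.index(sample_cell[sample])
        log2_rep = log2_cell[:, ci] + rng.normal(0, cfg.replicate_sd, n_rows)
        linear = np.exp2(log2_rep) * float(depth[sample])
        counts = (rng.poisson(linear).astype(float)
                  if cfg.count_mode == "poisson" else np.round(linear))
        counts[zero_here[:, ci]] = 0.0
        cols[sample] = counts
    return pd.DataFrame(cols, index=ids)


def simulate_activity(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, SampleSheet, GroundTruth]:
    """Draw the raw count matrix (CE rows plus non-SE background enhancers)
    and the ground truth that generated it."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    sheet = _make_sheet(cfg)
    states, specificity = _plant_states(cfg, sheet, rng)
    depth = pd.Series(
        rng.uniform(cfg.depth_low, cfg.depth_high, cfg.n_samples),
        index=sheet.samples, name="depth_factor")

    ce_counts = _draw_counts(cfg, states.to_numpy(), sheet, depth, rng,
                             list(states.index), allow_zeros=True)
    other_ids = [f"ENH_{i:05d}" for i in range(cfg.n_other_enhancers)]
    other_states = rng.random((cfg.n_other_enhancers, cfg.n_cells)) \
        < cfg.other_active_rate
    other_counts = _draw_counts(cfg, other_states, sheet, depth, rng,
                                other_ids, allow_zeros=False)
    counts = pd.concat([ce_counts, other_counts])
    truth = GroundTruth(states=states, specificity=specificity,
                        depth_factors=depth)
    return counts, sheet, truth


def simulate_log2_matrix(cfg: SimulationConfig,
                         rng: np.random.Generator | None = None):
    """Draw per-CE log2 activities directly from the generating components.

    Bypasses counts, depth and normalization: each (CE, cell line) value is
    a draw from N(mu_active, sd_active) or N(mu_inactive, sd_inactive)
    according to the planted state.  Returns ``(matrix, sheet, truth)`` with
    ``matrix`` at the log2 stage (no zeros), ready for mixture fitting —
    useful when the object under study is the state model itself.
    """
    from .activity_matrix import ActivityMatrix

    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    sheet = _make_sheet(cfg)
    states, specificity = _plant_states(cfg, sheet, rng)
    mu = np.where(states.to_numpy(), cfg.mu_active, cfg.mu_inactive)
    sd = np.where(states.to_numpy(), cfg.sd_active, cfg.sd_inactive)
    values = pd.DataFrame(rng.normal(mu, sd), index=states.index,
                          columns=states.columns)
    matrix = ActivityMatrix(values, stage="log2",
                            zero_mask=pd.DataFrame(False,
                                                   index=values.index,
                                                   columns=values.columns))
    truth = GroundTruth(states=states, specificity=specificity,
                        depth_factors=pd.Series(1.0, index=sheet.samples,
                                                name="depth_factor"))
    return matrix, sheet, truth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full dataset: regions, counts, sheet, CE->SE map and ground truth."""
    regions = simulate_regions(cfg)
    counts, sheet, truth = simulate_activity(cfg)
    ce_to_se = CEtoSEMap(mapping=dict(zip(regions.ce_table["ce_id"],
                                          regions.ce_table["se_id"])))
    return SimulatedDataset(config=cfg, sheet=sheet, regions=regions,
                            counts=counts,
                            ce_ids=list(truth.states.index),
                            ce_to_se=ce_to_se, truth=truth)


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write per-sample BEDs, counts TSV, sample sheet and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.counts.to_csv(out / "counts.tsv", sep="\t", index_label="region_id")
    ds.sheet.to_tsv(out / "sample_sheet.tsv")
    ds.truth.states.astype(int).to_csv(out / "true_states.tsv", sep="\t",
                                       index_label="ce_id")
    ds.truth.specificity.rename("specificity").to_csv(
        out / "true_specificity.tsv", sep="\t", index_label="ce_id")
    ds.truth.depth_factors.to_csv(out / "true_depth_factors.tsv", sep="\t",
                                  index_label="sample_id")
    ds.regions.ce_table.to_csv(out / "true_ce_regions.tsv", sep="\t",
                               index=False)
    ds.regions.se_table.to_csv(out / "true_se_regions.tsv", sep="\t",
                               index=False)
    beds = out / "sample_beds"
    beds.mkdir(exist_ok=True)
    for sample in ds.sheet.samples:
        for kind, lookup in (("se", ds.regions.sample_ses),
                             ("ce", ds.regions.sample_ces)):
            rows = [(r.chrom, r.start, r.end) for r in lookup[sample]]
            pd.DataFrame(rows).to_csv(beds / f"{sample}.{kind}.bed",
                                      sep="\t", header=False, index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=2, sort_keys=True)
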