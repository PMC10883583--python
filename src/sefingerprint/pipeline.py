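"""End-to-end orchestration: counts -> states -> specificity -> database.

The stages mirror the method: aggregate replicates, RLE-normalize over the
genome-wide enhancer set, impute zeros, log2, drop CEs contributing <=3% of
their SE's activity everywhere, fit global priors and per-CE mixtures, call
states, scan prevalence cutoffs with the VI criterion, and summarize cell-
and cancer-specific CEs into fingerprint SEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import activity_matrix as am
from . import mixture_states as ms
from . import specificity as sp
from .fingerprint_db import FingerprintDB, build_db
from .genome_intervals import CEtoSEMap
from .synthetic_data import SimulatedDataset

__all__ = ["PipelineResult", "run_pipeline", "run_on_dataset"]


@dataclass
class PipelineResult:
    """Every intermediate and final product of one pipeline run."""

    aggregated: am.ActivityMatrix
    normalized: am.ActivityMatrix
    log2: am.ActivityMatrix
    contribution_mask: pd.DataFrame
    retained_ces: list[str]
    priors: ms.GlobalPriors
    states: pd.DataFrame
    fits: dict[str, ms.MixtureFit]
    fit_table: pd.DataFrame
    profiles: pd.DataFrame
    scan: sp.ThresholdScan | None
    threshold: float
    cell_calls: list[sp.SpecificityCall]
    cancer_calls: pd.DataFrame
    se_summary: pd.DataFrame
    db: FingerprintDB | None = None


def _cell_calls_frame(calls: list[sp.SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"ce_id": c.ce_id, "mode": c.mode, "cells": ",".join(sorted(c.cells))}
         for c in calls],
        columns=["ce_id", "mode", "cells"],
    )


def run_pipeline(
    counts: pd.DataFrame,
    sheet: am.SampleSheet,
    ce_ids: list[str],
    ce_to_se: CEtoSEMap,
    se_regions: pd.DataFrame | None = None,
    ce_regions: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    contribution_threshold: float = 0.03,
    prevalence_threshold: float | str = "auto",
    aggregate_how: str = "sum",
    prior_mode: str = "map",
    tol: float = 1e-8,
    max_iter: int = 1000,
    metadata: dict | None = None,
) -> PipelineResult:
    """Run the full fingerprinting pipeline from a raw count matrix.

    ``counts`` rows are unified enhancer regions (CE rows named in
    ``ce_ids``; any other rows are non-SE enhancers used only for depth
    normalization and excluded from modeling), columns are samples listed in
    ``sheet``.  ``prevalence_threshold`` is ``"auto"`` (VI inflection-point
    scan) or a fixed value.  When region tables are supplied the result
    includes an integrity-checked :class:`FingerprintDB`.
    """
    raw = am.ActivityMatrix(counts.astype(float), stage="raw")
    aggregated = am.aggregate_replicates(raw, sheet, how=aggregate_how)
    normalized = am.rle_normalize(aggregated)
    imputed = am.impute_zeros(normalized)
    log2m = am.log2_transform(imputed)

    ce_norm = am.ActivityMatrix(normalized.values.loc[ce_ids],
                                stage="normalized",
                                size_factors=normalized.size_factors)
    contribution_mask, retained = am.se_contribution_filter(
        ce_norm, ce_to_se, threshold=contribution_threshold)

    ce_log2 = am.ActivityMatrix(
        log2m.values.loc[ce_ids], stage="log2",
        zero_mask=log2m.zero_mask.loc[ce_ids],
        size_factors=log2m.size_factors)
    priors = ms.fit_global_priors(ce_log2, tol=tol, max_iter=max_iter)
    states, fits, fit_table = ms.fit_states(
        ce_log2, priors, ce_ids=retained, tol=tol, max_iter=max_iter,
        prior_mode=prior_mode)

    profiles = sp.compute_prevalence(states)
    labels = [sheet.cell_to_cancer()[c] for c in states.columns]
    scan = None
    if prevalence_threshold == "auto":
        scan = sp.select_threshold(profiles, ce_log2.values.loc[retained],
                                   labels)
        threshold = scan.selected
    else:
        threshold = float(prevalence_threshold)

    cell_calls = sp.call_cell_specific(profiles, states, threshold)
    cancer_calls = sp.call_cancer_specific(cell_calls, sheet)
    se_summary = sp.summarize_cancer_specific_se(cancer_calls, ce_to_se)

    db = None
    if se_regions is not None and ce_regions is not None:
        meta = dict(metadata or {})
        meta.setdefault("contribution_threshold", contribution_threshold)
        meta.setdefault("prevalence_threshold", threshold)
        db = build_db(
            se_regions=se_regions, ce_regions=ce_regions, ce_to_se=ce_to_se,
            states=states, cell_calls=_cell_calls_frame(cell_calls),
            cancer_calls=cancer_calls, se_summary=se_summary, sheet=sheet,
            genes=genes, metadata=meta)

    return PipelineResult(
        aggregated=aggregated, normalized=normalized, log2=log2m,
        contribution_mask=contribution_mask, retained_ces=retained,
        priors=priors, states=states, fits=fits, fit_table=fit_table,
        profiles=profiles, scan=scan, threshold=threshold,
        cell_calls=cell_calls, cancer_calls=cancer_calls,
        se_summary=se_summary, db=db)


def run_on_dataset(ds: SimulatedDataset, **kwargs) -> PipelineResult:
    """Convenience wrapper running the pipeline on a simulated dataset."""
    se_regions = ds.regions.se_table.set_index("se_id")[
        ["chrom", "start", "end"]]
    ce_regions = ds.regions.ce_table.set_index("ce_id")[
        ["chrom", "start", "end"]]
    meta = kwargs.pop("metadata", {})
    meta.setdefault("simulation_seed", ds.config.seed)
    return run_pipeline(
        ds.counts, ds.sheet, ds.ce_ids, ds.ce_to_se,
        se_regions=se_regions, ce_regions=ce_regions, metadata=meta,
        **kwargs)
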