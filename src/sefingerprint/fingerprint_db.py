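"""Queryable database of cancer-specific super-enhancer fingerprints.

Bundles the unified region tables, the CE->SE map, state calls and the
cell-/cancer-specific call tables into a single self-describing plain-text
archive (JSON metadata + TSV tables) supporting four query modes: by cancer
type, by cell line, by gene target and by genomic location.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .activity_matrix import SampleSheet
from .genome_intervals import CEtoSEMap

logger = logging.getLogger(__name__)

__all__ = ["FingerprintDB", "build_db", "query", "export"]

_REGION_COLS = ["chrom", "start", "end"]
_LOCATION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass
class FingerprintDB:
    """All pipeline outputs, cross-referenced and ready to query.

    Region tables are indexed by uid with chrom/start/end columns; ``genes``
    (optional) needs gene/chrom/tss columns and enables gene-mode queries.
    ``metadata`` records the parameters (overlap cutoff, prevalence
    threshold, seeds, versions) the run used.
    """

    se_regions: pd.DataFrame
    ce_regions: pd.DataFrame
    ce_to_se: CEtoSEMap
    states: pd.DataFrame
    cell_calls: pd.DataFrame
    cancer_calls: pd.DataFrame
    se_summary: pd.DataFrame
    sheet: SampleSheet
    genes: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    # -- persistence --------------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.se_regions.to_csv(out / "se_regions.tsv", sep="\t",
                               index_label="se_id")
        self.ce_regions.to_csv(out / "ce_regions.tsv", sep="\t",
                               index_label="ce_id")
        pd.DataFrame(
            sorted(self.ce_to_se.mapping.items()),
            columns=["ce_id", "se_id"],
        ).to_csv(out / "ce_to_se.tsv", sep="\t", index=False)
        self.states.astype(int).to_csv(out / "states.tsv", sep="\t",
                                       index_label="ce_id")
        self.cell_calls.to_csv(out / "cell_calls.tsv", sep="\t", index=False)
        self.cancer_calls.to_csv(out / "cancer_calls.tsv", sep="\t",
                                 index=False)
        self.se_summary.to_csv(out / "se_summary.tsv", sep="\t", index=False)
        self.sheet.to_tsv(out / "sample_sheet.tsv")
        if self.genes is not None:
            self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        meta = dict(self.metadata)
        meta["unassigned_ces"] = sorted(self.ce_to_se.unassigned)
        meta["tables"] = sorted(p.name for p in out.glob("*.tsv"))
        with open(out / "db.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, in_dir) -> "FingerprintDB":
        src = Path(in_dir)
        with open(src / "db.json") as fh:
            meta = json.load(fh)
        unassigned = meta.pop("unassigned_ces", [])
        meta.pop("tables", None)
        pairs = pd.read_csv(src / "ce_to_se.tsv", sep="\t", dtype=str)
        genes_path = src / "genes.tsv"
        str_cols = {"cells": str, "specific_active_ces": str,
                    "specific_inactive_ces": str, "cancer_type": str}
        return cls(
            se_regions=pd.read_csv(src / "se_regions.tsv", sep="\t",
                                   index_col="se_id"),
            ce_regions=pd.read_csv(src / "ce_regions.tsv", sep="\t",
                                   index_col="ce_id"),
            ce_to_se=CEtoSEMap(mapping=dict(zip(pairs["ce_id"],
                                                pairs["se_id"])),
                               unassigned=list(unassigned)),
            states=pd.read_csv(src / "states.tsv", sep="\t",
                               index_col="ce_id").astype(bool),
            cell_calls=pd.read_csv(src / "cell_calls.tsv", sep="\t",
                                   dtype=str, keep_default_na=False),
            cancer_calls=pd.read_csv(src / "cancer_calls.tsv", sep="\t",
                                     dtype=str, keep_default_na=False),
            se_summary=pd.read_csv(src / "se_summary.tsv", sep="\t",
                                   dtype=str, keep_default_na=False),
            sheet=SampleSheet.from_tsv(src / "sample_sheet.tsv"),
            genes=(pd.read_csv(genes_path, sep="\t")
                   if genes_path.exists() else None),
            metadata=meta,
        )


def build_db(
    se_regions: pd.DataFrame,
    ce_regions: pd.DataFrame,
    ce_to_se: CEtoSEMap,
    states: pd.DataFrame,
    cell_calls: pd.DataFrame,
    cancer_calls: pd.DataFrame,
    se_summary: pd.DataFrame,
    sheet: SampleSheet,
    genes: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> FingerprintDB:
    """Assemble and integrity-check a :class:`FingerprintDB`.

    Every call must reference an existing CE, every called CE must map to an
    existing SE, and every mapped SE must be in the SE table; dangling ids
    are rejected and listed.
    """
    for frame, name in ((se_regions, "se_regions"), (ce_regions,
                                                     "ce_regions")):
        missing = [c for c in _REGION_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} missing columns {missing}")
    called = set(cell_calls.get("ce_id", pd.Series(dtype=str))) \
        | set(cancer_calls.get("ce_id", pd.Series(dtype=str)))
    dangling = sorted(ce for ce in called if ce not in ce_regions.index)
    if dangling:
        raise ValueError(f"calls reference unknown CEs: {dangling}")
    unmapped = sorted(ce for ce in called if ce_to_se.se_of(ce) is None)
    if unmapped:
        raise ValueError(f"called CEs lack SE assignment: {unmapped}")
    bad_se = sorted({ce_to_se.se_of(ce) for ce in called}
                    - set(se_regions.index))
    if bad_se:
        raise ValueError(f"CE->SE map references unknown SEs: {bad_se}")
    return FingerprintDB(
        se_regions=se_regions, ce_regions=ce_regions, ce_to_se=ce_to_se,
        states=states.astype(bool), cell_calls=cell_calls,
        cancer_calls=cancer_calls, se_summary=se_summary, sheet=sheet,
        genes=genes, metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# queries


def _calls_with_se(db: FingerprintDB, calls: pd.DataFrame) -> pd.DataFrame:
    out = calls.copy()
    out["se_id"] = [db.ce_to_se.se_of(ce) for ce in out["ce_id"]]
    return out


def _se_records(db: FingerprintDB, sub: pd.DataFrame) -> list[dict]:
    records = []
    for se_id, grp in sub.groupby("se_id", sort=True):
        region = db.se_regions.loc[se_id]
        records.append({
            "se_id": se_id,
            "location": f"{region['chrom']}:{int(region['start'])}"
                        f"-{int(region['end'])}",
            "specific_active_ces": sorted(
                grp.loc[grp["mode"] == "specific_active", "ce_id"]),
            "specific_inactive_ces": sorted(
                grp.loc[grp["mode"] == "specific_inactive", "ce_id"]),
        })
    return records


def query(db: FingerprintDB, mode: str, key: str,
          gene_window: int = 50_000) -> dict:
    """Query the fingerprint database.

    Modes: ``cancer`` (cancer-specific active/inactive SEs of a cancer
    type), ``cell`` (SEs carrying cell-specific CEs in one cell line),
    ``gene`` (SEs within ``gene_window`` bp of the gene's TSS or overlapping
    its body, with per-cancer CE statuses) and ``location``
    (``chrom:start-end``; SEs intersecting the interval, with per-cancer CE
    statuses).  Unknown keys give an empty result with a warning; a
    malformed location is rejected.
    """
    if mode == "cancer":
        if key not in db.sheet.cancer_types:
            logger.warning("unknown cancer type %r", key)
            return {"cancer_type": key, "ses": []}
        sub = _calls_with_se(
            db, db.cancer_calls[db.cancer_calls["cancer_type"] == key])
        return {"cancer_type": key, "ses": _se_records(db, sub)}

    if mode == "cell":
        if key not in db.sheet.cell_lines:
            logger.warning("unknown cell line %r", key)
            return {"cell_line": key, "ses": []}
        hit = db.cell_calls["cells"].str.split(",").apply(lambda c: key in c)
        sub = _calls_with_se(db, db.cell_calls[hit])
        return {"cell_line": key, "ses": _se_records(db, sub)}

    if mode == "gene":
        if db.genes is None:
            raise ValueError("gene queries require a gene table")
        rows = db.genes[db.genes["gene"] == key]
        if rows.empty:
            logger.warning("unknown gene %r", key)
            return {"gene": key, "ses": []}
        g = rows.iloc[0]
        body_start = int(g.get("start", g["tss"]))
        body_end = int(g.get("end", g["tss"] + 1))
        win_lo = int(g["tss"]) - gene_window
        win_hi = int(g["tss"]) + gene_window
        lo = min(win_lo, body_start)
        hi = max(win_hi, body_end)
        ses = db.se_regions[
            (db.se_regions["chrom"] == g["chrom"])
            & (db.se_regions["start"] < hi)
            & (db.se_regions["end"] > lo)
        ]
        return {"gene": key, "window_bp": gene_window,
                "ses": _location_records(db, ses)}

    if mode == "location":
        match = _LOCATION_RE.match(key)
        if not match:
            raise ValueError(f"malformed location {key!r}; "
                             "expected chrom:start-end")
        chrom = match["chrom"]
        start, end = int(match["start"]), int(match["end"])
        if start >= end:
            raise ValueError(f"malformed location {key!r}: start >= end")
        ses = db.se_regions[
            (db.se_regions["chrom"] == chrom)
            & (db.se_regions["start"] < end)
            & (db.se_regions["end"] > start)
        ]
        return {"location": key, "ses": _location_records(db, ses)}

    raise ValueError(f"unknown query mode {mode!r}")


def _location_records(db: FingerprintDB, ses: pd.DataFrame) -> list[dict]:
    calls = _calls_with_se(db, db.cancer_calls) if len(db.cancer_calls) \
        else pd.DataFrame(columns=["ce_id", "mode", "cancer_type", "se_id"])
    records = []
    for se_id, region in ses.sort_index().iterrows():
        grp = calls[calls["se_id"] == se_id]
        statuses = [
            {"cancer_type": r.cancer_type, "ce_id": r.ce_id, "mode": r.mode}
            for r in grp.sort_values(["cancer_type", "ce_id"])
                        .itertuples(index=False)
        ]
        records.append({
            "se_id": se_id,
            "location": f"{region['chrom']}:{int(region['start'])}"
                        f"-{int(region['end'])}",
            "cancer_statuses": statuses,
        })
    return records


# ---------------------------------------------------------------------------
# exports


def export(db: FingerprintDB, what: str, path) -> None:
    """Export ``se_bed`` / ``ce_bed`` (BED6, name=uid, score=0, strand='.')
    or ``calls_json`` (cancer-specific calls keyed by cancer type)."""
    if what in ("se_bed", "ce_bed"):
        table = db.se_regions if what == "se_bed" else db.ce_regions
        rows = [(r["chrom"], int(r["start"]), int(r["end"]), uid, 0, ".")
                for uid, r in table.sort_values(_REGION_COLS).iterrows()]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        return
    if what == "calls_json":
        doc: dict[str, list] = {}
        for r in db.cancer_calls.sort_values(
                ["cancer_type", "ce_id", "mode"]).itertuples(index=False):
            doc.setdefault(r.cancer_type, []).append({
                "ce_id": r.ce_id,
                "se_id": db.ce_to_se.se_of(r.ce_id),
                "mode": r.mode,
                "cells": r.cells.split(",") if r.cells else [],
            })
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
        return
    raise ValueError(f"unknown export kind {what!r}")
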