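"""Readers and writers for the pipeline's plain-text table dialects.

All tables are UTF-8 with Unix newlines and '.' decimal separators
(Fiji exports under European locales emit commas; those must be
converted before ingestion).  TSV for gene-wise tables, long-format CSV
for profiles and measurements.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from apicobasal.polarity import PolarityMeasurement
from apicobasal.profiles import AxisProfile

logger = logging.getLogger(__name__)

#: default column names of an enrichment record table
ENRICHMENT_COLUMNS = ("gene_id", "log2fc", "p_value", "fdr", "loc_class")


class ColumnMappingError(ValueError):
    """A mapped column is missing from the input table."""


def write_enrichment_table(records: pd.DataFrame, path) -> None:
    """Write an enrichment record table as TSV (gene_id as a column)."""
    out = records.reset_index() if records.index.name == "gene_id" else records
    out.to_csv(path, sep="\t", index=False)


def read_enrichment_table(
    path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an enrichment record table, optionally remapping columns.

    ``column_map`` maps canonical names (``gene_id``, ``log2fc``,
    ``p_value``, ``fdr``, optionally ``loc_class``) to the file's column
    headers — this is how an externally produced differential table
    (e.g. a published processed supplementary table, where the user
    chooses which fold-change column feeds classification) is ingested.
    Rows with unparseable numeric values are rejected with their line
    numbers logged; an empty file yields an empty table with a warning.
    """
    try:
        raw = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty enrichment table", stacklevel=2)
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS))
    column_map = dict(column_map or {})
    mapping = {
        canonical: column_map.get(canonical, canonical)
        for canonical in ENRICHMENT_COLUMNS
    }
    for canonical in ("gene_id", "log2fc", "fdr"):
        if mapping[canonical] not in raw.columns:
            raise ColumnMappingError(
                f"column {mapping[canonical]!r} (for {canonical!r}) not in {path}"
            )
    out = pd.DataFrame({"gene_id": raw[mapping["gene_id"]].astype(str)})
    numeric_cols = ["log2fc", "fdr"]
    if mapping["p_value"] in raw.columns:
        numeric_cols.append("p_value")
    for canonical in numeric_cols:
        out[canonical] = pd.to_numeric(raw[mapping[canonical]], errors="coerce")
    if mapping["loc_class"] in raw.columns:
        out["loc_class"] = raw[mapping["loc_class"]]
    bad = out[[c for c in numeric_cols]].isna().any(axis=1)
    if bad.any():
        for line in (np.flatnonzero(bad) + 2):  # +2: header + 1-based
            logger.warning("%s: rejecting malformed row at line %d", path, line)
        out = out[~bad]
    ordered = [c for c in ENRICHMENT_COLUMNS if c in out.columns]
    return out[ordered].reset_index(drop=True)


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profiles(profiles: Sequence[AxisProfile], path) -> None:
    """Write profiles as long-format CSV (profile_id, channel, position, value)."""
    rows = []
    for p in profiles:
        for x, v in zip(p.positions, p.values):
            rows.append({"profile_id": p.profile_id, "channel": p.channel,
                         "position": x, "value": v})
    pd.DataFrame(rows, columns=["profile_id", "channel", "position", "value"]).to_csv(
        path, index=False
    )


def read_profiles(path) -> list[AxisProfile]:
    """Read long-format profile CSV back into AxisProfile objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    profiles = []
    for (pid, channel), sub in df.groupby(["profile_id", "channel"], sort=False):
        sub = sub.sort_values("position")
        profiles.append(
            AxisProfile(
                profile_id=str(pid),
                positions=sub["position"].to_numpy(),
                values=sub["value"].to_numpy(),
                channel=str(channel),
            )
        )
    return profiles


def write_measurements(measurements: Sequence[PolarityMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "group_id": m.group_id,
                "rna_id": m.rna_id,
                "condition": m.condition,
                "cell_type": m.cell_type,
                "apical_mfi": m.apical_mfi,
                "basal_mfi": m.basal_mfi,
                "bg_mfi": m.bg_mfi,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_measurements(path) -> list[PolarityMeasurement]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        PolarityMeasurement(
            group_id=str(r.group_id),
            apical_mfi=float(r.apical_mfi),
            basal_mfi=float(r.basal_mfi),
            bg_mfi=float(r.bg_mfi),
            cell_type=str(r.cell_type),
            condition=str(r.condition),
            rna_id=str(r.rna_id),
        )
        for r in df.itertuples(index=False)
    ]
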