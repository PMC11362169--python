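"""Peptide-level HDX state tables: parsing, validation, filtering, uptake.

The on-disk format mirrors a DynamX-style state-data CSV export
(``Protein, Start, End, Sequence, Score, State, Exposure, Replicate,
Center, MaxUptake``) with every column name remappable through a column
map.  In memory, tables are held in canonical lower-case columns.  All
residue coordinates are 1-based inclusive.

Validation never silently drops data: malformed rows go to a rejection
report, and every peptide excluded by a filter or a missing reference is
recorded in an audit log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UptakeTable",
    "DEFAULT_COLUMN_MAP",
    "PEPTIDE_KEY",
    "max_uptake",
    "read_state_table",
    "write_state_table",
    "filter_peptides",
    "uptake_from_centroids",
]

#: canonical name -> default CSV header (DynamX-style state export)
DEFAULT_COLUMN_MAP = {
    "protein": "Protein",
    "start": "Start",
    "end": "End",
    "sequence": "Sequence",
    "state": "State",
    "exposure": "Exposure",
    "replicate": "Replicate",
    "centroid": "Center",
    "score": "Score",
    "max_uptake": "MaxUptake",
}

REQUIRED = ["protein", "start", "end", "sequence", "state", "exposure",
            "replicate", "centroid"]

#: columns identifying a peptide
PEPTIDE_KEY = ["protein", "start", "end", "sequence"]
#: columns identifying a measurement row
ROW_KEY = PEPTIDE_KEY + ["state", "exposure", "replicate"]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: uptake below this (Da) is flagged as suspicious rather than an error
NEGATIVE_UPTAKE_FLAG = -0.5
#: relative uptake above this indicates an inconsistent max-uptake value
RELATIVE_UPTAKE_FLAG = 1.05


def max_uptake(sequence: str) -> int:
    """Exchangeable-amide count of a peptide.

    Convention: the first residue back-exchanges too fast to retain label
    and prolines carry no amide hydrogen, so the count is
    ``len − n_prolines − 1``, floored at zero.
    """
    seq = sequence.upper()
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"non-standard residue code(s) {sorted(bad)} in {sequence!r}")
    return max(len(seq) - seq.count("P") - 1, 0)


@dataclass
class UptakeTable:
    """Replicate-level peptide deuterium measurements.

    ``data`` uses canonical columns (:data:`DEFAULT_COLUMN_MAP` keys plus
    derived ``uptake`` / ``relative_uptake`` once computed); ``rejected``
    holds rows that failed validation with a ``reason`` column; ``audit``
    accumulates structured processing notes.
    """

    data: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)
    audit: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def peptides(self) -> pd.DataFrame:
        return self.data[PEPTIDE_KEY].drop_duplicates().reset_index(drop=True)

    @property
    def states(self) -> list[str]:
        return sorted(self.data["state"].unique())

    def note(self, stage: str, **info) -> None:
        self.audit.append({"stage": stage, **info})

    def write_audit(self, path) -> None:
        Path(path).write_text(json.dumps(self.audit, indent=2, default=str) + "\n")


def _validate_rows(df: pd.DataFrame) -> pd.Series:
    """Per-row rejection reason ('' = valid)."""
    reason = pd.Series("", index=df.index)

    def flag(mask, msg):
        bad = mask & (reason == "")
        reason[bad] = msg

    flag(df["end"] < df["start"], "end < start")
    flag(df["sequence"].str.len() != df["end"] - df["start"] + 1,
         "sequence length does not match start/end")
    flag(~df["sequence"].str.upper().str.fullmatch("[ACDEFGHIKLMNPQRSTVWY]+"),
         "non-standard residue code")
    flag(df["exposure"] < 0, "negative exposure")
    flag(~np.isfinite(df["centroid"]), "non-finite centroid")
    if "max_uptake" in df.columns:
        flag(df["max_uptake"] < 0, "negative max uptake")
    return reason


def read_state_table(path, column_map: dict | None = None) -> UptakeTable:
    """Read and validate a peptide-level state-data CSV.

    ``column_map`` maps canonical names to the file's headers and defaults
    to the DynamX-style layout.  Missing required columns raise; duplicate
    measurement keys raise; individually malformed rows are moved to the
    rejection report instead of being silently dropped.  A ``max_uptake``
    column is derived from the sequence when absent.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [cmap[k] for k in REQUIRED if cmap[k] not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    present = {v: k for k, v in cmap.items() if v in raw.columns}
    df = raw.rename(columns=present)[list(present.values())]
    df = df.astype({"start": int, "end": int, "exposure": float,
                    "centroid": float, "sequence": str, "protein": str,
                    "state": str})
    dup = df.duplicated(subset=ROW_KEY)
    if dup.any():
        raise ValueError(
            "duplicate measurement keys: "
            f"{df.loc[dup, ROW_KEY].head(5).to_dict('records')}")

    reason = _validate_rows(df)
    rejected = df[reason != ""].assign(reason=reason[reason != ""])
    good = df[reason == ""].reset_index(drop=True).copy()
    if "max_uptake" not in good.columns:
        good["max_uptake"] = good["sequence"].map(max_uptake)
    table = UptakeTable(good, rejected.reset_index(drop=True))
    table.note("read_state_table", path=str(path), rows=len(good),
               rejected=len(rejected))
    return table


def write_state_table(table: UptakeTable, path, column_map: dict | None = None) -> None:
    """Serialise a table back to the CSV layout given by ``column_map``."""
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    cols = [k for k in cmap if k in table.data.columns]
    out = table.data[cols].rename(columns={k: cmap[k] for k in cols})
    # %.17g keeps float64 values bit-exact through a write/read cycle
    out.to_csv(path, index=False, float_format="%.17g")


def filter_peptides(table: UptakeTable, min_score: float = 6.0,
                    min_replicates: int = 3, n_replicates: int = 4,
                    mode: str = "reference"):
    """Confidence filter: score strictly above ``min_score`` and identified
    in at least ``min_replicates`` of ``n_replicates`` replicates.

    ``mode="reference"`` (default) counts identifications in the
    non-deuterated reference runs (exposure 0) per state; ``"per_exposure"``
    demands the replicate quorum at every exposure.  Returns
    ``(filtered_table, audit_entries)``; every exclusion is recorded with
    its reason.
    """
    if mode not in ("reference", "per_exposure"):
        raise ValueError(f"unknown mode {mode!r}")
    df = table.data
    audit = []
    keep_keys = []
    for key, grp in df.groupby(PEPTIDE_KEY, sort=False):
        peptide = dict(zip(PEPTIDE_KEY, key))
        score = grp["score"].max() if "score" in grp.columns else np.nan
        if not np.isnan(score) and not score > min_score:
            audit.append({**peptide, "excluded": True,
                          "reason": f"score {score:g} not > {min_score:g}"})
            continue
        if mode == "reference":
            counts = (grp[grp["exposure"] == 0]
                      .groupby("state")["replicate"].nunique())
        else:
            counts = grp.groupby(["state", "exposure"])["replicate"].nunique()
        if len(counts) == 0 or (counts < min_replicates).any():
            k = int(counts.min()) if len(counts) else 0
            audit.append({**peptide, "excluded": True,
                          "reason": f"identified in {k}/{n_replicates} replicates"})
            continue
        keep_keys.append(key)

    idx = pd.MultiIndex.from_frame(df[PEPTIDE_KEY])
    mask = idx.isin(keep_keys)
    out = UptakeTable(df[mask].reset_index(drop=True), table.rejected,
                      list(table.audit))
    out.note("filter_peptides", kept=len(keep_keys),
             excluded=len(audit), min_score=min_score,
             min_replicates=min_replicates, mode=mode)
    out.audit.extend(audit)
    return out, audit


def uptake_from_centroids(table: UptakeTable, reference_state: str | None = None,
                          per_state_reference: bool = True) -> UptakeTable:
    """Derive deuterium uptake from centroid masses.

    The non-deuterated reference for a peptide is the mean exposure-0
    centroid (per state by default, or taken from ``reference_state``).
    ``uptake = centroid(t) − reference`` in Da and ``relative_uptake =
    uptake / max_uptake``; negative uptake is permitted (noise) but values
    below −0.5 Da, and relative uptake above 1.05, are flagged.  Peptides
    without a reference are excluded with an audit entry.
    """
    df = table.data.copy()
    ref_rows = df[df["exposure"] == 0]
    if reference_state is not None:
        ref_rows = ref_rows[ref_rows["state"] == reference_state]
        ref = ref_rows.groupby(PEPTIDE_KEY)["centroid"].mean()
        join_key = PEPTIDE_KEY
    elif per_state_reference:
        ref = ref_rows.groupby(PEPTIDE_KEY + ["state"])["centroid"].mean()
        join_key = PEPTIDE_KEY + ["state"]
    else:
        ref = ref_rows.groupby(PEPTIDE_KEY)["centroid"].mean()
        join_key = PEPTIDE_KEY

    ref = ref.rename("reference_centroid").reset_index()
    merged = df.merge(ref, on=join_key, how="left")
    missing = merged["reference_centroid"].isna()
    audit = []
    if missing.any():
        for key in merged.loc[missing, PEPTIDE_KEY].drop_duplicates().to_dict("records"):
            audit.append({**key, "excluded": True, "reason": "no non-deuterated reference"})
    good = merged[~missing].reset_index(drop=True).copy()
    good["uptake"] = good["centroid"] - good["reference_centroid"]
    with np.errstate(divide="ignore", invalid="ignore"):
        good["relative_uptake"] = np.where(good["max_uptake"] > 0,
                                           good["uptake"] / good["max_uptake"],
                                           np.nan)
    good["flag_negative"] = good["uptake"] < NEGATIVE_UPTAKE_FLAG
    good["flag_overshoot"] = good["relative_uptake"] > RELATIVE_UPTAKE_FLAG

    out = UptakeTable(good, table.rejected, list(table.audit))
    out.note("uptake_from_centroids", rows=len(good),
             excluded_peptides=len(audit),
             flagged_negative=int(good["flag_negative"].sum()),
             flagged_overshoot=int(good["flag_overshoot"].sum()))
    out.audit.extend(audit)
    return out
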