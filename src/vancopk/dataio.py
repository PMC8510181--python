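"""NONMEM-style CSV dataset exchange.

One row per event. Dose rows: EVID=1, AMT (mg) > 0, RATE (mg/h), MDV=1.
Observation rows: EVID=0, MDV=0, DV (ug/mL). TIME in hours since the first
dose, non-decreasing within subject. Covariate columns (constant within a
subject/episode): WT kg, HT cm, AGE months, SEX (male=1), SCR mg/dL, DFLT
days, ALB g/dL, ALT U/L, UD (biliary atresia=1). Missing values are ".".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk_core import CovariateSet, DoseEvent, Observation, SubjectRecord

__all__ = ["PKDatasetDialect", "DatasetError", "read_dataset", "write_dataset", "records_to_frame"]

REQUIRED = ["ID", "TIME", "DV", "AMT", "RATE", "EVID", "MDV"]
COVARIATE_COLUMNS = ["WT", "HT", "AGE", "SEX", "SCR", "DFLT", "ALB", "ALT", "UD"]


class DatasetError(ValueError):
    """Schema or row-level dataset validation failure."""


@dataclass(frozen=True)
class PKDatasetDialect:
    missing_token: str = "."
    bql_column: str = "BQL"  # optional flag column, written when any obs is flagged


def records_to_frame(records: list[SubjectRecord], dialect: PKDatasetDialect | None = None) -> pd.DataFrame:
    dialect = dialect or PKDatasetDialect()
    rows = []
    any_bql = any(o.below_quantification for r in records for o in r.observations)
    for r in records:
        c = r.covariates
        cov = {
            "WT": c.weight, "HT": c.height, "AGE": c.age,
            "SEX": 1 if c.sex == "male" else 0,
            "SCR": c.scr, "DFLT": c.dflt, "ALB": c.albumin, "ALT": c.alt,
            "UD": 1 if c.underlying_disease == "biliary_atresia" else 0,
        }
        events = [("dose", d.start_time, d) for d in r.doses] + [
            ("obs", o.time, o) for o in r.observations
        ]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, t, e in events:
            row = {"ID": r.subject_id, "TIME": t, **cov}
            if kind == "dose":
                row.update(DV=np.nan, AMT=e.amount, RATE=e.rate, EVID=1, MDV=1)
                if any_bql:
                    row[dialect.bql_column] = 0
            else:
                row.update(DV=e.concentration, AMT=np.nan, RATE=np.nan, EVID=0, MDV=0)
                if any_bql:
                    row[dialect.bql_column] = int(e.below_quantification)
            rows.append(row)
    cols = REQUIRED + COVARIATE_COLUMNS + ([dialect.bql_column] if any_bql else [])
    return pd.DataFrame(rows)[cols]


def write_dataset(records: list[SubjectRecord], path, dialect: PKDatasetDialect | None = None):
    """Write records as CSV, numeric fields at 6 significant digits."""
    dialect = dialect or PKDatasetDialect()
    frame = records_to_frame(records, dialect)
    frame.to_csv(path, index=False, float_format="%.6g", na_rep=dialect.missing_token)
    return path


def read_dataset(path, dialect: PKDatasetDialect | None = None) -> list[SubjectRecord]:
    """Read and validate a NONMEM-style CSV into subject records.

    Every invariant violation is reported with its (1-based, header-exclusive)
    row number; all violations are collected into a single error.
    """
    dialect = dialect or PKDatasetDialect()
    try:
        frame = pd.read_csv(path, na_values=[dialect.missing_token], dtype={"ID": str})
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: empty dataset")
    missing = [c for c in REQUIRED + COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise DatasetError(f"{path}: empty dataset")

    errors: list[str] = []
    has_bql = dialect.bql_column in frame.columns
    records: list[SubjectRecord] = []
    for sid, group in frame.groupby("ID", sort=False):
        times = group["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            bad = group.index[1:][np.diff(times) < 0]
            errors.append(f"row {bad[0] + 1}: TIME decreases within subject {sid}")
        first = group.iloc[0]
        try:
            cov = CovariateSet(
                weight=float(first["WT"]),
                height=float(first["HT"]),
                age=float(first["AGE"]),
                sex="male" if int(first["SEX"]) == 1 else "female",
                scr=float(first["SCR"]),
                dflt=float(first["DFLT"]),
                albumin=float(first["ALB"]),
                alt=float(first["ALT"]),
                underlying_disease="biliary_atresia" if int(first["UD"]) == 1 else "other",
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {first.name + 1}: invalid covariates for {sid}: {exc}")
            continue
        doses, obs = [], []
        for ridx, row in group.iterrows():
            evid = int(row["EVID"])
            try:
                if evid == 1:
                    if not (row["AMT"] > 0):
                        errors.append(f"row {ridx + 1}: dose row needs AMT > 0 (subject {sid})")
                        continue
                    if int(row["MDV"]) != 1:
                        errors.append(f"row {ridx + 1}: dose row must have MDV=1 (subject {sid})")
                        continue
                    rate = row["RATE"]
                    duration = float(row["AMT"]) / float(rate) if rate and rate > 0 else 1.0
                    doses.append(DoseEvent(float(row["TIME"]), float(row["AMT"]), duration))
                elif evid == 0:
                    if int(row["MDV"]) != 0 or pd.isna(row["DV"]):
                        errors.append(
                            f"row {ridx + 1}: observation row needs MDV=0 and DV present (subject {sid})"
                        )
                        continue
                    if pd.notna(row["AMT"]) and row["AMT"] > 0:
                        errors.append(
                            f"row {ridx + 1}: observation row (EVID=0) cannot carry a dose AMT (subject {sid})"
                        )
                        continue
                    bql = bool(int(row[dialect.bql_column])) if has_bql and pd.notna(row.get(dialect.bql_column)) else False
                    obs.append(Observation(float(row["TIME"]), float(row["DV"]), bql))
                else:
                    errors.append(f"row {ridx + 1}: unsupported EVID={evid} (subject {sid})")
            except ValueError as exc:
                errors.append(f"row {ridx + 1}: {exc} (subject {sid})")
        try:
            records.append(SubjectRecord(str(sid), cov, doses, obs))
        except ValueError as exc:
            errors.append(f"subject {sid}: {exc}")
    if errors:
        raise DatasetError(f"{path}: " + "; ".join(errors[:20]))
    return records
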