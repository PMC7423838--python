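"""CSV readers/writers and feature-table assembly.

File formats (comma-separated, UTF-8, header row, "." decimal separator):

* DVH CSV, long format: ``patient_id, structure, dose_gy, volume_fraction``.
* Clinical CSV, one row per patient: ``patient_id, age, sex, kps,
  smoking_status, pack_years, a2m_mg_dl, chemo_timing, rt_modality,
  total_dose_gy, fraction_number, treatment_days, subtype`` plus one
  ``grade_<endpoint>`` column per toxicity endpoint.
* Feature CSV, one row per patient: dosimetric columns
  ``{structure}_D{x}``, ``{structure}_mean``, ``{structure}_max`` (EQD2 Gy),
  fractional columns ``{structure}_fD{x}``, ``..._fmean``, ``..._fmax``
  (Gy/day), clinical covariates in native units, and per endpoint the
  ordinal ``grade_<endpoint>`` plus binary ``<endpoint>_ge2`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dvh import DEFAULT_ALPHA_BETA, DEFAULT_DX_GRID, DVHCurve, EQD2Params, summarize_structure
from .errors import DataError, SchemaError, ValidationError
from .records import ClinicalRecord

DVH_COLUMNS = ("patient_id", "structure", "dose_gy", "volume_fraction")
CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "kps",
    "smoking_status",
    "pack_years",
    "a2m_mg_dl",
    "chemo_timing",
    "rt_modality",
    "total_dose_gy",
    "fraction_number",
    "treatment_days",
    "subtype",
)

#: Clinical covariates emitted as numeric feature columns.
CLINICAL_FEATURES = (
    "age",
    "sex",
    "kps",
    "smoking_ordinal",
    "ever_smoker",
    "pack_years",
    "a2m_mg_dl",
    "chemo",
    "sbrt",
    "total_dose_gy",
    "dose_per_fraction",
    "fraction_number",
    "treatment_days",
)


@dataclass
class FeatureTable:
    """Patients x features matrix with endpoint labels.

    ``data`` is indexed by patient id.  Dosimetric and clinical feature
    names are tracked so downstream stages (decorrelation is restricted to
    dosimetric variables) can tell them apart.
    """

    data: pd.DataFrame
    dosimetric: list[str]
    clinical: list[str]
    endpoints: list[str]

    def __post_init__(self) -> None:
        missing = [
            c for c in (*self.dosimetric, *self.clinical) if c not in self.data.columns
        ]
        if missing:
            raise SchemaError(f"feature columns missing from table: {missing}")
        feat = self.data[[*self.dosimetric, *self.clinical]]
        if feat.isna().any().any():
            bad = feat.columns[feat.isna().any()].tolist()
            raise ValidationError(f"missing values in feature columns: {bad}")
        for ep in self.endpoints:
            grade_col, bin_col = f"grade_{ep}", f"{ep}_ge2"
            if grade_col in self.data.columns and bin_col in self.data.columns:
                expected = (self.data[grade_col] >= 2).astype(int)
                if not (self.data[bin_col] == expected).all():
                    raise ValidationError(
                        f"binary column {bin_col} inconsistent with {grade_col}"
                    )

    @property
    def feature_names(self) -> list[str]:
        return [*self.dosimetric, *self.clinical]

    def grades(self, endpoint: str) -> pd.Series:
        col = f"grade_{endpoint}"
        if col not in self.data.columns:
            raise DataError(f"no grade column for endpoint {endpoint!r}")
        return self.data[col]

    def binary(self, endpoint: str) -> pd.Series:
        col = f"{endpoint}_ge2"
        if col not in self.data.columns:
            raise DataError(f"no binary outcome column for endpoint {endpoint!r}")
        return self.data[col]


# ---------------------------------------------------------------------------
# DVH CSV


def write_dvh_csv(curves: Iterable[DVHCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": c.patient_id,
                    "structure": c.structure,
                    "dose_gy": c.dose_gy,
                    "volume_fraction": c.volume_fraction,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dvh_csv(path: str | Path) -> list[DVHCurve]:
    """Read a long-format DVH CSV into validated curves.

    Rows are grouped by (patient_id, structure) preserving file order;
    each group must satisfy the cumulative-DVH invariants.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse DVH CSV {path}: {exc}") from exc
    missing = [c for c in DVH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"DVH CSV {path} missing columns: {missing}")
    for col in ("dose_gy", "volume_fraction"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = (df.index[bad | df[col].isna()] + 2).tolist()[:5]
            raise ValidationError(f"non-numeric {col} in {path} at line(s) {rows}")
        df[col] = pd.to_numeric(df[col])
    curves = []
    for (pid, struct), grp in df.groupby(["patient_id", "structure"], sort=False):
        curves.append(
            DVHCurve(
                patient_id=str(pid),
                structure=str(struct),
                dose_gy=grp["dose_gy"].to_numpy(),
                volume_fraction=grp["volume_fraction"].to_numpy(),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Clinical CSV


def write_clinical_csv(
    records: Sequence[ClinicalRecord],
    path: str | Path,
    grades: pd.DataFrame | None = None,
) -> None:
    """Write clinical records, optionally with per-endpoint grade columns.

    ``grades`` is indexed by patient id with one column per endpoint.
    """
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in CLINICAL_COLUMNS}
        if grades is not None:
            for ep in grades.columns:
                row[f"grade_{ep}"] = int(grades.loc[r.patient_id, ep])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical_csv(
    path: str | Path,
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """Read clinical records and any ``grade_*`` endpoint columns."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse clinical CSV {path}: {exc}") from exc
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical CSV {path} missing columns: {missing}")
    grade_cols = [c for c in df.columns if c.startswith("grade_")]
    records = []
    for _, row in df.iterrows():
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                kps=float(row["kps"]),
                smoking_status=str(row["smoking_status"]),
                pack_years=float(row["pack_years"]),
                a2m_mg_dl=float(row["a2m_mg_dl"]),
                chemo_timing=str(row["chemo_timing"]),
                rt_modality=str(row["rt_modality"]),
                total_dose_gy=float(row["total_dose_gy"]),
                fraction_number=int(row["fraction_number"]),
                treatment_days=int(row["treatment_days"]),
                subtype=str(row["subtype"]),
            )
        )
    grades = pd.DataFrame(
        {c.removeprefix("grade_"): df[c].astype(int).to_numpy() for c in grade_cols},
        index=pd.Index([r.patient_id for r in records], name="patient_id"),
    )
    for ep in grades.columns:
        vals = grades[ep]
        if ((vals < 0) | (vals > 5)).any():
            raise ValidationError(f"grades for endpoint {ep!r} outside 0..5 in {path}")
    return records, grades


# ---------------------------------------------------------------------------
# Feature assembly


def clinical_feature_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Numeric encoding of clinical covariates (one row per patient)."""
    rows = {}
    for r in records:
        rows[r.patient_id] = {
            "age": r.age,
            "sex": float(r.sex == "female"),
            "kps": r.kps,
            "smoking_ordinal": float(r.smoking_ordinal),
            "ever_smoker": float(r.smoking_status != "never"),
            "pack_years": r.pack_years,
            "a2m_mg_dl": r.a2m_mg_dl,
            "chemo": float(r.has_chemo),
            "sbrt": float(r.is_sbrt),
            "total_dose_gy": r.total_dose_gy,
            "dose_per_fraction": r.dose_per_fraction,
            "fraction_number": float(r.fraction_number),
            "treatment_days": float(r.treatment_days),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def build_feature_table(
    dvhs: Sequence[DVHCurve],
    records: Sequence[ClinicalRecord],
    grades: pd.DataFrame | None = None,
    alpha_beta: Mapping[str, float] | None = None,
    dx_grid: Sequence[int] = DEFAULT_DX_GRID,
    fractional_structures: Sequence[str] = ("esophagus",),
    fractional_on_physical: bool = True,
) -> FeatureTable:
    """Assemble the patients x features matrix from DVHs and clinical data.

    Every patient must have a DVH for every structure present in the input
    and a clinical record; fail-fast on anything missing.
    """
    alpha_beta = dict(DEFAULT_ALPHA_BETA if alpha_beta is None else alpha_beta)
    by_patient = {r.patient_id: r for r in records}
    if len(by_patient) != len(records):
        raise ValidationError("duplicate patient ids in clinical records")

    structures = sorted({c.structure for c in dvhs})
    for s in structures:
        if s not in alpha_beta:
            raise SchemaError(f"no alpha/beta ratio configured for structure {s!r}")

    rows: dict[str, dict[str, float]] = {pid: {} for pid in by_patient}
    seen: set[tuple[str, str]] = set()
    for curve in dvhs:
        rec = by_patient.get(curve.patient_id)
        if rec is None:
            raise DataError(f"DVH for unknown patient {curve.patient_id!r}")
        key = (curve.patient_id, curve.structure)
        if key in seen:
            raise ValidationError(f"duplicate DVH for {key}")
        seen.add(key)
        params = EQD2Params(alpha_beta[curve.structure], rec.fraction_number)
        metrics = summarize_structure(
            curve,
            params,
            rec.treatment_days,
            dx_grid=dx_grid,
            include_fractional=curve.structure in fractional_structures,
            fractional_on_physical=fractional_on_physical,
        )
        row = rows[curve.patient_id]
        s = curve.structure
        for x, v in metrics.dx.items():
            row[f"{s}_D{x}"] = v
        row[f"{s}_mean"] = metrics.mean_dose
        row[f"{s}_max"] = metrics.max_dose
        if metrics.fdx is not None:
            for x, v in metrics.fdx.items():
                row[f"{s}_fD{x}"] = v
            row[f"{s}_fmean"] = metrics.fmean
            row[f"{s}_fmax"] = metrics.fmax

    for pid in by_patient:
        have = {s for p, s in seen if p == pid}
        if have != set(structures):
            raise DataError(
                f"patient {pid!r} missing DVHs for structures {sorted(set(structures) - have)}"
            )

    dosi = pd.DataFrame.from_dict(rows, orient="index")
    dosi.index.name = "patient_id"
    clin = clinical_feature_frame(records)
    data = dosi.join(clin, how="inner")

    endpoints: list[str] = []
    if grades is not None:
        for ep in grades.columns:
            aligned = grades[ep].reindex(data.index)
            if aligned.isna().any():
                raise DataError(f"missing grades for endpoint {ep!r}")
            data[f"grade_{ep}"] = aligned.astype(int)
            data[f"{ep}_ge2"] = (aligned >= 2).astype(int)
            endpoints.append(ep)

    return FeatureTable(
        data=data,
        dosimetric=list(dosi.columns),
        clinical=list(clin.columns),
        endpoints=endpoints,
    )


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, index=True)


def read_feature_csv(path: str | Path) -> FeatureTable:
    """Read a feature CSV written by :func:`write_feature_csv`.

    Dosimetric columns are recognised by the ``{structure}_D/mean/max``
    naming pattern; ``grade_*`` columns define the endpoints.
    """
    df = pd.read_csv(path, index_col="patient_id")
    df.index = df.index.astype(str)
    endpoints = [c.removeprefix("grade_") for c in df.columns if c.startswith("grade_")]
    clinical = [c for c in CLINICAL_FEATURES if c in df.columns]
    special = set(clinical) | {f"grade_{e}" for e in endpoints} | {f"{e}_ge2" for e in endpoints}
    dosimetric = [c for c in df.columns if c not in special]
    return FeatureTable(df, dosimetric=dosimetric, clinical=clinical, endpoints=endpoints)
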