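"""CSV readers/writers for the package's table dialects.

Three long-format tables carry a campaign:

* chemical table — ``cas, name, class, molecular_weight_g_mol, auc,
  eef, bcf_l_per_kg, override``
* assay table — ``cas, assay_id, acc_log10_uM, active, flags``
  (``active`` 0/1, ``flags`` semicolon-delimited)
* sample table — ``sample_id, site_id, matrix, species, sex, year,
  cas, value, unit, detected, loq`` (one row per measurement)

Long format was chosen because analyte panels differ across the studies
a campaign aggregates; a wide table would be mostly holes.  Readers
validate schema up front (unknown units for a matrix, duplicated
(sample_id, cas) pairs) and name the offending file/row in errors.
Writers and readers round-trip losslessly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from estromix.bioactivity import AssayActivity, ChemicalRecord, Override
from estromix.exposure import MATRIX_UNITS, Measurement, Sample

CHEMICAL_COLUMNS = [
    "cas",
    "name",
    "class",
    "molecular_weight_g_mol",
    "auc",
    "eef",
    "bcf_l_per_kg",
    "override",
]
ASSAY_COLUMNS = ["cas", "assay_id", "acc_log10_uM", "active", "flags"]
SAMPLE_COLUMNS = [
    "sample_id",
    "site_id",
    "matrix",
    "species",
    "sex",
    "year",
    "cas",
    "value",
    "unit",
    "detected",
    "loq",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _opt(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def chemicals_to_frame(chemicals: Mapping[str, ChemicalRecord]) -> pd.DataFrame:
    rows = []
    for c in chemicals.values():
        rows.append(
            {
                "cas": c.cas,
                "name": c.name,
                "class": c.chem_class,
                "molecular_weight_g_mol": c.molecular_weight,
                "auc": c.auc_score,
                "eef": c.eef,
                "bcf_l_per_kg": c.bcf_tissue_water,
                "override": c.override_status.value if c.override_status else "",
            }
        )
    return pd.DataFrame(rows, columns=CHEMICAL_COLUMNS)


def frame_to_chemicals(df: pd.DataFrame, path="<frame>") -> dict[str, ChemicalRecord]:
    _require_columns(df, CHEMICAL_COLUMNS, path)
    out: dict[str, ChemicalRecord] = {}
    for i, rec in enumerate(df.to_dict("records")):
        cas = str(rec["cas"])
        if cas in out:
            raise ValueError(f"{path}: row {i}: duplicate chemical {cas}")
        override = _opt(rec["override"])
        out[cas] = ChemicalRecord(
            cas=cas,
            name=str(_opt(rec["name"]) or ""),
            chem_class=str(_opt(rec["class"]) or ""),
            molecular_weight=_opt(rec["molecular_weight_g_mol"]),
            auc_score=_opt(rec["auc"]),
            eef=_opt(rec["eef"]),
            bcf_tissue_water=_opt(rec["bcf_l_per_kg"]),
            override_status=Override(override) if override else None,
        )
    return out


def read_chemicals(path) -> dict[str, ChemicalRecord]:
    return frame_to_chemicals(pd.read_csv(path, float_precision="round_trip"), path)


def write_chemicals(chemicals: Mapping[str, ChemicalRecord], path) -> None:
    chemicals_to_frame(chemicals).to_csv(path, index=False, float_format="%.17g")


def assays_to_frame(assays: Iterable[AssayActivity]) -> pd.DataFrame:
    rows = [
        {
            "cas": a.cas,
            "assay_id": a.assay_id,
            "acc_log10_uM": a.acc_log10_uM,
            "active": int(a.active),
            "flags": ";".join(sorted(a.quality_flags)),
        }
        for a in assays
    ]
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def frame_to_assays(df: pd.DataFrame, path="<frame>") -> list[AssayActivity]:
    _require_columns(df, ASSAY_COLUMNS, path)
    out = []
    for i, rec in enumerate(df.to_dict("records")):
        flags = _opt(rec["flags"])
        try:
            out.append(
                AssayActivity(
                    cas=str(rec["cas"]),
                    assay_id=str(rec["assay_id"]),
                    acc_log10_uM=_opt(rec["acc_log10_uM"]),
                    active=bool(int(rec["active"])),
                    quality_flags=(
                        frozenset(str(flags).split(";")) if flags else frozenset()
                    ),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return out


def read_assays(path) -> list[AssayActivity]:
    return frame_to_assays(pd.read_csv(path, float_precision="round_trip"), path)


def write_assays(assays: Iterable[AssayActivity], path) -> None:
    assays_to_frame(assays).to_csv(path, index=False, float_format="%.17g")


def samples_to_frame(samples: Iterable[Sample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for m in s.measurements:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "site_id": s.site_id,
                    "matrix": s.matrix,
                    "species": s.species or "",
                    "sex": s.sex or "",
                    "year": s.year,
                    "cas": m.cas,
                    "value": m.value,
                    "unit": m.unit,
                    "detected": int(m.detected),
                    "loq": m.loq,
                }
            )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def frame_to_samples(df: pd.DataFrame, path="<frame>") -> list[Sample]:
    _require_columns(df, SAMPLE_COLUMNS, path)
    dupes = df.duplicated(subset=["sample_id", "cas"], keep=False)
    if dupes.any():
        first = df.loc[dupes, ["sample_id", "cas"]].iloc[0]
        raise ValueError(
            f"{path}: duplicated (sample_id, cas) pair "
            f"({first['sample_id']}, {first['cas']})"
        )
    samples: list[Sample] = []
    for (sample_id,), grp in df.groupby(["sample_id"], sort=True):
        meta = grp.iloc[0]
        matrix = str(meta["matrix"])
        if matrix not in MATRIX_UNITS:
            raise ValueError(f"{path}: sample {sample_id}: unknown matrix {matrix!r}")
        measurements = []
        for i, rec in grp.iterrows():
            unit = str(rec["unit"])
            if unit != MATRIX_UNITS[matrix]:
                raise ValueError(
                    f"{path}: row {i} (sample {sample_id}, {rec['cas']}): unit "
                    f"{unit} not permitted in matrix {matrix} "
                    f"(expected {MATRIX_UNITS[matrix]})"
                )
            try:
                measurements.append(
                    Measurement(
                        cas=str(rec["cas"]),
                        value=_opt(rec["value"]),
                        unit=unit,
                        detected=bool(int(rec["detected"])),
                        loq=_opt(rec["loq"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
        samples.append(
            Sample(
                sample_id=str(sample_id),
                site_id=str(meta["site_id"]),
                matrix=matrix,
                year=int(meta["year"]),
                measurements=tuple(measurements),
                species=str(_opt(meta["species"]) or "") or None,
                sex=str(_opt(meta["sex"]) or "") or None,
            )
        )
    return samples


def read_samples(path) -> list[Sample]:
    return frame_to_samples(pd.read_csv(path, float_precision="round_trip"), path)


def write_samples(samples: Iterable[Sample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def detection_frequency(samples: Iterable[Sample]) -> pd.DataFrame:
    """Detection frequency and detected-concentration range per chemical
    and matrix.

    DF = detected / analyzed × 100, computed within each matrix over the
    samples where the chemical was analyzed at all; matrices where a
    chemical was never analyzed produce no row.  Ranges are in the
    matrix's native unit.
    """
    rows = []
    for s in samples:
        for m in s.measurements:
            rows.append(
                {
                    "cas": m.cas,
                    "matrix": s.matrix,
                    "detected": m.detected,
                    "value": m.value if m.detected else None,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["cas", "matrix", "n_analyzed", "n_detected", "df_pct",
                     "min_detected", "max_detected"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["cas", "matrix"])
        .agg(
            n_analyzed=("detected", "size"),
            n_detected=("detected", "sum"),
            min_detected=("value", "min"),
            max_detected=("value", "max"),
        )
        .reset_index()
    )
    out["df_pct"] = 100.0 * out["n_detected"] / out["n_analyzed"]
    return out[
        ["cas", "matrix", "n_analyzed", "n_detected", "df_pct",
         "min_detected", "max_detected"]
    ]
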