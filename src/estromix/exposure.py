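"""Exposure-activity ratios (EARs) from monitoring measurements.

An EAR divides an environmental concentration by the chemical's ACC5
potency; summing EARs over a sample's detected e-EDCs (concentration
addition) gives the mixture score ``EAR_mix``.

Matrix handling
---------------
* marine water / WWTP effluent — measured in ng/L, used directly after
  conversion to µg/L;
* mussel / fish tissue — ng/g wet weight, back-calculated to a water
  concentration with a tissue-water bioconcentration factor (BCF, L/kg);
* fish bile — ng/mL, used *directly* (numerically identical to µg/L);
  comparability with effect benchmarks is restored downstream by the
  bile-specific thresholds, not by a BCF translation here.

Non-detects contribute zero to ``EAR_mix`` (no ½-LOQ substitution).
Bile EARs are interpreted for exogenous exposure only, so female fish —
which carry physiological levels of endogenous steroidal estrogens —
should be excluded up front with :func:`exclude_female_bile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from estromix.bioactivity import Acc5Record, ChemicalRecord, EstrogenicityStatus, Status

WATER_MATRICES = ("marine_water", "wwtp_effluent")
TISSUE_MATRICES = ("mussel_tissue", "fish_tissue")
MATRICES = WATER_MATRICES + TISSUE_MATRICES + ("bile",)

#: Permissible concentration unit per matrix.
MATRIX_UNITS: dict[str, str] = {
    "marine_water": "ng_per_L",
    "wwtp_effluent": "ng_per_L",
    "mussel_tissue": "ng_per_g",
    "fish_tissue": "ng_per_g",
    "bile": "ng_per_mL",
}


@dataclass(frozen=True)
class Measurement:
    """One chemical concentration in one sample, possibly censored."""

    cas: str
    value: Optional[float]  # native unit; None for non-detects
    unit: str
    detected: bool
    loq: Optional[float] = None  # same native unit

    def __post_init__(self) -> None:
        if self.unit not in set(MATRIX_UNITS.values()):
            raise ValueError(f"unknown unit {self.unit!r} for {self.cas}")
        if self.detected:
            if self.value is None or self.value < 0:
                raise ValueError(
                    f"detected measurement for {self.cas} requires value >= 0, "
                    f"got {self.value}"
                )


@dataclass(frozen=True)
class Sample:
    """A monitoring observation: one site visit, one matrix, many analytes."""

    sample_id: str
    site_id: str
    matrix: str
    year: int
    measurements: tuple[Measurement, ...] = field(default_factory=tuple)
    species: Optional[str] = None
    sex: Optional[str] = None  # male | female | unknown

    def __post_init__(self) -> None:
        if self.matrix not in MATRIX_UNITS:
            raise ValueError(f"unknown matrix {self.matrix!r} in {self.sample_id}")
        expected = MATRIX_UNITS[self.matrix]
        for m in self.measurements:
            if m.unit != expected:
                raise ValueError(
                    f"sample {self.sample_id}: measurement {m.cas} has unit "
                    f"{m.unit} but matrix {self.matrix} requires {expected}"
                )


@dataclass(frozen=True)
class EarTable:
    """Per-chemical and per-sample EAR results.

    ``per_chemical`` columns: sample_id, site_id, matrix, cas, ear_acc5,
    pct_contribution.  ``per_sample`` columns: sample_id, site_id,
    matrix, ear_mix.  Contributions are on the EAR scale and sum to 100
    within each sample whose ``ear_mix`` is positive.
    """

    per_chemical: pd.DataFrame
    per_sample: pd.DataFrame


def exclude_female_bile(samples: Iterable[Sample]) -> list[Sample]:
    """Drop bile samples not confirmed male (endogenous-estrogen confound)."""
    return [s for s in samples if s.matrix != "bile" or s.sex == "male"]


def to_water_equivalent(
    m: Measurement, chem: Optional[ChemicalRecord], matrix: str
) -> float:
    """Convert a detected measurement to µg/L (water-equivalent).

    ng/L → value/1000; bile ng/mL → value unchanged (ng/mL ≡ µg/L);
    tissue ng/g wet weight → treated as µg/kg and divided by the
    chemical's BCF (L/kg), yielding µg/L.
    """
    if not m.detected:
        raise ValueError(f"cannot convert non-detect for {m.cas}")
    if matrix in WATER_MATRICES:
        return m.value / 1000.0
    if matrix == "bile":
        return float(m.value)
    if matrix in TISSUE_MATRICES:
        if chem is None or chem.bcf_tissue_water is None:
            raise ValueError(
                f"tissue measurement for {m.cas} requires a tissue-water BCF; "
                "none is available (chemical outside the BCF applicability "
                "domain must be excluded from tissue EARs)"
            )
        if not chem.bcf_tissue_water > 0:
            raise ValueError(f"BCF for {m.cas} must be > 0")
        return float(m.value) / chem.bcf_tissue_water
    raise ValueError(f"unknown matrix {matrix!r}")


def compute_ear(conc_ug_L: float, acc5_ug_L: float) -> float:
    """EAR = measured (water-equivalent) concentration / ACC5, both µg/L."""
    if not acc5_ug_L > 0:
        raise ValueError(f"acc5_ug_L must be > 0, got {acc5_ug_L}")
    if conc_ug_L == 0:
        return 0.0
    return conc_ug_L / acc5_ug_L


def compute_ear_table(
    samples: Sequence[Sample],
    acc5: Mapping[str, Acc5Record],
    statuses: Iterable[EstrogenicityStatus],
    chemicals: Optional[Mapping[str, ChemicalRecord]] = None,
) -> EarTable:
    """Per-chemical EARs and per-sample EAR_mix over a set of samples.

    Only detected measurements of chemicals with status ``active_eedc``
    enter the sums; everything else contributes zero.  A detected active
    e-EDC lacking an ACC5 record is an error (its EAR is undefined, and
    dropping it silently would bias ``EAR_mix`` low).
    """
    active = {s.cas for s in statuses if s.status is Status.ACTIVE_EEDC}
    chem_rows: list[dict] = []
    sample_rows: list[dict] = []
    for s in samples:
        ear_sum = 0.0
        rows_here: list[dict] = []
        for m in s.measurements:
            if not m.detected or m.cas not in active:
                continue
            if m.cas not in acc5:
                raise ValueError(
                    f"detected active e-EDC {m.cas} in sample {s.sample_id} "
                    "has no ACC5 record"
                )
            chem = chemicals.get(m.cas) if chemicals else None
            conc = to_water_equivalent(m, chem, s.matrix)
            ear = compute_ear(conc, acc5[m.cas].acc5_ug_per_L)
            rows_here.append(
                {
                    "sample_id": s.sample_id,
                    "site_id": s.site_id,
                    "matrix": s.matrix,
                    "cas": m.cas,
                    "ear_acc5": ear,
                }
            )
            ear_sum += ear
        for r in rows_here:
            r["pct_contribution"] = (
                100.0 * r["ear_acc5"] / ear_sum if ear_sum > 0 else 0.0
            )
        chem_rows.extend(rows_here)
        sample_rows.append(
            {
                "sample_id": s.sample_id,
                "site_id": s.site_id,
                "matrix": s.matrix,
                "ear_mix": ear_sum,
            }
        )
    per_chemical = pd.DataFrame(
        chem_rows,
        columns=["sample_id", "site_id", "matrix", "cas", "ear_acc5", "pct_contribution"],
    )
    per_sample = pd.DataFrame(
        sample_rows, columns=["sample_id", "site_id", "matrix", "ear_mix"]
    )
    return EarTable(per_chemical=per_chemical, per_sample=per_sample)
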