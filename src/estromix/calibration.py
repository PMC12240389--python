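"""Cross-check of EAR_mix against estradiol-equivalent mixture scores.

The established way to score an estrogenic mixture is the estradiol
equivalency quotient: EEQ_i = concentration_i × EEF_i, with EEF the
potency of chemical *i* relative to 17β-estradiol, and EEQ_mix their sum.
EEFs exist for only a handful of chemicals, whereas ACC5-based EARs cover
every chemical active in the HTS roster.  This module

* computes EEQ_mix per sample from the chemical registry's EEFs,
* checks rank agreement between EAR_mix and EEQ_mix (Spearman), and
* computes the per-sample EAR_mix/EEQ_mix ratios whose median is the
  unit-translation constant used to turn E2 effect concentrations into
  EAR-scale thresholds.

EEQs are computed on native concentration scales (bile ng/mL etc.); the
ratio is unitless only in the sense that the same concentration scale
appears in both numerator and denominator, which is exactly what the
threshold translation requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from estromix.bioactivity import ChemicalRecord
from estromix.exposure import EarTable, Sample


@dataclass(frozen=True)
class EeqTable:
    """Per-chemical EEQs and per-sample EEQ_mix.

    ``per_chemical`` columns: sample_id, cas, eeq.  ``per_sample``
    columns: sample_id, eeq_mix.
    """

    per_chemical: pd.DataFrame
    per_sample: pd.DataFrame


def compute_eeq_table(
    samples: Sequence[Sample], chemicals: Mapping[str, ChemicalRecord]
) -> EeqTable:
    """EEQ_i = concentration × EEF for detected, EEF-bearing chemicals.

    Chemicals without an EEF contribute nothing; a sample with no
    eligible detections has ``eeq_mix = 0``.
    """
    chem_rows: list[dict] = []
    sample_rows: list[dict] = []
    for s in samples:
        total = 0.0
        for m in s.measurements:
            if not m.detected:
                continue
            chem = chemicals.get(m.cas)
            if chem is None or chem.eef is None:
                continue
            eeq = float(m.value) * chem.eef
            chem_rows.append({"sample_id": s.sample_id, "cas": m.cas, "eeq": eeq})
            total += eeq
        sample_rows.append({"sample_id": s.sample_id, "eeq_mix": total})
    return EeqTable(
        per_chemical=pd.DataFrame(chem_rows, columns=["sample_id", "cas", "eeq"]),
        per_sample=pd.DataFrame(sample_rows, columns=["sample_id", "eeq_mix"]),
    )


def compute_eeq_mix(sample: Sample, chemicals: Mapping[str, ChemicalRecord]) -> float:
    """EEQ_mix for a single sample (sum of per-chemical EEQs)."""
    table = compute_eeq_table([sample], chemicals)
    return float(table.per_sample["eeq_mix"].iloc[0])


def calibration_frame(
    ear: EarTable,
    eeq: EeqTable,
    restrict_to_eef_chemicals: bool = False,
    chemicals: Mapping[str, ChemicalRecord] | None = None,
) -> pd.DataFrame:
    """Join EAR_mix with EEQ_mix per sample and attach their ratio.

    With ``restrict_to_eef_chemicals`` the EAR_mix entering the ratio is
    recomputed over only EEF-bearing chemicals, so numerator and
    denominator cover the same chemical set (an alternative, stricter
    reading of the calibration; off by default).  The ratio is NaN where
    ``eeq_mix`` is zero.
    """
    if restrict_to_eef_chemicals:
        if chemicals is None:
            raise ValueError("restrict_to_eef_chemicals requires the registry")
        eef_cas = {cas for cas, c in chemicals.items() if c.eef is not None}
        sub = ear.per_chemical[ear.per_chemical["cas"].isin(eef_cas)]
        ear_mix = (
            sub.groupby("sample_id")["ear_acc5"]
            .sum()
            .reindex(ear.per_sample["sample_id"], fill_value=0.0)
            .reset_index()
            .rename(columns={"ear_acc5": "ear_mix"})
        )
    else:
        ear_mix = ear.per_sample[["sample_id", "ear_mix"]]
    out = ear_mix.merge(eeq.per_sample, on="sample_id", how="inner")
    out["ratio"] = np.where(
        out["eeq_mix"] > 0, out["ear_mix"] / out["eeq_mix"], np.nan
    )
    return out


def median_ear_eeq_ratio(
    ear: EarTable,
    eeq: EeqTable,
    restrict_to_eef_chemicals: bool = False,
    chemicals: Mapping[str, ChemicalRecord] | None = None,
) -> float:
    """Median over samples of EAR_mix/EEQ_mix; zero-EEQ samples excluded."""
    frame = calibration_frame(ear, eeq, restrict_to_eef_chemicals, chemicals)
    ratios = frame["ratio"].dropna()
    if ratios.empty:
        raise ValueError("no sample has eeq_mix > 0; ratio undefined")
    return float(ratios.median())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho requires equal-length 1-d vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rho is undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
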