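"""Site and sample classification against the mixture thresholds.

Sites are characterized by the 95th percentile of their bile EAR_mix
values (the upper end of the site's exposure distribution) and placed in
one of four regions formed by the bile threshold range:

* ``high_high_certainty`` — p95 at or above the highest LOEC_bEAR;
* ``high_low_certainty``  — within the LOEC_bEAR range;
* ``medium``              — between the lowest NOEC_bEAR and lowest
  LOEC_bEAR;
* ``low``                 — below the lowest NOEC_bEAR.

Individual samples use a two-threshold scheme instead (the lowest bile
thresholds, or the water thresholds for non-bile matrices): low below
the NOEC threshold, medium in [NOEC, LOEC), high at or above the LOEC.
Lower bounds are inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from estromix.thresholds import ThresholdSet


class SiteClass(IntEnum):
    """Ordered site classification (higher = more estrogenic potential)."""

    LOW = 0
    MEDIUM = 1
    HIGH_LOW_CERTAINTY = 2
    HIGH_HIGH_CERTAINTY = 3

    @property
    def label(self) -> str:
        return self.name.lower()


class ActivityLevel(IntEnum):
    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class SiteClassification:
    site_id: str
    n_samples: int
    p95_ear_mix: float
    site_class: SiteClass


@dataclass(frozen=True)
class SampleActivity:
    sample_id: str
    activity: ActivityLevel
    governing_noec: float
    governing_loec: float


def site_percentile(ear_mix_values: Sequence[float], q: float = 0.95) -> float:
    """Linear-interpolation percentile of a site's EAR_mix values."""
    values = np.asarray(list(ear_mix_values), dtype=float)
    if values.size == 0:
        raise ValueError("site_percentile requires at least one value")
    return float(np.percentile(values, q * 100.0))


def classify_site(p95: float, t: ThresholdSet) -> SiteClass:
    """Place a site's p95 EAR_mix in the four-region bile scheme."""
    if p95 >= t.loec_bear_high:
        return SiteClass.HIGH_HIGH_CERTAINTY
    if p95 >= t.loec_bear_low:
        return SiteClass.HIGH_LOW_CERTAINTY
    if p95 >= t.noec_bear_low:
        return SiteClass.MEDIUM
    return SiteClass.LOW


def classify_sites(
    per_sample: pd.DataFrame, t: ThresholdSet, q: float = 0.95
) -> pd.DataFrame:
    """Site table from per-sample EAR_mix rows (columns site_id, ear_mix)."""
    rows = []
    for site_id, grp in per_sample.groupby("site_id", sort=True):
        p95 = site_percentile(grp["ear_mix"].to_numpy(), q=q)
        rows.append(
            {
                "site_id": site_id,
                "n_samples": len(grp),
                "p95_ear_mix": p95,
                "site_class": classify_site(p95, t).label,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "n_samples", "p95_ear_mix", "site_class"])


def classify_sample(
    ear_mix: float,
    matrix: str,
    t: ThresholdSet,
    use_highest_loec: bool = False,
) -> SampleActivity:
    """Low / medium / high estrogenic activity of one sample.

    Bile samples are judged against the lowest bile thresholds (or, in
    sensitivity mode, the highest LOEC_bEAR); all other matrices use the
    water thresholds.
    """
    if matrix == "bile":
        noec = t.noec_bear_low
        loec = t.loec_bear_high if use_highest_loec else t.loec_bear_low
    else:
        noec, loec = t.noec_ear, t.loec_ear
    if ear_mix >= loec:
        level = ActivityLevel.HIGH
    elif ear_mix >= noec:
        level = ActivityLevel.MEDIUM
    else:
        level = ActivityLevel.LOW
    return SampleActivity(
        sample_id="", activity=level, governing_noec=noec, governing_loec=loec
    )


def classify_samples(
    per_sample: pd.DataFrame, t: ThresholdSet, use_highest_loec: bool = False
) -> pd.DataFrame:
    """Activity table from per-sample rows (sample_id, matrix, ear_mix)."""
    rows = []
    for rec in per_sample.itertuples(index=False):
        sa = classify_sample(rec.ear_mix, rec.matrix, t, use_highest_loec)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "matrix": rec.matrix,
                "ear_mix": rec.ear_mix,
                "activity": sa.activity.label,
                "governing_noec": sa.governing_noec,
                "governing_loec": sa.governing_loec,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "matrix",
            "ear_mix",
            "activity",
            "governing_noec",
            "governing_loec",
        ],
    )


@dataclass(frozen=True)
class FieldResponse:
    """Field measures of organism response at one site."""

    site_id: str
    pct_male_vtg: Optional[float]
    pct_female_altered_timing: Optional[float]


def concordance_table(
    classes: Iterable[SiteClassification] | pd.DataFrame,
    field: Iterable[FieldResponse] | pd.DataFrame,
) -> pd.DataFrame:
    """Join site classes with field organism-response measures.

    The ``aligned`` flag is this package's operationalization of the
    qualitative agreement check (it is reported, never fed back into
    classification): a site classed medium or above is corroborated when
    any male fish express vitellogenin (males normally express none) or
    when the fraction of females with altered reproductive timing
    exceeds the cohort median; a low-class site is corroborated when no
    male expresses vitellogenin.  Sites without field data get NA.
    """
    if not isinstance(classes, pd.DataFrame):
        classes = pd.DataFrame(
            [
                {
                    "site_id": c.site_id,
                    "n_samples": c.n_samples,
                    "p95_ear_mix": c.p95_ear_mix,
                    "site_class": c.site_class.label,
                }
                for c in classes
            ]
        )
    if not isinstance(field, pd.DataFrame):
        field = pd.DataFrame(
            [
                {
                    "site_id": f.site_id,
                    "pct_male_vtg": f.pct_male_vtg,
                    "pct_female_altered_timing": f.pct_female_altered_timing,
                }
                for f in field
            ]
        )
    if field.empty:
        field = pd.DataFrame(
            columns=["site_id", "pct_male_vtg", "pct_female_altered_timing"]
        )
    out = classes.merge(field, on="site_id", how="left")
    has_field = out["pct_male_vtg"].notna()
    timing_median = (
        float(out.loc[has_field, "pct_female_altered_timing"].median())
        if has_field.any()
        else float("nan")
    )
    aligned: list[object] = []
    for rec in out.itertuples(index=False):
        if pd.isna(rec.pct_male_vtg):
            aligned.append(pd.NA)
            continue
        elevated = SiteClass[rec.site_class.upper()] >= SiteClass.MEDIUM
        if elevated:
            timing_high = (
                not pd.isna(rec.pct_female_altered_timing)
                and rec.pct_female_altered_timing > timing_median
            )
            aligned.append(bool(rec.pct_male_vtg > 0 or timing_high))
        else:
            aligned.append(bool(rec.pct_male_vtg == 0))
    out["aligned"] = pd.array(aligned, dtype="boolean")
    return out
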