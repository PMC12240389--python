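"""Chemical prioritization decision tree.

Within each sample of medium or high estrogenic activity, every
contributing e-EDC gets a role:

* **driver** — its individual EAR meets or exceeds the governing
  threshold (LOEC threshold in a high sample, NOEC threshold in a
  medium sample);
* **major contributor** — not a driver but contributes ≥ 1% of EAR_mix;
* **minor contributor** — contributes < 1%.

Each role carries a provisional priority.  In a high sample: driver and
major contributor → high priority; a minor contributor that still
individually exceeds the NOEC threshold → watch list; otherwise low
priority.  In a medium sample: driver and major contributor → watch
list; minor contributor → low priority.  A chemical seen in multiple
samples takes the highest provisional category.  Active e-EDCs detected
only in low-activity samples are low priority; detected chemicals never
tested in the assay roster cannot be assessed (insufficient
information).  Chemicals analyzed but never detected are excluded from
prioritization and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Set

import pandas as pd

from estromix.bioactivity import EstrogenicityStatus, Status
from estromix.classify import ActivityLevel, SampleActivity


class Role(str, Enum):
    DRIVER = "driver"
    MAJOR_CONTRIBUTOR = "major_contributor"
    MINOR_CONTRIBUTOR = "minor_contributor"


class Priority(IntEnum):
    """Ordered priority categories (higher value = higher priority)."""

    INSUFFICIENT_INFORMATION = 0
    LOW_PRIORITY = 1
    WATCH_LIST = 2
    HIGH_PRIORITY = 3

    @property
    def label(self) -> str:
        return self.name.lower()


#: Minimum percent contribution to EAR_mix counted as "major".
MAJOR_CONTRIBUTION_PCT = 1.0


@dataclass(frozen=True)
class ChemicalRole:
    sample_id: str
    cas: str
    role: Role
    pct_contribution: float
    provisional_priority: Priority


@dataclass(frozen=True)
class PriorityAssignment:
    cas: str
    category: Priority
    supporting_samples: tuple[str, ...] = ()
    roles_seen: frozenset[Role] = field(default_factory=frozenset)


def assign_roles(
    sample_activity: SampleActivity,
    ear_rows: pd.DataFrame,
) -> list[ChemicalRole]:
    """Roles and provisional priorities for one medium/high sample.

    ``ear_rows`` holds the sample's per-chemical EAR results (columns
    cas, ear_acc5, pct_contribution).  Tests are applied in order:
    driver first, then the 1% contribution test, then (in high samples)
    the NOEC exceedance test.  Exceedance at exactly the threshold
    counts.
    """
    level = sample_activity.activity
    if level is ActivityLevel.LOW:
        raise ValueError(
            "prioritization applies only to samples of medium or high activity"
        )
    noec = sample_activity.governing_noec
    loec = sample_activity.governing_loec
    roles: list[ChemicalRole] = []
    for rec in ear_rows.itertuples(index=False):
        ear = rec.ear_acc5
        pct = rec.pct_contribution
        if level is ActivityLevel.HIGH:
            if ear >= loec:
                role, prio = Role.DRIVER, Priority.HIGH_PRIORITY
            elif pct >= MAJOR_CONTRIBUTION_PCT:
                role, prio = Role.MAJOR_CONTRIBUTOR, Priority.HIGH_PRIORITY
            elif ear >= noec:
                role, prio = Role.MINOR_CONTRIBUTOR, Priority.WATCH_LIST
            else:
                role, prio = Role.MINOR_CONTRIBUTOR, Priority.LOW_PRIORITY
        else:  # medium
            if ear >= noec:
                role, prio = Role.DRIVER, Priority.WATCH_LIST
            elif pct >= MAJOR_CONTRIBUTION_PCT:
                role, prio = Role.MAJOR_CONTRIBUTOR, Priority.WATCH_LIST
            else:
                role, prio = Role.MINOR_CONTRIBUTOR, Priority.LOW_PRIORITY
        roles.append(
            ChemicalRole(
                sample_id=rec.sample_id,
                cas=rec.cas,
                role=role,
                pct_contribution=pct,
                provisional_priority=prio,
            )
        )
    return roles


def resolve_categories(
    provisional: Iterable[ChemicalRole],
    statuses: Iterable[EstrogenicityStatus],
    detected_cas: Set[str],
) -> list[PriorityAssignment]:
    """Collapse per-sample provisional priorities to one category each.

    Conflicting assignments resolve to the higher category.  Detected
    active e-EDCs that never appear in a medium/high sample fall to low
    priority; detected chemicals with insufficient assay information
    keep that status as their category.  Non-detected chemicals and
    detected non-estrogenic chemicals (inactive or AUC-excluded) are
    outside the prioritization and yield no assignment.
    """
    status_by_cas = {s.cas: s.status for s in statuses}
    by_cas: dict[str, list[ChemicalRole]] = {}
    for r in provisional:
        by_cas.setdefault(r.cas, []).append(r)

    out: list[PriorityAssignment] = []
    for cas in sorted(detected_cas):
        status = status_by_cas.get(cas, Status.INSUFFICIENT_INFORMATION)
        if status is Status.INSUFFICIENT_INFORMATION:
            out.append(
                PriorityAssignment(cas=cas, category=Priority.INSUFFICIENT_INFORMATION)
            )
            continue
        if status is not Status.ACTIVE_EEDC:
            continue
        roles = by_cas.get(cas, [])
        if not roles:
            out.append(PriorityAssignment(cas=cas, category=Priority.LOW_PRIORITY))
            continue
        out.append(
            PriorityAssignment(
                cas=cas,
                category=max(r.provisional_priority for r in roles),
                supporting_samples=tuple(sorted({r.sample_id for r in roles})),
                roles_seen=frozenset(r.role for r in roles),
            )
        )
    return out


@dataclass(frozen=True)
class DriverSummary:
    """Single-chemical exceedance statistics over classified samples."""

    n_above_noec: int
    n_above_loec: int
    frac_single_chemical_above_noec: float
    frac_single_chemical_above_loec: float
    driver_counts_per_high_sample: dict[str, int]


def driver_fraction(
    sample_activities: pd.DataFrame,
    per_chemical: pd.DataFrame,
) -> DriverSummary:
    """How often a single chemical alone explains a threshold exceedance.

    ``sample_activities`` comes from :func:`estromix.classify.classify_samples`
    (columns sample_id, activity, governing_noec, governing_loec);
    ``per_chemical`` from the EAR table.  For samples above the NOEC
    (medium or high) the question is whether any single chemical's EAR
    meets the NOEC threshold; for samples above the LOEC (high), whether
    any single EAR meets the LOEC.  Also reports, per high sample, the
    number of drivers (chemicals individually at or above the LOEC).
    """
    max_ear = per_chemical.groupby("sample_id")["ear_acc5"].max()
    n_driver = {}
    single_noec = []
    single_loec = []
    n_above_noec = 0
    n_above_loec = 0
    for rec in sample_activities.itertuples(index=False):
        if rec.activity == "low":
            continue
        n_above_noec += 1
        m = float(max_ear.get(rec.sample_id, 0.0))
        single_noec.append(m >= rec.governing_noec)
        if rec.activity == "high":
            n_above_loec += 1
            single_loec.append(m >= rec.governing_loec)
            ears = per_chemical.loc[
                per_chemical["sample_id"] == rec.sample_id, "ear_acc5"
            ]
            n_driver[rec.sample_id] = int((ears >= rec.governing_loec).sum())
    return DriverSummary(
        n_above_noec=n_above_noec,
        n_above_loec=n_above_loec,
        frac_single_chemical_above_noec=(
            sum(single_noec) / n_above_noec if n_above_noec else 0.0
        ),
        frac_single_chemical_above_loec=(
            sum(single_loec) / n_above_loec if n_above_loec else 0.0
        ),
        driver_counts_per_high_sample=n_driver,
    )
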