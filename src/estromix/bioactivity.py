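"""Per-chemical estrogenicity status and potency from ER-agonist HTS data.

The screening framework rests on a roster of *in vitro* high-throughput
assays that all interrogate a single molecular initiating event: agonism
of the estrogen receptor.  For each chemical this module

1. drops assay results carrying disqualifying data-quality flags,
2. decides whether the chemical is an estrogenic endocrine-disrupting
   chemical (e-EDC) — active in at least one roster assay *and* supported
   by an ER-pathway-model AUC score above a cutoff (default 0.01; AUC is
   scaled so the reference potent estrogen EE2 scores 1), and
3. condenses the chemical's activity-concentration-at-cutoff (ACC) values
   across its active assays into a single conservative potency, the 5th
   percentile of log10 ACC (the "ACC5"), converted from µM into µg/L via
   the molecular weight.

Chemicals active in assays but lacking an AUC score must carry an explicit
manual override (``force_active`` / ``force_inactive``); guessing silently
is refused because such cases require expert read-across evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: The 18 ER-agonist assay endpoints used for e-EDC identification.
#: All target ER activation only (antagonism endpoints are excluded so
#: that receptor activation is not masked).
ER_AGONIST_ASSAYS: tuple[str, ...] = (
    "ACEA_ER_80hr",
    "ATG_ERE_CIS_up",
    "ATG_ERa_TRANS_up",
    "NVS_NR_bER",
    "NVS_NR_hER",
    "NVS_NR_mERa",
    "OT_ER_ERaERa_0480",
    "OT_ER_ERaERa_1440",
    "OT_ER_ERaERb_0480",
    "OT_ER_ERaERb_1440",
    "OT_ER_ERbERb_0480",
    "OT_ER_ERbERb_1440",
    "OT_ERa_EREGFP_0120",
    "OT_ERa_EREGFP_0480",
    "TOX21_ERa_BLA_Agonist_ratio",
    "TOX21_ERa_LUC_BG1_Agonist",
    "TOX21_ERa_LUC_VM7_Agonist",
    "UPITT_HCI_U2OS_AGONIST",
)

#: Default AUC cutoff below (or at) which an assay-active chemical is
#: treated as non-estrogenic (a false positive of assay interference).
DEFAULT_AUC_CUTOFF = 0.01

#: Quality flags excluded by default when filtering assay results.  The
#: flag vocabulary follows the common curve-fit diagnostics attached to
#: HTS concentration-response fits; the set is a config item.
DEFAULT_EXCLUDED_FLAGS: frozenset[str] = frozenset(
    {
        "Borderline",
        "OnlyHighestConcActive",
        "GainACCLessThanLowestConc",
        "BiochemicalAssayInterference",
        "AverageNumberOfReplicatesLessThan2",
    }
)


class Status(str, Enum):
    """Estrogenicity determination for one chemical."""

    ACTIVE_EEDC = "active_eedc"
    INACTIVE = "inactive"
    EXCLUDED_LOW_AUC = "excluded_low_auc"
    INSUFFICIENT_INFORMATION = "insufficient_information"


class Override(str, Enum):
    FORCE_ACTIVE = "force_active"
    FORCE_INACTIVE = "force_inactive"


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and screening metadata for one chemical.

    Parameters
    ----------
    cas
        CAS registry number (or any unique identifier string).
    name
        Human-readable chemical name.
    chem_class
        Chemical class label (hormone, bisphenol, alkylphenol, ...).
    molecular_weight
        g/mol; required (> 0) for any chemical with assay data because it
        anchors the µM → µg/L conversion of ACC5.
    auc_score
        ER-pathway-model area-under-the-curve score, scaled so EE2 = 1.
        Optional: absent for chemicals never evaluated by the model.
    eef
        Estradiol equivalency factor, potency relative to 17β-estradiol
        (E2 = 1).  Optional; known for only a handful of chemicals.
    bcf_tissue_water
        Tissue-to-water bioconcentration factor in L/kg used to
        back-calculate tissue residues to water concentrations. Optional.
    override_status
        Manual evaluation outcome that supersedes the AUC rule.
    """

    cas: str
    name: str = ""
    chem_class: str = ""
    molecular_weight: Optional[float] = None
    auc_score: Optional[float] = None
    eef: Optional[float] = None
    bcf_tissue_water: Optional[float] = None
    override_status: Optional[Override] = None

    def __post_init__(self) -> None:
        if self.molecular_weight is not None and not self.molecular_weight > 0:
            raise ValueError(
                f"molecular_weight must be > 0 for {self.cas}, "
                f"got {self.molecular_weight}"
            )
        if self.eef is not None and self.eef < 0:
            raise ValueError(f"eef must be >= 0 for {self.cas}, got {self.eef}")


@dataclass(frozen=True)
class AssayActivity:
    """One chemical × assay HTS result.

    ``acc_log10_uM`` is the log10 of the activity concentration at cutoff
    in µM — the minimum concentration producing a measurable response.
    It must be finite whenever ``active`` is true.
    """

    cas: str
    assay_id: str
    acc_log10_uM: Optional[float]
    active: bool
    quality_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.active and (
            self.acc_log10_uM is None or not math.isfinite(self.acc_log10_uM)
        ):
            raise ValueError(
                f"active assay result {self.cas}/{self.assay_id} requires a "
                f"finite acc_log10_uM, got {self.acc_log10_uM}"
            )


@dataclass(frozen=True)
class Acc5Record:
    """Aggregated potency for one chemical: 5th percentile of log10 ACC."""

    cas: str
    acc5_log10_uM: float
    acc5_ug_per_L: float
    n_assays_used: int


@dataclass(frozen=True)
class EstrogenicityStatus:
    cas: str
    status: Status


def filter_assay_results(
    records: Iterable[AssayActivity],
    excluded_flags: Iterable[str] = DEFAULT_EXCLUDED_FLAGS,
) -> list[AssayActivity]:
    """Drop assay results carrying any disqualifying data-quality flag.

    A record is retained iff its flag set is disjoint from
    ``excluded_flags``.  Input order is preserved.
    """
    excluded = frozenset(excluded_flags)
    return [r for r in records if not (frozenset(r.quality_flags) & excluded)]


def identify_eedcs(
    chemicals: Mapping[str, ChemicalRecord],
    assays: Iterable[AssayActivity],
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
    assay_roster: Sequence[str] = ER_AGONIST_ASSAYS,
) -> list[EstrogenicityStatus]:
    """Assign exactly one estrogenicity status to every chemical.

    Decision order per chemical:

    * no assay results in the roster → ``insufficient_information``
    * assay results but none active → ``inactive``
    * ≥ 1 active result:
        * manual override, if present, wins (``force_active`` →
          ``active_eedc``, ``force_inactive`` → ``inactive``)
        * else AUC > ``auc_cutoff`` → ``active_eedc``; AUC ≤ cutoff →
          ``excluded_low_auc`` (treated as a false positive)
        * a missing AUC without an override is an error: these chemicals
          require manual evaluation and must not be guessed.
    """
    roster = set(assay_roster)
    in_roster: dict[str, list[AssayActivity]] = {cas: [] for cas in chemicals}
    for a in assays:
        if a.assay_id in roster and a.cas in in_roster:
            in_roster[a.cas].append(a)

    statuses: list[EstrogenicityStatus] = []
    for cas, chem in chemicals.items():
        rows = in_roster[cas]
        if not rows:
            status = Status.INSUFFICIENT_INFORMATION
        elif not any(r.active for r in rows):
            status = Status.INACTIVE
        elif chem.override_status is Override.FORCE_ACTIVE:
            status = Status.ACTIVE_EEDC
        elif chem.override_status is Override.FORCE_INACTIVE:
            status = Status.INACTIVE
        elif chem.auc_score is None:
            raise ValueError(
                f"chemical {cas} ({chem.name or 'unnamed'}) is active in ER "
                "agonist assays but has neither an AUC score nor a manual "
                "override; refusing to guess its estrogenicity"
            )
        elif chem.auc_score > auc_cutoff:
            status = Status.ACTIVE_EEDC
        else:
            status = Status.EXCLUDED_LOW_AUC
        statuses.append(EstrogenicityStatus(cas=cas, status=status))
    return statuses


def compute_acc5(
    assays_for_chemical: Iterable[AssayActivity],
    molecular_weight: float,
    percentile_q: float = 0.05,
) -> Acc5Record:
    """Aggregate active assay ACCs into a single conservative potency.

    The ACC5 is the ``percentile_q``-th quantile (default 5th percentile,
    linear interpolation between order statistics at rank ``q*(n-1)``)
    of log10 ACC over the chemical's *active* assay results; inactive
    results carry no concentration information and are ignored.  The
    value is converted to µg/L via 1 µM = ``molecular_weight`` µg/L.
    """
    if not molecular_weight > 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    rows = [a for a in assays_for_chemical if a.active]
    if not rows:
        raise ValueError("compute_acc5 requires at least one active assay result")
    cas_values = {a.cas for a in rows}
    if len(cas_values) != 1:
        raise ValueError(f"assay results span multiple chemicals: {sorted(cas_values)}")
    accs = np.asarray([a.acc_log10_uM for a in rows], dtype=float)
    acc5_log10 = float(np.percentile(accs, percentile_q * 100.0))
    return Acc5Record(
        cas=rows[0].cas,
        acc5_log10_uM=acc5_log10,
        acc5_ug_per_L=float(10.0**acc5_log10 * molecular_weight),
        n_assays_used=len(rows),
    )
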