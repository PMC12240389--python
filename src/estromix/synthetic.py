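"""Synthetic monitoring campaigns with known ground truth.

The generator emulates the structure of an opportunistic multi-matrix
monitoring campaign: a chemical roster in which a few potent true
e-EDCs sit among decoys (assay-active but with ER-pathway AUC ≤ 0.01,
i.e. assay-interference false positives), inactive chemicals, and
chemicals never tested in the ER assay roster; per-chemical lognormal
concentrations with multiplicative site effects (environmental
monitoring data are strongly right-skewed); and left-censoring at a
limit of quantification, reported as non-detects with the value
withheld.  ``driver_spec`` entries force chosen chemicals to a target
median EAR, creating known dominant drivers.

All randomness flows from the single configured seed, so campaigns are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from estromix.bioactivity import (
    DEFAULT_EXCLUDED_FLAGS,
    ER_AGONIST_ASSAYS,
    AssayActivity,
    ChemicalRecord,
    filter_assay_results,
)
from estromix.exposure import MATRIX_UNITS, Measurement, Sample


@dataclass(frozen=True)
class CampaignConfig:
    """Knobs of the simulated campaign; defaults give a bile survey
    loosely sized like a multi-year field program (18 sites).

    Concentrations are parameterized on the water-equivalent µg/L scale
    and converted to each matrix's native unit on output.  ``conc_sigma``
    and ``site_sigma`` are natural-log standard deviations of the
    lognormal sample- and site-level variation.  ``eef_anchor_ratio``
    sets the EAR:EEQ proportionality around which EEFs of true e-EDCs
    are drawn (with lognormal noise ``eef_noise_sigma``); setting
    ``eef_noise_sigma = 0`` produces the exactly proportional
    configuration in which every sample's EAR_mix/EEQ_mix ratio equals
    the anchor.
    """

    n_sites: int = 18
    samples_per_site: int = 20
    matrix_weights: dict[str, float] = field(
        default_factory=lambda: {"bile": 1.0}
    )
    n_chemicals: int = 30
    n_true_eedcs: int = 5
    n_decoys: int = 4
    n_untested: int = 4
    eedc_acc_log10_range: tuple[float, float] = (-3.0, -0.5)
    other_acc_log10_range: tuple[float, float] = (-1.0, 1.5)
    assay_sigma: float = 0.3
    flag_prob: float = 0.1
    conc_log10_median_range: tuple[float, float] = (-4.0, -1.0)
    conc_sigma: float = 1.0
    site_sigma: float = 0.5
    loq_ug_L: float = 1e-4
    driver_spec: tuple[tuple[str, float], ...] = ()
    eef_anchor_ratio: float = 27.0
    eef_noise_sigma: float = 0.3
    female_bile_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "samples_per_site", "n_chemicals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_true_eedcs < 0 or self.n_decoys < 0 or self.n_untested < 0:
            raise ValueError("chemical group counts must be >= 0")
        if self.n_true_eedcs + self.n_decoys + self.n_untested > self.n_chemicals:
            raise ValueError("chemical groups exceed roster size")
        for name in ("assay_sigma", "conc_sigma", "site_sigma", "eef_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.matrix_weights or any(
            m not in MATRIX_UNITS for m in self.matrix_weights
        ):
            raise ValueError(f"matrix_weights keys must be among {list(MATRIX_UNITS)}")
        if not 0 <= self.female_bile_fraction <= 1:
            raise ValueError("female_bile_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for recovery checks.

    ``chemicals`` columns: cas, true_status, true_acc5_log10_uM,
    true_acc5_ug_per_L, auc, eef.  ``samples`` columns: sample_id,
    site_id, matrix, sex, true_ear_mix.
    """

    chemicals: pd.DataFrame
    samples: pd.DataFrame
    site_multipliers: dict[str, float]
    intended_drivers: tuple[str, ...]


@dataclass(frozen=True)
class Campaign:
    chemicals: dict[str, ChemicalRecord]
    assays: list[AssayActivity]
    samples: list[Sample]
    truth: GroundTruth


def _cas(i: int) -> str:
    return f"SYN-{i:03d}"


def generate_campaign(cfg: CampaignConfig) -> Campaign:
    """Simulate one campaign; deterministic for a fixed config seed."""
    rng = np.random.default_rng(cfg.seed)
    roster = list(ER_AGONIST_ASSAYS)
    excluded_flags = sorted(DEFAULT_EXCLUDED_FLAGS)

    groups: list[str] = (
        ["active_eedc"] * cfg.n_true_eedcs
        + ["excluded_low_auc"] * cfg.n_decoys
        + ["insufficient_information"] * cfg.n_untested
        + ["inactive"]
        * (cfg.n_chemicals - cfg.n_true_eedcs - cfg.n_decoys - cfg.n_untested)
    )

    chemicals: dict[str, ChemicalRecord] = {}
    assays: list[AssayActivity] = []
    truth_rows: list[dict] = []
    true_acc5_ug_L: dict[str, float] = {}

    for i, group in enumerate(groups):
        cas = _cas(i)
        mw = float(rng.uniform(200.0, 500.0))
        bcf = float(10.0 ** rng.uniform(1.0, 3.0))
        auc: Optional[float] = None
        acc5_log10 = np.nan
        acc5_ug = np.nan
        eef: Optional[float] = None

        if group != "insufficient_information":
            k = int(rng.integers(4, len(roster) + 1))
            assay_ids = rng.choice(roster, size=k, replace=False)
            if group == "active_eedc":
                center = float(rng.uniform(*cfg.eedc_acc_log10_range))
            else:
                center = float(rng.uniform(*cfg.other_acc_log10_range))
            draws = center + rng.normal(0.0, cfg.assay_sigma, size=k)
            active = group in ("active_eedc", "excluded_low_auc")
            rows = []
            for j, (assay_id, acc) in enumerate(zip(assay_ids, draws)):
                # never flag the first two rows so every tested chemical
                # keeps at least two usable results after filtering
                flags: frozenset[str] = frozenset()
                if j >= 2 and rng.random() < cfg.flag_prob:
                    flags = frozenset({str(rng.choice(excluded_flags))})
                rows.append(
                    AssayActivity(
                        cas=cas,
                        assay_id=str(assay_id),
                        acc_log10_uM=float(acc) if active else None,
                        active=active,
                        quality_flags=flags,
                    )
                )
            assays.extend(rows)
            if active:
                kept = [r for r in filter_assay_results(rows) if r.active]
                acc5_log10 = float(np.percentile([r.acc_log10_uM for r in kept], 5.0))
                acc5_ug = float(10.0**acc5_log10 * mw)
                true_acc5_ug_L[cas] = acc5_ug
            if group == "active_eedc":
                auc = float(rng.uniform(0.1, 1.0))
                noise = (
                    float(np.exp(rng.normal(0.0, cfg.eef_noise_sigma)))
                    if cfg.eef_noise_sigma > 0
                    else 1.0
                )
                eef = noise / (cfg.eef_anchor_ratio * acc5_ug)
            elif group == "excluded_low_auc":
                auc = float(rng.uniform(0.001, 0.01))
            else:
                auc = float(rng.uniform(0.0, 0.5))

        chemicals[cas] = ChemicalRecord(
            cas=cas,
            name=f"synthetic-compound-{i:03d}",
            chem_class={"active_eedc": "hormone", "excluded_low_auc": "decoy"}.get(
                group, "industrial"
            ),
            molecular_weight=mw,
            auc_score=auc,
            eef=eef,
            bcf_tissue_water=bcf,
        )
        truth_rows.append(
            {
                "cas": cas,
                "true_status": group,
                "true_acc5_log10_uM": acc5_log10,
                "true_acc5_ug_per_L": acc5_ug,
                "auc": auc if auc is not None else np.nan,
                "eef": eef if eef is not None else np.nan,
            }
        )

    # baseline median concentration (µg/L water-equivalent) per chemical
    driver_targets = dict(cfg.driver_spec)
    unknown = set(driver_targets) - set(chemicals)
    if unknown:
        raise ValueError(f"driver_spec names unknown chemicals: {sorted(unknown)}")
    medians: dict[str, float] = {}
    for cas in chemicals:
        if cas in driver_targets:
            if cas not in true_acc5_ug_L:
                raise ValueError(
                    f"driver_spec chemical {cas} has no assay activity; its "
                    "target EAR is undefined"
                )
            medians[cas] = driver_targets[cas] * true_acc5_ug_L[cas]
        else:
            medians[cas] = float(10.0 ** rng.uniform(*cfg.conc_log10_median_range))

    matrices = sorted(cfg.matrix_weights)
    weights = np.array([cfg.matrix_weights[m] for m in matrices], dtype=float)
    weights = weights / weights.sum()

    site_ids = [f"site_{i:02d}" for i in range(cfg.n_sites)]
    site_mult = {s: float(np.exp(rng.normal(0.0, cfg.site_sigma))) for s in site_ids}

    active_cas = {r["cas"] for r in truth_rows if r["true_status"] == "active_eedc"}
    samples: list[Sample] = []
    sample_truth_rows: list[dict] = []
    n = 0
    for site in site_ids:
        for _ in range(cfg.samples_per_site):
            matrix = str(rng.choice(matrices, p=weights))
            sex = None
            if matrix == "bile":
                sex = (
                    "female" if rng.random() < cfg.female_bile_fraction else "male"
                )
            unit = MATRIX_UNITS[matrix]
            measurements = []
            true_ear = 0.0
            for cas, chem in chemicals.items():
                conc = medians[cas] * site_mult[site] * float(
                    np.exp(rng.normal(0.0, cfg.conc_sigma))
                )
                if matrix in ("marine_water", "wwtp_effluent"):
                    native = conc * 1000.0
                    loq_native = cfg.loq_ug_L * 1000.0
                elif matrix == "bile":
                    native = conc
                    loq_native = cfg.loq_ug_L
                else:
                    native = conc * chem.bcf_tissue_water
                    loq_native = cfg.loq_ug_L * chem.bcf_tissue_water
                detected = conc >= cfg.loq_ug_L
                measurements.append(
                    Measurement(
                        cas=cas,
                        value=float(native) if detected else None,
                        unit=unit,
                        detected=detected,
                        loq=float(loq_native),
                    )
                )
                if detected and cas in active_cas:
                    true_ear += conc / true_acc5_ug_L[cas]
            sample_id = f"samp_{n:04d}"
            n += 1
            samples.append(
                Sample(
                    sample_id=sample_id,
                    site_id=site,
                    matrix=matrix,
                    year=2020,
                    measurements=tuple(measurements),
                    species="synthetic sole" if matrix == "bile" else None,
                    sex=sex,
                )
            )
            sample_truth_rows.append(
                {
                    "sample_id": sample_id,
                    "site_id": site,
                    "matrix": matrix,
                    "sex": sex,
                    "true_ear_mix": true_ear,
                }
            )

    truth = GroundTruth(
        chemicals=pd.DataFrame(truth_rows),
        samples=pd.DataFrame(sample_truth_rows),
        site_multipliers=site_mult,
        intended_drivers=tuple(sorted(driver_targets)),
    )
    return Campaign(chemicals=chemicals, assays=assays, samples=samples, truth=truth)


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline-vs-truth comparison for one generated campaign."""

    status_confusion: pd.DataFrame  # rows: truth, columns: estimated
    acc5_relative_error: pd.DataFrame  # cas, true, estimated, rel_error
    drivers_high_priority: dict[str, bool]


def recover_parameters(
    statuses,
    acc5_records,
    priority_assignments,
    truth: GroundTruth,
) -> RecoveryReport:
    """Compare pipeline outputs with the generator's ground truth.

    ``statuses`` is the estrogenicity-status list, ``acc5_records`` a
    cas → Acc5Record mapping, and ``priority_assignments`` the final
    priority list.  Reports the status confusion matrix, the relative
    error of recovered ACC5 values (µg/L scale), and whether each
    intended driver ended in the high-priority category.
    """
    est = {s.cas: s.status.value for s in statuses}
    t = truth.chemicals
    confusion = pd.crosstab(
        t["true_status"],
        t["cas"].map(est).fillna("missing"),
        rownames=["truth"],
        colnames=["estimated"],
    )

    rows = []
    for rec in t.itertuples(index=False):
        if np.isnan(rec.true_acc5_ug_per_L) or rec.cas not in acc5_records:
            continue
        est_acc5 = acc5_records[rec.cas].acc5_ug_per_L
        rows.append(
            {
                "cas": rec.cas,
                "true": rec.true_acc5_ug_per_L,
                "estimated": est_acc5,
                "rel_error": abs(est_acc5 - rec.true_acc5_ug_per_L)
                / rec.true_acc5_ug_per_L,
            }
        )
    acc5_err = pd.DataFrame(rows, columns=["cas", "true", "estimated", "rel_error"])

    category = {p.cas: p.category for p in priority_assignments}
    drivers = {
        cas: (cas in category and category[cas].name == "HIGH_PRIORITY")
        for cas in truth.intended_drivers
    }
    return RecoveryReport(
        status_confusion=confusion,
        acc5_relative_error=acc5_err,
        drivers_high_priority=drivers,
    )
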