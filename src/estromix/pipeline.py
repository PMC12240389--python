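"""One-shot orchestration: tables in, screening reports out.

``run_pipeline`` wires the stages together:

bioactivity (flag filtering, e-EDC identification, ACC5) →
exposure (EAR / EAR_mix) → optional calibration (EAR:EEQ ratio) →
thresholds → classification (sites + samples) → prioritization.

The bundle of result tables can be written to an output directory along
with a provenance log (config echo, package/library versions, threshold
values actually used) sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy
import yaml

import estromix
from estromix import calibration as calib
from estromix.bioactivity import (
    DEFAULT_AUC_CUTOFF,
    DEFAULT_EXCLUDED_FLAGS,
    Acc5Record,
    Status,
    compute_acc5,
    filter_assay_results,
    identify_eedcs,
)
from estromix.classify import classify_samples, classify_sites
from estromix.exposure import compute_ear_table, exclude_female_bile
from estromix.prioritize import (
    ChemicalRole,
    Priority,
    assign_roles,
    driver_fraction,
    resolve_categories,
)
from estromix.classify import ActivityLevel, SampleActivity
from estromix.tables import (
    detection_frequency,
    read_assays,
    read_chemicals,
    read_samples,
)
from estromix.thresholds import (
    BenchmarkConfig,
    ThresholdSet,
    derive_thresholds,
    report_rounded,
)

log = logging.getLogger("estromix")


@dataclass
class RunConfig:
    """Paths and knobs for one screening run; defaults reproduce the
    published threshold arithmetic exactly."""

    chemical_table: Optional[str] = None
    assay_table: Optional[str] = None
    sample_table: Optional[str] = None
    output_dir: Optional[str] = None
    benchmarks: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    excluded_flags: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDED_FLAGS))
    auc_cutoff: float = DEFAULT_AUC_CUTOFF
    acc5_percentile_q: float = 0.05
    site_percentile_q: float = 0.95
    male_bile_only: bool = True
    use_highest_loec: bool = False
    recompute_calibration_ratio: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bench = BenchmarkConfig(**raw.pop("benchmarks", {}))
        flags = raw.pop("excluded_flags", None)
        cfg = cls(benchmarks=bench, **raw)
        if flags is not None:
            cfg.excluded_flags = tuple(flags)
        return cfg


@dataclass
class ReportBundle:
    thresholds: ThresholdSet
    calibration_ratio_used: float
    calibration_source: str  # "configured" | "recomputed"
    ear_per_chemical: pd.DataFrame
    ear_per_sample: pd.DataFrame
    site_report: pd.DataFrame
    sample_report: pd.DataFrame
    priority_report: pd.DataFrame
    not_detected_report: pd.DataFrame
    detection_frequency: pd.DataFrame
    calibration_report: Optional[pd.DataFrame] = None
    driver_summary: Optional[dict] = None


def _priority_frame(assignments, chemicals) -> pd.DataFrame:
    rows = []
    for a in assignments:
        chem = chemicals.get(a.cas)
        rows.append(
            {
                "cas": a.cas,
                "name": chem.name if chem else "",
                "category": a.category.label,
                "roles_seen": ";".join(sorted(r.value for r in a.roles_seen)),
                "n_supporting_samples": len(a.supporting_samples),
            }
        )
    return pd.DataFrame(
        rows, columns=["cas", "name", "category", "roles_seen", "n_supporting_samples"]
    )


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full screening workflow from the configured tables."""
    try:
        chemicals = read_chemicals(cfg.chemical_table)
        assay_rows = read_assays(cfg.assay_table)
        samples = read_samples(cfg.sample_table)
    except Exception as exc:  # stage-tagged abort
        raise RuntimeError(f"[read_tables] {exc}") from exc
    return run_pipeline_objects(cfg, chemicals, assay_rows, samples)


def run_pipeline_objects(cfg: RunConfig, chemicals, assay_rows, samples) -> ReportBundle:
    """Same as :func:`run_pipeline` but on already-loaded objects."""
    log.info(
        "loaded %d chemicals, %d assay rows, %d samples",
        len(chemicals), len(assay_rows), len(samples),
    )
    if not samples:
        log.warning("sample table is empty; reports will be empty")

    # --- bioactivity ------------------------------------------------
    try:
        kept = filter_assay_results(assay_rows, cfg.excluded_flags)
        statuses = identify_eedcs(chemicals, kept, auc_cutoff=cfg.auc_cutoff)
        active = {s.cas for s in statuses if s.status is Status.ACTIVE_EEDC}
        acc5: dict[str, Acc5Record] = {}
        for cas in active:
            rows = [a for a in kept if a.cas == cas and a.active]
            acc5[cas] = compute_acc5(
                rows, chemicals[cas].molecular_weight, cfg.acc5_percentile_q
            )
    except Exception as exc:
        raise RuntimeError(f"[bioactivity] {exc}") from exc

    # --- exposure ---------------------------------------------------
    try:
        eligible = exclude_female_bile(samples) if cfg.male_bile_only else list(samples)
        ear = compute_ear_table(eligible, acc5, statuses, chemicals)
    except Exception as exc:
        raise RuntimeError(f"[exposure] {exc}") from exc

    # --- calibration (optional) ------------------------------------
    ratio = cfg.benchmarks.calibration_ratio
    source = "configured"
    calibration_report = None
    if cfg.recompute_calibration_ratio:
        try:
            bile = [s for s in eligible if s.matrix == "bile"]
            eeq = calib.compute_eeq_table(bile, chemicals)
            bile_ids = {s.sample_id for s in bile}
            bile_ear = type(ear)(
                per_chemical=ear.per_chemical[
                    ear.per_chemical["sample_id"].isin(bile_ids)
                ],
                per_sample=ear.per_sample[ear.per_sample["sample_id"].isin(bile_ids)],
            )
            calibration_report = calib.calibration_frame(bile_ear, eeq)
            ratio = calib.median_ear_eeq_ratio(bile_ear, eeq)
            source = "recomputed"
        except Exception as exc:
            raise RuntimeError(f"[calibration] {exc}") from exc

    # --- thresholds -------------------------------------------------
    bench = BenchmarkConfig(
        noec_ug_L=cfg.benchmarks.noec_ug_L,
        loec_ug_L=cfg.benchmarks.loec_ug_L,
        calibration_ratio=ratio,
        bcf_bw_low=cfg.benchmarks.bcf_bw_low,
        bcf_bw_high=cfg.benchmarks.bcf_bw_high,
    )
    thresholds = derive_thresholds(bench)
    log.info("thresholds (ratio=%s, %s): %s", ratio, source, thresholds)

    # --- classification ---------------------------------------------
    try:
        bile_per_sample = ear.per_sample[ear.per_sample["matrix"] == "bile"]
        site_report = classify_sites(bile_per_sample, thresholds, cfg.site_percentile_q)
        sample_report = classify_samples(
            ear.per_sample, thresholds, cfg.use_highest_loec
        )
    except Exception as exc:
        raise RuntimeError(f"[classify] {exc}") from exc

    # --- prioritization ---------------------------------------------
    try:
        roles: list[ChemicalRole] = []
        for rec in sample_report.itertuples(index=False):
            if rec.activity == "low":
                continue
            sa = SampleActivity(
                sample_id=rec.sample_id,
                activity=ActivityLevel[rec.activity.upper()],
                governing_noec=rec.governing_noec,
                governing_loec=rec.governing_loec,
            )
            rows = ear.per_chemical[ear.per_chemical["sample_id"] == rec.sample_id]
            roles.extend(assign_roles(sa, rows))
        detected = {
            m.cas for s in eligible for m in s.measurements if m.detected
        }
        assignments = resolve_categories(roles, statuses, detected)
        priority_report = _priority_frame(assignments, chemicals)
        analyzed = {m.cas for s in eligible for m in s.measurements}
        never_detected = sorted(analyzed - detected)
        not_detected_report = pd.DataFrame(
            {
                "cas": never_detected,
                "name": [
                    chemicals[c].name if c in chemicals else "" for c in never_detected
                ],
            }
        )
        summary = driver_fraction(sample_report, ear.per_chemical)
    except Exception as exc:
        raise RuntimeError(f"[prioritize] {exc}") from exc

    bundle = ReportBundle(
        thresholds=thresholds,
        calibration_ratio_used=ratio,
        calibration_source=source,
        ear_per_chemical=ear.per_chemical,
        ear_per_sample=ear.per_sample,
        site_report=site_report,
        sample_report=sample_report,
        priority_report=priority_report,
        not_detected_report=not_detected_report,
        detection_frequency=detection_frequency(eligible),
        calibration_report=calibration_report,
        driver_summary={
            "n_above_noec": summary.n_above_noec,
            "n_above_loec": summary.n_above_loec,
            "frac_single_chemical_above_noec": summary.frac_single_chemical_above_noec,
            "frac_single_chemical_above_loec": summary.frac_single_chemical_above_loec,
            "driver_counts_per_high_sample": summary.driver_counts_per_high_sample,
        },
    )
    if cfg.output_dir:
        write_bundle(bundle, cfg)
    return bundle


def write_bundle(bundle: ReportBundle, cfg: RunConfig) -> Path:
    """Write all report CSVs plus a provenance log to ``cfg.output_dir``."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.ear_per_chemical.to_csv(out / "ear_per_chemical.csv", index=False)
    bundle.ear_per_sample.to_csv(out / "ear_per_sample.csv", index=False)
    bundle.site_report.to_csv(out / "site_report.csv", index=False)
    bundle.sample_report.to_csv(out / "sample_report.csv", index=False)
    bundle.priority_report.to_csv(out / "priority_report.csv", index=False)
    bundle.not_detected_report.to_csv(out / "not_detected.csv", index=False)
    bundle.detection_frequency.to_csv(out / "detection_frequency.csv", index=False)
    report_rounded(bundle.thresholds).to_csv(out / "thresholds.csv", index=False)
    if bundle.calibration_report is not None:
        bundle.calibration_report.to_csv(out / "calibration_report.csv", index=False)

    provenance = {
        "config": _jsonable(asdict(cfg)),
        "calibration_ratio_used": bundle.calibration_ratio_used,
        "calibration_source": bundle.calibration_source,
        "thresholds": asdict(bundle.thresholds),
        "driver_summary": bundle.driver_summary,
        "versions": {
            "python": platform.python_version(),
            "estromix": estromix.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
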