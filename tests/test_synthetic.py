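"""Campaign generator: determinism, censoring, decoys, recovery."""

import numpy as np
import pandas as pd
import pytest

from estromix import calibration as calib
from estromix.bioactivity import (
    Status,
    compute_acc5,
    filter_assay_results,
    identify_eedcs,
)
from estromix.exposure import compute_ear_table, exclude_female_bile
from estromix.pipeline import RunConfig, run_pipeline_objects
from estromix.synthetic import (
    Campaign,
    CampaignConfig,
    generate_campaign,
    recover_parameters,
)
from estromix.tables import assays_to_frame, chemicals_to_frame, samples_to_frame


def small_cfg(**kwargs):
    defaults = dict(n_sites=4, samples_per_site=5, n_chemicals=12,
                    n_true_eedcs=3, n_decoys=2, n_untested=2, seed=11)
    defaults.update(kwargs)
    return CampaignConfig(**defaults)


def run_stages(campaign: Campaign):
    kept = filter_assay_results(campaign.assays)
    statuses = identify_eedcs(campaign.chemicals, kept)
    acc5 = {
        s.cas: compute_acc5(
            [a for a in kept if a.cas == s.cas and a.active],
            campaign.chemicals[s.cas].molecular_weight,
        )
        for s in statuses
        if s.status is Status.ACTIVE_EEDC
    }
    ear = compute_ear_table(
        exclude_female_bile(campaign.samples), acc5, statuses, campaign.chemicals
    )
    return kept, statuses, acc5, ear


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        a = generate_campaign(small_cfg())
        b = generate_campaign(small_cfg())
        pd.testing.assert_frame_equal(
            chemicals_to_frame(a.chemicals), chemicals_to_frame(b.chemicals)
        )
        pd.testing.assert_frame_equal(
            assays_to_frame(a.assays), assays_to_frame(b.assays)
        )
        pd.testing.assert_frame_equal(
            samples_to_frame(a.samples), samples_to_frame(b.samples)
        )
        pd.testing.assert_frame_equal(a.truth.samples, b.truth.samples)

    def test_different_seed_changes_concentrations(self):
        a = generate_campaign(small_cfg(seed=1))
        b = generate_campaign(small_cfg(seed=2))
        assert not samples_to_frame(a.samples).equals(samples_to_frame(b.samples))


class TestCensoring:
    def test_loq_above_everything_censors_all(self):
        campaign = generate_campaign(small_cfg(loq_ug_L=1e9))
        assert all(
            not m.detected for s in campaign.samples for m in s.measurements
        )
        assert (campaign.truth.samples["true_ear_mix"] == 0).all()
        _, _, _, ear = run_stages(campaign)
        assert (ear.per_sample["ear_mix"] == 0).all()

    def test_nondetect_values_are_withheld(self):
        campaign = generate_campaign(small_cfg())
        for s in campaign.samples:
            for m in s.measurements:
                if not m.detected:
                    assert m.value is None
                    assert m.loq is not None


class TestGroundTruthConsistency:
    def test_statuses_recovered_exactly(self):
        campaign = generate_campaign(small_cfg())
        _, statuses, acc5, _ = run_stages(campaign)
        est = {s.cas: s.status.value for s in statuses}
        for rec in campaign.truth.chemicals.itertuples(index=False):
            assert est[rec.cas] == rec.true_status

    def test_acc5_recovered_exactly(self):
        campaign = generate_campaign(small_cfg())
        _, _, acc5, _ = run_stages(campaign)
        for rec in campaign.truth.chemicals.itertuples(index=False):
            if rec.cas in acc5:
                assert acc5[rec.cas].acc5_ug_per_L == pytest.approx(
                    rec.true_acc5_ug_per_L
                )

    def test_pipeline_ear_mix_matches_truth(self):
        campaign = generate_campaign(small_cfg())
        _, _, _, ear = run_stages(campaign)
        merged = ear.per_sample.merge(campaign.truth.samples, on="sample_id")
        np.testing.assert_allclose(
            merged["ear_mix"], merged["true_ear_mix"], rtol=1e-10
        )

    def test_decoy_only_campaign_has_no_estrogenic_activity(self):
        cfg = small_cfg(n_true_eedcs=0, n_decoys=5)
        campaign = generate_campaign(cfg)
        _, statuses, acc5, ear = run_stages(campaign)
        assert not any(s.status is Status.ACTIVE_EEDC for s in statuses)
        assert (ear.per_sample["ear_mix"] == 0).all()


class TestProportionalPotencyLink:
    def test_generator_calibration_closed_form(self):
        cfg = small_cfg(eef_noise_sigma=0.0, eef_anchor_ratio=27.0)
        campaign = generate_campaign(cfg)
        _, _, _, ear = run_stages(campaign)
        eeq = calib.compute_eeq_table(campaign.samples, campaign.chemicals)
        assert calib.median_ear_eeq_ratio(ear, eeq) == pytest.approx(27.0, rel=1e-12)
        frame = calib.calibration_frame(ear, eeq)
        assert calib.spearman_rho(
            frame["ear_mix"], frame["eeq_mix"]
        ) == pytest.approx(1.0, abs=1e-12)


class TestDriverSpec:
    def test_forced_driver_dominates_high_samples(self):
        # one chemical forced to a median EAR ten times the lowest bile LOEC
        cfg = CampaignConfig(
            n_sites=10,
            samples_per_site=20,
            n_chemicals=15,
            n_true_eedcs=4,
            n_decoys=2,
            n_untested=2,
            driver_spec=(("SYN-000", 27000.0),),
            seed=5,
        )
        campaign = generate_campaign(cfg)
        bundle = run_pipeline_objects(
            RunConfig(), campaign.chemicals, campaign.assays, campaign.samples
        )
        high = bundle.sample_report[bundle.sample_report["activity"] == "high"]
        assert len(high) >= 100
        loec = high["governing_loec"].iloc[0]
        per_chem = bundle.ear_per_chemical
        n_driver = sum(
            (
                per_chem[
                    (per_chem["sample_id"] == sid) & (per_chem["cas"] == "SYN-000")
                ]["ear_acc5"]
                >= loec
            ).any()
            for sid in high["sample_id"]
        )
        assert n_driver / len(high) >= 0.9

    def test_driver_spec_unknown_chemical_rejected(self):
        with pytest.raises(ValueError):
            generate_campaign(small_cfg(driver_spec=(("NOPE-1", 10.0),)))


class TestRecoverParameters:
    def test_noiseless_recovery_is_exact(self):
        cfg = small_cfg(assay_sigma=0.0, conc_sigma=0.0, site_sigma=0.0,
                        loq_ug_L=0.0, flag_prob=0.0)
        campaign = generate_campaign(cfg)
        bundle = run_pipeline_objects(
            RunConfig(), campaign.chemicals, campaign.assays, campaign.samples
        )
        _, statuses, acc5, _ = run_stages(campaign)
        from estromix.prioritize import Priority, PriorityAssignment

        assignments = [
            PriorityAssignment(
                cas=rec.cas, category=Priority[rec.category.upper()]
            )
            for rec in bundle.priority_report.itertuples(index=False)
        ]
        report = recover_parameters(statuses, acc5, assignments, campaign.truth)
        conf = report.status_confusion
        # all mass on the diagonal: estimated status equals true status
        for truth_label in conf.index:
            assert conf.loc[truth_label, truth_label] == conf.loc[truth_label].sum()
        assert (report.acc5_relative_error["rel_error"] < 1e-12).all()

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            CampaignConfig(n_sites=0)
        with pytest.raises(ValueError):
            CampaignConfig(n_chemicals=3, n_true_eedcs=2, n_decoys=2, n_untested=2)
        with pytest.raises(ValueError):
            CampaignConfig(conc_sigma=-0.1)
        with pytest.raises(ValueError):
            CampaignConfig(matrix_weights={"blood": 1.0})
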