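"""Driver/contributor decision tree and priority-category resolution."""

import pandas as pd
import pytest

from estromix.bioactivity import EstrogenicityStatus, Status
from estromix.classify import ActivityLevel, SampleActivity
from estromix.prioritize import (
    ChemicalRole,
    Priority,
    Role,
    assign_roles,
    driver_fraction,
    resolve_categories,
)

# default bile thresholds: NOEC 540, LOEC 2700
NOEC, LOEC = 540.0, 2700.0


def sample_activity(level, sample_id="s1"):
    return SampleActivity(
        sample_id=sample_id,
        activity=level,
        governing_noec=NOEC,
        governing_loec=LOEC,
    )


def ear_rows(sample_id, ears):
    total = sum(ears.values())
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "site_id": "A",
                "matrix": "bile",
                "cas": cas,
                "ear_acc5": e,
                "pct_contribution": 100.0 * e / total,
            }
            for cas, e in ears.items()
        ]
    )


class TestAssignRoles:
    def test_high_sample_driver_major_and_boundary_major(self):
        # EAR_mix 3000: A exceeds the LOEC alone, B and C contribute >= 1%
        rows = ear_rows("s1", {"A": 2800.0, "B": 150.0, "C": 30.0})
        roles = {
            r.cas: r
            for r in assign_roles(sample_activity(ActivityLevel.HIGH), rows)
        }
        assert roles["A"].role is Role.DRIVER
        assert roles["A"].provisional_priority is Priority.HIGH_PRIORITY
        assert roles["B"].role is Role.MAJOR_CONTRIBUTOR
        assert roles["B"].provisional_priority is Priority.HIGH_PRIORITY
        assert roles["C"].role is Role.MAJOR_CONTRIBUTOR  # exactly 1%
        assert roles["C"].provisional_priority is Priority.HIGH_PRIORITY

    def test_high_sample_minor_contributor_above_noec_goes_to_watch_list(self):
        # 550/60000 < 1% but 550 >= NOEC 540
        rows = ear_rows("s1", {"big": 59450.0, "small": 550.0})
        roles = {
            r.cas: r
            for r in assign_roles(sample_activity(ActivityLevel.HIGH), rows)
        }
        assert roles["small"].role is Role.MINOR_CONTRIBUTOR
        assert roles["small"].provisional_priority is Priority.WATCH_LIST

    def test_high_sample_minor_contributor_below_noec_is_low_priority(self):
        rows = ear_rows("s1", {"big": 99990.0, "tiny": 10.0})
        roles = {
            r.cas: r
            for r in assign_roles(sample_activity(ActivityLevel.HIGH), rows)
        }
        assert roles["tiny"].role is Role.MINOR_CONTRIBUTOR
        assert roles["tiny"].provisional_priority is Priority.LOW_PRIORITY

    def test_medium_sample_noec_exceedance_is_driver_watch_list(self):
        rows = ear_rows("s1", {"A": 600.0, "B": 400.0})
        roles = {
            r.cas: r
            for r in assign_roles(sample_activity(ActivityLevel.MEDIUM), rows)
        }
        assert roles["A"].role is Role.DRIVER
        assert roles["A"].provisional_priority is Priority.WATCH_LIST
        assert roles["B"].role is Role.MAJOR_CONTRIBUTOR
        assert roles["B"].provisional_priority is Priority.WATCH_LIST

    def test_low_sample_rejected(self):
        with pytest.raises(ValueError):
            assign_roles(sample_activity(ActivityLevel.LOW), ear_rows("s1", {"A": 1.0}))

    def test_roles_partition_the_sample(self):
        rows = ear_rows("s1", {"A": 2800.0, "B": 150.0, "C": 1.0})
        roles = assign_roles(sample_activity(ActivityLevel.HIGH), rows)
        assert sorted(r.cas for r in roles) == ["A", "B", "C"]

    def test_sole_detected_eedc_driver_is_full_contributor(self):
        rows = ear_rows("s1", {"A": 3000.0})
        (role,) = assign_roles(sample_activity(ActivityLevel.HIGH), rows)
        assert role.role is Role.DRIVER
        assert role.pct_contribution == pytest.approx(100.0)

    def test_raising_concentration_never_demotes_role(self):
        order = {
            Role.MINOR_CONTRIBUTOR: 0,
            Role.MAJOR_CONTRIBUTOR: 1,
            Role.DRIVER: 2,
        }
        others = {"big": 59450.0}
        previous = -1
        for ear in [5.0, 550.0, 700.0, 2800.0]:
            rows = ear_rows("s1", {**others, "x": ear})
            roles = {
                r.cas: r
                for r in assign_roles(sample_activity(ActivityLevel.HIGH), rows)
            }
            assert order[roles["x"].role] >= previous
            previous = order[roles["x"].role]


def provisional(cas, sample_id, prio, role=Role.MINOR_CONTRIBUTOR):
    return ChemicalRole(
        sample_id=sample_id,
        cas=cas,
        role=role,
        pct_contribution=50.0,
        provisional_priority=prio,
    )


class TestResolveCategories:
    def _statuses(self):
        return [
            EstrogenicityStatus(cas="A", status=Status.ACTIVE_EEDC),
            EstrogenicityStatus(cas="B", status=Status.ACTIVE_EEDC),
            EstrogenicityStatus(cas="U", status=Status.INSUFFICIENT_INFORMATION),
            EstrogenicityStatus(cas="D", status=Status.EXCLUDED_LOW_AUC),
        ]

    def test_conflicts_resolve_to_higher_category(self):
        provisionals = [
            provisional("A", "s1", Priority.WATCH_LIST),
            provisional("A", "s2", Priority.HIGH_PRIORITY, Role.DRIVER),
        ]
        out = resolve_categories(provisionals, self._statuses(), {"A"})
        assert out[0].category is Priority.HIGH_PRIORITY
        assert out[0].roles_seen == {Role.MINOR_CONTRIBUTOR, Role.DRIVER}

    def test_resolution_is_order_independent_and_idempotent(self):
        provisionals = [
            provisional("A", "s1", Priority.WATCH_LIST),
            provisional("A", "s2", Priority.HIGH_PRIORITY),
            provisional("A", "s3", Priority.LOW_PRIORITY),
        ]
        forward = resolve_categories(provisionals, self._statuses(), {"A"})
        backward = resolve_categories(provisionals[::-1], self._statuses(), {"A"})
        assert forward == backward
        again = resolve_categories(provisionals, self._statuses(), {"A"})
        assert forward == again

    def test_active_eedc_only_in_low_samples_is_low_priority(self):
        out = resolve_categories([], self._statuses(), {"A"})
        assert len(out) == 1
        assert out[0].cas == "A"
        assert out[0].category is Priority.LOW_PRIORITY

    def test_untested_detected_chemical_is_insufficient_information(self):
        out = resolve_categories([], self._statuses(), {"U"})
        assert out[0].category is Priority.INSUFFICIENT_INFORMATION

    def test_detected_excluded_chemical_gets_no_assignment(self):
        assert resolve_categories([], self._statuses(), {"D"}) == []

    def test_undetected_chemicals_get_no_assignment(self):
        assert resolve_categories([], self._statuses(), set()) == []


class TestDriverFraction:
    def _activities(self, rows):
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

    def test_every_high_sample_single_chemical(self):
        acts = self._activities(
            [("s1", "bile", 3000.0, "high", NOEC, LOEC)]
        )
        per_chem = ear_rows("s1", {"A": 2900.0, "B": 100.0})
        out = driver_fraction(acts, per_chem)
        assert out.frac_single_chemical_above_loec == pytest.approx(1.0)
        assert out.driver_counts_per_high_sample == {"s1": 1}

    def test_no_single_chemical_exceedance(self):
        acts = self._activities([("s1", "bile", 3000.0, "high", NOEC, LOEC)])
        per_chem = ear_rows("s1", {"A": 1500.0, "B": 1500.0})
        out = driver_fraction(acts, per_chem)
        assert out.frac_single_chemical_above_loec == pytest.approx(0.0)
        # both chemicals still exceed the NOEC individually
        assert out.frac_single_chemical_above_noec == pytest.approx(1.0)

    def test_low_samples_are_ignored(self):
        acts = self._activities(
            [
                ("s1", "bile", 100.0, "low", NOEC, LOEC),
                ("s2", "bile", 600.0, "medium", NOEC, LOEC),
            ]
        )
        per_chem = ear_rows("s2", {"A": 300.0, "B": 300.0})
        out = driver_fraction(acts, per_chem)
        assert out.n_above_noec == 1
        assert out.n_above_loec == 0
        assert out.frac_single_chemical_above_noec == pytest.approx(0.0)
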