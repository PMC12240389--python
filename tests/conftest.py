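"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from estromix.bioactivity import AssayActivity, ChemicalRecord
from estromix.exposure import Measurement, Sample


def percentile_oracle(values, q):
    """Sort-and-interpolate percentile at rank q*(n-1), written
    independently of numpy's implementation."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def spearman_oracle(x, y):
    """Rank (average ranks for ties) then Pearson, from first principles."""

    def avg_ranks(v):
        v = list(map(float, v))
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


@pytest.fixture
def simple_chemicals() -> dict[str, ChemicalRecord]:
    """A tiny registry: one potent e-EDC, one weak one, one decoy-style."""
    return {
        "50-28-2": ChemicalRecord(
            cas="50-28-2",
            name="17beta-estradiol",
            chem_class="hormone",
            molecular_weight=272.38,
            auc_score=0.94,
            eef=1.0,
        ),
        "80-05-7": ChemicalRecord(
            cas="80-05-7",
            name="bisphenol A",
            chem_class="industrial",
            molecular_weight=228.29,
            auc_score=0.21,
            eef=1e-5,
            bcf_tissue_water=68.0,
        ),
        "99-99-9": ChemicalRecord(
            cas="99-99-9",
            name="decoyphenol",
            chem_class="industrial",
            molecular_weight=300.0,
            auc_score=0.01,
        ),
    }


def make_assay(cas, assay_id="ACEA_ER_80hr", acc=0.0, active=True, flags=()):
    return AssayActivity(
        cas=cas,
        assay_id=assay_id,
        acc_log10_uM=acc if active else None,
        active=active,
        quality_flags=frozenset(flags),
    )


def make_bile_sample(sample_id, site_id, concs_ng_mL, sex="male", year=2015):
    """Bile sample from a {cas: concentration or None} mapping."""
    measurements = tuple(
        Measurement(
            cas=cas,
            value=v,
            unit="ng_per_mL",
            detected=v is not None,
            loq=0.1,
        )
        for cas, v in concs_ng_mL.items()
    )
    return Sample(
        sample_id=sample_id,
        site_id=site_id,
        matrix="bile",
        year=year,
        measurements=measurements,
        species="English sole",
        sex=sex,
    )
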