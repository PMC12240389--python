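"""Small published reference tables bundled with the package.

These are transcriptions of printed summary tables from the Salish Sea
English sole bile survey that anchors the default configuration:

* ``load_salish_site_p95`` — per-site 95th-percentile EAR_mix summaries
  for the 18 bile sampling locations (male English sole, 2011–2019);
* ``load_salish_field_response`` — field measures of organism response
  (percent male vitellogenin induction and percent females with altered
  reproductive timing, surveyed 1997–2001) for the ten sites that have
  them.

They let the site-classification stage be exercised end to end without
access to the underlying per-sample bile chemistry.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from estromix.classify import FieldResponse


def _read(name: str) -> pd.DataFrame:
    with resources.files("estromix.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_salish_site_p95() -> pd.DataFrame:
    """Columns: site_id, n_samples, p95_ear_mix (18 rows)."""
    return _read("salish_site_p95.csv")


def load_salish_field_response() -> list[FieldResponse]:
    df = _read("salish_field_response.csv")
    return [
        FieldResponse(
            site_id=rec.site_id,
            pct_male_vtg=rec.pct_male_vtg,
            pct_female_altered_timing=rec.pct_female_altered_timing,
        )
        for rec in df.itertuples(index=False)
    ]
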