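"""Effect-anchored EAR thresholds in water- and bile-concentration space.

Anchors are the no- and lowest-observed-effect concentrations (NOEC
0.005 µg/L, LOEC 0.025 µg/L) for vitellogenin induction in adult male
zebrafish exposed to 17β-estradiol.  The calibration ratio (median
EAR_mix/EEQ_mix, default 27) translates those E2 concentrations onto the
EAR scale; a range of bile-water bioaccumulation factors for E2 in
juvenile rainbow trout (BCF_bw 4000–13000) then carries the water
thresholds into bile-concentration space:

    NOEC_EAR  = NOEC × ratio          LOEC_EAR  = LOEC × ratio
    NOEC_bEAR = NOEC_EAR × BCF_bw     LOEC_bEAR = LOEC_EAR × BCF_bw

Thresholds are kept unrounded internally — classification always uses
exact values — and reported at two significant figures for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_NOEC_UG_L = 0.005
DEFAULT_LOEC_UG_L = 0.025
DEFAULT_CALIBRATION_RATIO = 27.0
DEFAULT_BCF_BW_LOW = 4000.0
DEFAULT_BCF_BW_HIGH = 13000.0


@dataclass(frozen=True)
class BenchmarkConfig:
    """E2 effect benchmarks and translation constants."""

    noec_ug_L: float = DEFAULT_NOEC_UG_L
    loec_ug_L: float = DEFAULT_LOEC_UG_L
    calibration_ratio: float = DEFAULT_CALIBRATION_RATIO
    bcf_bw_low: float = DEFAULT_BCF_BW_LOW
    bcf_bw_high: float = DEFAULT_BCF_BW_HIGH

    def __post_init__(self) -> None:
        if not 0 < self.noec_ug_L < self.loec_ug_L:
            raise ValueError(
                f"require 0 < NOEC < LOEC, got {self.noec_ug_L}, {self.loec_ug_L}"
            )
        if not self.calibration_ratio > 0:
            raise ValueError("calibration_ratio must be > 0")
        if not 0 < self.bcf_bw_low <= self.bcf_bw_high:
            raise ValueError(
                f"require 0 < bcf_bw_low <= bcf_bw_high, got "
                f"{self.bcf_bw_low}, {self.bcf_bw_high}"
            )


@dataclass(frozen=True)
class ThresholdSet:
    """Unrounded water- and bile-based EAR thresholds."""

    noec_ear: float
    loec_ear: float
    noec_bear_low: float
    noec_bear_high: float
    loec_bear_low: float
    loec_bear_high: float

    def __post_init__(self) -> None:
        if not self.noec_ear < self.loec_ear:
            raise ValueError("noec_ear must be < loec_ear")
        if not (
            self.noec_bear_low < self.loec_bear_low
            and self.noec_bear_high < self.loec_bear_high
        ):
            raise ValueError("bile NOEC thresholds must sit below bile LOECs")


def derive_thresholds(cfg: BenchmarkConfig = BenchmarkConfig()) -> ThresholdSet:
    """Translate E2 NOEC/LOEC benchmarks into EAR-scale thresholds."""
    noec_ear = cfg.noec_ug_L * cfg.calibration_ratio
    loec_ear = cfg.loec_ug_L * cfg.calibration_ratio
    return ThresholdSet(
        noec_ear=noec_ear,
        loec_ear=loec_ear,
        noec_bear_low=noec_ear * cfg.bcf_bw_low,
        noec_bear_high=noec_ear * cfg.bcf_bw_high,
        loec_bear_low=loec_ear * cfg.bcf_bw_low,
        loec_bear_high=loec_ear * cfg.bcf_bw_high,
    )


def round_sig(value: float, sig_figs: int) -> float:
    """Round half-up to ``sig_figs`` significant figures."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    scale = 10.0 ** (exponent - sig_figs + 1)
    # floor(x + 0.5) implements round-half-up on the scaled value
    return math.floor(abs(value) / scale + 0.5) * scale * math.copysign(1.0, value)


def report_rounded(t: ThresholdSet, sig_figs: int = 2) -> pd.DataFrame:
    """Display table with exact and significant-figure-rounded thresholds.

    Rounding is presentational only; classification elsewhere always
    uses the exact values.
    """
    rows = [
        ("noec_ear", t.noec_ear),
        ("loec_ear", t.loec_ear),
        ("noec_bear_low", t.noec_bear_low),
        ("noec_bear_high", t.noec_bear_high),
        ("loec_bear_low", t.loec_bear_low),
        ("loec_bear_high", t.loec_bear_high),
    ]
    return pd.DataFrame(
        [
            {"threshold": name, "exact": v, "rounded": round_sig(v, sig_figs)}
            for name, v in rows
        ]
    )
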