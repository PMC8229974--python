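"""Phenotype quantities and classification thresholds.

Percent inhibition by rhsTRAIL (100 ng/mL) comes from a proliferation
assay: 100*(1 - treated/untreated radioactivity).  RFI is the ratio of
specific-antibody to control-staining mean fluorescence intensity.  The
methylation classification partitions the (DR4%, DR5%) plane at the 1%
threshold into four categories, with a highly-methylated flag at >=10%
on both genes; TRAIL sensitivity is three-way at >=80% (sensitive) and
<25% (resistant) inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "MethylationCategory",
    "MethylationCall",
    "TrailCategory",
    "MethylationBand",
    "percent_inhibition",
    "rfi",
    "classify_methylation",
    "classify_trail",
    "methylation_band",
    "methylation_category_codes",
]


class MethylationCategory(str, Enum):
    UNMETHYLATED = "UNMETHYLATED"          # DR4 < 1% and DR5 < 1%
    DR4_PREF_UNMETH = "DR4_PREF_UNMETH"    # DR4 < 1%, DR5 >= 1%
    DR5_PREF_UNMETH = "DR5_PREF_UNMETH"    # DR4 >= 1%, DR5 < 1%
    METHYLATED = "METHYLATED"              # both >= 1%


class TrailCategory(str, Enum):
    SENSITIVE = "SENSITIVE"        # percent inhibition >= 80
    INTERMEDIATE = "INTERMEDIATE"  # 25 <= inhibition < 80
    RESISTANT = "RESISTANT"        # inhibition < 25


class MethylationBand(str, Enum):
    UNMETHYLATED = "unmethylated"  # [0, 1)
    WEAK = "weak"                  # [1, 10)
    HIGH = "high"                  # [10, 100]


@dataclass(frozen=True)
class MethylationCall:
    category: MethylationCategory
    highly_methylated: bool  # both genes >= 10%


def percent_inhibition(cpm_treated: float, cpm_untreated: float) -> float:
    """Percent growth inhibition from treated/untreated counts per minute.

    100*(1 - treated/untreated); negative values (growth stimulation) are
    retained, clipped at -100.
    """
    if cpm_untreated <= 0:
        raise ValueError("untreated counts must be positive")
    if cpm_treated < 0:
        raise ValueError("treated counts must be non-negative")
    return float(max(100.0 * (1.0 - cpm_treated / cpm_untreated), -100.0))


def rfi(mfi_specific: float, mfi_control: float) -> float:
    """Relative fluorescence intensity: specific / control staining MFI."""
    if mfi_specific <= 0 or mfi_control <= 0:
        raise ValueError("MFI values must be positive")
    return float(mfi_specific / mfi_control)


def _check_pct(value: float, name: str) -> float:
    v = float(value)
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"{name} must lie in [0, 100], got {value}")
    return v


def methylation_category_codes(dr4_pct, dr5_pct) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized category codes for arrays of (DR4%, DR5%) pairs.

    Codes: 0 UNMETHYLATED, 1 DR4_PREF_UNMETH, 2 DR5_PREF_UNMETH,
    3 METHYLATED; the second array is the highly-methylated flag.
    """
    d4 = np.asarray(dr4_pct, float)
    d5 = np.asarray(dr5_pct, float)
    if np.any((d4 < 0) | (d4 > 100) | (d5 < 0) | (d5 > 100)):
        raise ValueError("percent methylation must lie in [0, 100]")
    codes = np.where(
        d4 < 1.0,
        np.where(d5 < 1.0, 0, 1),
        np.where(d5 < 1.0, 2, 3),
    )
    high = (d4 >= 10.0) & (d5 >= 10.0)
    return codes, high


_CODE_TO_CATEGORY = {
    0: MethylationCategory.UNMETHYLATED,
    1: MethylationCategory.DR4_PREF_UNMETH,
    2: MethylationCategory.DR5_PREF_UNMETH,
    3: MethylationCategory.METHYLATED,
}


def classify_methylation(dr4_pct: float, dr5_pct: float) -> MethylationCall:
    """Four-way partition of the (DR4%, DR5%) plane at the 1% threshold.

    highly_methylated iff both genes are >= 10% (which implies METHYLATED).
    """
    code, high = methylation_category_codes(
        _check_pct(dr4_pct, "dr4_pct"), _check_pct(dr5_pct, "dr5_pct")
    )
    return MethylationCall(_CODE_TO_CATEGORY[int(code)], bool(high))


def classify_trail(percent_inhibition: float) -> TrailCategory:
    """Three-way TRAIL-sensitivity partition of [-100, 100]."""
    v = float(percent_inhibition)
    if not -100.0 <= v <= 100.0:
        raise ValueError(f"percent inhibition must lie in [-100, 100], got {v}")
    if v >= 80.0:
        return TrailCategory.SENSITIVE
    if v < 25.0:
        return TrailCategory.RESISTANT
    return TrailCategory.INTERMEDIATE


def methylation_band(pct: float) -> MethylationBand:
    """Half-open bands [0,1) unmethylated, [1,10) weak, [10,100] high."""
    v = _check_pct(pct, "pct")
    if v < 1.0:
        return MethylationBand.UNMETHYLATED
    if v < 10.0:
        return MethylationBand.WEAK
    return MethylationBand.HIGH
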