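"""Four-way MET copy-number status calling, and the FISH-side reference
classification.

The NGS decision table combines the MET gene copy number (GCN, from the
capture bins over MET) with the 7q arm segmentation:

===============  ==========================================================
MET GCN < 2.3    negative
MET GCN >= 2.3   by the amplified fraction of 7q:
                 fraction >= 80%                       -> polysomy
                 MET region not CNG or fraction <= 10% -> amplification
                 otherwise (CNG MET region, 10-80%)    -> pan-MET
                                                          amplification
===============  ==========================================================

The polysomy clause is evaluated first so that an arm-wide gain is never
reported as focal amplification; the boundaries (<=10%, 10~80%, >=80%)
follow the decision table of record.

FISH reference rule: amplification when MET/CEP7 ratio > 2.0; otherwise
polysomy when mean GCN >= 5; otherwise negative. FISH reports only the ratio
and the mean signal count, so this is the simplest rule consistent with
ratio-based amplification calling; it is config-overridable and external
FISH labels can always be supplied instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyDataError, ValidationError
from .io import CAPTURE, Bin
from .segmentation import ArmSegmentation

NEGATIVE = "negative"
AMPLIFICATION = "amplification"
PAN_MET_AMPLIFICATION = "pan_met_amplification"
POLYSOMY = "polysomy"

#: the four NGS statuses, in reporting order
STATUSES = (NEGATIVE, AMPLIFICATION, PAN_MET_AMPLIFICATION, POLYSOMY)

#: the three FISH statuses
FISH_STATUSES = (NEGATIVE, AMPLIFICATION, POLYSOMY)


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision-table thresholds.

    gcn_threshold
        MET GCN below this is negative; it is also the CNG threshold shared
        with the arm caller (default 2.3).
    frac_amp_max / frac_polysomy_min
        Amplified-fraction boundaries of the decision table: <= frac_amp_max
        (default 0.10) is focal amplification, >= frac_polysomy_min (default
        0.80) is polysomy, in between is pan-MET amplification.
    fish_ratio_threshold / fish_gcn_threshold
        FISH rule: MET/CEP7 ratio > 2.0 -> amplification; mean GCN >= 5
        without a high ratio -> polysomy.
    met_band
        Optional band-name override for the MET anchor band (e.g. "q31.2");
        by default the band containing the MET capture bins is used.
    """

    gcn_threshold: float = 2.3
    frac_amp_max: float = 0.10
    frac_polysomy_min: float = 0.80
    fish_ratio_threshold: float = 2.0
    fish_gcn_threshold: float = 5.0
    met_band: str | None = None

    def __post_init__(self):
        if not (0.0 < self.frac_amp_max < self.frac_polysomy_min < 1.0):
            raise ValidationError("need 0 < frac_amp_max < frac_polysomy_min < 1")
        if self.gcn_threshold <= 0:
            raise ValidationError("gcn_threshold must be positive")


@dataclass(frozen=True)
class MetCall:
    """The four-way MET status with its evidence."""

    status: str
    met_gcn: float
    amplified_fraction: float
    met_region_cng: bool
    met_band: str

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValidationError(f"unknown MET status {self.status!r}")


@dataclass(frozen=True)
class FishResult:
    """A FISH readout (mean MET and CEP7 signals per cell) with its call."""

    mean_gcn: float
    cep7: float
    ratio: float
    status: str


def met_gcn_estimate(capture_bins: Sequence[Bin], gene: str = "MET") -> float:
    """MET gene copy number as the unweighted mean of the MET capture bins."""
    cns = [
        b.cn
        for b in capture_bins
        if b.kind == CAPTURE and (b.gene or "").upper() == gene.upper()
    ]
    if not cns:
        raise EmptyDataError(f"no {gene} capture bins and no externally supplied GCN")
    return float(np.mean(cns))


def classify_met(
    met_gcn: float,
    seg: ArmSegmentation,
    cfg: ClassifierConfig | None = None,
    met_band: str | None = None,
) -> MetCall:
    """Apply the four-way decision table to a finalized arm segmentation.

    ``met_band`` (or ``cfg.met_band``) names the anchor band whose region
    supplies the CNG flag; it must be present in the segmentation's band map.
    """
    cfg = cfg or ClassifierConfig()
    band = met_band or cfg.met_band
    if band is None:
        raise ValidationError("MET anchor band not specified and not resolvable")
    hit = seg.region_containing(band)
    if hit is None:
        raise ValidationError(f"MET anchor band {band!r} is absent from the band map")
    _, region = hit
    region.contains_met_band = True
    met_region_cng = region.is_cng
    frac = seg.amplified_fraction

    if met_gcn < cfg.gcn_threshold:
        status = NEGATIVE
    elif frac >= cfg.frac_polysomy_min:
        status = POLYSOMY
    elif (not met_region_cng) or frac <= cfg.frac_amp_max:
        status = AMPLIFICATION
    else:
        status = PAN_MET_AMPLIFICATION
    return MetCall(
        status=status,
        met_gcn=float(met_gcn),
        amplified_fraction=float(frac),
        met_region_cng=met_region_cng,
        met_band=band,
    )


def met_cep7_ratio(mean_gcn: float, cep7: float) -> float:
    """MET/CEP7 signal ratio (displayed to one decimal in reports)."""
    if cep7 <= 0:
        raise ValidationError("CEP7 signal count must be > 0")
    return float(mean_gcn) / float(cep7)


def classify_fish(
    mean_gcn: float,
    cep7: float,
    cfg: ClassifierConfig | None = None,
) -> FishResult:
    """FISH-side classification from mean MET and CEP7 signals per cell."""
    cfg = cfg or ClassifierConfig()
    ratio = met_cep7_ratio(mean_gcn, cep7)
    if ratio > cfg.fish_ratio_threshold:
        status = AMPLIFICATION
    elif mean_gcn >= cfg.fish_gcn_threshold:
        status = POLYSOMY
    else:
        status = NEGATIVE
    return FishResult(mean_gcn=float(mean_gcn), cep7=float(cep7), ratio=ratio, status=status)
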