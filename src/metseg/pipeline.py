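"""End-to-end driver: bins + band map -> arm segmentation -> MET call."""
from __future__ import annotations

from typing import Sequence

from .classifier import ClassifierConfig, MetCall, classify_met, met_gcn_estimate
from .errors import ValidationError
from .io import CAPTURE, Bin, CytoBand
from .segmentation import ArmSegmentation, SegmentationConfig, segment_arm


def locate_gene_band(
    bins: Sequence[Bin], bands: Sequence[CytoBand], gene: str = "MET"
) -> str:
    """Name of the band containing the midpoint of a gene's capture bins."""
    gene_bins = [
        b for b in bins if b.kind == CAPTURE and (b.gene or "").upper() == gene.upper()
    ]
    if not gene_bins:
        raise ValidationError(f"no {gene} capture bins to locate the anchor band from")
    mid = (min(b.start for b in gene_bins) + max(b.end for b in gene_bins)) // 2
    for band in bands:
        if band.start <= mid < band.end:
            return band.name
    raise ValidationError(f"{gene} locus at {mid} falls outside the supplied band map")


def call_sample(
    bins: Sequence[Bin],
    band_map: Sequence[CytoBand],
    chrom: str = "chr7",
    seg_cfg: SegmentationConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    met_gcn: float | None = None,
    met_band: str | None = None,
) -> tuple[MetCall, ArmSegmentation]:
    """Run the full caller on one sample.

    Segments the q arm of ``chrom`` from the off-target bins, estimates the
    MET gene copy number from the capture bins (unless supplied), resolves
    the MET anchor band (override > config > band containing the MET capture
    bins), and applies the decision table.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    q_bands = [b for b in band_map if b.chrom == chrom and b.arm == "q"]
    if not q_bands:
        raise ValidationError(f"band map has no q bands for {chrom}")
    chrom_bins = [b for b in bins if b.chrom == chrom]
    seg = segment_arm(chrom_bins, q_bands, seg_cfg)
    if met_gcn is None:
        met_gcn = met_gcn_estimate(chrom_bins)
    band = met_band or clf_cfg.met_band
    if band is None:
        band = locate_gene_band(chrom_bins, q_bands)
    call = classify_met(met_gcn, seg, clf_cfg, met_band=band)
    return call, seg
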