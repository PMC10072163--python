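"""Cytoband-level segmentation of a chromosome arm by t-test merging.

The arm caller works on the wide off-target bins of a targeted panel. Each
bin is assigned to the cytoband containing its midpoint; adjacent bands whose
bin copy numbers are statistically indistinguishable (Welch t-test,
P >= alpha, default 0.1) are grown into regions; similar adjacent regions are
then merged iteratively; and each final region is flagged as a copy-number
gain (CNG) when its mean copy number exceeds the CNG threshold (default 2.3,
diploid baseline 2). The amplified fraction of the arm — the fraction of the
arm's genomic length covered by CNG regions — is the quantity that separates
focal amplification (small) from arm-level polysomy (large).

Region formation and merging:

* a band joins the growing region only when its t-test against every band
  already in the region is non-significant (all-pairs rule; an adjacent-only
  variant is selectable via ``SegmentationConfig.pairwise``);
* two adjacent regions merge when the fraction ``f`` of non-significant
  cross-region band pairs exceeds 50% (rule i), or when the larger region has
  more than seven bands and ``f`` exceeds 30% (rule ii); sweeps run
  left-to-right, recomputing after each merge, until a full sweep makes no
  change (a fixpoint).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EmptyDataError, ValidationError
from .io import CAPTURE, OFFTARGET, Bin, CytoBand


@dataclass(frozen=True)
class SegmentationConfig:
    """Tuning constants of the arm caller.

    alpha
        Non-significance threshold for the band t-tests: P >= alpha means
        "no difference" (default 0.1).
    cng_threshold
        A region is a copy-number gain when its mean copy number is strictly
        higher than this (default 2.3).
    merge_frac_major / merge_frac_minor / merge_big_region_bands
        Merge rule i: merge when the non-significant cross-pair fraction f is
        strictly higher than ``merge_frac_major`` (default 0.5). Merge rule
        ii: merge when the larger region has strictly more than
        ``merge_big_region_bands`` bands (default 7) and f is strictly higher
        than ``merge_frac_minor`` (default 0.3).
    min_bins_per_band
        Bands with fewer bins are pre-merged into a neighbour so every t-test
        is defined (default 2).
    pairwise
        "all" (default): a band joins a region only if non-significant
        against every member band. "adjacent": only against the last band.
    equal_var
        Use the pooled-variance t-test instead of Welch's (default False).
    """

    alpha: float = 0.1
    cng_threshold: float = 2.3
    merge_frac_major: float = 0.5
    merge_frac_minor: float = 0.3
    merge_big_region_bands: int = 7
    min_bins_per_band: int = 2
    pairwise: str = "all"
    equal_var: bool = False

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.cng_threshold <= 0:
            raise ValidationError("cng_threshold must be positive")
        if not (0.0 < self.merge_frac_minor <= self.merge_frac_major < 1.0):
            raise ValidationError("need 0 < merge_frac_minor <= merge_frac_major < 1")
        if self.merge_big_region_bands < 1 or self.min_bins_per_band < 1:
            raise ValidationError("band/bin count thresholds must be >= 1")
        if self.pairwise not in ("all", "adjacent"):
            raise ValidationError("pairwise must be 'all' or 'adjacent'")


@dataclass(frozen=True)
class BandProfile:
    """A cytoband (or a run of pre-merged cytobands) with its member
    off-target bin copy numbers."""

    bands: tuple[CytoBand, ...]
    bin_cns: tuple[float, ...]

    @property
    def band(self) -> CytoBand:
        return self.bands[0]

    @property
    def name(self) -> str:
        return "+".join(b.name for b in self.bands)

    @property
    def chrom(self) -> str:
        return self.bands[0].chrom

    @property
    def start(self) -> int:
        return self.bands[0].start

    @property
    def end(self) -> int:
        return self.bands[-1].end

    @property
    def length(self) -> int:
        return sum(b.length for b in self.bands)

    @property
    def n_bins(self) -> int:
        return len(self.bin_cns)

    @property
    def mean_cn(self) -> float:
        return float(np.mean(self.bin_cns)) if self.bin_cns else math.nan


@dataclass
class Region:
    """A contiguous run of band profiles with pooled statistics.

    ``mean_cn`` is the unweighted mean over all member *bins* (bins are the
    measurement unit, so larger bands weigh more than band means would).
    """

    bands: tuple[BandProfile, ...]
    mean_cn: float
    genomic_length: int
    is_cng: bool
    contains_met_band: bool = False

    @classmethod
    def from_profiles(cls, profiles: Sequence[BandProfile], cng_threshold: float) -> "Region":
        profiles = tuple(profiles)
        cns = [c for p in profiles for c in p.bin_cns]
        if not cns:
            raise EmptyDataError("region has no bins")
        mean_cn = float(np.mean(cns))
        length = sum(p.length for p in profiles)
        if length <= 0:
            raise ValidationError("region has non-positive genomic length")
        return cls(
            bands=profiles,
            mean_cn=mean_cn,
            genomic_length=length,
            is_cng=mean_cn > cng_threshold,
        )

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_bins(self) -> int:
        return sum(p.n_bins for p in self.bands)

    def band_names(self) -> list[str]:
        return [b.name for p in self.bands for b in p.bands]


@dataclass
class ArmSegmentation:
    """Final segmentation of one chromosome arm: an ordered, non-overlapping
    partition of the band set into regions, with the amplified fraction."""

    arm: str
    regions: list[Region]
    arm_length: int
    amplified_fraction: float

    def region_containing(self, band_name: str) -> tuple[int, Region] | None:
        for i, r in enumerate(self.regions):
            if band_name in r.band_names():
                return i, r
        return None

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "region": i,
                    "start_band": r.bands[0].bands[0].name,
                    "end_band": r.bands[-1].bands[-1].name,
                    "n_bands": r.n_bands,
                    "n_bins": r.n_bins,
                    "mean_cn": r.mean_cn,
                    "length_bp": r.genomic_length,
                    "is_cng": r.is_cng,
                }
                for i, r in enumerate(self.regions)
            ]
        )


# ---------------------------------------------------------------------------
# Band aggregation
# ---------------------------------------------------------------------------

def assign_bins_to_bands(
    bins: Sequence[Bin],
    bands: Sequence[CytoBand],
    min_bins_per_band: int = 2,
) -> list[BandProfile]:
    """Assign off-target bins to the band containing their midpoint.

    Capture bins are excluded; bins whose midpoint falls outside every band
    are dropped. Bands ending up with fewer than ``min_bins_per_band`` bins
    are pre-merged into the adjacent band whose mean copy number is closer
    (left on ties; a band with no bins at all, which has no mean, goes to its
    left neighbour, or right if it is first), so that every downstream t-test
    is defined.
    """
    if not bands:
        raise EmptyDataError("no bands supplied")
    bands = sorted(bands, key=lambda b: b.start)
    starts = np.array([b.start for b in bands])
    member_cns: list[list[float]] = [[] for _ in bands]
    n_assigned = 0
    for b in bins:
        if b.kind == CAPTURE:
            continue
        if b.chrom != bands[0].chrom:
            continue
        idx = int(np.searchsorted(starts, b.midpoint, side="right")) - 1
        if idx >= 0 and b.midpoint < bands[idx].end:
            member_cns[idx].append(float(b.cn))
            n_assigned += 1
    if n_assigned == 0:
        raise EmptyDataError(
            f"no off-target bins fall within the supplied {bands[0].chrom} bands"
        )
    profiles = [BandProfile((band,), tuple(cns)) for band, cns in zip(bands, member_cns)]

    # pre-merge undersized bands
    while len(profiles) > 1:
        i = next((k for k, p in enumerate(profiles) if p.n_bins < min_bins_per_band), None)
        if i is None:
            break
        p = profiles[i]
        left = profiles[i - 1] if i > 0 else None
        right = profiles[i + 1] if i + 1 < len(profiles) else None
        if left is None:
            j = i + 1
        elif right is None or p.n_bins == 0:
            j = i - 1
        else:
            d_left = abs(left.mean_cn - p.mean_cn)
            d_right = abs(right.mean_cn - p.mean_cn)
            j = i - 1 if d_left <= d_right else i + 1
        lo, hi = min(i, j), max(i, j)
        merged = BandProfile(
            bands=profiles[lo].bands + profiles[hi].bands,
            bin_cns=profiles[lo].bin_cns + profiles[hi].bin_cns,
        )
        profiles[lo : hi + 1] = [merged]
    return profiles


# ---------------------------------------------------------------------------
# Band t-test
# ---------------------------------------------------------------------------

def band_ttest(
    a: BandProfile,
    b: BandProfile,
    alpha: float = 0.1,
    equal_var: bool = False,
) -> tuple[float, bool]:
    """Two-sided t-test on the bin copy numbers of two bands.

    Welch's unequal-variance form by default. Returns ``(p, p >= alpha)``.
    Degenerate rule: when both bands have zero variance, p = 1 if the means
    are equal, else p = 0.
    """
    if a.n_bins < 2 or b.n_bins < 2:
        raise ValidationError(
            f"band t-test requires >= 2 bins per band "
            f"(got {a.n_bins} for {a.name}, {b.n_bins} for {b.name})"
        )
    x = np.asarray(a.bin_cns, dtype=float)
    y = np.asarray(b.bin_cns, dtype=float)
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        p = 1.0 if math.isclose(float(x[0]), float(y[0]), rel_tol=0.0, abs_tol=1e-12) else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
        if math.isnan(p):  # pragma: no cover - scipy returns nan only in degenerate cases
            p = 1.0
    return p, p >= alpha


class _PCache:
    """Memoised pairwise band t-test p-values (band profiles are immutable
    and persist through region merging, so identity keys are safe)."""

    def __init__(self, cfg: SegmentationConfig):
        self.cfg = cfg
        self._cache: dict[tuple[int, int], float] = {}

    def p(self, a: BandProfile, b: BandProfile) -> float:
        key = (id(a), id(b)) if id(a) <= id(b) else (id(b), id(a))
        if key not in self._cache:
            self._cache[key] = band_ttest(a, b, self.cfg.alpha, self.cfg.equal_var)[0]
        return self._cache[key]

    def nonsig(self, a: BandProfile, b: BandProfile) -> bool:
        return self.p(a, b) >= self.cfg.alpha


# ---------------------------------------------------------------------------
# Region formation and merging
# ---------------------------------------------------------------------------

def form_initial_regions(
    profiles: Sequence[BandProfile],
    cfg: SegmentationConfig | None = None,
    _cache: _PCache | None = None,
) -> list[Region]:
    """Grow regions greedily left-to-right along the arm.

    A band joins the current region only if its t-test against every band
    already in the region (or only the last band, with ``pairwise='adjacent'``)
    is non-significant; otherwise it starts a new region. The result is an
    ordered partition of the bands.
    """
    cfg = cfg or SegmentationConfig()
    if not profiles:
        raise EmptyDataError("no band profiles to segment")
    cache = _cache or _PCache(cfg)
    regions: list[Region] = []
    current: list[BandProfile] = [profiles[0]]
    for p in profiles[1:]:
        members = current if cfg.pairwise == "all" else current[-1:]
        if all(cache.nonsig(m, p) for m in members):
            current.append(p)
        else:
            regions.append(Region.from_profiles(current, cfg.cng_threshold))
            current = [p]
    regions.append(Region.from_profiles(current, cfg.cng_threshold))
    return regions


def merge_regions(
    regions: Sequence[Region],
    cfg: SegmentationConfig | None = None,
    _cache: _PCache | None = None,
) -> list[Region]:
    """Merge similar adjacent regions until a fixpoint.

    For each adjacent pair let S be the region with fewer bands and L the
    other (S = left on ties); f is the fraction of cross band pairs (one band
    from S, one from L) whose t-test is non-significant. The pair merges when
    f > merge_frac_major (rule i) or when L has > merge_big_region_bands
    bands and f > merge_frac_minor (rule ii). Sweeps run left-to-right,
    recomputing statistics after each merge, and repeat until a full sweep
    makes no merge.
    """
    cfg = cfg or SegmentationConfig()
    cache = _cache or _PCache(cfg)
    regs = list(regions)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(regs) - 1:
            a, b = regs[i], regs[i + 1]
            s, l = (a, b) if a.n_bands <= b.n_bands else (b, a)
            pairs = [(sb, lb) for sb in s.bands for lb in l.bands]
            f = sum(cache.nonsig(sb, lb) for sb, lb in pairs) / len(pairs)
            if f > cfg.merge_frac_major or (
                l.n_bands > cfg.merge_big_region_bands and f > cfg.merge_frac_minor
            ):
                regs[i : i + 2] = [Region.from_profiles(a.bands + b.bands, cfg.cng_threshold)]
                changed = True
            else:
                i += 1
    return regs


def amplified_fraction(seg: ArmSegmentation) -> float:
    """Fraction of the arm's genomic length covered by CNG regions."""
    if seg.arm_length <= 0:
        raise ValidationError("arm length must be positive")
    return sum(r.genomic_length for r in seg.regions if r.is_cng) / seg.arm_length


def segment_arm(
    bins: Sequence[Bin],
    bands: Sequence[CytoBand],
    cfg: SegmentationConfig | None = None,
) -> ArmSegmentation:
    """Run the full arm caller: band aggregation, region formation, merging,
    CNG flagging and amplified-fraction computation.

    ``bands`` is the band map of one arm (e.g. the q bands of chromosome 7);
    the arm length is the genomic span from the first band start to the last
    band end of that map.
    """
    cfg = cfg or SegmentationConfig()
    if not bands:
        raise EmptyDataError("empty band map")
    arms = {b.arm for b in bands}
    chroms = {b.chrom for b in bands}
    if len(arms) != 1 or len(chroms) != 1:
        raise ValidationError("segment_arm expects bands of a single chromosome arm")
    bands = sorted(bands, key=lambda b: b.start)
    profiles = assign_bins_to_bands(bins, bands, cfg.min_bins_per_band)
    cache = _PCache(cfg)
    initial = form_initial_regions(profiles, cfg, _cache=cache)
    merged = merge_regions(initial, cfg, _cache=cache)
    arm_length = bands[-1].end - bands[0].start
    seg = ArmSegmentation(
        arm=f"{bands[0].chrom}{bands[0].arm}",
        regions=merged,
        arm_length=arm_length,
        amplified_fraction=0.0,
    )
    seg.amplified_fraction = amplified_fraction(seg)
    return seg
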