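"""Seeded generator of bin-level copy-number profiles with known MET-status
truth.

Emulates the data model of a targeted panel run through an off-target-aware
CNV caller: 150 kb off-target bins tiled across a synthetic chromosome 7
(with a ~15-band q arm), plus 120 bp capture bins over MET. Event geometry
is band-snapped so truth fractions are exact:

* negative — diploid (cn 2) everywhere;
* amplification — a focal window of one band (<= 10% of 7q) containing the
  MET band raised to ``focal_cn`` (default uniform 5-15);
* pan-MET amplification — a contiguous band window covering ``pan_fraction``
  of 7q (default uniform 0.15-0.60) containing the MET band, raised to
  ``arm_gain_cn``;
* polysomy — the whole q arm raised to ``arm_gain_cn`` (default uniform
  2.5-4).

Observed copy numbers add Gaussian noise on the linear scale (tissue sd
0.15, plasma sd 0.25 by default). Plasma profiles attenuate the tissue
signal towards diploid by the tumor fraction:
``plasma cn = 2 + tumor_fraction * (tissue cn - 2)``; the plasma MSAF is
emitted as ``min(1, tumor_fraction / 2)`` (heterozygous-variant
approximation). Same seed, same output, bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    AMPLIFICATION,
    NEGATIVE,
    PAN_MET_AMPLIFICATION,
    POLYSOMY,
    STATUSES,
)
from .errors import ValidationError
from .io import CAPTURE, OFFTARGET, Bin, CytoBand, write_cnr, write_cytobands

#: synthetic chromosome 7 geometry
CHROM = "chr7"
P_ARM_END = 60_000_000
Q_ARM_END = 159_000_000
Q_BAND_SIZE = 6_600_000
MET_POS = 110_000_000  # falls in the 8th q band, "q31.2"
MET_BAND = "q31.2"

_Q_BAND_NAMES = (
    "q11.1", "q11.2", "q21.1", "q21.2", "q21.3", "q22", "q31.1", "q31.2",
    "q31.3", "q32.1", "q32.2", "q33", "q34", "q35", "q36",
)
_P_BAND_NAMES = ("p22", "p15", "p11")


def default_band_map() -> list[CytoBand]:
    """Synthetic chr7 band map: 3 p bands over 0-60 Mb, 15 equal q bands of
    6.6 Mb over 60-159 Mb (MET in q31.2)."""
    bands = []
    p_size = P_ARM_END // len(_P_BAND_NAMES)
    for i, name in enumerate(_P_BAND_NAMES):
        bands.append(CytoBand(CHROM, i * p_size, (i + 1) * p_size, name))
    for i, name in enumerate(_Q_BAND_NAMES):
        start = P_ARM_END + i * Q_BAND_SIZE
        bands.append(CytoBand(CHROM, start, start + Q_BAND_SIZE, name))
    return bands


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters. Ranges are (low, high) for uniform draws."""

    band_map: tuple[CytoBand, ...] = field(default_factory=lambda: tuple(default_band_map()))
    offtarget_bin_size: int = 150_000
    n_met_capture_bins: int = 20
    capture_bin_size: int = 120
    noise_sd_tissue: float = 0.15
    noise_sd_plasma: float = 0.25
    status: str = NEGATIVE
    focal_cn: tuple[float, float] = (5.0, 15.0)
    arm_gain_cn: tuple[float, float] = (2.5, 4.0)
    pan_fraction: tuple[float, float] = (0.15, 0.60)
    tumor_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.noise_sd_tissue < 0 or self.noise_sd_plasma < 0:
            raise ValidationError("noise sds must be >= 0")
        if not (0.10 < self.pan_fraction[0] <= self.pan_fraction[1] < 0.80):
            raise ValidationError("pan_fraction range must lie inside (0.10, 0.80)")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValidationError("tumor_fraction must be in [0, 1]")

    @property
    def q_bands(self) -> list[CytoBand]:
        return [b for b in self.band_map if b.arm == "q"]


def _uniform(rng, lo_hi):
    lo, hi = lo_hi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _event_window(spec: SyntheticSpec, rng) -> tuple[float, int, int]:
    """Draw (event cn, first q-band index, last q-band index inclusive) for
    the spec's status; the window always contains the MET band and snaps to
    band boundaries. Negative status returns (2.0, -1, -1)."""
    q = spec.q_bands
    met_idx = next(i for i, b in enumerate(q) if b.name == MET_BAND)
    if spec.status == NEGATIVE:
        return 2.0, -1, -1
    if spec.status == AMPLIFICATION:
        return _uniform(rng, spec.focal_cn), met_idx, met_idx
    if spec.status == POLYSOMY:
        return _uniform(rng, spec.arm_gain_cn), 0, len(q) - 1
    # pan-MET: a band-snapped contiguous window containing the MET band
    frac = _uniform(rng, spec.pan_fraction)
    n_bands = max(2, round(frac * len(q)))
    lo = max(0, met_idx - n_bands + 1)
    hi = min(met_idx, len(q) - n_bands)
    start = int(rng.integers(lo, hi + 1))
    return _uniform(rng, spec.arm_gain_cn), start, start + n_bands - 1


def _underlying_bins(spec: SyntheticSpec, rng) -> tuple[list[Bin], float]:
    """Noiseless bins for the spec's event (event draws consume ``rng``).
    Returns (bins, MET-window cn)."""
    q = spec.q_bands
    event_cn, lo, hi = _event_window(spec, rng)
    if lo >= 0:
        win_start, win_end = q[lo].start, q[hi].end
    else:
        win_start = win_end = -1
    bins: list[Bin] = []
    size = spec.offtarget_bin_size
    for start in range(0, Q_ARM_END, size):
        end = min(start + size, Q_ARM_END)
        mid = (start + end) // 2
        cn = event_cn if win_start <= mid < win_end else 2.0
        bins.append(Bin(CHROM, start, end, cn=cn, gene="Antitarget", kind=OFFTARGET))
    met_cn = event_cn if win_start <= MET_POS < win_end else 2.0
    for i in range(spec.n_met_capture_bins):
        start = MET_POS + i * spec.capture_bin_size
        bins.append(
            Bin(CHROM, start, start + spec.capture_bin_size, cn=met_cn, gene="MET", kind=CAPTURE)
        )
    return bins, met_cn


def _add_noise(bins: Sequence[Bin], sd: float, rng) -> list[Bin]:
    noise = rng.normal(0.0, sd, size=len(bins)) if sd > 0 else np.zeros(len(bins))
    return [replace(b, cn=max(0.0, b.cn + float(e))) for b, e in zip(bins, noise)]


def simulate_underlying(spec: SyntheticSpec) -> tuple[list[Bin], str]:
    """The noiseless profile for ``spec`` (same event draws as
    :func:`simulate_tissue_profile` at the same seed)."""
    rng = np.random.default_rng(spec.seed)
    bins, _ = _underlying_bins(spec, rng)
    return bins, spec.status


def simulate_tissue_profile(spec: SyntheticSpec) -> tuple[list[Bin], str]:
    """A noisy tissue profile with its truth label; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    bins, _ = _underlying_bins(spec, rng)
    return _add_noise(bins, spec.noise_sd_tissue, rng), spec.status


def simulate_plasma_profile(
    underlying_bins: Sequence[Bin],
    tumor_fraction: float,
    noise_sd_plasma: float = 0.25,
    seed: int = 0,
) -> list[Bin]:
    """Attenuate a noiseless tissue profile to a plasma profile:
    ``cn = 2 + tumor_fraction * (tissue cn - 2)`` plus Gaussian noise."""
    if not (0.0 <= tumor_fraction <= 1.0):
        raise ValidationError("tumor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    attenuated = [replace(b, cn=2.0 + tumor_fraction * (b.cn - 2.0)) for b in underlying_bins]
    return _add_noise(attenuated, noise_sd_plasma, rng)


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    status: str
    tumor_fraction: float
    msaf: float
    tissue_bins: tuple[Bin, ...]
    plasma_bins: tuple[Bin, ...]
    fish_mean_gcn: float | None = None
    fish_cep7: float | None = None


#: cohort prevalence used when none is supplied (equal representation of the
#: four statuses, to exercise every branch of the caller)
DEFAULT_PREVALENCE = {s: 0.25 for s in STATUSES}


def _fish_truth(status: str, rng) -> tuple[float, float]:
    """Mean MET / CEP7 signals consistent with the truth status:
    amplification (incl. pan-MET) -> ratio > 2; polysomy -> GCN >= 5 at
    ratio <= 2; negative -> GCN < 5 at ratio <= 2."""
    if status in (AMPLIFICATION, PAN_MET_AMPLIFICATION):
        cep7 = float(rng.uniform(2.0, 4.0))
        ratio = float(rng.uniform(2.5, 6.0))
        return cep7 * ratio, cep7
    if status == POLYSOMY:
        gcn = float(rng.uniform(5.0, 8.0))
        ratio = float(rng.uniform(1.2, 1.9))
        return gcn, gcn / ratio
    gcn = float(rng.uniform(2.0, 4.5))
    ratio = float(rng.uniform(0.8, 1.4))
    return gcn, gcn / ratio


def simulate_cohort(
    n: int,
    prevalence: dict[str, float] | None = None,
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    with_fish: bool = True,
    tumor_fraction_range: tuple[float, float] = (0.01, 0.60),
) -> list[CohortSample]:
    """Simulate a cohort of paired tissue/plasma profiles.

    Statuses are drawn multinomially from ``prevalence`` (default: equal
    quarters); per-sample seeds derive deterministically from ``seed``;
    tumor fractions are drawn uniformly from ``tumor_fraction_range``.
    """
    base = spec or SyntheticSpec()
    prev = prevalence or DEFAULT_PREVALENCE
    total = sum(prev.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"prevalence must sum to 1 (got {total})")
    unknown = set(prev) - set(STATUSES)
    if unknown:
        raise ValidationError(f"unknown statuses in prevalence: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    statuses = list(rng.choice(list(prev), size=n, p=[prev[s] for s in prev]))
    cohort = []
    for i, status in enumerate(statuses):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tf = float(rng.uniform(*tumor_fraction_range))
        s = replace(base, status=str(status), seed=sub_seed, tumor_fraction=tf)
        tissue, truth = simulate_tissue_profile(s)
        underlying, _ = simulate_underlying(s)
        plasma = simulate_plasma_profile(
            underlying, tf, s.noise_sd_plasma, seed=sub_seed + 1
        )
        fish = _fish_truth(truth, rng) if with_fish else (None, None)
        cohort.append(
            CohortSample(
                sample_id=f"S{i + 1:04d}",
                status=truth,
                tumor_fraction=tf,
                msaf=min(1.0, tf / 2.0),
                tissue_bins=tuple(tissue),
                plasma_bins=tuple(plasma),
                fish_mean_gcn=fish[0],
                fish_cep7=fish[1],
            )
        )
    return cohort


def simulate_cutoff_cohort(
    n_neg: int = 30,
    n_pos: int = 10,
    neg_mean: float = 2.0,
    neg_sd: float = 0.1,
    pos_mean: float = 2.6,
    pos_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """MET copy numbers for a cutoff-determination cohort: FISH-negative
    samples around diploid, FISH-polysomy samples shifted upward. Returns
    (values, boolean labels with True = polysomy)."""
    rng = np.random.default_rng(seed)
    neg = rng.normal(neg_mean, neg_sd, size=n_neg)
    pos = rng.normal(pos_mean, pos_sd, size=n_pos)
    values = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(n_neg, dtype=bool), np.ones(n_pos, dtype=bool)])
    return values, labels


def write_cohort(cohort: Sequence[CohortSample], outdir, band_map=None) -> Path:
    """Write a simulated cohort as CNR-dialect TSVs plus a truth table and
    the synthetic cytoband fixture. Returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cytobands(band_map or default_band_map(), outdir / "cytoBand.txt")
    rows = []
    for s in cohort:
        write_cnr(s.tissue_bins, outdir / f"{s.sample_id}.tissue.cnr.tsv")
        write_cnr(s.plasma_bins, outdir / f"{s.sample_id}.plasma.cnr.tsv")
        rows.append(
            {
                "sample_id": s.sample_id,
                "status": s.status,
                "tumor_fraction": s.tumor_fraction,
                "msaf": s.msaf,
                "fish_mean_gcn": s.fish_mean_gcn,
                "fish_cep7": s.fish_cep7,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
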