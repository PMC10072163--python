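"""Shared test helpers: compact constructors and independent oracles.

The oracles here deliberately re-derive results from first principles
(explicit Welch statistic, pair counting, partition enumeration from a
p-value matrix) so they share no code path with the implementation they
check.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

from metseg.io import Bin, CytoBand, OFFTARGET
from metseg.segmentation import BandProfile, Region, SegmentationConfig


def make_band(name, start, end, chrom="chr7"):
    return CytoBand(chrom=chrom, start=start, end=end, name=name)


def make_profile(cns, name="q21.1", start=0, end=1_000_000, chrom="chr7"):
    return BandProfile(
        bands=(make_band(name, start, end, chrom),),
        bin_cns=tuple(float(c) for c in cns),
    )


def make_profiles(cn_lists, band_size=1_000_000, chrom="chr7"):
    """One single-band profile per list, tiled contiguously along a q arm."""
    return [
        make_profile(cns, name=f"q{i + 11}", start=i * band_size, end=(i + 1) * band_size, chrom=chrom)
        for i, cns in enumerate(cn_lists)
    ]


def offtarget_bins(chrom, start, end, size, cn):
    return [
        Bin(chrom, s, min(s + size, end), cn=cn, gene="Antitarget", kind=OFFTARGET)
        for s in range(start, end, size)
    ]


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def welch_p(x, y):
    """Welch two-sided t-test p-value from the explicit formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0.0 and vy == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def p_matrix(cn_lists):
    n = len(cn_lists)
    p = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = welch_p(cn_lists[i], cn_lists[j])
    return p


def oracle_initial_partition(pmat, alpha):
    """Greedy-by-definition partition: the first block is the longest prefix
    whose bands are pairwise non-significant (any sub-block of a valid block
    is valid, so longest-valid-prefix equals greedy growth); recurse."""
    n = pmat.shape[0]
    blocks, start = [], 0
    while start < n:
        end = start + 1
        best = end
        while end <= n:
            idx = range(start, end)
            if all(pmat[i, j] >= alpha for i in idx for j in idx if i < j):
                best = end
                end += 1
            else:
                break
        blocks.append(list(range(start, best)))
        start = best
    return blocks


def oracle_merge(blocks, pmat, alpha, cfg: SegmentationConfig):
    """Straightforward re-statement of the merge rules over band indices."""
    blocks = [list(b) for b in blocks]
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(blocks) - 1:
            a, b = blocks[i], blocks[i + 1]
            s, l = (a, b) if len(a) <= len(b) else (b, a)
            nonsig = sum(pmat[x, y] >= alpha for x in s for y in l)
            f = nonsig / (len(s) * len(l))
            if f > cfg.merge_frac_major or (
                len(l) > cfg.merge_big_region_bands and f > cfg.merge_frac_minor
            ):
                blocks[i : i + 2] = [a + b]
                changed = True
            else:
                i += 1
    return blocks


def pairwise_auc(values, labels):
    """AUC as the literal fraction of (positive, negative) pairs ordered
    correctly, ties counted one half."""
    pos = [v for v, y in zip(values, labels) if y]
    neg = [v for v, y in zip(values, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
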