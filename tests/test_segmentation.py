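"""Band aggregation, t-tests, region formation/merging and the amplified
fraction, checked against independent first-principles oracles."""
import numpy as np
import pytest

import _helpers as H
from metseg.errors import EmptyDataError, ValidationError
from metseg.io import Bin, CAPTURE
from metseg.segmentation import (
    ArmSegmentation,
    Region,
    SegmentationConfig,
    amplified_fraction,
    assign_bins_to_bands,
    band_ttest,
    form_initial_regions,
    merge_regions,
    segment_arm,
)


# ---------------------------------------------------------------------------
# assign_bins_to_bands
# ---------------------------------------------------------------------------

def test_uniform_bins_give_uniform_profiles():
    bands = [H.make_band(f"q{i + 11}", i * 1000, (i + 1) * 1000) for i in range(10)]
    bins = H.offtarget_bins("chr7", 0, 10_000, 100, cn=2.0)
    profiles = assign_bins_to_bands(bins, bands)
    assert len(profiles) == 10
    assert all(p.n_bins == 10 for p in profiles)


def test_straddling_bin_goes_to_midpoint_band():
    bands = [H.make_band("q11", 0, 1000), H.make_band("q21", 1000, 2000)]
    # spans the boundary; midpoint 1050 lies in the second band
    straddler = Bin("chr7", 900, 1200, cn=3.0, gene="Antitarget")
    filler = H.offtarget_bins("chr7", 0, 2000, 250, cn=2.0)
    profiles = assign_bins_to_bands(filler + [straddler], bands)
    assert 3.0 in profiles[1].bin_cns
    assert 3.0 not in profiles[0].bin_cns


def test_capture_bins_are_excluded():
    bands = [H.make_band("q11", 0, 1000)]
    bins = H.offtarget_bins("chr7", 0, 1000, 100, cn=2.0)
    bins.append(Bin("chr7", 0, 120, cn=9.0, gene="MET", kind=CAPTURE))
    profiles = assign_bins_to_bands(bins, bands)
    assert 9.0 not in profiles[0].bin_cns


def test_undersized_band_merges_into_closer_mean_neighbor():
    bands = [
        H.make_band("q11", 0, 1000),
        H.make_band("q21", 1000, 2000),
        H.make_band("q31", 2000, 3000),
    ]
    bins = (
        [Bin("chr7", s, s + 100, cn=2.0, gene="Antitarget") for s in range(0, 1000, 100)]
        + [Bin("chr7", 1400, 1500, cn=2.1, gene="Antitarget")]  # single bin, own cn 2.1
        + [Bin("chr7", s, s + 100, cn=4.0, gene="Antitarget") for s in range(2000, 3000, 100)]
    )
    profiles = assign_bins_to_bands(bins, bands, min_bins_per_band=2)
    assert len(profiles) == 2
    assert profiles[0].name == "q11+q21"  # merged left: |2.0-2.1| < |4.0-2.1|
    assert 2.1 in profiles[0].bin_cns


def test_no_offtarget_bins_is_an_error():
    bands = [H.make_band("q11", 0, 1000)]
    with pytest.raises(EmptyDataError):
        assign_bins_to_bands([Bin("chr7", 0, 120, cn=2.0, gene="MET", kind=CAPTURE)], bands)


# ---------------------------------------------------------------------------
# band_ttest
# ---------------------------------------------------------------------------

def test_identical_bands_are_nonsignificant():
    a = H.make_profile([2.0, 2.1, 1.9, 2.0])
    p, nonsig = band_ttest(a, a)
    assert p == pytest.approx(1.0)
    assert nonsig


def test_welch_p_matches_hand_oracle():
    rng = np.random.default_rng(0)
    x = rng.normal(2.0, 0.01, 20)
    y = rng.normal(6.0, 0.01, 20)
    p, nonsig = band_ttest(H.make_profile(x), H.make_profile(y))
    assert p < 1e-6
    assert not nonsig
    assert p == pytest.approx(H.welch_p(x, y), rel=1e-9)


def test_zero_variance_degenerate_rule():
    a = H.make_profile([2.0, 2.0, 2.0])
    b = H.make_profile([2.0, 2.0])
    c = H.make_profile([3.0, 3.0])
    assert band_ttest(a, b)[0] == 1.0
    assert band_ttest(a, c)[0] == 0.0


def test_single_bin_band_violates_contract():
    with pytest.raises(ValidationError):
        band_ttest(H.make_profile([2.0]), H.make_profile([2.0, 2.1]))


# ---------------------------------------------------------------------------
# form_initial_regions
# ---------------------------------------------------------------------------

def test_flat_arm_forms_one_region():
    rng = np.random.default_rng(1)
    profiles = H.make_profiles([rng.normal(2.0, 0.02, 10) for _ in range(6)])
    regions = form_initial_regions(profiles)
    assert len(regions) == 1
    assert regions[0].n_bands == 6


def test_step_profile_splits_at_the_step():
    rng = np.random.default_rng(2)
    cn_lists = [rng.normal(2.0, 0.05, 10) for _ in range(5)] + [
        rng.normal(4.0, 0.05, 10) for _ in range(5)
    ]
    regions = form_initial_regions(H.make_profiles(cn_lists))
    assert [r.n_bands for r in regions] == [5, 5]
    assert regions[0].mean_cn == pytest.approx(2.0, abs=0.05)
    assert regions[1].mean_cn == pytest.approx(4.0, abs=0.05)


def test_single_band_forms_single_region():
    regions = form_initial_regions([H.make_profile([2.0, 2.1])])
    assert len(regions) == 1


def test_empty_band_list_is_an_error():
    with pytest.raises(EmptyDataError):
        form_initial_regions([])


# ---------------------------------------------------------------------------
# merge_regions rule table
# ---------------------------------------------------------------------------

def _region(profiles, cfg=None):
    cfg = cfg or SegmentationConfig()
    return Region.from_profiles(profiles, cfg.cng_threshold)


_BASE = np.random.default_rng(42).normal(2.0, 0.05, 12)


def _similar(n):
    """n bands bit-identical to a reference noisy band (pairwise p = 1)."""
    return [np.array(_BASE) for _ in range(n)]


def _different(n):
    """n bands shifted far above the reference (pairwise p ~ 0)."""
    return [np.array(_BASE) + 3.0 for _ in range(n)]


def test_rule_i_merges_when_f_above_half():
    # S = 1 band, L = 5 bands, 3 of them indistinguishable -> f = 0.6 > 0.5
    s = H.make_profiles(_similar(1))
    l = H.make_profiles(_similar(3) + _different(2), band_size=1_000_000)
    merged = merge_regions([_region(s), _region(l)])
    assert len(merged) == 1


def test_rule_ii_merges_big_region_at_lower_f():
    # L = 8 bands (> 7), 3 of them indistinguishable -> f = 0.375 in (0.3, 0.5]
    s = H.make_profiles(_similar(1))
    l = H.make_profiles(_similar(3) + _different(5))
    merged = merge_regions([_region(s), _region(l)])
    assert len(merged) == 1


def test_small_region_at_lower_f_does_not_merge():
    # L = 5 bands (not > 7), f = 0.4 <= 0.5 -> neither rule applies
    s = H.make_profiles(_similar(1))
    l = H.make_profiles(_similar(2) + _different(3))
    merged = merge_regions([_region(s), _region(l)])
    assert len(merged) == 2


def test_merging_is_a_fixpoint_and_conserves_bins():
    rng = np.random.default_rng(5)
    cn_lists = [rng.normal(rng.choice([2.0, 3.0]), 0.2, 8) for _ in range(8)]
    profiles = H.make_profiles(cn_lists)
    initial = form_initial_regions(profiles)
    merged = merge_regions(initial)
    again = merge_regions(merged)
    assert [r.n_bands for r in again] == [r.n_bands for r in merged]

    def bin_multiset(regions):
        return sorted(c for r in regions for p in r.bands for c in p.bin_cns)

    assert bin_multiset(merged) == bin_multiset(initial)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(100))
def test_segmentation_matches_first_principles_oracle(seed):
    """Greedy growth + iterative merging must equal the same rules restated
    independently over the pairwise p-value matrix (arms of <= 8 bands)."""
    rng = np.random.default_rng(seed)
    n_bands = int(rng.integers(2, 9))
    cn_lists = [
        rng.normal(rng.choice([2.0, 2.6, 3.5, 5.0]), rng.uniform(0.05, 0.3), int(rng.integers(3, 9)))
        for _ in range(n_bands)
    ]
    cfg = SegmentationConfig()
    profiles = H.make_profiles(cn_lists)
    result = merge_regions(form_initial_regions(profiles, cfg), cfg)
    sizes = [r.n_bands for r in result]

    pmat = H.p_matrix(cn_lists)
    blocks = H.oracle_merge(H.oracle_initial_partition(pmat, cfg.alpha), pmat, cfg.alpha, cfg)
    assert sizes == [len(b) for b in blocks]


# ---------------------------------------------------------------------------
# amplified fraction and region statistics
# ---------------------------------------------------------------------------

def _seg_with(regions, arm_length):
    seg = ArmSegmentation(arm="chr7q", regions=regions, arm_length=arm_length, amplified_fraction=0.0)
    seg.amplified_fraction = amplified_fraction(seg)
    return seg


def test_amplified_fraction_arithmetic():
    cng = _region([H.make_profile([4.0, 4.1], start=0, end=30_000_000)])
    normal = _region([H.make_profile([2.0, 2.1], name="q22", start=30_000_000, end=100_000_000)])
    assert cng.is_cng and not normal.is_cng
    assert _seg_with([cng, normal], 100_000_000).amplified_fraction == pytest.approx(0.30)
    assert _seg_with([cng], 30_000_000).amplified_fraction == pytest.approx(1.0)
    assert _seg_with([normal], 70_000_000).amplified_fraction == pytest.approx(0.0)


def test_amplified_fraction_monotone_in_cng_threshold():
    rng = np.random.default_rng(6)
    cn_lists = [rng.normal(rng.uniform(1.8, 4.0), 0.1, 10) for _ in range(10)]
    profiles = H.make_profiles(cn_lists)
    fracs = []
    for thr in (2.0, 2.3, 2.6, 3.0, 3.5):
        cfg = SegmentationConfig(cng_threshold=thr)
        regions = merge_regions(form_initial_regions(profiles, cfg), cfg)
        fracs.append(_seg_with(regions, profiles[-1].end - profiles[0].start).amplified_fraction)
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def test_region_means_scale_with_bin_cns():
    rng = np.random.default_rng(7)
    cn_lists = [rng.uniform(1.5, 4.0, 8) for _ in range(4)]
    cfg = SegmentationConfig()
    base = [_region(H.make_profiles(cn_lists)[i : i + 1]) for i in range(4)]
    for c in (0.5, 2.0, 3.0):
        scaled = [
            _region(H.make_profiles([np.asarray(l) * c for l in cn_lists])[i : i + 1])
            for i in range(4)
        ]
        for r0, r1 in zip(base, scaled):
            assert r1.mean_cn == pytest.approx(c * r0.mean_cn)


def test_segment_arm_rejects_mixed_arms(band_map):
    bins = H.offtarget_bins("chr7", 0, 159_000_000, 150_000, cn=2.0)
    with pytest.raises(ValidationError):
        segment_arm(bins, band_map)  # p and q bands mixed


def test_segment_arm_end_to_end(q_bands):
    rng = np.random.default_rng(8)
    bins = [
        Bin("chr7", b.start + i * 150_000, b.start + (i + 1) * 150_000,
            cn=float(rng.normal(2.0, 0.1)), gene="Antitarget")
        for b in q_bands
        for i in range(10)
    ]
    seg = segment_arm(bins, q_bands)
    assert seg.arm == "chr7q"
    assert seg.arm_length == q_bands[-1].end - q_bands[0].start
    assert sum(r.genomic_length for r in seg.regions) == seg.arm_length
    assert 0.0 <= seg.amplified_fraction <= 1.0
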