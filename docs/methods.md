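# Methods

## The calling problem

A targeted cancer panel reports a raised *MET* gene copy number (GCN) in two
biologically distinct situations: focal amplification of the *MET* locus
(7q31.2), an oncogenic driver and drug target, and polysomy of chromosome
7/7q, a proportional arm- or chromosome-level gain that is not considered a
driver. FISH separates the two with the MET/CEP7 ratio; `metseg` separates
them from the sequencing data alone by asking *how much of 7q is gained*:
focal amplification raises a small window around *MET*, polysomy raises
(nearly) the whole arm.

## Arm segmentation

Inputs are per-bin linear copy numbers (diploid = 2) from an off-target-aware
CNV caller: narrow capture bins over genes (~120 bp) and wide off-target bins
(~150 kb) tiling the genome. Coverage normalisation (against a pooled normal
background) is the upstream caller's job and is out of scope here; `metseg`
starts from the normalised copy numbers. If a table carries only `log2`
ratios, `cn = 2·2^log2`.

1. **Band aggregation.** Every off-target bin whose midpoint falls inside a
   7q cytoband joins that band. Bands with fewer than `min_bins_per_band`
   (default 2) bins are pre-merged into the adjacent band with the closer
   mean copy number (left on ties). A band with *no* bins has no mean, so
   the closer-mean rule is undefined; such bands are merged into their left
   neighbour (right if first) — a deterministic convention that only matters
   for band maps much finer than the bin size.
2. **Band comparison.** Two-sided Welch (unequal-variance) t-test on the bin
   copy numbers of two bands; `P >= alpha` (default 0.1) means
   indistinguishable. The test variant is configurable (`equal_var=True`
   selects the pooled form) because the procedure is specified only as "a
   t test"; Welch is the safer default when band bin counts and variances
   differ. Degenerate rule: if both bands have zero variance, P = 1 when the
   means are equal and 0 otherwise.
3. **Region formation.** Greedy left-to-right growth: a band joins the
   current region only if it is non-significant against **every** band
   already in the region. The all-pairs reading makes "no significant
   differences between any two bands" literal; because any sub-block of a
   valid block is valid, greedy growth equals taking the longest valid
   prefix repeatedly. An adjacent-only variant is available
   (`pairwise="adjacent"`); all-pairs is the default.
4. **Region merging.** For each adjacent pair, let S be the region with
   fewer bands and L the other (S = left on ties; only rule ii depends on
   which is L). With f = fraction of cross band pairs (one from S, one from
   L) that are non-significant, the pair merges when `f > 0.5` (rule i) or
   when L has `> 7` bands and `f > 0.3` (rule ii). Sweeps run left-to-right;
   after a merge the merged region is immediately re-compared to the next
   region (recompute-after-each-merge); sweeps repeat until one makes no
   merge. With ~10% of same-mean band pairs significant by chance at
   alpha = 0.1, initial regions fragment on a uniformly gained arm — the
   merge step is what reassembles them.
5. **CNG and amplified fraction.** Region mean copy number is the unweighted
   mean over member **bins** (not the mean of band means — bins are the
   measurement unit). A region is a copy-number gain (CNG) when its mean is
   strictly `> cng_threshold` (default 2.3). The amplified fraction is
   Σ length(CNG regions) / arm length, with arm length the span from the
   first to the last q band of the supplied map.

Threshold semantics follow the wording of each rule: "higher than" is a
strict `>` (merging, CNG), "P values >= 0.1" is inclusive. No multiplicity
correction is applied to the band t-tests, deliberately: the merge rules are
defined on raw pairwise p-values.

## Decision table

With GCN the unweighted mean of the *MET* capture bins (an externally
determined GCN can be supplied instead), evaluated in order:

1. GCN < 2.3 → **negative**;
2. amplified fraction ≥ 0.80 → **polysomy**;
3. MET-band region not CNG, or fraction ≤ 0.10 → **amplification**;
4. otherwise (CNG MET region, fraction in (0.10, 0.80)) →
   **pan-MET amplification**.

Putting the polysomy clause first makes the overlapping prose conditions
deterministic: an arm-wide gain is never reported as focal amplification.
The boundaries (≤ 10%, 10–80%, ≥ 80%) follow the summary decision table
rather than the strict inequalities of the prose. The 2.3 threshold is
shared between the negative gate and region CNG calling.

The MET anchor band defaults to the band containing the *MET* capture bins
in the supplied band map, with a config/CLI override (`--met-band`); source
descriptions of the method name 7q32.1 as the anchor, which may be a
misprint for the MET-containing band 7q31.2 — both are selectable, and with
either anchor the bundled synthetic map places the anchor inside every
simulated event window.

FISH reference rule: ratio > 2.0 → amplification; else mean GCN ≥ 5 →
polysomy; else negative. FISH polysomy has no canonical published
definition; this ratio-first rule is the simplest one consistent with the
three discordant reference readouts (ratios 2.7 / 1.9 / 1.6) and is
config-overridable; externally assigned FISH labels can always be supplied
instead.

## Cutoff determination

`roc_curve` calls a sample positive when its copy number is **at or above**
a candidate threshold (positives are the high-copy class, so the cutoff
reads as a lower bound). Candidates are the midpoints between consecutive
sorted unique values plus a sentinel below and above all values. AUC uses
the rank (Mann–Whitney) formulation with ties counted one half. The cutoff
is the threshold maximising J = sensitivity + specificity − 1; at equal J
the **smallest** threshold wins (maximises sensitivity, the screening
choice). The AUC interval is a stratified percentile bootstrap (2.5/97.5
percentiles over `n_boot` within-class resamples, seeded); the interval
construction used for the originally published CI is unknown, so no claim
is made that the mechanics coincide — only that both are 95% bootstrap-type
intervals for the same rank statistic.

## Agreement statistics

The reference method (FISH for tissue, tissue NGS for plasma) is always the
column/truth axis of the confusion matrix. One-vs-rest class metrics come
from the binary collapse of the k×k matrix; pan-MET amplification is kept
as its own class in the 4×4 plasma view and counted as "rest" in each
one-vs-rest collapse. Cohen's κ is the standard unweighted
`(Po − Pe)/(1 − Pe)`. Ratios with a zero denominator are reported as
undefined (`None`/`null`), never as 0. Displayed percentages use half-up
rounding at one decimal (tissue metrics) or the nearest percent (the
stratified plasma metrics).

On the bundled 53-sample tissue matrix the formula gives κ = 1498/1657 ≈
0.904; the value 0.886 reported alongside that matrix is not derivable from
it by the standard formula, and this package reports the formula value.
Likewise the reported tissue polysomy "specificity 90%" (the matrix gives
42/43 ≈ 97.7%) and the plasma polysomy specificities/concordances are not
reconstructible from the published counts; the bundled plasma cohort
reproduces exactly the derivable quantities (19→10, 48→6 detections,
amplification agreement (261−9)/261, and the MSAF > 5% strata 7/10 and
5/12).

MSAF (maximum somatic allele frequency) is the largest somatic VAF in a
sample, 0 for an empty variant list; `stratified_agreement` computes PPA/NPA
within any predicate-defined subset (MSAF or EGFR-VAF thresholds from the
CLI).

## Synthetic data generator

The generator emulates the panel's data model, not its noise physics: 150 kb
off-target bins across a synthetic chr7 (60 Mb p arm, 99 Mb q arm in 15
equal 6.6 Mb bands, *MET* at 110 Mb in "q31.2") and 20 capture bins of
120 bp over *MET*. Event geometry snaps to band boundaries so truth
fractions are exact: amplification raises the single MET band (6.7% of the
arm, ≤ 10%) to `focal_cn` ~ U(5, 15); polysomy raises the whole arm to
`arm_gain_cn` ~ U(2.5, 4); pan-MET raises a contiguous window of
round(15·U(0.15, 0.60)) bands containing the MET band. Observed copy
numbers add Gaussian noise on the linear scale — sd 0.15 for tissue, 0.25
for plasma — chosen so the tissue pipeline is near-perfect while plasma
calls degrade at low ctDNA content, mirroring the qualitative clinical
pattern. Plasma attenuation is the mixture identity
`cn = 2 + tf·(cn_tissue − 2)` with tumor fraction `tf`; MSAF is emitted as
`min(1, tf/2)` (heterozygous-variant approximation). Cohort simulation
draws statuses multinomially (default equal quarters, to exercise every
branch), derives per-sample seeds from the master seed, draws tf ~
U(0.01, 0.60), and generates FISH readouts consistent with the truth
(amplification → ratio > 2; polysomy → GCN ≥ 5 at ratio ≤ 2).

What the generator does **not** model: GC/mappability bias, FFPE artefacts,
subclonal heterogeneity, tumor purity in tissue (the caller applies no
purity correction), replication-timing waves, or read-level sampling.
Passing the recovery tests therefore demonstrates the correctness and
internal consistency of the decision machinery under idealised noise, not
clinical sensitivity on real libraries.

## Problem sizes and determinism

The standard verification runs use 200 simulated tissue samples for
truth-recovery (about 660 off-target bins each), 500 random ≤ 8-band arms
for the segmentation-vs-oracle comparison, and 100 simulated 40-patient
cohorts for cutoff recovery (negatives ~ N(2.0, 0.1²) ×30, polysomy ~
N(2.6, 0.2²) ×10, matching the cohort structure the 2.3 cutoff was derived
from); these sizes give stable rates while keeping a full run in well under
a minute. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds give bit-identical output,
including written files.

## Known limitations

- The method is specific to one arm/gene geometry (MET on 7q) by default;
  other genes would need their band anchor and arm map supplied.
- Bands much finer than the off-target bin size collapse during pre-merge,
  coarsening the segmentation.
- The amplified fraction is length-based; interstitial normal segments
  inside a gained region dilute it only through region formation, not
  through any within-region heterogeneity test.
- The bootstrap CI is percentile-based and can be anti-conservative for
  AUCs near 1 at small n.
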