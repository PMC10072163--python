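# metseg

Calling *MET* copy-number status — **negative**, focal **amplification**,
**pan-MET amplification**, or **polysomy** — from targeted-panel NGS data.

A raised *MET* gene copy number (GCN) on its own does not distinguish a focal,
drug-targetable amplification of the *MET* locus from polysomy of chromosome
7/7q, which raises the GCN without acting as an oncogenic driver. `metseg`
makes that distinction from the panel's own data: the wide off-target bins of
an off-target-aware CNV caller (e.g. cnvkit's antitarget bins, ~150 kb) give
an arm-level copy-number profile of 7q, which is segmented at cytoband
resolution and combined with the GCN from the capture bins over *MET*.

## Method

For each sample, with per-bin copy numbers `cn` (diploid = 2):

1. **Band aggregation.** Each off-target bin on 7q is assigned to the
   cytoband containing its midpoint; bands with fewer than 2 bins are
   pre-merged into the neighbouring band with the closer mean.
2. **Region formation.** Bands are grown into regions left-to-right; a band
   joins the current region only if a two-sided Welch t-test against every
   band already in the region gives *P* ≥ 0.1 (non-significant).
3. **Region merging.** Adjacent regions merge when the fraction *f* of
   non-significant cross-region band pairs exceeds 50%, or when the larger
   region has more than 7 bands and *f* exceeds 30%; sweeps repeat to a
   fixpoint.
4. **CNG and amplified fraction.** A region is a copy-number gain (CNG) when
   its mean copy number exceeds 2.3. The *amplified fraction* is the share of
   the 7q genomic length covered by CNG regions.
5. **Decision table.** With GCN = mean copy number of the *MET* capture bins:

   | MET GCN | amplified fraction of 7q | call |
   |---|---|---|
   | < 2.3 | — | negative |
   | ≥ 2.3 | ≥ 80% | polysomy |
   | ≥ 2.3 | ≤ 10% (or MET region not CNG) | amplification |
   | ≥ 2.3 | 10–80%, MET region CNG | pan-MET amplification |

The 2.3-copy cutoff is the Youden-optimal ROC threshold separating polysomy
from normal copy number (J = sensitivity + specificity − 1); `metseg.cutoff`
re-derives such thresholds from any labeled cohort, with a percentile
bootstrap CI for the AUC. `metseg.concordance` provides the diagnostic
agreement statistics (k×k confusion vs a reference, one-vs-rest
sensitivity/specificity/PPV/NPV/agreement, Cohen's κ, and MSAF-stratified
tissue–plasma PPA/NPA), and `metseg.synthetic` generates seeded cohorts with
known truth, including plasma profiles attenuated by the ctDNA tumor
fraction (`cn_plasma = 2 + tf·(cn_tissue − 2)`).

## Worked example

Simulate a polysomy sample and call it:

```sh
metseg simulate --n 1 --seed 5 --status polysomy --out demo/
metseg classify --cnr demo/S0001.tissue.cnr.tsv --cytoband demo/cytoBand.txt --out demo/call/
```

which prints:

```
S0001.tissue.cnr	status=polysomy	met_gcn=2.787	amplified_fraction=1.000
```

The *MET* GCN is raised (2.79 ≥ 2.3) but the CNG covers the entire arm
(amplified fraction 1.00 ≥ 0.80), so the gain is arm-level polysomy, not a
focal amplification. `demo/call/report.json` holds the full evidence (GCN,
amplified fraction, MET-band region state) and `report.regions.tsv` the
per-region segmentation. The same decision rules via the API:

```python
>>> from metseg import classify_fish
>>> classify_fish(10.5, 3.9).status   # MET/CEP7 ratio 2.7
'amplification'
>>> classify_fish(5.1, 2.7).status    # ratio 1.9, mean GCN >= 5
'polysomy'
```

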