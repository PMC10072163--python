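"""Bundled benchmark cohorts used by the test-suite and the acceptance
script.

Two small clinical comparison cohorts are reconstructed from their published
summary counts (the patient-level data are not public, so each cohort is
expanded from its cross-tabulation; per-sample covariates carry only the
information the summary fixes, e.g. which MSAF stratum a sample is in):

* a 53-sample tissue cohort with paired FISH and NGS MET status calls;
* a 261-sample cohort with paired tissue and plasma NGS calls, including the
  high-MSAF strata used for the "optimised" plasma agreement metrics;
* the three discordant FISH readouts used to exercise the FISH rule.
"""
from __future__ import annotations

from .classifier import AMPLIFICATION, NEGATIVE, PAN_MET_AMPLIFICATION, POLYSOMY
from .concordance import PairedSample

#: (FISH reference label, NGS test label, count) — 53 tissue samples
_TISSUE_FISH_NGS = (
    (AMPLIFICATION, AMPLIFICATION, 13),
    (AMPLIFICATION, NEGATIVE, 1),
    (POLYSOMY, POLYSOMY, 9),
    (POLYSOMY, NEGATIVE, 1),
    (NEGATIVE, POLYSOMY, 1),
    (NEGATIVE, NEGATIVE, 28),
)


def fish_ngs_tissue_pairs() -> list[tuple[str, str]]:
    """(FISH reference, NGS test) label pairs for the 53-sample tissue cohort."""
    return [(ref, test) for ref, test, n in _TISSUE_FISH_NGS for _ in range(n)]


#: (tissue status, plasma status, plasma MSAF, count) — 261 paired samples.
#: MSAF is 0.08 in the >5% stratum and 0.02 below it.
_TISSUE_PLASMA = (
    (AMPLIFICATION, AMPLIFICATION, 0.08, 7),
    (AMPLIFICATION, NEGATIVE, 0.08, 3),
    (AMPLIFICATION, AMPLIFICATION, 0.02, 3),
    (AMPLIFICATION, NEGATIVE, 0.02, 6),
    (PAN_MET_AMPLIFICATION, PAN_MET_AMPLIFICATION, 0.02, 2),
    (PAN_MET_AMPLIFICATION, NEGATIVE, 0.02, 6),
    (POLYSOMY, POLYSOMY, 0.08, 5),
    (POLYSOMY, NEGATIVE, 0.08, 7),
    (POLYSOMY, POLYSOMY, 0.02, 1),
    (POLYSOMY, NEGATIVE, 0.02, 35),
    (NEGATIVE, NEGATIVE, 0.02, 181),
    (NEGATIVE, POLYSOMY, 0.02, 5),
)


def tissue_plasma_pairs() -> list[PairedSample]:
    """261 paired tissue/plasma samples with MSAF strata."""
    pairs = []
    i = 0
    for tissue, plasma, msaf_plasma, n in _TISSUE_PLASMA:
        for _ in range(n):
            i += 1
            pairs.append(
                PairedSample(
                    sample_id=f"P{i:03d}",
                    tissue_status=tissue,
                    plasma_status=plasma,
                    msaf_tissue=0.20,
                    msaf_plasma=msaf_plasma,
                    egfr_vaf_plasma=msaf_plasma,
                )
            )
    return pairs


#: (mean MET signals, mean CEP7 signals, FISH status) for the three
#: discordant tissue cases
FISH_DISCORDANT_CASES = (
    (10.5, 3.9, AMPLIFICATION),  # ratio 2.7: FISH-positive, NGS-negative case
    (5.1, 2.7, POLYSOMY),        # ratio 1.9: FISH polysomy, NGS-negative case
    (3.6, 2.2, NEGATIVE),        # ratio 1.6: FISH-negative, NGS-polysomy case
)
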