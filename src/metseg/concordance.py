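"""Diagnostic-agreement statistics.

k x k confusion matrices against a reference method (FISH for tissue, or
tissue NGS for plasma), one-vs-rest class metrics, unweighted Cohen's kappa,
the maximum somatic allele frequency (MSAF) of a plasma sample, and
MSAF-stratified positive/negative percent agreement (PPA/NPA).

Orientation convention: the reference method is always the column (truth)
axis; the test method is the row axis. Metrics with a zero denominator are
surfaced as None ("undefined"), never silently zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import percent
from .errors import EmptyDataError, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k cross-tabulation: rows = test method, columns = reference."""

    classes: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        k = len(self.classes)
        if any(len(row) != k for row in self.counts) or len(self.counts) != k:
            raise ValidationError("confusion matrix must be k x k")
        if any(c < 0 for row in self.counts for c in row):
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise EmptyDataError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(row) for row in self.counts],
            index=pd.Index(self.classes, name="test"),
            columns=pd.Index(self.classes, name="reference"),
        )


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest collapse of a confusion matrix for one class, with the
    reference as truth. Undefined ratios (zero denominator) are None."""

    cls: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    agreement: float


@dataclass(frozen=True)
class PairedSample:
    """One patient's paired tissue/plasma MET calls with ctDNA content
    covariates (fractions in [0, 1])."""

    sample_id: str
    tissue_status: str
    plasma_status: str
    msaf_tissue: float | None = None
    msaf_plasma: float | None = None
    egfr_vaf_plasma: float | None = None
    cn7q_tissue: float | None = None

    def __post_init__(self):
        for name in ("msaf_tissue", "msaf_plasma", "egfr_vaf_plasma"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v!r} outside [0, 1] for {self.sample_id}")


@dataclass(frozen=True)
class StratifiedAgreement:
    ppa: float | None
    npa: float | None
    n_selected: int


def confusion(pairs: Iterable[tuple[str, str]], classes: Sequence[str]) -> ConfusionMatrix:
    """Build a confusion matrix from (reference label, test label) pairs."""
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    n = 0
    for ref, test in pairs:
        if ref not in index:
            raise ValidationError(f"unknown reference label {ref!r}")
        if test not in index:
            raise ValidationError(f"unknown test label {test!r}")
        counts[index[test], index[ref]] += 1
        n += 1
    if n == 0:
        raise EmptyDataError("no pairs supplied")
    return ConfusionMatrix(classes=classes, counts=tuple(tuple(int(c) for c in row) for row in counts))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def class_metrics(m: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest metrics for ``cls``, with the reference as truth."""
    if cls not in m.classes:
        raise ValidationError(f"class {cls!r} not in matrix classes {m.classes}")
    i = m.classes.index(cls)
    counts = np.asarray(m.counts)
    tp = int(counts[i, i])
    fp = int(counts[i, :].sum() - tp)
    fn = int(counts[:, i].sum() - tp)
    tn = int(counts.sum() - tp - fp - fn)
    return ClassMetrics(
        cls=cls,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        agreement=(tp + tn) / m.total,
    )


def cohen_kappa(m: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa: (Po - Pe) / (1 - Pe) with Po the observed
    diagonal agreement and Pe the chance agreement from the marginals."""
    counts = np.asarray(m.counts, dtype=float)
    n = counts.sum()
    po = np.trace(counts) / n
    pe = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        raise ValidationError("kappa undefined: expected agreement is 1 (degenerate marginals)")
    return float((po - pe) / (1.0 - pe))


def msaf(vafs: Sequence[float]) -> float:
    """Maximum somatic allele frequency; 0 by convention for an empty list."""
    vafs = list(vafs)
    for v in vafs:
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"VAF {v!r} outside [0, 1]")
    return max(vafs) if vafs else 0.0


def stratified_agreement(
    pairs: Sequence[PairedSample],
    target_status: str,
    where: Callable[[PairedSample], bool] | None = None,
) -> StratifiedAgreement:
    """PPA/NPA for ``target_status`` within the subset selected by ``where``
    (tissue is the comparator: PPA = plasma-positive among tissue-positive,
    NPA = plasma-negative among tissue-negative)."""
    subset = [p for p in pairs if where is None or where(p)]
    pos = [p for p in subset if p.tissue_status == target_status]
    neg = [p for p in subset if p.tissue_status != target_status]
    ppa = _ratio(sum(p.plasma_status == target_status for p in pos), len(pos))
    npa = _ratio(sum(p.plasma_status != target_status for p in neg), len(neg))
    return StratifiedAgreement(ppa=ppa, npa=npa, n_selected=len(subset))


def msaf_above(threshold: float) -> Callable[[PairedSample], bool]:
    """Filter: plasma MSAF strictly above ``threshold`` (samples without an
    MSAF value are excluded)."""
    return lambda p: p.msaf_plasma is not None and p.msaf_plasma > threshold


def egfr_vaf_above(threshold: float) -> Callable[[PairedSample], bool]:
    """Filter: plasma EGFR VAF strictly above ``threshold``."""
    return lambda p: p.egfr_vaf_plasma is not None and p.egfr_vaf_plasma > threshold


def cohort_prevalence(statuses: Sequence) -> dict[str, float]:
    """Fraction of each MET status in a cohort of calls (or status labels);
    the fractions sum to 1."""
    from .classifier import STATUSES

    labels = [s.status if hasattr(s, "status") else str(s) for s in statuses]
    if not labels:
        raise EmptyDataError("no calls supplied")
    order = list(STATUSES) + sorted(set(labels) - set(STATUSES))
    n = len(labels)
    return {c: labels.count(c) / n for c in order}


def read_pairs(path) -> list[PairedSample]:
    """Read a paired-sample TSV (sample_id, tissue_status, plasma_status
    [, msaf_tissue, msaf_plasma, egfr_vaf_plasma, cn7q_tissue])."""
    df = pd.read_csv(Path(path), sep="\t")
    required = {"sample_id", "tissue_status", "plasma_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    def opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    out = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            out.append(
                PairedSample(
                    sample_id=str(row["sample_id"]),
                    tissue_status=str(row["tissue_status"]),
                    plasma_status=str(row["plasma_status"]),
                    msaf_tissue=opt(row, "msaf_tissue"),
                    msaf_plasma=opt(row, "msaf_plasma"),
                    egfr_vaf_plasma=opt(row, "egfr_vaf_plasma"),
                    cn7q_tissue=opt(row, "cn7q_tissue"),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_pairs(pairs: Iterable[PairedSample], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "tissue_status": p.tissue_status,
                "plasma_status": p.plasma_status,
                "msaf_tissue": p.msaf_tissue,
                "msaf_plasma": p.msaf_plasma,
                "egfr_vaf_plasma": p.egfr_vaf_plasma,
                "cn7q_tissue": p.cn7q_tissue,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def metrics_block(m: ConfusionMatrix, classes: Sequence[str] | None = None) -> dict:
    """JSON-serialisable one-vs-rest metrics for each class plus kappa, with
    percentages at one-decimal display precision."""
    classes = list(classes or m.classes)
    block = {"n": m.total, "kappa": cohen_kappa(m), "classes": {}}
    for c in classes:
        cm = class_metrics(m, c)
        block["classes"][c] = {
            "tp": cm.tp,
            "fp": cm.fp,
            "fn": cm.fn,
            "tn": cm.tn,
            "sensitivity_pct": None if cm.sensitivity is None else percent(cm.sensitivity),
            "specificity_pct": None if cm.specificity is None else percent(cm.specificity),
            "ppv_pct": None if cm.ppv is None else percent(cm.ppv),
            "npv_pct": None if cm.npv is None else percent(cm.npv),
            "agreement_pct": percent(cm.agreement),
        }
    return block
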