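"""Readers and writers for bin-level copy-number tables, cytoband maps and
call reports, plus the sequencing quality-control gate.

All genomic coordinates are 0-based, half-open (UCSC/BED convention), in both
the CNR-dialect bin tables and the cytoband maps.

File dialects
-------------
CNR-dialect TSV
    Tab-separated with a header row. Required columns: ``chromosome`` (or
    ``chrom``), ``start``, ``end``, and at least one of ``log2`` / ``cn``.
    Optional: ``gene``, ``depth``, ``weight``, ``kind``. When only ``log2``
    is present the linear copy number is derived as ``cn = 2 * 2**log2``
    (diploid baseline 2). Bins whose ``gene`` label is one of the antitarget
    markers ("Antitarget", "Background", "-", empty) are treated as
    off-target bins; everything else is a capture bin.

UCSC cytoBand.txt
    Tab-separated, no header: chrom, chromStart, chromEnd, name, gieStain.
    Band names must start with ``p`` or ``q`` (the arm).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyDataError, FormatError, ValidationError

CAPTURE = "capture"
OFFTARGET = "offtarget"

#: gene labels that mark a bin as off-target (case-insensitive)
OFFTARGET_GENE_LABELS = frozenset({"antitarget", "background", "off-target", "offtarget", "-", ""})


def cn_from_log2(log2: float) -> float:
    """Linear copy number from a log2 copy ratio (diploid baseline 2)."""
    return 2.0 * 2.0 ** float(log2)


def log2_from_cn(cn: float) -> float:
    """Log2 copy ratio from a linear copy number; requires cn > 0."""
    if cn <= 0:
        raise ValidationError(f"cannot take log2 copy ratio of cn={cn!r} (must be > 0)")
    return math.log2(float(cn) / 2.0)


@dataclass(frozen=True)
class Bin:
    """One genomic interval with a copy-number estimate.

    ``kind`` distinguishes the narrow on-target capture bins (over genes such
    as MET) from the wide off-target bins used for arm-level segmentation.
    """

    chrom: str
    start: int
    end: int
    cn: float
    gene: str | None = None
    log2: float | None = None
    depth: float | None = None
    kind: str = OFFTARGET

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"bin {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.cn < 0:
            raise ValidationError(f"bin {self.chrom}:{self.start}-{self.end}: cn < 0")
        if self.kind not in (CAPTURE, OFFTARGET):
            raise ValidationError(f"unknown bin kind {self.kind!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CytoBand:
    """A Giemsa cytoband; the segmentation unit of the arm caller."""

    chrom: str
    start: int
    end: int
    name: str
    stain: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"band {self.chrom} {self.name}: end must exceed start")
        if not self.name or self.name[0] not in ("p", "q"):
            raise ValidationError(
                f"band name {self.name!r} on {self.chrom}: cannot derive arm "
                "(must start with 'p' or 'q')"
            )

    @property
    def arm(self) -> str:
        return self.name[0]

    @property
    def length(self) -> int:
        return self.end - self.start


def _float_or_none(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "na", "none", "."):
        return None
    return float(s)


def read_cnr(path) -> list[Bin]:
    """Read a CNR-dialect TSV of per-bin copy numbers.

    Returns one :class:`Bin` per data row, stably sorted by (chromosome,
    start). When only ``log2`` is present, ``cn`` is derived as
    ``2 * 2**log2``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    cols = {c.lower().strip(): c for c in df.columns}
    chrom_col = cols.get("chromosome") or cols.get("chrom")
    if chrom_col is None or "start" not in cols or "end" not in cols:
        raise FormatError(
            f"{path}: header must contain chromosome/start/end (found: {list(df.columns)})"
        )
    if "log2" not in cols and "cn" not in cols:
        raise FormatError(f"{path}: header must contain at least one of 'log2' or 'cn'")

    bins: list[Bin] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        rec = dict(zip(df.columns, row))
        try:
            start = int(str(rec[cols["start"]]).strip())
            end = int(str(rec[cols["end"]]).strip())
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: non-numeric coordinate ({exc})") from exc
        try:
            log2 = _float_or_none(rec.get(cols.get("log2"))) if "log2" in cols else None
            cn = _float_or_none(rec.get(cols.get("cn"))) if "cn" in cols else None
            depth = _float_or_none(rec.get(cols.get("depth"))) if "depth" in cols else None
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: non-numeric value ({exc})") from exc
        if cn is None:
            if log2 is None:
                raise FormatError(f"{path}:{line_no}: row has neither log2 nor cn")
            cn = cn_from_log2(log2)
        gene = str(rec[cols["gene"]]).strip() if "gene" in cols else None
        if "kind" in cols and str(rec[cols["kind"]]).strip():
            kind = str(rec[cols["kind"]]).strip().lower()
        else:
            kind = OFFTARGET if (gene or "").lower() in OFFTARGET_GENE_LABELS else CAPTURE
        try:
            bins.append(
                Bin(
                    chrom=str(rec[chrom_col]).strip(),
                    start=start,
                    end=end,
                    cn=cn,
                    gene=gene or None,
                    log2=log2,
                    depth=depth,
                    kind=kind,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{line_no}: {exc}") from exc
    bins.sort(key=lambda b: (b.chrom, b.start))  # Timsort is stable
    return bins


def write_cnr(bins: Iterable[Bin], path) -> None:
    """Write bins back out as a CNR-dialect TSV (floats at 6 significant digits)."""
    rows = [
        {
            "chromosome": b.chrom,
            "start": b.start,
            "end": b.end,
            "gene": b.gene if b.gene is not None else ("Antitarget" if b.kind == OFFTARGET else ""),
            "log2": b.log2 if b.log2 is not None else (log2_from_cn(b.cn) if b.cn > 0 else ""),
            "cn": b.cn,
            "depth": b.depth if b.depth is not None else "",
        }
        for b in bins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cytobands(path, chrom: str) -> list[CytoBand]:
    """Read a UCSC cytoBand.txt file, keeping only bands of ``chrom``, sorted.

    Raises :class:`ValidationError` on overlapping bands or band names whose
    first character is not a recognised arm prefix.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "stain"],
        dtype=str,
        keep_default_na=False,
    )
    bands = []
    for i, row in enumerate(df.itertuples(index=False)):
        if str(row.chrom).strip() != chrom:
            continue
        try:
            band = CytoBand(
                chrom=chrom,
                start=int(row.start),
                end=int(row.end),
                name=str(row.name).strip(),
                stain=str(row.stain).strip() or None,
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: non-numeric coordinate ({exc})") from exc
        bands.append(band)
    bands.sort(key=lambda b: b.start)
    for a, b in zip(bands, bands[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"{path}: bands {a.name} and {b.name} on {chrom} overlap "
                f"({a.start}-{a.end} vs {b.start}-{b.end})"
            )
    return bands


def write_cytobands(bands: Iterable[CytoBand], path) -> None:
    """Write bands in UCSC cytoBand.txt layout (no header)."""
    df = pd.DataFrame(
        [(b.chrom, b.start, b.end, b.name, b.stain or "gneg") for b in bands]
    )
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Sequencing QC gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Sequencing quality gate: more than 98% of exons at >= 100X coverage
    (strict >), mean depth at least 200X, mapping rate at least 95%."""

    min_exon_cov_frac: float = 0.98
    min_depth: float = 200.0
    min_map_rate: float = 0.95

    def __post_init__(self):
        if not (0.0 <= self.min_exon_cov_frac <= 1.0):
            raise ValidationError("min_exon_cov_frac must be in [0, 1]")
        if self.min_depth <= 0:
            raise ValidationError("min_depth must be > 0")
        if not (0.0 <= self.min_map_rate <= 1.0):
            raise ValidationError("min_map_rate must be in [0, 1]")


@dataclass(frozen=True)
class QcResult:
    passed: bool
    failures: tuple[str, ...]


def qc_check(
    exon_cov_frac: float,
    mean_depth: float,
    map_rate: float,
    thresholds: QcThresholds | None = None,
) -> QcResult:
    """Apply the sequencing QC gate; always returns a verdict listing every
    violated criterion."""
    t = thresholds or QcThresholds()
    failures = []
    if not exon_cov_frac > t.min_exon_cov_frac:
        failures.append(
            f"fraction of exons at >=100X is {exon_cov_frac:g}, "
            f"required > {t.min_exon_cov_frac:g}"
        )
    if not mean_depth >= t.min_depth:
        failures.append(f"mean depth is {mean_depth:g}X, required >= {t.min_depth:g}X")
    if not map_rate >= t.min_map_rate:
        failures.append(f"mapping rate is {map_rate:g}, required >= {t.min_map_rate:g}")
    return QcResult(passed=not failures, failures=tuple(failures))


# ---------------------------------------------------------------------------
# Call reports
# ---------------------------------------------------------------------------

def _regions_path(path: Path) -> Path:
    if path.suffix == ".json":
        return path.with_suffix(".regions.tsv")
    return Path(str(path) + ".regions.tsv")


def write_report(call, segmentation, path, sample: str = "sample") -> Path:
    """Write a machine-readable call report: a JSON object plus a flat TSV of
    the arm regions next to it. Returns the JSON path.

    Re-reading the JSON with :func:`read_report` reproduces the call fields
    bit-exactly (JSON floats round-trip exactly in Python).
    """
    path = Path(path)
    if not segmentation.regions:
        raise EmptyDataError("segmentation has no regions; nothing to report")
    report = {
        "sample": sample,
        "status": call.status,
        "met_gcn": call.met_gcn,
        "met_band": call.met_band,
        "met_region_cng": call.met_region_cng,
        "amplified_fraction": call.amplified_fraction,
        "arm": segmentation.arm,
        "arm_length": segmentation.arm_length,
        "regions": [
            {
                "region": i,
                "start_band": r.bands[0].bands[0].name,
                "end_band": r.bands[-1].bands[-1].name,
                "n_bands": r.n_bands,
                "n_bins": r.n_bins,
                "mean_cn": r.mean_cn,
                "length_bp": r.genomic_length,
                "is_cng": r.is_cng,
                "contains_met_band": r.contains_met_band,
            }
            for i, r in enumerate(segmentation.regions)
        ],
    }
    path.write_text(json.dumps(report, indent=2) + "\n")
    pd.DataFrame(report["regions"]).to_csv(_regions_path(path), sep="\t", index=False)
    return path


def read_report(path):
    """Read a JSON call report back into (sample, MetCall)."""
    from .classifier import MetCall  # local import to avoid a cycle

    data = json.loads(Path(path).read_text())
    call = MetCall(
        status=data["status"],
        met_gcn=data["met_gcn"],
        amplified_fraction=data["amplified_fraction"],
        met_region_cng=data["met_region_cng"],
        met_band=data["met_band"],
    )
    return data["sample"], call
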