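"""Core variant/interval data model and readers for VCF, BED and variant TSV.

All coordinates are held internally as 0-based half-open intervals; VCF
positions (1-based) are converted on read.  Chromosome names are normalized
by stripping a leading ``chr`` prefix so that BED and VCF inputs compare on
equal terms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "VariantRecord",
    "AnnotationTrack",
    "normalize_chrom",
    "read_variants",
    "write_variants",
    "read_bed",
    "overlaps",
]

_ALLELE_ALPHABET = frozenset("ACGTN")


class VariantIOError(ValueError):
    """Malformed variant/interval input."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; comparison is on the stripped name."""
    name = name.strip()
    if name.lower().startswith("chr"):
        return name[3:]
    return name


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise VariantIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise VariantIOError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class VariantRecord:
    """A single variant in VCF convention (1-based ``pos``, explicit alleles).

    ``label`` tags training membership (``functional``/``control``) and
    ``source`` records provenance (e.g. ``clinvar_pathogenic``).  ``pvalue``
    carries a GWAS association p-value where one exists.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None
    label: Optional[str] = None
    source: Optional[str] = None
    pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"pos must be >= 1, got {self.pos}")
        for allele, which in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not set(allele) <= _ALLELE_ALPHABET:
                raise VariantIOError(f"invalid {which} allele {allele!r}")
        if self.ref == self.alt:
            raise VariantIOError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.label not in (None, "functional", "control", "unlabeled"):
            raise VariantIOError(f"invalid label {self.label!r}")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def interval(self) -> GenomicInterval:
        """The reference-allele footprint, 0-based half-open."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref))

    def with_label(self, label: str) -> "VariantRecord":
        return replace(self, label=label)


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals with an interval-tree overlap index.

    Strand is stored on the intervals but ignored by overlap queries.
    """

    name: str
    _trees: dict = field(default_factory=dict, repr=False)
    _intervals: list = field(default_factory=list, repr=False)

    def add(self, interval: GenomicInterval, gene: Optional[str] = None) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, (interval, gene))
        self._intervals.append((interval, gene))

    def __len__(self) -> int:
        return len(self._intervals)

    def intervals(self) -> Iterator[tuple[GenomicInterval, Optional[str]]]:
        return iter(self._intervals)

    def intervals_on(self, chrom: str) -> list[tuple[GenomicInterval, Optional[str]]]:
        return [(iv, g) for iv, g in self._intervals if iv.chrom == chrom]

    def query(self, chrom: str, start: int, end: int) -> list[tuple[GenomicInterval, Optional[str]]]:
        """All stored intervals intersecting [start, end) on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda d: (d[0].start, d[0].end, d[1] or ""))
        return hits


def overlaps(track: AnnotationTrack, v: VariantRecord) -> list[tuple[GenomicInterval, int]]:
    """Track intervals overlapping the variant's reference footprint.

    Returns (interval, overlap length in bp) pairs; no overlap yields an
    empty list, never an error.
    """
    foot = v.interval()
    out = []
    for iv, _gene in track.query(foot.chrom, foot.start, foot.end):
        ol = foot.overlap_length(iv)
        if ol >= 1:
            out.append((iv, ol))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("chrom", "pos", "ref", "alt")
_TSV_OPTIONAL = ("id", "label", "source", "pvalue")


def read_variants(path: str | os.PathLike, format: Optional[str] = None) -> list[VariantRecord]:
    """Read variants from a VCF or a headered TSV, preserving input order.

    Multiallelic VCF rows are split into one record per alternate allele.
    ``format`` is inferred from the file extension when omitted.
    """
    path = os.fspath(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise VariantIOError(f"unknown variant format {format!r}")


def _read_vcf(path: str) -> list[VariantRecord]:
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.ref is None or not rec.alts:
                raise VariantIOError(f"VCF record without REF/ALT at {rec.chrom}:{rec.pos}")
            for alt in rec.alts:
                out.append(
                    VariantRecord(
                        chrom=normalize_chrom(rec.chrom),
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        id=rec.id,
                    )
                )
    return out


def _read_tsv(path: str) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise VariantIOError(f"{path}: empty file (header line required)")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise VariantIOError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                kwargs = {
                    "chrom": normalize_chrom(fields[idx["chrom"]]),
                    "pos": int(fields[idx["pos"]]),
                    "ref": fields[idx["ref"]].upper(),
                    "alt": fields[idx["alt"]].upper(),
                }
                for opt in _TSV_OPTIONAL:
                    if opt in idx and idx[opt] < len(fields):
                        raw = fields[idx[opt]]
                        if raw in ("", "."):
                            continue
                        kwargs[opt] = float(raw) if opt == "pvalue" else raw
                out.append(VariantRecord(**kwargs))
            except (VariantIOError, ValueError, IndexError) as exc:
                raise VariantIOError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return out


def write_variants(variants: Sequence[VariantRecord], path: str | os.PathLike) -> None:
    """Write a headered TSV that :func:`read_variants` round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS + _TSV_OPTIONAL) + "\n")
        for v in variants:
            pv = "." if v.pvalue is None else repr(v.pvalue)
            row = [v.chrom, str(v.pos), v.ref, v.alt, v.id or ".", v.label or ".", v.source or ".", pv]
            fh.write("\t".join(row) + "\n")


def read_bed(path: str | os.PathLike, name: str) -> AnnotationTrack:
    """Read a BED3/BED4(+) file into an indexed track.

    BED's native 0-based half-open convention is kept unchanged; an optional
    4th column is stored as a gene symbol, a 6th column as strand.
    """
    track = AnnotationTrack(name=name)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise VariantIOError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise VariantIOError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise VariantIOError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            gene = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            track.add(GenomicInterval(normalize_chrom(fields[0]), start, end, strand), gene=gene)
    return track


def dedupe_variants(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop duplicate (chrom, pos, ref, alt) keys, keeping first occurrence."""
    seen: set[tuple] = set()
    out = []
    for v in variants:
        k = v.key()
        if k not in seen:
            seen.add(k)
            out.append(v)
    return out
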