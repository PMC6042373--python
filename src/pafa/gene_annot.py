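"""Gene-centric functional annotation.

A variant is mapped to the annotated elements (exon, TSS, UTRs, enhancer,
TFBS, open chromatin) of every gene it touches, and scored against
gene-disease occurrence counts:

    score = sum_i S_i,
    S_i   = s_i * min(1, sum_j (L_o_ij / L_e_j) * W_T(type_j)),

where s_i is gene i's occurrence count across the configured gene-disease
tables, L_e_j the length of gene i's j-th overlapped element, L_o_ij the
variant/element overlap length, and W_T an element-type weight.  The cap
wraps the whole weighted sum, so S_i <= s_i always.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

from intervaltree import IntervalTree

from .variant_io import AnnotationTrack, GenomicInterval, VariantRecord, normalize_chrom

__all__ = [
    "ELEMENT_TYPES",
    "WeightScheme",
    "GeneElementMap",
    "ElementHit",
    "GeneScoreResult",
    "map_variant_to_elements",
    "gene_disease_score",
    "read_gene_elements",
    "read_disease_counts",
]

ELEMENT_TYPES = (
    "exon",
    "tss",
    "utr3",
    "utr5",
    "enhancer",
    "tfbs_peakseq",
    "tfbs_spp",
    "open_chromatin",
)

# Empirical element-type weights: exonic and TSS hits count fully, UTRs half,
# regulatory elements progressively less.
DEFAULT_WEIGHTS = {
    "exon": 1.0,
    "tss": 1.0,
    "utr3": 0.5,
    "utr5": 0.5,
    "enhancer": 0.3,
    "tfbs_peakseq": 0.2,
    "tfbs_spp": 0.2,
    "open_chromatin": 0.1,
}


@dataclass
class WeightScheme:
    """Element-type -> weight W_T in (0, 1]; extendable via configuration."""

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        for etype, w in self.weights.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight for {etype!r} must lie in (0, 1], got {w}")

    def weight(self, element_type: str) -> float:
        try:
            return self.weights[element_type]
        except KeyError:
            raise ValueError(f"unknown element type {element_type!r}") from None


@dataclass(frozen=True)
class ElementHit:
    gene: str
    element_type: str
    overlap_length: int
    element_length: int
    interval: GenomicInterval


class GeneElementMap:
    """Gene -> annotated elements, indexed by position for overlap queries.

    Elements are deduplicated by (gene, type, interval), so the same element
    reached via multiple transcripts is counted once.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._seen: set[tuple] = set()
        self._elements: list[tuple[str, str, GenomicInterval]] = []

    def add_element(self, gene: str, element_type: str, interval: GenomicInterval) -> None:
        if not gene:
            raise ValueError("gene symbol must be non-empty")
        key = (gene, element_type, interval.chrom, interval.start, interval.end)
        if key in self._seen:
            return
        self._seen.add(key)
        self._elements.append((gene, element_type, interval))
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, (gene, element_type, interval))

    def __len__(self) -> int:
        return len(self._elements)

    def elements(self) -> list[tuple[str, str, GenomicInterval]]:
        return list(self._elements)

    def genes(self) -> set[str]:
        return {g for g, _, _ in self._elements}

    def query(self, chrom: str, start: int, end: int) -> list[tuple[str, str, GenomicInterval]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda d: (d[0], d[1], d[2].start, d[2].end))
        return hits

    @classmethod
    def from_tracks(cls, tracks: Mapping[str, AnnotationTrack]) -> "GeneElementMap":
        """Build from one BED4 track per element type (4th column = gene)."""
        gmap = cls()
        for etype, track in tracks.items():
            for iv, gene in track.intervals():
                if gene is None:
                    raise ValueError(
                        f"element track {track.name!r} has an interval without a gene symbol"
                    )
                gmap.add_element(gene, etype, iv)
        return gmap


def map_variant_to_elements(v: VariantRecord, gmap: GeneElementMap) -> list[ElementHit]:
    """Exhaustive list of elements the variant's footprint overlaps, with
    exact overlap and element lengths."""
    foot = v.interval()
    hits = []
    for gene, etype, iv in gmap.query(foot.chrom, foot.start, foot.end):
        ol = foot.overlap_length(iv)
        if ol >= 1:
            hits.append(ElementHit(gene, etype, ol, iv.length, iv))
    return hits


@dataclass
class GeneScoreResult:
    total: float
    per_gene: dict  # gene -> S_i
    s_counts: dict  # gene -> s_i
    hits: list  # ElementHit


def gene_disease_score(
    v: VariantRecord,
    gmap: GeneElementMap,
    weights: WeightScheme,
    disease_counts: Mapping[str, int],
) -> GeneScoreResult:
    """Weighted gene-disease score for one variant (see module docstring).

    Genes absent from ``disease_counts`` get s_i = 0; genes the variant does
    not touch contribute nothing.
    """
    hits = map_variant_to_elements(v, gmap)
    by_gene: dict[str, float] = {}
    for h in hits:
        w = weights.weight(h.element_type)
        by_gene[h.gene] = by_gene.get(h.gene, 0.0) + (h.overlap_length / h.element_length) * w
    per_gene = {}
    for gene, weighted_sum in by_gene.items():
        s_i = int(disease_counts.get(gene, 0))
        per_gene[gene] = s_i * min(1.0, weighted_sum)
    s_counts = {g: int(disease_counts.get(g, 0)) for g in by_gene}
    return GeneScoreResult(
        total=float(sum(per_gene.values())),
        per_gene=per_gene,
        s_counts=s_counts,
        hits=hits,
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gene_elements(path: str | os.PathLike) -> GeneElementMap:
    """Read a combined element BED: chrom, start, end, gene, element_type."""
    gmap = GeneElementMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns (chrom start end gene type)")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            gmap.add_element(f[3], f[4], GenomicInterval(normalize_chrom(f[0]), start, end))
    return gmap


def read_disease_counts(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column (gene, count) TSV with a header line; repeated genes
    accumulate."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                counts[f[0]] = counts.get(f[0], 0) + int(f[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}") from exc
    return counts
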