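"""Variant Set Enrichment Analysis (VSEA).

Test and background variant sets are mapped to the genes whose annotated
elements they overlap; each pathway is then tested for over-representation
of test genes against background genes with a one-sided Fisher's exact test
(the hypergeometric tail), with Benjamini-Hochberg adjustment across
pathways.  Counting is at the gene level — a gene hit by many variants
counts once — because gene extraction precedes testing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .gene_annot import GeneElementMap, map_variant_to_elements
from .variant_io import VariantRecord

__all__ = [
    "PathwayDB",
    "EnrichmentRow",
    "read_gmt",
    "variants_to_genes",
    "enrich",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayDB:
    """Named gene sets (e.g. canonical pathways from MSigDB-style GMT)."""

    pathways: dict  # pathway name -> set of gene symbols
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"pathway {name!r} contains an empty gene symbol")

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | os.PathLike, source: str = "") -> PathwayDB:
    """Read GMT: one pathway per line, tab-separated name, description, genes."""
    pathways = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: expected name, description, >= 1 gene")
            pathways[f[0]] = {g for g in f[2:] if g}
    return PathwayDB(pathways=pathways, source=source or os.fspath(path))


def variants_to_genes(variants: Iterable[VariantRecord], gmap: GeneElementMap) -> set[str]:
    """Union of genes whose annotated elements the variants overlap."""
    genes: set[str] = set()
    for v in variants:
        genes.update(h.gene for h in map_variant_to_elements(v, gmap))
    return genes


@dataclass(frozen=True)
class EnrichmentRow:
    pathway: str
    a: int  # test genes in pathway
    b: int  # test genes not in pathway
    c: int  # background genes in pathway
    d: int  # background genes not in pathway
    odds_ratio: float
    p: float
    p_adj: float


def enrich(
    test_genes: set[str],
    background_genes: set[str],
    db: PathwayDB,
    alternative: str = "greater",
) -> list[EnrichmentRow]:
    """Per-pathway 2x2 Fisher's exact test of test vs background genes.

    The two gene sets are the two rows of the table exactly as given: the
    background is a comparison group, not a universe containing the test
    set (keeping the rows independent is what makes the hypergeometric
    null calibrated).  Test genes absent from the background are fine and
    merely logged.  Returns one row per pathway in the database's order,
    with Benjamini-Hochberg adjusted p-values alongside the raw ones.
    """
    if not test_genes:
        raise ValueError("test gene set is empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    stray = test_genes - background_genes
    if stray:
        logger.info("%d test genes are absent from the background set", len(stray))

    names, tables, pvals = [], [], []
    for name, pathway in db.pathways.items():
        a = len(test_genes & pathway)
        b = len(test_genes) - a
        c = len(background_genes & pathway)
        d = len(background_genes) - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
        names.append(name)
        tables.append((a, b, c, d, float(odds)))
        pvals.append(float(min(p, 1.0)))

    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentRow(name, a, b, c, d, odds, p, float(pa))
        for name, (a, b, c, d, odds), p, pa in zip(names, tables, pvals, p_adj)
    ]
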