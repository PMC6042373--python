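"""Seeded synthetic-data generators for every input the toolkit consumes.

The generators provide planted ground truth for recovery tests and a
download-free stand-in for the population-frequency, annotation-track,
conservation, pathway and gene-disease resources the method was designed
around.  All generators are pure functions of their configuration (seed
included): a fixed seed reproduces outputs bit-identically.

Population model
----------------
Subpopulation allele frequencies follow the Balding-Nichols model: for an
ancestral frequency p0 and differentiation parameter F, each subpopulation
draws p_i ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F), so that E[p_i] = p0 and
Var[p_i] = F p0 (1-p0).  Observed frequencies are binomial draws of n_i
allele copies at p_i, so finite-sample corrections in the F_ST estimator
are actually exercised.

Training cohort
---------------
Functional variants preferentially overlap the informative annotation
tracks, carry elevated conservation, and draw their subpopulation
frequencies from a high-differentiation regime; controls do the opposite.
``effect_size`` in [0, 1] scales every one of those separations — at 0 the
two classes are exchangeable (a null cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import (
    ConservationTrack,
    FeatureMatrix,
    FeatureRegistry,
    annotation_features,
    assemble_matrix,
    conservation_features,
    population_features,
)
from .gene_annot import GeneElementMap
from .popdiff import PopulationFrequencyTable
from .variant_io import AnnotationTrack, GenomicInterval, VariantRecord
from .vsea import PathwayDB

__all__ = [
    "SimulationConfig",
    "simulate_frequency_table",
    "simulate_training_cohort",
    "simulate_pathways",
    "TrainingCohort",
    "PathwaySim",
    "cohort_feature_matrix",
]

SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass
class SimulationConfig:
    """All knobs for the generators; defaults define the study conditions."""

    seed: int = 0
    # population-frequency generator
    n_populations: int = 5
    sample_size: int = 500  # allele copies per subpopulation
    n_loci: int = 5000
    F: float = 0.1  # Balding-Nichols differentiation parameter
    ancestral_range: tuple = (0.05, 0.95)
    # genome layout
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    # training cohort
    n_variants: int = 2000
    n_informative_tracks: int = 10
    n_noise_tracks: int = 200
    effect_size: float = 0.6  # informative overlap-probability separation
    base_overlap: float = 0.5  # informative-track overlap prob at effect 0
    noise_overlap: float = 0.3
    conservation_missing_rate: float = 0.1
    functional_F: float = 0.2  # differentiation regime of functional variants
    control_F: float = 0.02
    # pathway / enrichment generator
    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size: int = 200
    n_test_variants: int = 400
    n_background_variants: int = 1000
    planted_fraction: float = 0.3  # of test variants drawn from the planted pathway
    element_length: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must lie in (0, 1)")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must lie in [0, 1]")
        if not (0.0 <= self.planted_fraction < 1.0):
            raise ValueError("planted_fraction must lie in [0, 1)")
        for name in ("n_populations", "sample_size", "n_loci", "n_variants", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _population_names(s: int) -> list[str]:
    if s == len(SUPERPOPULATIONS):
        return list(SUPERPOPULATIONS)
    return [f"POP{i+1}" for i in range(s)]


def _balding_nichols_locus(
    rng: np.random.Generator, cfg: SimulationConfig, F: float
) -> PopulationFrequencyTable:
    p0 = rng.uniform(*cfg.ancestral_range)
    a, b = p0 * (1.0 - F) / F, (1.0 - p0) * (1.0 - F) / F
    true_p = rng.beta(a, b, size=cfg.n_populations)
    n = np.full(cfg.n_populations, cfg.sample_size)
    observed = rng.binomial(n, true_p) / n
    return PopulationFrequencyTable(
        populations=_population_names(cfg.n_populations), p=observed, n=n
    )


def simulate_frequency_table(
    cfg: SimulationConfig,
) -> tuple[list[PopulationFrequencyTable], np.ndarray]:
    """Balding-Nichols frequency tables for ``n_loci`` loci, plus the true
    (planted) differentiation parameter per locus."""
    rng = np.random.default_rng(cfg.seed)
    tables = [_balding_nichols_locus(rng, cfg, cfg.F) for _ in range(cfg.n_loci)]
    return tables, np.full(cfg.n_loci, cfg.F)


# ---------------------------------------------------------------------------
# Training cohort
# ---------------------------------------------------------------------------

@dataclass
class TrainingCohort:
    variants: list
    labels: np.ndarray  # +1 functional / -1 control, aligned to variants
    tracks: list  # AnnotationTrack, informative first then noise
    conservation: list  # ConservationTrack
    freq_tables: dict  # variant key -> PopulationFrequencyTable
    informative_track_names: list = field(default_factory=list)
    noise_track_names: list = field(default_factory=list)


def simulate_training_cohort(cfg: SimulationConfig) -> TrainingCohort:
    """A labeled cohort with planted signal in all three feature classes.

    Each variant sits on its own locus (spaced so element intervals never
    collide); each track's intervals are built around exactly the variants
    it overlaps, so overlap indicators are independent Bernoulli draws with
    class-dependent probability on informative tracks and class-independent
    probability on noise tracks.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))

    spacing = 400
    bases = np.array(list("ACGT"))
    variants = []
    for i in range(n):
        chrom = str(1 + i % cfg.n_chromosomes)
        pos = 200 + (i // cfg.n_chromosomes) * spacing
        if pos + 100 > cfg.chrom_length:
            raise ValueError("chrom_length too small for n_variants at this spacing")
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref=str(ref),
                alt=str(alt),
                id=f"sv{i:05d}",
                label="functional" if labels[i] == 1 else "control",
                source="synthetic",
            )
        )

    eff = cfg.effect_size
    q_func = min(1.0, cfg.base_overlap + eff / 2.0)
    q_ctrl = max(0.0, cfg.base_overlap - eff / 2.0)
    p_overlap = np.where(labels == 1, q_func, q_ctrl)

    tracks, informative_names, noise_names = [], [], []
    half = 10  # element half-width around the variant position
    for t in range(cfg.n_informative_tracks + cfg.n_noise_tracks):
        informative = t < cfg.n_informative_tracks
        name = f"{'inf' if informative else 'noise'}_track_{t:03d}"
        prob = p_overlap if informative else np.full(n, cfg.noise_overlap)
        hit = rng.random(n) < prob
        track = AnnotationTrack(name=name)
        for v, h in zip(variants, hit):
            if h:
                start = v.pos - 1 - half
                track.add(GenomicInterval(v.chrom, start, start + 2 * half))
        tracks.append(track)
        (informative_names if informative else noise_names).append(name)

    # conservation: two score tracks with a class-dependent mean shift
    conservation = []
    shift = 0.3 * eff
    for cname in ("phastcons_like", "phylop_like"):
        values = {}
        mean = np.where(labels == 1, 0.5 + shift, 0.5 - shift)
        scores = np.clip(rng.normal(mean, 0.15), 0.0, 1.0)
        present = rng.random(n) >= cfg.conservation_missing_rate
        for v, s, keep in zip(variants, scores, present):
            if keep:
                values[(v.chrom, v.pos)] = float(s)
        conservation.append(ConservationTrack(name=cname, values=values))

    # population frequencies: high-differentiation regime for functionals
    f_func = cfg.control_F + (cfg.functional_F - cfg.control_F) * eff
    freq_tables = {}
    for v, lab in zip(variants, labels):
        F = f_func if lab == 1 else cfg.control_F
        freq_tables[v.key()] = _balding_nichols_locus(rng, cfg, F)

    return TrainingCohort(
        variants=variants,
        labels=labels,
        tracks=tracks,
        conservation=conservation,
        freq_tables=freq_tables,
        informative_track_names=informative_names,
        noise_track_names=noise_names,
    )


def cohort_feature_matrix(
    cohort: TrainingCohort, registry: Optional[FeatureRegistry] = None
) -> tuple[FeatureMatrix, FeatureRegistry]:
    """Assemble the cohort's variant-by-feature matrix (population features
    first, then conservation, then annotation tracks)."""
    registry = registry or FeatureRegistry()
    sources = [
        lambda v: population_features(v, cohort.freq_tables.get(v.key()), registry),
        lambda v: conservation_features(v, cohort.conservation, registry),
        lambda v: annotation_features(v, cohort.tracks, registry),
    ]
    matrix = assemble_matrix(cohort.variants, sources, registry)
    return matrix, registry


# ---------------------------------------------------------------------------
# Pathways / enrichment
# ---------------------------------------------------------------------------

@dataclass
class PathwaySim:
    db: PathwayDB
    planted_pathway: Optional[str]
    gmap: GeneElementMap
    disease_counts: dict
    test_variants: list
    background_variants: list
    test_genes: set
    background_genes: set


def simulate_pathways(cfg: SimulationConfig) -> PathwaySim:
    """A gene universe partitioned into overlapping pathways, one exon-like
    element per gene, disease counts with known values, and test/background
    variant sets.

    With ``planted_fraction > 0`` that share of test variants is drawn from
    the first pathway's genes (the planted pathway); the rest of the test
    set and the whole background set are drawn disjointly from the
    remaining universe, so an unplanted run is a calibrated null.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    gmap = GeneElementMap()
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)  # ceil
    gene_interval = {}
    stride = cfg.chrom_length // per_chrom
    if stride < cfg.element_length + 1:
        raise ValueError("chrom_length too small for n_genes at this element_length")
    for i, gene in enumerate(genes):
        chrom = str(1 + i // per_chrom)
        start = (i % per_chrom) * stride
        iv = GenomicInterval(chrom, start, start + cfg.element_length)
        gmap.add_element(gene, "exon", iv)
        gene_interval[gene] = iv

    pathways = {}
    for j in range(cfg.n_pathways):
        members = rng.choice(cfg.n_genes, size=cfg.pathway_size, replace=False)
        pathways[f"PW{j:03d}"] = {genes[g] for g in members}
    planted = "PW000" if cfg.planted_fraction > 0 else None
    db = PathwayDB(pathways=pathways, source="synthetic")

    disease_counts = {g: int(c) for g, c in zip(genes, rng.integers(0, 5, cfg.n_genes))}

    n_test, n_bg = cfg.n_test_variants, cfg.n_background_variants
    n_planted = int(round(cfg.planted_fraction * n_test))
    planted_pool = sorted(pathways["PW000"]) if planted else []
    chosen_planted = (
        list(rng.choice(planted_pool, size=min(n_planted, len(planted_pool)), replace=False))
        if n_planted
        else []
    )
    rest_pool = sorted(set(genes) - set(chosen_planted))
    rest = rng.choice(len(rest_pool), size=(n_test - len(chosen_planted)) + n_bg, replace=False)
    test_genes = set(chosen_planted) | {rest_pool[i] for i in rest[: n_test - len(chosen_planted)]}
    background_genes = {rest_pool[i] for i in rest[n_test - len(chosen_planted):]}

    def _variant_in_gene(gene: str, idx: int) -> VariantRecord:
        iv = gene_interval[gene]
        pos0 = int(rng.integers(iv.start, iv.end))
        return VariantRecord(
            chrom=iv.chrom, pos=pos0 + 1, ref="A", alt="G", id=f"pv{idx:05d}", source="synthetic"
        )

    test_variants = [_variant_in_gene(g, i) for i, g in enumerate(sorted(test_genes))]
    background_variants = [
        _variant_in_gene(g, i) for i, g in enumerate(sorted(background_genes), start=len(test_variants))
    ]

    return PathwaySim(
        db=db,
        planted_pathway=planted,
        gmap=gmap,
        disease_counts=disease_counts,
        test_variants=test_variants,
        background_variants=background_variants,
        test_genes=test_genes,
        background_genes=background_genes,
    )
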