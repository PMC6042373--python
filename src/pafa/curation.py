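"""Training-set curation: labeled functional/control variant construction.

The pipeline mirrors the filtration flow used to assemble the published
training sets from curated databases, but runs on any inputs in the standard
formats:

1. pathogenic/benign conflict resolution — records labeled both ways are
   kept on the functional side and dropped from the control side;
2. significant, element-overlapping trait-associated SNPs (cSNPs, p <= 1e-8)
   join the functional set;
3. a seeded random pool of low-differentiation variants (F_ST < 0.01, keys
   not already used) is drawn as control candidates;
4. a preliminary L1-logistic model (cSNPs positive vs the candidate pool
   negative) ranks the candidates; those with the most negative decision
   values ("inversely associated") become controls;
5. optional simulated rare benign variants adjacent (+/- 50 bp) to the
   functional anchors join the controls;
6. the larger class is down-sampled (seeded) to balance the sets.

Every stage records its survivor count in ``provenance_counts``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .classifier import train_l1_logistic
from .features import FeatureMatrix
from .popdiff import PopulationFrequencyTable, fst_unbiased
from .variant_io import AnnotationTrack, VariantRecord, dedupe_variants, overlaps

__all__ = [
    "LabeledVariantSets",
    "CurationConfig",
    "resolve_conflicts",
    "select_csnps",
    "select_control_candidates",
    "rank_inverse_controls",
    "InverseControlResult",
    "simulate_adjacent_variants",
    "label_recurrent",
    "build_training_sets",
]

VariantKey = tuple  # (chrom, pos, ref, alt)


@dataclass
class LabeledVariantSets:
    functional: list
    control: list
    provenance_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fk = {v.key() for v in self.functional}
        ck = {v.key() for v in self.control}
        if len(fk) != len(self.functional) or len(ck) != len(self.control):
            raise ValueError("duplicate variant keys within a labeled set")
        if fk & ck:
            raise ValueError("functional and control sets must be disjoint")


def resolve_conflicts(
    pathogenic: Sequence[VariantRecord], benign: Sequence[VariantRecord]
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Drop pathogenic/benign conflicts from the benign side only.

    Variants present in both inputs stay functional; each side is
    deduplicated by (chrom, pos, ref, alt).
    """
    keep_path = dedupe_variants(pathogenic)
    path_keys = {v.key() for v in keep_path}
    keep_benign = [v for v in dedupe_variants(benign) if v.key() not in path_keys]
    return keep_path, keep_benign


def select_csnps(
    gwas_variants: Sequence[VariantRecord],
    element_tracks: Sequence[AnnotationTrack],
    alpha: float = 1e-8,
) -> list[VariantRecord]:
    """Keep trait-associated SNPs with p <= alpha that overlap at least one
    genomic element; input order preserved."""
    out = []
    for v in gwas_variants:
        if v.pvalue is None:
            raise ValueError(f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} lacks a p-value")
        if v.pvalue > alpha:
            continue
        if any(overlaps(track, v) for track in element_tracks):
            out.append(v)
    return out


def select_control_candidates(
    kg_variants: Sequence[VariantRecord],
    freq_tables: Mapping[VariantKey, PopulationFrequencyTable],
    exclusions: set,
    fst_max: float = 0.01,
    k: int = 100_000,
    seed: int = 0,
    msg_denominator: str = "printed",
) -> list[VariantRecord]:
    """Seeded uniform sample of up to ``k`` low-differentiation variants.

    Eligible: defined F_ST < ``fst_max``, key not excluded; duplicates
    dropped.  The whole eligible pool is returned when it is smaller
    than ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = []
    for v in dedupe_variants(kg_variants):
        if v.key() in exclusions:
            continue
        t = freq_tables.get(v.key())
        if t is None:
            continue
        comp = fst_unbiased(t, msg_denominator=msg_denominator)
        if comp.defined and comp.fst < fst_max:
            eligible.append(v)
    if len(eligible) <= k:
        return eligible
    rng = random.Random(seed)
    return rng.sample(eligible, k)


@dataclass
class InverseControlResult:
    selected: list
    shortfall: int  # how many of the requested m lacked a negative score
    decisions: dict  # variant key -> decision value


def rank_inverse_controls(
    candidates: Sequence[VariantRecord],
    csnp_matrix: FeatureMatrix,
    candidate_matrix: FeatureMatrix,
    m: int,
    C: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
) -> InverseControlResult:
    """Select the ``m`` candidates most inversely associated with cSNPs.

    A preliminary L1-logistic model is trained with the cSNP rows as
    positives and the candidate rows as negatives; candidates are ranked by
    signed decision value (ascending, ties broken by variant key) and only
    negative-scoring ones are eligible.  Fewer than ``m`` negatives is
    reported as a shortfall, not an error.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if csnp_matrix.registry is not candidate_matrix.registry and (
        csnp_matrix.registry.fingerprint() != candidate_matrix.registry.fingerprint()
    ):
        raise ValueError("cSNP and candidate matrices use different registries")
    if len(candidates) != candidate_matrix.n_rows:
        raise ValueError("candidate list / matrix row mismatch")

    merged = FeatureMatrix(
        rows=list(csnp_matrix.rows) + list(candidate_matrix.rows),
        registry=csnp_matrix.registry,
    )
    y = [1] * csnp_matrix.n_rows + [-1] * candidate_matrix.n_rows
    model = train_l1_logistic(merged, y, C=C, seed=seed, tol=tol)
    decisions = {
        v.key(): model.decision(row)
        for v, row in zip(candidates, candidate_matrix.rows)
    }
    ranked = sorted(candidates, key=lambda v: (decisions[v.key()], v.key()))
    negative = [v for v in ranked if decisions[v.key()] < 0]
    selected = negative[:m]
    return InverseControlResult(
        selected=selected, shortfall=max(0, m - len(negative)), decisions=decisions
    )


def simulate_adjacent_variants(
    anchors: Sequence[VariantRecord],
    window: int = 50,
    per_anchor: int = 1,
    exclusions: Optional[set] = None,
    seed: int = 0,
) -> list[VariantRecord]:
    """Simulated variants adjacent to anchors: positions drawn uniformly from
    [pos - window, pos + window] excluding the anchor position itself (and
    clipped at position 1), with a random alternate allele against an ``N``
    reference placeholder.  Excluded keys and duplicates are dropped."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if per_anchor < 1:
        raise ValueError("per_anchor must be >= 1")
    exclusions = exclusions or set()
    rng = random.Random(seed)
    out, seen = [], set()
    for anchor in anchors:
        lo = max(1, anchor.pos - window)
        hi = anchor.pos + window
        positions = [p for p in range(lo, hi + 1) if p != anchor.pos]
        for _ in range(per_anchor):
            pos = rng.choice(positions)
            alt = rng.choice("ACGT")
            v = VariantRecord(
                chrom=anchor.chrom,
                pos=pos,
                ref="N",
                alt=alt,
                label="control",
                source="simulated_adjacent",
            )
            if v.key() in exclusions or v.key() in seen:
                continue
            seen.add(v.key())
            out.append(v)
    return out


def label_recurrent(
    donors_by_variant: Mapping[VariantKey, Iterable[str]], min_donors: int = 2
) -> dict:
    """Recurrence flags: True iff a variant was observed in at least
    ``min_donors`` *distinct* donors."""
    return {
        key: len(set(donors)) >= min_donors
        for key, donors in donors_by_variant.items()
    }


@dataclass
class CurationConfig:
    """Inputs and thresholds for :func:`build_training_sets`.

    ``featurize`` maps a variant list to a FeatureMatrix on a shared
    registry (composed by the caller from the configured tracks and
    frequency resources).
    """

    pathogenic: Sequence[VariantRecord]
    benign: Sequence[VariantRecord]
    gwas_variants: Sequence[VariantRecord]
    element_tracks: Sequence[AnnotationTrack]
    kg_variants: Sequence[VariantRecord]
    kg_freq_tables: Mapping[VariantKey, PopulationFrequencyTable]
    featurize: Callable[[Sequence[VariantRecord]], FeatureMatrix]
    alpha: float = 1e-8
    fst_max: float = 0.01
    k: int = 100_000
    m: int = 100_000
    window: int = 50
    simulate_per_anchor: int = 1
    C: float = 1.0
    seed: int = 0


def build_training_sets(config: CurationConfig) -> LabeledVariantSets:
    """Run the full curation flow and return balanced labeled sets.

    functional = conflict-resolved pathogenic  ∪  significant overlapping cSNPs;
    control    = conflict-resolved benign  ∪  inversely-associated low-F_ST
    variants  ∪  (optionally) simulated adjacent rare variants; the larger
    side is then down-sampled (seeded) to the smaller side's size.
    """
    prov: dict[str, int] = {
        "input_pathogenic": len(config.pathogenic),
        "input_benign": len(config.benign),
        "input_gwas": len(config.gwas_variants),
        "input_kg": len(config.kg_variants),
    }

    functional_clinvar, control_clinvar = resolve_conflicts(config.pathogenic, config.benign)
    prov["pathogenic_after_conflicts"] = len(functional_clinvar)
    prov["benign_after_conflicts"] = len(control_clinvar)

    csnps = select_csnps(config.gwas_variants, config.element_tracks, alpha=config.alpha)
    prov["csnps_selected"] = len(csnps)

    functional = dedupe_variants(list(functional_clinvar) + list(csnps))
    prov["functional_before_balance"] = len(functional)
    functional_keys = {v.key() for v in functional}

    gwas_keys = {v.key() for v in config.gwas_variants}
    candidates = select_control_candidates(
        config.kg_variants,
        config.kg_freq_tables,
        exclusions=functional_keys | gwas_keys,
        fst_max=config.fst_max,
        k=config.k,
        seed=config.seed,
    )
    prov["control_candidates"] = len(candidates)

    ranked = rank_inverse_controls(
        candidates,
        config.featurize(csnps),
        config.featurize(candidates),
        m=config.m,
        C=config.C,
        seed=config.seed,
    )
    prov["inverse_controls"] = len(ranked.selected)
    prov["inverse_control_shortfall"] = ranked.shortfall

    control_pool = list(control_clinvar) + list(ranked.selected)
    if config.simulate_per_anchor > 0:
        simulated = simulate_adjacent_variants(
            functional,
            window=config.window,
            per_anchor=config.simulate_per_anchor,
            exclusions=functional_keys | {v.key() for v in control_pool},
            seed=config.seed,
        )
        prov["simulated_controls"] = len(simulated)
        control_pool += simulated
    else:
        prov["simulated_controls"] = 0

    control = [v for v in dedupe_variants(control_pool) if v.key() not in functional_keys]
    prov["control_before_balance"] = len(control)

    if not functional or not control:
        raise ValueError("curation produced an empty functional or control set")

    # seeded balancing: down-sample the larger side
    rng = random.Random(config.seed + 1)
    target = min(len(functional), len(control))
    if len(functional) > target:
        functional = sorted(rng.sample(functional, target), key=lambda v: v.key())
    if len(control) > target:
        control = sorted(rng.sample(control, target), key=lambda v: v.key())
    prov["functional_final"] = len(functional)
    prov["control_final"] = len(control)

    functional = [v.with_label("functional") for v in functional]
    control = [v.with_label("control") for v in control]
    return LabeledVariantSets(functional=functional, control=control, provenance_counts=prov)
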