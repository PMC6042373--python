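"""Sparse variant-by-feature matrix assembly.

Three feature classes feed the scoring model: population-level metrics
(per-superpopulation allele frequencies, F_ST, dispersion score),
evolutionary conservation scores, and genomic annotations (binary overlap
with element tracks, distance to the nearest transcript start site).

Missing-vs-zero discipline: a feature with no overlapping relationship is
*missing* and is simply absent from the sparse vector; a genuine score of
0.0 is stored.  The linear model's sparse decision function lets absent
entries contribute 0 to the dot product — that is the operational meaning
of "missing" downstream, but the matrix itself never confuses the two
(the one documented exception: an undefined F_ST at a monomorphic locus is
substituted with 0 and counted).
"""

from __future__ import annotations

import hashlib
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .popdiff import PopulationFrequencyTable, dispersion_score, fst_unbiased
from .variant_io import AnnotationTrack, VariantRecord, overlaps

__all__ = [
    "FeatureRegistry",
    "ConservationTrack",
    "FeatureMatrix",
    "annotation_features",
    "tss_distance_feature",
    "conservation_features",
    "population_features",
    "assemble_matrix",
]

logger = logging.getLogger(__name__)

FEATURE_GROUPS = ("population", "conservation", "annotation")

FeatureVector = dict  # feature index -> float; absent index means missing


class FeatureRegistry:
    """Ordered feature-name -> fixed 1-based index map.

    Indices are contiguous from 1 and never reassigned; registering an
    existing name under a different group is an error.
    """

    def __init__(self) -> None:
        self._index: dict[str, int] = {}
        self._group: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def get_or_register(self, name: str, group: str) -> int:
        if group not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {group!r}")
        if name in self._index:
            if self._group[name] != group:
                raise ValueError(
                    f"feature {name!r} already registered with group "
                    f"{self._group[name]!r}, not {group!r}"
                )
            return self._index[name]
        idx = len(self._index) + 1
        self._index[name] = idx
        self._group[name] = group
        return idx

    def index_of(self, name: str) -> int:
        return self._index[name]

    def items(self) -> list[tuple[str, int, str]]:
        return [(name, idx, self._group[name]) for name, idx in self._index.items()]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name, idx, group in self.items():
            h.update(f"{name}\t{idx}\t{group}\n".encode())
        return h.hexdigest()[:16]

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("index\tname\tgroup\n")
            for name, idx, group in self.items():
                fh.write(f"{idx}\t{name}\t{group}\n")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "FeatureRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            rows = []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rows.append((int(f[cols["index"]]), f[cols["name"]], f[cols["group"]]))
        for idx, name, group in sorted(rows):
            got = reg.get_or_register(name, group)
            if got != idx:
                raise ValueError(f"non-contiguous registry indices in {path}")
        return reg


@dataclass
class ConservationTrack:
    """Per-position conservation scores, e.g. phastCons or phyloP.

    Lookup at an absent position returns None (missing), never 0.
    """

    name: str
    values: dict = field(default_factory=dict)  # (chrom, 1-based pos) -> float

    def get(self, chrom: str, pos: int) -> Optional[float]:
        return self.values.get((chrom, pos))

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, name: str) -> "ConservationTrack":
        """Read a (chrom, pos, score) TSV with a header line."""
        from .variant_io import normalize_chrom

        values = {}
        with open(path) as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                try:
                    values[(normalize_chrom(f[0]), int(f[1]))] = float(f[2])
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}: malformed row at line {lineno}") from exc
        return cls(name=name, values=values)


def _put(vec: FeatureVector, idx: int, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"non-finite feature value for index {idx}")
    vec[idx] = float(value)


# ---------------------------------------------------------------------------
# Per-variant feature extractors
# ---------------------------------------------------------------------------

def annotation_features(
    v: VariantRecord,
    tracks: Iterable[AnnotationTrack],
    registry: FeatureRegistry,
    mode: str = "binary",
) -> FeatureVector:
    """One feature per track: 1.0 on overlap (or the overlap fraction of the
    variant footprint with ``mode="fraction"``); missing when no overlap."""
    vec: FeatureVector = {}
    foot_len = v.interval().length
    for track in tracks:
        idx = registry.get_or_register(track.name, "annotation")
        hits = overlaps(track, v)
        if not hits:
            continue
        if mode == "binary":
            _put(vec, idx, 1.0)
        elif mode == "fraction":
            _put(vec, idx, max(ol for _, ol in hits) / foot_len)
        else:
            raise ValueError(f"unknown annotation mode {mode!r}")
    return vec


def tss_distance_feature(
    v: VariantRecord,
    tss_track: AnnotationTrack,
    registry: FeatureRegistry,
    transform: str = "raw",
) -> FeatureVector:
    """Absolute bp distance to the nearest TSS start on the variant's
    chromosome (0 when the variant lies inside a TSS interval); missing when
    the chromosome carries no TSS.  ``transform="log10"`` emits log10(1+d)."""
    idx = registry.get_or_register(f"tss_distance_{tss_track.name}", "annotation")
    entries = tss_track.intervals_on(v.chrom)
    if not entries:
        return {}
    vpos = v.pos - 1  # 0-based
    if overlaps(tss_track, v):
        d = 0
    else:
        d = min(abs(vpos - iv.start) for iv, _ in entries)
    if transform == "log10":
        d = math.log10(1 + d)
    elif transform != "raw":
        raise ValueError(f"unknown TSS distance transform {transform!r}")
    return {idx: float(d)}


def conservation_features(
    v: VariantRecord,
    tracks: Iterable[ConservationTrack],
    registry: FeatureRegistry,
) -> FeatureVector:
    """One numeric feature per conservation track; positions absent from a
    track stay missing (a stored 0.0 is a real score, not absence)."""
    vec: FeatureVector = {}
    for track in tracks:
        idx = registry.get_or_register(track.name, "conservation")
        score = track.get(v.chrom, v.pos)
        if score is not None:
            _put(vec, idx, score)
    return vec


def population_features(
    v: VariantRecord,
    t: Optional[PopulationFrequencyTable],
    registry: FeatureRegistry,
    clamp_fst: bool = True,
    msg_denominator: str = "printed",
    _undefined_counter: Optional[list] = None,
) -> FeatureVector:
    """Per-population allele frequencies plus F_ST and the dispersion score.

    A variant absent from the frequency resource yields an all-missing
    vector.  An undefined (monomorphic) F_ST is substituted with 0.0 and
    counted via the module logger — the one sanctioned missing-to-zero
    conversion.  Negative F_ST estimates are clamped to 0 by default for
    feature use (``clamp_fst=False`` preserves the raw estimator).
    """
    vec: FeatureVector = {}
    if t is None:
        return vec
    for pop, freq in zip(t.populations, t.p):
        idx = registry.get_or_register(f"af_{pop}", "population")
        _put(vec, idx, float(freq))
    comp = fst_unbiased(t, msg_denominator=msg_denominator)
    fst_idx = registry.get_or_register("fst", "population")
    if comp.defined:
        fst = comp.fst
        if clamp_fst and fst < 0:
            fst = 0.0
    else:
        fst = 0.0
        if _undefined_counter is not None:
            _undefined_counter.append(v.key())
        logger.debug("undefined F_ST at %s:%d substituted with 0", v.chrom, v.pos)
    _put(vec, fst_idx, fst)
    ds_idx = registry.get_or_register("ds", "population")
    _put(vec, ds_idx, dispersion_score(t))
    return vec


# ---------------------------------------------------------------------------
# Matrix assembly and serialization
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Sparse variant-by-feature matrix: one dict row per variant, indices
    from a shared registry.  Stored explicitly so that genuine 0.0 values
    survive serialization (a CSR view is derived for model fitting)."""

    rows: list  # list[dict[int, float]]
    registry: FeatureRegistry

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_csr(self) -> sp.csr_matrix:
        n_feat = len(self.registry)
        data, indices, indptr = [], [], [0]
        for row in self.rows:
            for idx in sorted(row):
                indices.append(idx - 1)
                data.append(row[idx])
            indptr.append(len(indices))
        return sp.csr_matrix(
            (np.array(data, dtype=float), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
            shape=(len(self.rows), n_feat),
        )

    def write_svmlight(self, path: str | os.PathLike, labels: Optional[Sequence[float]] = None) -> None:
        """svmlight/libsvm sparse text: ``label index:value ...`` per row."""
        if labels is None:
            labels = [0] * len(self.rows)
        with open(path, "w") as fh:
            for row, lab in zip(self.rows, labels):
                parts = [f"{int(lab):d}" if float(lab) == int(lab) else repr(lab)]
                parts += [f"{idx}:{row[idx]!r}" for idx in sorted(row)]
                fh.write(" ".join(parts) + "\n")

    @classmethod
    def read_svmlight(
        cls, path: str | os.PathLike, registry: FeatureRegistry
    ) -> tuple["FeatureMatrix", np.ndarray]:
        rows, labels = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split()
                labels.append(float(parts[0]))
                row = {}
                for tok in parts[1:]:
                    idx, val = tok.split(":")
                    row[int(idx)] = float(val)
                rows.append(row)
        return cls(rows=rows, registry=registry), np.array(labels)


def assemble_matrix(
    variants: Sequence[VariantRecord],
    sources: Sequence[Callable[[VariantRecord], FeatureVector]],
    registry: FeatureRegistry,
) -> FeatureMatrix:
    """Row r is the union of the per-source sparse vectors for variant r.

    Sources are callables variant -> FeatureVector sharing ``registry``;
    registry uniqueness makes index collisions between sources impossible.
    """
    rows = []
    for v in variants:
        row: FeatureVector = {}
        for source in sources:
            row.update(source(v))
        rows.append(row)
    return FeatureMatrix(rows=rows, registry=registry)
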