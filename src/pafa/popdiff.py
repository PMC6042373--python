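"""Population-differentiation metrics.

Implements the unbiased moment estimator of Wright's fixation index F_ST from
per-subpopulation allele frequencies and sample sizes, the dispersion score
(DS) summarizing spread of allele frequencies around their unweighted mean,
categorical differentiation calls, and per-population allele-frequency
preference flags.

Estimator
---------
For s subpopulations with observed alternate-allele frequencies p_1..p_s and
sample sizes n_1..n_s (allele copies),

    MSG = [ sum_i n_i p_i (1 - p_i) ] / (sum_i n_i - 1)
    MSP = [ sum_i n_i (p_i - p_w)^2 ] / (s - 1),   p_w = sum_i n_i p_i / sum_i n_i
    n_c = [ sum_i n_i - (sum_i n_i^2) / (sum_i n_i) ] / (s - 1)
    F_ST = (MSP - MSG) / (MSP + (n_c - 1) MSG)

MSG is the within-population mean square, MSP the between-population mean
square, and n_c a variance-corrected average sample size.  The MSG
denominator above is the form this implementation defaults to; the classical
moment-estimator denominator sum_i (n_i - 1) is available via
``msg_denominator="classical"``.  At a monomorphic locus the denominator of
F_ST vanishes and the estimate is flagged undefined.

The dispersion score is

    DS = sqrt( sum_i (p_i - p_u)^2 / n ),   p_u = sum_i p_i / s,  n = sum_i n_i.

Note the denominator is the *total sample size* n, not s: DS is defined
operationally, not as a textbook standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationFrequencyTable",
    "FstComponents",
    "fst_unbiased",
    "dispersion_score",
    "fst_category",
    "population_preference",
]

# F_ST interpretation thresholds: <= LITTLE_MAX little differentiation,
# > LARGE_MIN high differentiation, moderate in between (closed upper bound).
LITTLE_MAX = 0.05
LARGE_MIN = 0.25


@dataclass
class PopulationFrequencyTable:
    """Per-locus subpopulation allele frequencies and sample sizes.

    ``n`` counts sampled allele copies (haploid counts).
    """

    populations: Sequence[str]
    p: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        s = len(self.populations)
        if not (len(self.p) == len(self.n) == s):
            raise ValueError("populations, p and n must have equal length")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any(self.n < 1):
            raise ValueError("sample sizes must be >= 1")

    @property
    def s(self) -> int:
        return len(self.populations)

    @property
    def n_tot(self) -> float:
        return float(self.n.sum())

    @property
    def n_bar(self) -> float:
        """Plain average sample size (stored for completeness; the estimator
        uses the variance-corrected n_c instead)."""
        return self.n_tot / self.s


@dataclass
class FstComponents:
    """Intermediate quantities and the F_ST estimate for one locus."""

    msg: float
    msp: float
    n_c: float
    fst: float  # NaN when undefined (monomorphic locus)
    p_w: float  # weighted mean frequency
    p_u: float  # unweighted mean frequency
    defined: bool = field(default=True)


def fst_unbiased(
    t: PopulationFrequencyTable, msg_denominator: str = "printed"
) -> FstComponents:
    """Unbiased F_ST estimate with its MSG/MSP/n_c components.

    ``msg_denominator``: ``"printed"`` uses sum(n_i) - 1; ``"classical"``
    uses sum(n_i - 1) = sum(n_i) - s, the standard moment-estimator form.
    Raises for fewer than two populations.  A monomorphic locus (zero
    denominator) yields ``fst = nan`` with ``defined = False``.
    """
    if t.s < 2:
        raise ValueError("F_ST requires at least two populations")
    n, p = t.n, t.p
    n_sum = n.sum()
    if n_sum <= 1:
        raise ValueError("total sample size must exceed 1")
    if msg_denominator == "printed":
        msg_den = n_sum - 1.0
    elif msg_denominator == "classical":
        msg_den = n_sum - t.s
    else:
        raise ValueError(f"unknown msg_denominator {msg_denominator!r}")
    if msg_den <= 0:
        raise ValueError("MSG denominator is non-positive for these sample sizes")

    msg = float(np.sum(n * p * (1.0 - p)) / msg_den)
    p_w = float(np.sum(n * p) / n_sum)
    msp = float(np.sum(n * (p - p_w) ** 2) / (t.s - 1))
    n_c = float((n_sum - np.sum(n**2) / n_sum) / (t.s - 1))
    p_u = float(np.mean(p))

    denom = msp + (n_c - 1.0) * msg
    if denom == 0.0:
        return FstComponents(msg, msp, n_c, math.nan, p_w, p_u, defined=False)
    return FstComponents(msg, msp, n_c, (msp - msg) / denom, p_w, p_u, defined=True)


def dispersion_score(t: PopulationFrequencyTable) -> float:
    """DS = sqrt( sum_i (p_i - mean(p))^2 / total sample size ).

    Zero iff all subpopulation frequencies are equal.
    """
    if t.s < 2:
        raise ValueError("dispersion score requires at least two populations")
    p_u = np.mean(t.p)
    return float(np.sqrt(np.sum((t.p - p_u) ** 2) / t.n_tot))


def fst_category(fst: float) -> str:
    """Differentiation category: little (<= 0.05), moderate (<= 0.25), large.

    Both boundaries are closed on the lower category.  Undefined (NaN)
    estimates must be resolved by the caller first.
    """
    if math.isnan(fst):
        raise ValueError(
            "F_ST is undefined (monomorphic locus); handle undefined loci before categorizing"
        )
    if fst <= LITTLE_MAX:
        return "little"
    if fst <= LARGE_MIN:
        return "moderate"
    return "large"


def population_preference(
    t: PopulationFrequencyTable, margin: float = 0.10
) -> list[str]:
    """Per-population flags: ``higher`` if that population's frequency exceeds
    every other population's by at least ``margin``; ``lower`` symmetric;
    ``none`` otherwise.  At most one population can be higher and one lower.
    """
    if t.s < 2:
        raise ValueError("population preference requires at least two populations")
    if not (0.0 < margin < 1.0):
        raise ValueError("margin must lie in (0, 1)")
    p = t.p
    flags = []
    for i in range(t.s):
        others = np.delete(p, i)
        if np.all(p[i] >= others + margin):
            flags.append("higher")
        elif np.all(p[i] <= others - margin):
            flags.append("lower")
        else:
            flags.append("none")
    return flags
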