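"""Genetic maps, recombination arithmetic and conditional QTL-genotype probabilities.

Distances are in centiMorgans (cM), recombination fractions are gamete-level
probabilities under the Haldane (no-interference) mapping function.  Recombinant
inbred lines (RIL) accumulate recombination over repeated selfing; the effective
fraction between two loci is R = 2r/(1+2r), which is what makes a RIL genome
"longer" than the same DH genome for threshold purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "haldane_r",
    "inverse_haldane",
    "ril_accumulated_R",
    "PopulationType",
    "DH",
    "BC1",
    "RIL",
    "GeneticMap",
    "IntervalProbabilities",
    "interval_probabilities",
]


def haldane_r(d):
    """Map distance (cM) -> recombination fraction, Haldane: r = (1 - e^(-2d/100))/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative (cM)")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return float(r) if r.ndim == 0 else r


def inverse_haldane(r):
    """Recombination fraction -> map distance (cM): d = -50 ln(1 - 2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def ril_accumulated_R(r):
    """One-meiosis fraction r -> accumulated fraction after repeated selfing, R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


@dataclass(frozen=True)
class PopulationType:
    """Biparental population with two genotype classes per locus.

    ``df_per_env`` is the chi-square degrees of freedom contributed per
    environment by the overall QEI test (one mean difference per environment);
    ``genome_expansion`` multiplies the genome length in the effective-test
    count (1.9 for RIL because accumulated recombination roughly doubles
    short map distances).
    """

    kind: str
    df_per_env: int = 1
    genome_expansion: float = 1.0

    def __post_init__(self):
        if self.kind not in ("DH", "BC1", "RIL"):
            raise ValueError(f"unsupported population type: {self.kind!r}")

    @property
    def is_ril(self) -> bool:
        return self.kind == "RIL"

    def effective_fraction(self, r):
        """Population-level recombination fraction for a gamete-level r."""
        return ril_accumulated_R(r) if self.is_ril else r

    @classmethod
    def from_string(cls, kind: str) -> "PopulationType":
        kind = kind.upper()
        if kind == "RIL":
            return RIL
        if kind == "BC1":
            return BC1
        if kind == "DH":
            return DH
        raise ValueError(f"unsupported population type: {kind!r}")


DH = PopulationType("DH")
BC1 = PopulationType("BC1")
RIL = PopulationType("RIL", genome_expansion=1.9)


class GeneticMap:
    """Ordered marker positions per chromosome; the coordinate system for scans.

    Positions must be strictly increasing within a chromosome and marker names
    unique genome-wide.  Chromosomes keep their order of first appearance.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chromosome", "position_cM"}
        if not required.issubset(table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        table = table[["marker", "chromosome", "position_cM"]].copy()
        table["marker"] = table["marker"].astype(str)
        table["chromosome"] = table["chromosome"].astype(str)
        table["position_cM"] = table["position_cM"].astype(float)
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicated marker name: {dup!r}")
        for chrom, sub in table.groupby("chromosome", sort=False):
            pos = sub["position_cM"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions must be strictly increasing on chromosome {chrom}"
                )
        self.table = table.reset_index(drop=True)
        self.chromosomes: list[str] = list(dict.fromkeys(table["chromosome"]))
        self._by_chrom = {
            chrom: sub.reset_index(drop=True)
            for chrom, sub in self.table.groupby("chromosome", sort=False)
        }
        # global column index of each chromosome's first marker
        self._offsets = {}
        off = 0
        for chrom in self.chromosomes:
            self._offsets[chrom] = off
            off += len(self._by_chrom[chrom])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_names(self) -> list[str]:
        return list(self.table["marker"])

    def positions(self, chromosome: str) -> np.ndarray:
        return self._by_chrom[str(chromosome)]["position_cM"].to_numpy()

    def markers(self, chromosome: str) -> list[str]:
        return list(self._by_chrom[str(chromosome)]["marker"])

    def offset(self, chromosome: str) -> int:
        """Global column index of the chromosome's first marker."""
        return self._offsets[str(chromosome)]

    def chromosome_length(self, chromosome: str) -> float:
        pos = self.positions(chromosome)
        return float(pos[-1] - pos[0])

    @property
    def total_length(self) -> float:
        return float(sum(self.chromosome_length(c) for c in self.chromosomes))

    def contains(self, chromosome: str, position: float) -> bool:
        if str(chromosome) not in self._by_chrom:
            return False
        pos = self.positions(chromosome)
        return bool(pos[0] <= position <= pos[-1])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneticMap({len(self.chromosomes)} chromosomes, "
            f"{self.n_markers} markers, {self.total_length:.1f} cM)"
        )


#: flanking-marker group order: (x_left, x_right) = (+,+), (+,-), (-,+), (-,-)
GROUP_ORDER = ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class IntervalProbabilities:
    """Conditional QTL-genotype probabilities at a testing position in an interval.

    ``pi[l, k]`` = P(QTL genotype k | flanking-marker group l), groups ordered
    (P1/P1, P1/P2, P2/P1, P2/P2), genotypes ordered (QQ, qq).  ``lam`` and
    ``rho`` are the coefficients of the conditional expectation
    E(g | x_left, x_right) = lam*x_left + rho*x_right.  For RIL the stored
    fractions are the accumulated (R) values actually used to build ``pi``.
    """

    r1: float
    r2: float
    r: float
    pi: np.ndarray = field(repr=False)
    lam: float = 0.0
    rho: float = 0.0


def interval_probabilities(
    d_left: float, d_right: float, population: PopulationType = DH
) -> IntervalProbabilities:
    """Probabilities of the two QTL genotypes within the four flanking-marker groups.

    ``d_left``/``d_right`` are the map distances (cM) from the testing position
    to the left and right flanking markers.  The flanking-pair fraction is
    composed from r1, r2 by the no-interference identity r = r1 + r2 - 2 r1 r2;
    for RIL each fraction is then mapped through the accumulated-recombination
    transform before entering the group formulas.
    """
    if d_left < 0 or d_right < 0:
        raise ValueError("testing position lies outside the interval")
    r1 = haldane_r(d_left)
    r2 = haldane_r(d_right)
    if population.is_ril:
        r1, r2 = ril_accumulated_R(r1), ril_accumulated_R(r2)
    # flanking fraction composed from the per-side fractions (accumulated for
    # RIL) by the no-interference identity, matching the Markov chain the
    # simulator uses and keeping every pi row normalized
    r = r1 + r2 - 2.0 * r1 * r2

    pi = np.empty((4, 2))
    if r == 0.0:
        # zero-length interval: the position coincides with both markers
        pi[:] = [[1, 0], [1, 0], [0, 1], [0, 1]]
        lam, rho = 0.5, 0.5
    else:
        p11 = (1 - r1) * (1 - r2) / (1 - r)
        p12 = r1 * r2 / (1 - r)
        p21 = (1 - r1) * r2 / r
        p22 = r1 * (1 - r2) / r
        pi[0] = (p11, p12)
        pi[1] = (p21, p22)
        pi[2] = (p22, p21)  # mirror of group 2
        pi[3] = (p12, p11)  # mirror of group 1
        e_pp = (1 - r1 - r2) / (1 - r)  # E(g | +,+)
        e_pm = (r2 - r1) / r            # E(g | +,-)
        lam = 0.5 * (e_pp + e_pm)
        rho = 0.5 * (e_pp - e_pm)
    return IntervalProbabilities(r1=float(r1), r2=float(r2), r=float(r), pi=pi,
                                 lam=float(lam), rho=float(rho))


def group_index(x_left: np.ndarray, x_right: np.ndarray) -> np.ndarray:
    """Flanking-marker group label (0..3) in GROUP_ORDER for coded genotypes +/-1."""
    return ((x_left < 0).astype(int) << 1) | (x_right < 0).astype(int)
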