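"""Genomic relationship and molecular-diversity statistics.

Implements the VanRaden genomic relationship matrix

    G = M̆ M̆' / (2 Σ_j p_j (1 - p_j)),      M̆ = M - 2P,

where M is the complete dosage matrix and P repeats the alternate-allele
frequency p_j in column j, together with the Modified Roger's genetic
distance, expected heterozygosity and allele coverage used to judge core
collections.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "DistanceMatrix",
    "vanraden_g",
    "modified_rogers",
    "expected_heterozygosity",
    "allele_coverage",
]


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric V x V genomic relationship matrix with aligned ids."""

    G: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G must be square")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        if len(self.individual_ids) != self.G.shape[0]:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.individual_ids, columns=self.individual_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric V x V genetic distance matrix, entries in [0, 1]."""

    D: np.ndarray
    individual_ids: list[str]
    measure: str = "modified_rogers"

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise ValueError("distance diagonal must be zero")
        if np.any(self.D < -1e-12) or np.any(self.D > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.D.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.individual_ids, columns=self.individual_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def vanraden_g(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    Allele frequencies are the observed frequencies of the analyzed matrix.
    Raises if every locus is monomorphic (zero scaling denominator); filter
    on minor allele frequency beforehand rather than silently dropping loci.
    """
    g._require_complete()
    p = g.alt_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all loci monomorphic: VanRaden denominator is zero")
    m = g.dosage - 2.0 * p
    return KinshipMatrix(m @ m.T / denom, list(g.individual_ids))


def modified_rogers(g: GenotypeMatrix) -> DistanceMatrix:
    """Modified Roger's distance between all pairs of individuals.

    For individual v, the within-individual frequency of the alternate
    allele at a diploid biallelic locus is dosage/2 (so 0, 0.5 or 1), and

        MR(v, v') = sqrt( (1 / 2J) Σ_j Σ_a (p_vja - p_v'ja)^2 ).

    With two alleles per locus the inner sum is twice the squared dosage/2
    difference, which makes MR a scaled Euclidean distance: identical
    individuals sit at 0 and opposite homozygotes at every locus at 1.
    """
    g._require_complete()
    half = g.dosage / 2.0
    # per-locus sum over the two alleles = 2 * (d/2 - d'/2)^2
    sq = pdist(half, metric="sqeuclidean") * 2.0
    d = np.sqrt(sq / (2.0 * g.n_loci))
    return DistanceMatrix(squareform(np.minimum(d, 1.0)), list(g.individual_ids))


def _subset_freq(g: GenotypeMatrix, subset: Sequence[int] | None) -> np.ndarray:
    if subset is None:
        sub = g
    else:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("subset must be non-empty")
        sub = g.take_individuals(subset)
    sub._require_complete()
    return sub.alt_freq


def expected_heterozygosity(g: GenotypeMatrix, subset: Sequence[int] | None = None) -> float:
    """Expected heterozygosity HE = mean_j (1 - Σ_a p_ja²) over a subset.

    Allele frequencies are computed within the subset; for biallelic loci
    this is the mean of 2 p_j (1 - p_j).
    """
    p = _subset_freq(g, subset)
    return float(np.mean(2.0 * p * (1.0 - p)))


def allele_coverage(
    g: GenotypeMatrix,
    core: Sequence[int],
    literal_complement: bool = False,
) -> float:
    """Percentage of the population's alleles retained by a core subset.

    An allele counts as present in a set when at least one copy occurs
    there.  Returns 100 * |alleles(core)| / |alleles(population)|, so a
    core carrying every population allele scores 100.  With
    ``literal_complement=True`` the complement (1 - core/pop) * 100 is
    returned instead, i.e. the percentage of alleles lost.
    """
    core = np.asarray(core)
    if core.size == 0:
        raise ValueError("core must be non-empty")
    g._require_complete()

    def allele_count(rows: np.ndarray) -> int:
        d = g.dosage[rows]
        has_alt = (d > 0).any(axis=0)
        has_ref = (d < 2).any(axis=0)
        return int(has_alt.sum() + has_ref.sum())

    pop = allele_count(np.arange(g.n_individuals))
    cov = 100.0 * allele_count(core) / pop
    return 100.0 - cov if literal_complement else cov
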