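"""Genotype matrices: I/O, quality filtering, imputation and PC scores.

The central container is :class:`GenotypeMatrix`, an individuals x loci
dosage matrix (counts of the alternate allele, 0/1/2) with an explicit
missingness mask.  All downstream machinery (kinship, prediction models,
training-set criteria) consumes imputed instances of this container.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ScoreMatrix",
    "read_genotypes",
    "write_genotypes",
    "filter_genotypes",
    "impute_missing",
    "pc_scores",
]


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with missing-data mask.

    Parameters
    ----------
    dosage
        ``(V, J)`` array of alternate-allele counts.  Entries at masked
        positions are ignored (kept as 0 internally).
    missing
        ``(V, J)`` boolean array; ``True`` marks a missing call.
    individual_ids, locus_ids
        Row and column labels, preserved in file order.
    """

    dosage: np.ndarray
    missing: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.missing is None:
            self.missing = np.zeros(self.dosage.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.dosage.shape != self.missing.shape:
            raise ValueError("dosage and missing mask shapes differ")
        obs = self.dosage[~self.missing]
        if obs.size and (np.any(obs < 0) or np.any(obs > 2)):
            raise ValueError("observed dosages must lie in {0, 1, 2}")
        if len(self.individual_ids) != self.dosage.shape[0]:
            raise ValueError("individual_ids length mismatch")
        if len(self.locus_ids) != self.dosage.shape[1]:
            raise ValueError("locus_ids length mismatch")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_complete(self) -> bool:
        return not bool(self.missing.any())

    @property
    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        obs = (~self.missing).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.missing, 0, self.dosage).sum(axis=0) / (2.0 * obs)
        return np.where(obs > 0, p, np.nan)

    @property
    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    def locus_missing_rate(self) -> np.ndarray:
        return self.missing.mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return self.missing.mean(axis=1)

    def centered(self) -> np.ndarray:
        """Dosages centered by twice the allele frequency (complete matrices)."""
        self._require_complete()
        return self.dosage - 2.0 * self.alt_freq

    def _require_complete(self) -> None:
        if not self.is_complete:
            raise ValueError("operation requires an imputed (complete) matrix")

    def take_individuals(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[idx],
            self.missing[idx],
            [self.individual_ids[i] for i in idx],
            list(self.locus_ids),
        )

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.missing[:, idx],
            list(self.individual_ids),
            [self.locus_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosage.astype(float), index=self.individual_ids, columns=self.locus_ids
        )
        return df.mask(pd.DataFrame(self.missing, index=df.index, columns=df.columns))


@dataclasses.dataclass
class ScoreMatrix:
    """Principal-component scores of the centered dosage matrix.

    ``scores`` is ``(V, K)`` with ``scores = U @ diag(s)`` from the thin SVD
    of the column-centered dosages; columns are orthogonal with non-increasing
    variance.  This is the score matrix S consumed by the D-optimality, PEV
    and r-score training-set criteria.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    individual_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (diploid GT) or a dosage table.

    ``format="vcf"`` expects biallelic diploid records; the dosage is the
    number of alternate alleles in GT and ``./.`` is missing.
    ``format="matrix"`` expects a tab-delimited table, rows = individuals,
    header = locus ids, ``NA`` for missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    dosages: list[np.ndarray] = []
    mask: list[np.ndarray] = []
    loci: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {rec.CHROM}:{rec.POS}; filter to biallelic first"
            )
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([g[:-1] for g in rec.genotypes], dtype=float)
        if alleles.shape[1] != 2:
            raise ValueError(f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
        miss = np.any(alleles < 0, axis=1)
        dose = np.where(miss, 0, np.clip(alleles, 0, None).sum(axis=1))
        dosages.append(dose)
        mask.append(miss)
        name = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        loci.append(name)
        del gts
    vcf.close()
    if not loci:
        raise ValueError(f"no variant records in {path}")
    dosage = np.vstack(dosages).T.astype(np.int8)
    missing = np.vstack(mask).T
    return GenotypeMatrix(dosage, missing, ids, loci)


def _read_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    missing = df.isna().to_numpy()
    dosage = df.fillna(0).to_numpy().astype(np.int8)
    return GenotypeMatrix(dosage, missing, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    """Write as a minimal VCF v4.2 (GT only, ``./.`` missing) or dosage table."""
    path = Path(path)
    if format == "matrix":
        df = g.to_frame()
        df.to_csv(path, sep="\t", na_rep="NA")
        return
    if format != "vcf":
        raise ValueError(f"unknown genotype format: {format!r}")
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            calls = [
                "./." if g.missing[v, j] else gt_code[int(g.dosage[v, j])]
                for v in range(g.n_individuals)
            ]
            fh.write(f"1\t{j + 1}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


# ----------------------------------------------------------------------
# Filtering and imputation
# ----------------------------------------------------------------------

def filter_genotypes(
    g: GenotypeMatrix,
    max_alleles: int = 2,
    min_maf: float = 0.01,
    max_locus_missing: float = 0.30,
    max_indiv_missing: float = 0.45,
    log: list[str] | None = None,
) -> GenotypeMatrix:
    """Apply GBS-style quality filters: loci first, then individuals.

    Loci failing the minor-allele-frequency floor or the per-locus
    missingness ceiling are dropped, then individuals exceeding the
    per-individual missingness ceiling (recomputed on the surviving loci)
    are dropped.  Allele frequencies are recomputed after filtering.  The
    order of application is appended to ``log`` when provided.
    """
    # max_alleles is structural for this container: >2 alleles cannot be
    # represented, so the argument only documents the contract.
    if max_alleles != 2:
        raise ValueError("only biallelic matrices are representable")
    maf = g.minor_allele_freq
    locus_ok = (np.nan_to_num(maf) >= min_maf) & (g.locus_missing_rate() <= max_locus_missing)
    if log is not None:
        log.append(
            f"locus filter: kept {int(locus_ok.sum())}/{g.n_loci} "
            f"(min_maf={min_maf}, max_locus_missing={max_locus_missing})"
        )
    if not locus_ok.any():
        raise ValueError("no loci survive filtering")
    out = g.take_loci(np.flatnonzero(locus_ok))
    indiv_ok = out.individual_missing_rate() <= max_indiv_missing
    if log is not None:
        log.append(
            f"individual filter: kept {int(indiv_ok.sum())}/{out.n_individuals} "
            f"(max_indiv_missing={max_indiv_missing})"
        )
    if not indiv_ok.any():
        raise ValueError("no individuals survive filtering")
    return out.take_individuals(np.flatnonzero(indiv_ok))


def impute_missing(g: GenotypeMatrix, method: str = "mean_round") -> GenotypeMatrix:
    """Fill missing dosages with a deterministic single-pass rule.

    ``"mean_round"`` replaces a missing call with ``2 p_j`` rounded
    half-up to the nearest integer in {0,1,2}; ``"mode"`` uses the most
    frequent observed dosage at the locus (lowest dosage wins ties).
    """
    if g.is_complete:
        return GenotypeMatrix(
            g.dosage.copy(), None, list(g.individual_ids), list(g.locus_ids)
        )
    n_obs = (~g.missing).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [g.locus_ids[j] for j in np.flatnonzero(n_obs == 0)[:5]]
        raise ValueError(f"all-missing loci (e.g. {bad}); filter loci before imputing")
    if method == "mean_round":
        # round-half-up, so 2p = 1.5 imputes to 2
        fill = np.floor(2.0 * g.alt_freq + 0.5).astype(g.dosage.dtype)
    elif method == "mode":
        counts = np.stack(
            [((g.dosage == d) & ~g.missing).sum(axis=0) for d in (0, 1, 2)]
        )
        fill = counts.argmax(axis=0).astype(g.dosage.dtype)
    else:
        raise ValueError(f"unknown imputation method: {method!r}")
    dosage = np.where(g.missing, fill[np.newaxis, :], g.dosage)
    return GenotypeMatrix(dosage, None, list(g.individual_ids), list(g.locus_ids))


# ----------------------------------------------------------------------
# PC scores
# ----------------------------------------------------------------------

def pc_scores(
    g: GenotypeMatrix,
    n_components: int | None = None,
    explained_variance_target: float = 0.95,
) -> ScoreMatrix:
    """Principal-component scores of the column-centered dosage matrix.

    When ``n_components`` is ``None`` the number of components retained is
    the smallest K whose cumulative explained variance reaches
    ``explained_variance_target``, capped at V-1.
    """
    g._require_complete()
    x = g.dosage - g.dosage.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    # strip numerically-null directions (column-centering kills one)
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size else 0
    u, s = u[:, :rank], s[:rank]
    var = s**2 / max(g.n_individuals - 1, 1)
    if n_components is None:
        cum = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(cum, explained_variance_target) + 1)
        k = min(k, g.n_individuals - 1, rank)
    else:
        k = int(n_components)
        if k > rank:
            warnings.warn(
                f"n_components={k} exceeds rank {rank}; truncating", stacklevel=2
            )
            k = rank
    return ScoreMatrix(u[:, :k] * s[:k], var[:k], list(g.individual_ids))
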