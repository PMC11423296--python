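"""Synthetic genotype and phenotype panels for wild perennial populations.

The generator emulates the structure of a genotyping-by-sequencing (GBS)
panel of wild palms sampled from a few nearby locations: ~200 individuals
in 3 spatial groups, ~10,000 biallelic SNPs with GBS-like missingness,
two years of records for three yield traits with narrow-sense
heritabilities in the 0.6-0.85 range.

Population structure follows the Balding-Nichols model: ancestral allele
frequencies are uniform on [maf_floor, 1 - maf_floor]; each group draws
its own frequency from Beta(p(1-f)/f, (1-p)(1-f)/f), where f is a drift
(F_ST-like) parameter, and dosages are Binomial(2, group frequency).  The
default drift is small because the emulated population lacks distinct
structure.  Phenotypes follow a fixed-year-effect model: one record per
individual and year, value = year effect + breeding value + iid residual,
with the residual variance solved so that the record-level heritability
matches the target.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: trait -> target narrow-sense heritability; values sit in the range
#: reported for fruit dry mass, oil content and pulp dry mass panels.
DEFAULT_TRAITS: dict[str, float] = {"FDM": 0.75, "OC": 0.80, "PDM": 0.70}


def _default_group_sizes(n: int, n_groups: int) -> tuple[int, ...]:
    """Scale the 66/24/55 location split to ``n`` individuals."""
    base = (66, 24, 55)[:n_groups] if n_groups <= 3 else (1,) * n_groups
    w = np.asarray(base, dtype=float)
    sizes = np.floor(w / w.sum() * n).astype(int)
    sizes[-1] += n - sizes.sum()
    return tuple(int(s) for s in sizes)


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic panel.

    ``h2_target`` maps trait name to record-level narrow-sense
    heritability; ``fst`` is the Balding-Nichols drift parameter in (0,1);
    ``missing_locus_rate`` / ``missing_indiv_rate`` are the marginal
    missingness intensities applied per locus and per individual.
    """

    n_individuals: int = 201
    n_loci: int = 10444
    n_groups: int = 3
    group_sizes: tuple[int, ...] | None = None
    fst: float = 0.05
    maf_floor: float = 0.05
    n_qtl: int | None = None
    h2_target: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )
    n_years: int = 2
    year_effect_sd: float = 0.5
    missing_locus_rate: float = 0.08
    missing_indiv_rate: float = 0.04
    effect_distribution: str = "gaussian"
    founders_frac: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly in (0, 1)")
        for trait, h2 in self.h2_target.items():
            if not 0.0 < h2 < 1.0:
                raise ValueError(f"h2_target[{trait!r}] must lie strictly in (0, 1)")
        if self.n_qtl is None:
            self.n_qtl = min(300, self.n_loci)
        if self.n_qtl > self.n_loci:
            raise ValueError("n_qtl cannot exceed n_loci")
        if self.effect_distribution not in ("gaussian", "sparse_large"):
            raise ValueError(f"unknown effect_distribution: {self.effect_distribution!r}")
        if self.founders_frac is not None and not 0.0 < self.founders_frac <= 1.0:
            raise ValueError("founders_frac must lie in (0, 1]")
        if self.group_sizes is None:
            self.group_sizes = _default_group_sizes(self.n_individuals, self.n_groups)
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes length must equal n_groups")
        if sum(self.group_sizes) != self.n_individuals:
            raise ValueError("group_sizes must sum to n_individuals")

    def group_labels(self) -> np.ndarray:
        """Per-individual group label (1-based), in panel order."""
        return np.repeat(np.arange(1, self.n_groups + 1), self.group_sizes)


@dataclasses.dataclass
class SimulatedDataset:
    """A simulated panel: genotypes, true genetic values and phenotypes."""

    genotypes: GenotypeMatrix
    groups: np.ndarray
    true_breeding_values: pd.DataFrame  # individuals x traits
    qtl_indices: dict[str, np.ndarray]
    qtl_effects: dict[str, np.ndarray]
    phenotypes: pd.DataFrame  # columns: individual, group, year, trait, value
    realized_h2: dict[str, float]


def simulate_genotypes(
    config: SimulationConfig, *, complete: bool = False
) -> GenotypeMatrix:
    """Draw a structured dosage panel under the Balding-Nichols model.

    With ``complete=True`` no missingness is injected (the configuration's
    missingness intensities are ignored); otherwise entries are masked
    missing by the union of a per-locus and a per-individual Bernoulli
    process.  Deterministic for a fixed ``config.seed``.

    When ``founders_frac`` is set, each group's individuals are drawn as
    offspring of random pairs from a founder pool of that fraction of the
    group size, instead of independent Binomial(2, p_group) draws.  This
    overlays family clusters (half/full sibs) on the group structure,
    emulating wild stands where most genotypes are closely related —
    e.g. palms recruited from the seed rain of a few mother trees.
    """
    rng = np.random.default_rng(config.seed)
    p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=config.n_loci)
    f = config.fst
    a, b = p_anc * (1.0 - f) / f, (1.0 - p_anc) * (1.0 - f) / f
    dosage = np.empty((config.n_individuals, config.n_loci), dtype=np.int8)
    row = 0
    for size in config.group_sizes:
        p_group = np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)
        if config.founders_frac is None:
            dosage[row : row + size] = rng.binomial(2, p_group, size=(size, config.n_loci))
        else:
            n_f = max(2, int(round(size * config.founders_frac)))
            founders = rng.binomial(2, p_group, size=(n_f, config.n_loci))
            for i in range(size):
                pa, pb = rng.choice(n_f, size=2, replace=False)
                gamete_a = rng.random(config.n_loci) < founders[pa] / 2.0
                gamete_b = rng.random(config.n_loci) < founders[pb] / 2.0
                dosage[row + i] = gamete_a.astype(np.int8) + gamete_b.astype(np.int8)
        row += size
    if complete:
        missing = np.zeros(dosage.shape, dtype=bool)
    else:
        by_locus = rng.random(dosage.shape) < rng.uniform(
            0.0, 2.0 * config.missing_locus_rate, size=config.n_loci
        )
        by_indiv = (
            rng.random(dosage.shape)
            < rng.uniform(0.0, 2.0 * config.missing_indiv_rate, size=config.n_individuals)[:, None]
        )
        missing = by_locus | by_indiv
        # keep at least one observed call per locus
        all_gone = missing.all(axis=0)
        if all_gone.any():
            missing[0, all_gone] = False
    ids = [f"ind{v + 1:03d}" for v in range(config.n_individuals)]
    loci = [f"snp{j + 1:05d}" for j in range(config.n_loci)]
    return GenotypeMatrix(dosage, missing, ids, loci)


def _draw_effects(rng: np.random.Generator, n: int, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return rng.normal(0.0, 1.0, size=n)
    # sparse_large: few loci, each with an effect bounded away from zero
    return rng.choice([-1.0, 1.0], size=n) * (0.5 + np.abs(rng.normal(0.0, 1.0, size=n)))


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> SimulatedDataset:
    """Simulate multi-year trait records on top of a complete genotype panel.

    Breeding values are sums of centered QTL dosages times effects; the
    residual standard deviation is solved per trait so that
    Var(g) / (Var(g) + Var(eps)) equals the target heritability at the
    record level.  Year effects are fixed draws shared by all individuals.
    """
    if not genotypes.is_complete:
        raise ValueError("phenotype simulation needs a complete (imputed) genotype panel")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    centered = genotypes.centered()
    groups = (
        config.group_labels()
        if genotypes.n_individuals == config.n_individuals
        else np.ones(genotypes.n_individuals, dtype=int)
    )
    records = []
    tbv = {}
    qtl_idx: dict[str, np.ndarray] = {}
    qtl_eff: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    years = np.arange(1, config.n_years + 1)
    for trait, h2 in config.h2_target.items():
        idx = np.sort(rng.choice(genotypes.n_loci, size=config.n_qtl, replace=False))
        eff = _draw_effects(rng, config.n_qtl, config.effect_distribution)
        g = centered[:, idx] @ eff
        var_g = float(np.var(g))
        if var_g <= 0:
            raise ValueError("degenerate genetic variance; increase n_qtl or diversity")
        sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
        year_eff = rng.normal(0.0, config.year_effect_sd, size=config.n_years)
        eps = rng.normal(0.0, sd_e, size=(genotypes.n_individuals, config.n_years))
        realized[trait] = var_g / (var_g + float(np.var(eps)))
        qtl_idx[trait], qtl_eff[trait], tbv[trait] = idx, eff, g
        for m, year in enumerate(years):
            records.append(
                pd.DataFrame(
                    {
                        "individual": genotypes.individual_ids,
                        "group": groups,
                        "year": year,
                        "trait": trait,
                        "value": year_eff[m] + g + eps[:, m],
                    }
                )
            )
    return SimulatedDataset(
        genotypes=genotypes,
        groups=groups,
        true_breeding_values=pd.DataFrame(tbv, index=genotypes.individual_ids),
        qtl_indices=qtl_idx,
        qtl_effects=qtl_eff,
        phenotypes=pd.concat(records, ignore_index=True),
        realized_h2=realized,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full panel: phenotypes simulated from the complete genotypes, then
    GBS-like missingness injected into the delivered genotype matrix."""
    complete = simulate_genotypes(config, complete=True)
    ds = simulate_phenotypes(complete, config)
    with_missing = simulate_genotypes(config)  # same seed: same underlying dosages
    ds.genotypes = with_missing
    return ds


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)
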