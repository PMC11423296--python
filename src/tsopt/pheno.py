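"""Adjusted genotype means from multi-year records.

Raw records (one per individual, year and trait, with no experimental
design) are reduced to one adjusted mean per genotype by ordinary least
squares on the two-way fixed-effects model

    y = 1 mu + X_year a + X_geno g + eps,

reported as least-squares means at the average year, which makes the
result invariant to the identifiability constraint placed on the year
effects.  These means are the response used to train the prediction
models.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["AdjustedMeans", "adjusted_means"]

REQUIRED_COLUMNS = ("individual", "year", "trait", "value")


@dataclasses.dataclass
class AdjustedMeans:
    """Per-genotype adjusted means for one trait.

    ``single_year`` flags genotypes observed in only one year (their mean
    is still estimable under additive year effects, but rests on them).
    """

    trait: str
    individual_ids: list[str]
    values: np.ndarray
    n_records: np.ndarray
    single_year: np.ndarray
    sigma2_eps: float

    def __len__(self) -> int:
        return len(self.individual_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "trait": self.trait,
                "adjusted_mean": self.values,
                "n_records": self.n_records,
            }
        )

    def align(self, ids: list[str]) -> np.ndarray:
        """Values reordered to match ``ids``; raises on unknown ids."""
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        return self.values[[pos[g] for g in ids]]


def adjusted_means(
    records: pd.DataFrame, trait: str, constraint: str = "sum_to_zero"
) -> AdjustedMeans:
    """Extract adjusted means for one trait from raw phenotype records.

    Parameters
    ----------
    records
        Long table with columns ``individual, year, trait, value`` (extra
        columns such as ``group`` are ignored).
    trait
        Trait name to extract.
    constraint
        Identifiability constraint on year effects: ``"sum_to_zero"`` or
        ``"reference"`` (first year as baseline).  The reported means are
        least-squares means at the average year and do not depend on this
        choice; the option exists to make that invariance checkable.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")
    sub = records.loc[records["trait"] == trait].dropna(subset=["value"])
    if len(sub) < 2:
        raise ValueError(f"need >= 2 records for trait {trait!r}")
    if sub.duplicated(["individual", "year"]).any():
        raise ValueError(f"duplicate (individual, year) records for trait {trait!r}")

    genos = list(pd.unique(sub["individual"]))
    years = np.sort(pd.unique(sub["year"]))
    g_idx = sub["individual"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    y_idx = sub["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
    n, V, M = len(sub), len(genos), len(years)

    _check_connectivity(g_idx, y_idx, M)

    # design: V genotype indicator columns (absorbing the intercept)
    # followed by M-1 year columns in the chosen coding
    X = np.zeros((n, V + M - 1))
    X[np.arange(n), g_idx] = 1.0
    if constraint == "sum_to_zero":
        for m in range(M - 1):
            X[:, V + m] = (y_idx == m).astype(float) - (y_idx == M - 1).astype(float)
        year_profile = np.zeros(M - 1)  # contrasts average to zero over years
    elif constraint == "reference":
        for m in range(1, M):
            X[:, V + m - 1] = (y_idx == m).astype(float)
        year_profile = np.full(M - 1, 1.0 / M)  # average of 0, e_2, ..., e_M
    else:
        raise ValueError(f"unknown constraint: {constraint!r}")

    beta, _, rank, _ = np.linalg.lstsq(X, sub["value"].to_numpy(), rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            "aliased fixed effects: year/genotype design is rank deficient "
            f"(rank {rank} < {X.shape[1]}); check design connectivity"
        )
    resid = sub["value"].to_numpy() - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else float("nan")

    means = beta[:V] + (year_profile @ beta[V:] if M > 1 else 0.0)
    n_rec = np.bincount(g_idx, minlength=V)
    n_years_per_geno = (
        pd.DataFrame({"g": g_idx, "y": y_idx}).groupby("g")["y"].nunique().reindex(range(V)).to_numpy()
    )
    return AdjustedMeans(
        trait=trait,
        individual_ids=[str(g) for g in genos],
        values=means,
        n_records=n_rec,
        single_year=n_years_per_geno == 1,
        sigma2_eps=sigma2,
    )


def _check_connectivity(g_idx: np.ndarray, y_idx: np.ndarray, n_years: int) -> None:
    """Warn when some year shares no genotype with the rest of the design."""
    if n_years <= 1:
        return
    seen = {0}
    grew = True
    genos_by_year = [set(g_idx[y_idx == m]) for m in range(n_years)]
    while grew:
        grew = False
        pool = set().union(*(genos_by_year[m] for m in seen))
        for m in range(n_years):
            if m not in seen and genos_by_year[m] & pool:
                seen.add(m)
                grew = True
    if len(seen) < n_years:
        warnings.warn(
            "disconnected year/genotype design: adjusted means are not "
            "comparable across all years",
            stacklevel=3,
        )
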