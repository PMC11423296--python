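"""Validation harness: cross-validation, leave-one-location-out real
validation, and random-training-set baselines.

Predictive prowess is summarized by the correlation between observed
adjusted means and genomic predictions, rho(ybar, yhat), and the mean
squared prediction error MSPE = mean((ybar - yhat)^2).  In repeated
k-fold cross-validation each fold is predicted from the remaining folds
and the per-fold outputs are assembled into a single vector before the
metrics are computed, once per repeat.  Real validation trains on all
but one spatial group and predicts the held-out group.  Random baselines
re-evaluate the same prediction machinery on many uniformly drawn
training sets of fixed size, the reference distribution against which an
optimized training set is judged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .models import (
    BayesBSettings,
    VarianceComponents,
    bayesb_fit,
    bayesb_predict,
    gblup_predict,
)

__all__ = [
    "FoldPlan",
    "ValidationReport",
    "make_folds",
    "cross_validate",
    "real_validate",
    "random_baseline",
    "evaluate_training_set",
    "rho_mspe",
]


@dataclasses.dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray  # (n_repeats, V) fold label per individual
    n_repeats: int
    seed: int

    def folds(self, repeat: int):
        for f in range(self.k):
            yield np.flatnonzero(self.assignments[repeat] == f)


@dataclasses.dataclass
class ValidationReport:
    """Long-format results: one row per (model, scenario, source, repeat)."""

    rows: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return (
            self.rows.groupby(["model", "scenario", "source"])[["rho", "mspe"]]
            .agg(["mean", "std"])
            .reset_index()
        )


def rho_mspe(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and mean squared prediction error.

    Returns ``(nan, mspe)`` when either vector is constant (the
    correlation is undefined there and reported as missing).
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    mspe = float(np.mean((observed - predicted) ** 2))
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return float("nan"), mspe
    return float(np.corrcoef(observed, predicted)[0, 1]), mspe


def make_folds(V: int, k: int, n_repeats: int = 1, seed: int = 0) -> FoldPlan:
    """Random balanced partition into k folds, re-shuffled per repeat.

    Fold sizes differ by at most one; 145 individuals at k = 5 gives five
    folds of exactly 29.
    """
    if k > V:
        raise ValueError("k cannot exceed the number of individuals")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, V, k + 1).astype(int)))
    assignments = np.vstack([rng.permutation(base) for _ in range(n_repeats)])
    return FoldPlan(k=k, assignments=assignments, n_repeats=n_repeats, seed=seed)


def _predict_split(
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model: str,
    K=None,
    M: GenotypeMatrix | None = None,
    vc: VarianceComponents | None = None,
    bayesb_settings: BayesBSettings | None = None,
) -> np.ndarray:
    if model == "gblup":
        if K is None:
            raise ValueError("GBLUP needs a kinship matrix")
        return gblup_predict(y[train_idx], K, train_idx, test_idx, vc=vc)
    if model == "bayesb":
        if M is None:
            raise ValueError("BayesB needs a marker matrix")
        X = M.dosage.astype(float) if isinstance(M, GenotypeMatrix) else np.asarray(M, float)
        fit = bayesb_fit(y[train_idx], X[train_idx], bayesb_settings)
        return bayesb_predict(fit, X[test_idx])
    raise ValueError(f"unknown model {model!r}")


def cross_validate(
    y,
    model: str,
    plan: FoldPlan,
    K=None,
    M: GenotypeMatrix | None = None,
    vc: VarianceComponents | None = None,
    bayesb_settings: BayesBSettings | None = None,
    scenario: str = "kfold",
) -> ValidationReport:
    """Repeated k-fold cross-validation.

    Per repeat, every fold is predicted from the remaining folds, the
    fold outputs are assembled into one V-length vector and rho/MSPE are
    computed on that vector.
    """
    yv = np.asarray(y.values if hasattr(y, "values") else y, float)
    rows = []
    for rep in range(plan.n_repeats):
        yhat = np.full(yv.size, np.nan)
        for test_idx in plan.folds(rep):
            train_idx = np.setdiff1d(np.arange(yv.size), test_idx)
            yhat[test_idx] = _predict_split(
                yv, train_idx, test_idx, model, K=K, M=M, vc=vc,
                bayesb_settings=bayesb_settings,
            )
        rho, mspe = rho_mspe(yv, yhat)
        rows.append(
            {"model": model, "scenario": scenario, "source": "full",
             "repeat": rep, "rho": rho, "mspe": mspe}
        )
    return ValidationReport(pd.DataFrame(rows))


def real_validate(
    y,
    model: str,
    groups,
    K=None,
    M: GenotypeMatrix | None = None,
    vc: VarianceComponents | None = None,
    bayesb_settings: BayesBSettings | None = None,
) -> ValidationReport:
    """Leave-one-location-out validation over spatial groups.

    Each group in turn is predicted from the complement; the report
    carries one row per held-out group.  Singleton groups yield an
    undefined correlation, reported as missing.
    """
    yv = np.asarray(y.values if hasattr(y, "values") else y, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("real validation needs at least 2 groups")
    rows = []
    for lab in labels:
        test_idx = np.flatnonzero(groups == lab)
        train_idx = np.flatnonzero(groups != lab)
        yhat = _predict_split(
            yv, train_idx, test_idx, model, K=K, M=M, vc=vc,
            bayesb_settings=bayesb_settings,
        )
        rho, mspe = rho_mspe(yv[test_idx], yhat)
        rows.append(
            {"model": model, "scenario": f"location:{lab}", "source": "full",
             "repeat": 0, "rho": rho, "mspe": mspe}
        )
    return ValidationReport(pd.DataFrame(rows))


def evaluate_training_set(
    y,
    train_idx,
    model: str = "gblup",
    test_idx=None,
    K=None,
    M: GenotypeMatrix | None = None,
    vc: VarianceComponents | None = None,
    bayesb_settings: BayesBSettings | None = None,
    source: str = "optimized",
    scenario: str = "untargeted",
) -> dict:
    """Score one training set: predict its test set and report rho/MSPE.

    In the untargeted scenario the test set defaults to the complement of
    the training set, matching the construction of the random baselines.
    """
    yv = np.asarray(y.values if hasattr(y, "values") else y, float)
    train_idx = np.asarray(train_idx)
    if test_idx is None:
        test_idx = np.setdiff1d(np.arange(yv.size), train_idx)
    else:
        test_idx = np.asarray(test_idx)
    yhat = _predict_split(
        yv, train_idx, test_idx, model, K=K, M=M, vc=vc,
        bayesb_settings=bayesb_settings,
    )
    rho, mspe = rho_mspe(yv[test_idx], yhat)
    return {"model": model, "scenario": scenario, "source": source,
            "repeat": 0, "rho": rho, "mspe": mspe}


def random_baseline(
    y,
    model: str,
    size: int,
    n_sets: int = 100,
    seed: int = 0,
    scenario: str = "untargeted",
    test_idx=None,
    candidates=None,
    K=None,
    M: GenotypeMatrix | None = None,
    vc: VarianceComponents | None = None,
    bayesb_settings: BayesBSettings | None = None,
) -> ValidationReport:
    """Distribution of rho/MSPE over uniformly drawn training sets.

    Untargeted: each random set of the stated size predicts its own
    complement.  Targeted: sets are drawn from ``candidates`` (default:
    everything outside the fixed ``test_idx``) and predict ``test_idx``.
    Deterministic for a fixed master seed.
    """
    yv = np.asarray(y.values if hasattr(y, "values") else y, float)
    if size >= yv.size:
        raise ValueError("training size must be below the panel size")
    rng = np.random.default_rng(seed)
    if test_idx is not None:
        test_idx = np.asarray(test_idx)
        pool = (
            np.asarray(candidates)
            if candidates is not None
            else np.setdiff1d(np.arange(yv.size), test_idx)
        )
    else:
        pool = np.arange(yv.size)
    rows = []
    for rep in range(n_sets):
        train_idx = np.sort(rng.choice(pool, size=size, replace=False))
        rows.append(
            evaluate_training_set(
                yv, train_idx, model=model, test_idx=test_idx, K=K, M=M, vc=vc,
                bayesb_settings=bayesb_settings,
                source=f"random:{rep}", scenario=scenario,
            )
            | {"repeat": rep}
        )
    return ValidationReport(pd.DataFrame(rows))
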