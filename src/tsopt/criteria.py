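"""Training-set quality criteria.

Each criterion maps a candidate training subset (and, for targeted
criteria, a test subset) to a scalar score with a declared optimization
direction.  Model-based criteria (D-optimality, CDmean, CDmin, PEV,
r-score) work from the genomic relationship matrix G or the PC-score
matrix S of the centered dosages; distance-based criteria (MaxiMin,
MiniMax, the multiple-design criterion and the entry-to-nearest-entry
core-collection objective) work from the Modified Roger's distance matrix.

In the untargeted scenario the test set defaults to every candidate not
in the training set; a targeted criterion scores the named test subset.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .genotypes import ScoreMatrix
from .kinship import DistanceMatrix, KinshipMatrix
from .models import VarianceComponents

__all__ = [
    "CriterionContext",
    "CriterionResult",
    "CRITERIA",
    "d_optimality",
    "cdmean",
    "cdmin",
    "pev_criterion",
    "r_score",
    "maximin",
    "minimax",
    "multiple_design",
    "ene_value",
    "evaluate",
    "signed_score",
]

_DOPT_EPS = 1e-10


@dataclasses.dataclass
class CriterionContext:
    """Shared inputs for the criteria, aligned to one individual index.

    ``variance_ratio`` is sigma2_e / sigma2_g used by the CD criteria; it
    defaults to (1 - h2) / h2 when variance components are supplied and to
    1 otherwise.  ``lambda_pev`` defaults to 1/J (J = number of markers)
    and ``lambda_rscore`` to 1, the conventional regularizations of the
    PEV and r-score formulations.
    """

    G: np.ndarray | None = None
    S: np.ndarray | None = None
    D: np.ndarray | None = None
    n_markers: int | None = None
    lambda_pev: float | None = None
    lambda_rscore: float = 1.0
    vc: VarianceComponents | None = None
    variance_ratio: float | None = None
    distance_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.G, KinshipMatrix):
            self.G = self.G.G
        if isinstance(self.S, ScoreMatrix):
            self.S = self.S.scores
        if isinstance(self.D, DistanceMatrix):
            self.D = self.D.D
        sizes = {m.shape[0] for m in (self.G, self.S, self.D) if m is not None}
        if len(sizes) > 1:
            raise ValueError("G, S, D must share one individual index")
        if self.lambda_pev is None:
            self.lambda_pev = 1.0 / self.n_markers if self.n_markers else 1e-3
        if self.variance_ratio is None:
            if self.vc is not None and self.vc.sigma2_g > 0:
                self.variance_ratio = self.vc.sigma2_e / self.vc.sigma2_g
            else:
                self.variance_ratio = 1.0
        if self.distance_band is None and self.D is not None:
            off = self.D[np.triu_indices(self.D.shape[0], k=1)]
            if off.size:
                self.distance_band = (
                    float(np.quantile(off, 0.10)),
                    float(np.quantile(off, 0.90)),
                )

    @property
    def n_candidates(self) -> int:
        for m in (self.G, self.S, self.D):
            if m is not None:
                return m.shape[0]
        raise ValueError("empty context")


@dataclasses.dataclass
class CriterionResult:
    name: str
    value: float
    direction: str  # "maximize" | "minimize"
    training_idx: np.ndarray
    test_idx: np.ndarray
    feasible: bool = True


def _prep(train, test, ctx: CriterionContext, need_test: bool):
    train = np.asarray(train, dtype=int)
    if train.size < 2:
        raise ValueError("training set needs at least 2 members")
    if test is None:
        if need_test:
            mask = np.ones(ctx.n_candidates, dtype=bool)
            mask[train] = False
            test = np.flatnonzero(mask)
        else:
            test = np.empty(0, dtype=int)
    else:
        test = np.asarray(test, dtype=int)
    return train, test


# ----------------------------------------------------------------------
# score-matrix criteria
# ----------------------------------------------------------------------

def d_optimality(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """log det(S_tr S_tr' + eps I): volume spanned by the training scores.

    Maximizing the determinant minimizes the generalized variance of
    marker-effect estimates; the small ridge guards rank deficiency when
    the subset outnumbers the retained components.
    """
    train, test = _prep(train, test, ctx, need_test=False)
    s = ctx.S[train]
    _, logdet = np.linalg.slogdet(s @ s.T + _DOPT_EPS * np.eye(train.size))
    return CriterionResult("dopt", float(logdet), "maximize", train, test)


def pev_criterion(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Mean prediction-error variance of the test set under a ridge fit.

    With W = (1, S) the intercept-augmented score matrix,
    value = mean diag( W_ts (W_tr' W_tr + lambda I)^-1 W_ts' ); the ideal
    training set minimizes it.
    """
    train, test = _prep(train, test, ctx, need_test=True)
    if test.size == 0:
        raise ValueError("PEV needs a non-empty test set")
    lam = ctx.lambda_pev
    if lam <= 0:
        raise ValueError("PEV requires lambda > 0")
    k = ctx.S.shape[1]
    w_tr = np.column_stack([np.ones(train.size), ctx.S[train]])
    w_ts = np.column_stack([np.ones(test.size), ctx.S[test]])
    A = w_tr.T @ w_tr + lam * np.eye(k + 1)
    sol = np.linalg.solve(A, w_ts.T)
    value = float(np.mean(np.einsum("ij,ji->i", w_ts, sol)))
    return CriterionResult("pev", value, "minimize", train, test)


def r_score(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Expected-accuracy criterion: correlation-like score between ridge
    predictions for the test set and their (unobserved) phenotypes.

    With A = S_tr'(S_tr S_tr' + lambda I)^-1 and C the centering matrix of
    the matching dimension,

        q12 = Tr[S_ts' C_ts S_ts A S_tr],
        q1  = (n_ts - 1) + Tr[S_ts' C_ts S_ts],
        q2  = Tr[A' S_ts' C_ts S_ts A] + Tr[A' S_tr' C_tr S_tr A],

    and the value is q12 / sqrt(q1 q2) (the product denominator under a
    root, read as a correlation; the raw q12 / (q1 q2) form is available
    via ``sqrt_denominator=False``).  Higher is better.
    """
    return _r_score_impl(train, ctx, test, sqrt_denominator=True)


def _r_score_impl(train, ctx, test, sqrt_denominator: bool) -> CriterionResult:
    train, test = _prep(train, test, ctx, need_test=True)
    if test.size < 2:
        raise ValueError("r-score needs >= 2 test individuals")
    lam = ctx.lambda_rscore
    s_tr, s_ts = ctx.S[train], ctx.S[test]
    A = np.linalg.solve(s_tr @ s_tr.T + lam * np.eye(train.size), s_tr).T  # K x n_tr
    c_ts = s_ts - s_ts.mean(axis=0)  # C_ts S_ts
    c_tr = s_tr - s_tr.mean(axis=0)
    sts_c_sts = s_ts.T @ c_ts  # K x K
    q12 = float(np.trace(sts_c_sts @ (A @ s_tr)))
    q1 = float(test.size - 1 + np.trace(sts_c_sts))
    q2 = float(np.trace(A.T @ sts_c_sts @ A) + np.trace(A.T @ (s_tr.T @ c_tr) @ A))
    denom = q1 * q2
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate score blocks: r-score undefined")
    value = q12 / np.sqrt(denom) if sqrt_denominator else q12 / denom
    return CriterionResult("rscore", value, "maximize", train, test)


# ----------------------------------------------------------------------
# CD criteria
# ----------------------------------------------------------------------

def _cd_diagonal(train: np.ndarray, ctx: CriterionContext) -> np.ndarray:
    """Diagonal of the coefficient-of-determination matrix for all candidates.

    CD = diag(G Z' P Z G) / diag(G), with V = Z G Z' + ratio I on the
    training block and P = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1 the GLS
    projection absorbing the intercept.  Entries lie in [0, 1]: the
    squared accuracy with which each candidate's genetic value would be
    predicted from phenotypes on the training set.
    """
    G = ctx.G
    if G is None:
        raise ValueError("CD criteria require G in the context")
    Vt = G[np.ix_(train, train)] + ctx.variance_ratio * np.eye(train.size)
    try:
        Vi = np.linalg.inv(Vt)
    except np.linalg.LinAlgError:
        Vi = np.linalg.inv(Vt + 1e-8 * np.eye(train.size))
    one = np.ones(train.size)
    u = Vi @ one
    P = Vi - np.outer(u, u) / float(one @ u)
    T = G[train, :]  # Z G
    cd = np.einsum("ij,jk,ki->i", T.T, P, T)
    diag_g = np.diag(G).copy()
    diag_g[diag_g <= 0] = np.nan
    return cd / diag_g


def cdmean(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Mean CD over the test block; the closer to 1 the better."""
    train, test = _prep(train, test, ctx, need_test=True)
    if test.size == 0:
        raise ValueError("CDmean needs a non-empty test set")
    cd = _cd_diagonal(train, ctx)
    return CriterionResult("cdmean", float(np.nanmean(cd[test])), "maximize", train, test)


def cdmin(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Minimum CD over the test block: worst-case expected reliability."""
    train, test = _prep(train, test, ctx, need_test=True)
    if test.size == 0:
        raise ValueError("CDmin needs a non-empty test set")
    cd = _cd_diagonal(train, ctx)
    return CriterionResult("cdmin", float(np.nanmin(cd[test])), "maximize", train, test)


# ----------------------------------------------------------------------
# distance criteria
# ----------------------------------------------------------------------

def maximin(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Minimum pairwise distance within the training set (maximize)."""
    train, test = _prep(train, test, ctx, need_test=False)
    sub = ctx.D[np.ix_(train, train)]
    value = float(sub[np.triu_indices(train.size, k=1)].min())
    return CriterionResult("maximin", value, "maximize", train, test)


def minimax(train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Maximum train-to-test distance (minimize): keep the training set
    close to every test genotype."""
    train, test = _prep(train, test, ctx, need_test=True)
    if test.size == 0:
        raise ValueError("MiniMax needs a non-empty test set")
    value = float(ctx.D[np.ix_(train, test)].max())
    return CriterionResult("minimax", value, "minimize", train, test)


def multiple_design(
    train, ctx: CriterionContext, test=None, distance_band: tuple[float, float] | None = None
) -> CriterionResult:
    """Within-set spread minus train-to-test remoteness, inside a band.

    value = mean within-train distance - mean train-test distance;
    candidate sets whose component means fall outside ``distance_band``
    (default: the central 80% of the observed pairwise distances) are
    marked infeasible.
    """
    train, test = _prep(train, test, ctx, need_test=True)
    if test.size == 0:
        raise ValueError("multiple-design criterion needs a non-empty test set")
    band = distance_band or ctx.distance_band
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("distance band must satisfy 0 <= lo < hi <= 1")
    within = float(ctx.D[np.ix_(train, train)][np.triu_indices(train.size, k=1)].mean())
    between = float(ctx.D[np.ix_(train, test)].mean())
    feasible = lo <= within <= hi and lo <= between <= hi
    return CriterionResult(
        "mult", within - between, "maximize", train, test, feasible=feasible
    )


def ene_value(selected, ctx: CriterionContext, test=None) -> CriterionResult:
    """Entry-to-nearest-entry: mean distance from each selected entry to
    the closest other selected entry (maximize for diverse cores)."""
    selected, test = _prep(selected, test, ctx, need_test=False)
    sub = ctx.D[np.ix_(selected, selected)].copy()
    np.fill_diagonal(sub, np.inf)
    value = float(sub.min(axis=1).mean())
    return CriterionResult("ene", value, "maximize", selected, test)


# ----------------------------------------------------------------------
# registry
# ----------------------------------------------------------------------

CRITERIA: dict[str, Callable[..., CriterionResult]] = {
    "dopt": d_optimality,
    "cdmean": cdmean,
    "cdmin": cdmin,
    "pev": pev_criterion,
    "rscore": r_score,
    "maximin": maximin,
    "minimax": minimax,
    "mult": multiple_design,
    "ene": ene_value,
}


def evaluate(name: str, train, ctx: CriterionContext, test=None) -> CriterionResult:
    """Evaluate a criterion by registry name."""
    try:
        fn = CRITERIA[name]
    except KeyError:
        raise ValueError(f"unknown criterion {name!r}; known: {sorted(CRITERIA)}") from None
    return fn(train, ctx, test)


def signed_score(name: str, train, ctx: CriterionContext, test=None) -> float:
    """Criterion value on a to-maximize scale (-inf when infeasible)."""
    res = evaluate(name, train, ctx, test)
    if not res.feasible:
        return -np.inf
    return res.value if res.direction == "maximize" else -res.value
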