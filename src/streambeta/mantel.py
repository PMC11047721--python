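"""Mantel permutation tests and distance-decay regressions.

The Mantel statistic is the Pearson correlation between the unfolded
lower triangles of two distance matrices. Because the n(n−1)/2 pairwise
entries are not independent, significance comes from a permutation null:
the rows and columns of one matrix are relabelled simultaneously (never
its unfolded entries independently, which would break the within-site
dependence structure) and the correlation recomputed. The reported
p-value uses the add-one estimator p = (1 + #{r* >= r}) / (n_perm + 1),
so it can never be exactly zero. For small n an exact mode enumerates
all n! relabelings.

Distance-decay fits are plain OLS of one unfolded dissimilarity on one
unfolded distance; they describe the trend, and their classical t-test
p-value is flagged as pseudo-replicated — inference belongs to the
Mantel test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DistanceMatrix, ValidationError

#: Maximum number of sites for which all n! relabelings are enumerated.
EXACT_ENUMERATION_MAX_SITES = 7


def unfold(D: DistanceMatrix) -> np.ndarray:
    """Lower-triangle entries in the package-wide fixed pair ordering.

    For sites 1..n the order is (2,1), (3,1), (3,2), (4,1), ... read
    row-major below the diagonal — identical, by symmetry, to scipy's
    condensed (upper row-major) ordering, so ``squareform`` interoperates.
    """
    iu = np.triu_indices(D.n_sites, k=1)
    return D.values[iu]


def refold(v: np.ndarray, site_ids: tuple[str, ...]) -> DistanceMatrix:
    """Inverse of :func:`unfold`: rebuild the symmetric matrix."""
    n = len(site_ids)
    if v.size != n * (n - 1) // 2:
        raise ValidationError(f"vector length {v.size} does not fit {n} sites")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m += m.T
    return DistanceMatrix(site_ids, m, signed=bool((np.asarray(v) < 0).any()))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int | None
    exact: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class RegressionFit:
    """OLS summary of unfolded Dy against unfolded Dx.

    ``p_slope`` is the classical t-test p-value; ``pseudo_replicated``
    marks that the n site pairs are not independent observations.
    """

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    pseudo_replicated: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _check_aligned(Dy: DistanceMatrix, Dx: DistanceMatrix) -> None:
    if Dy.site_ids != Dx.site_ids:
        raise ValidationError("distance matrices must share site ordering")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float((xc @ yc) / denom)


def _tail_count(r_null: np.ndarray, r_obs: float, tail: str) -> np.ndarray:
    eps = 1e-12  # count ties as extreme
    if tail == "greater":
        return r_null >= r_obs - eps
    if tail == "two-sided":
        return np.abs(r_null) >= abs(r_obs) - eps
    raise ValidationError(f"unknown tail: {tail!r}")


def mantel(
    Dy: DistanceMatrix,
    Dx: DistanceMatrix,
    n_perm: int | str = 9999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation.

    ``n_perm="exact"`` enumerates all n! relabelings (n <= 7) and reports
    the exact tail probability including the identity relabeling;
    otherwise ``n_perm`` Monte-Carlo relabelings are drawn with ``seed``
    and the add-one p-value estimator is used. ``tail="greater"`` is the
    distance-decay alternative (dissimilarity rises with distance);
    ``"two-sided"`` tests |r|.
    """
    _check_aligned(Dy, Dx)
    y = unfold(Dy)
    x = unfold(Dx)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValidationError("zero-variance distance matrix in Mantel test")
    r_obs = _pearson(x, y)
    n = Dy.n_sites
    iu = np.triu_indices(n, k=1)
    M = Dy.values

    if n_perm == "exact":
        if n > EXACT_ENUMERATION_MAX_SITES:
            raise ValidationError(
                f"exact enumeration limited to n <= {EXACT_ENUMERATION_MAX_SITES}"
            )
        r_null = np.array(
            [
                _pearson(x, M[np.ix_(p, p)][iu])
                for p in itertools.permutations(range(n))
            ]
        )
        p_val = float(_tail_count(r_null, r_obs, tail).mean())
        return MantelResult(r_obs, p_val, r_null.size, tail, seed, exact=True)

    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = _pearson(x, M[np.ix_(perm, perm)][iu])
        if _tail_count(np.array([r_star]), r_obs, tail)[0]:
            hits += 1
    p_val = (1 + hits) / (n_perm + 1)
    return MantelResult(r_obs, p_val, n_perm, tail, seed)


#: Row/column layout of the 3x3 Mantel grid.
PREDICTOR_ROWS = ("geography", "elevation", "environment")
BETA_COLUMNS = ("total", "turnover", "nestedness")


def mantel_table(
    beta: dict[str, DistanceMatrix],
    predictors: dict[str, DistanceMatrix],
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
    on_degenerate: str = "raise",
) -> dict[str, dict[str, MantelResult | None]]:
    """All beta-index x predictor Mantel tests from one seed stream.

    ``beta`` maps total/turnover/nestedness to their dissimilarity
    matrices; ``predictors`` maps geography/elevation/environment to the
    explanatory distances. Each of the nine tests draws its permutations
    from an independent child of the master seed, so results do not
    depend on evaluation order. With ``on_degenerate="skip"``, a
    zero-variance matrix (e.g. a turnover matrix that is identically zero
    in a perfectly nested community) yields ``None`` instead of an error.
    """
    if on_degenerate not in ("raise", "skip"):
        raise ValidationError(f"unknown on_degenerate policy: {on_degenerate!r}")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(predictors) * len(beta)))
    grid: dict[str, dict[str, MantelResult | None]] = {}
    for pred_name, Dx in predictors.items():
        grid[pred_name] = {}
        for beta_name, Dy in beta.items():
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            try:
                grid[pred_name][beta_name] = mantel(
                    Dy, Dx, n_perm=n_perm, seed=child_seed, tail=tail
                )
            except ValidationError:
                if on_degenerate == "raise":
                    raise
                grid[pred_name][beta_name] = None
    return grid


def distance_decay(Dy: DistanceMatrix, Dx: DistanceMatrix) -> RegressionFit:
    """OLS of unfolded dissimilarity on unfolded distance."""
    _check_aligned(Dy, Dx)
    x = unfold(Dx)
    y = unfold(Dy)
    if np.ptp(x) == 0:
        raise ValidationError("degenerate (constant) predictor distance")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_slope=float(fit.pvalue),
        n=int(x.size),
    )
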