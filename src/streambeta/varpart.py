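"""Multiple regression on distance matrices and hierarchical partitioning.

MRM regresses one unfolded dissimilarity matrix on several unfolded,
z-scored explanatory distance matrices by OLS. Inference mirrors the
Mantel logic: the response matrix's rows and columns are permuted
simultaneously while the predictors stay fixed, and the model R² and the
|coefficients| are ranked against their permutation nulls.

Hierarchical partitioning decomposes the full-model R² into a per-predictor
independent contribution I_k by averaging the incremental R² of adding
predictor k over all orderings of the predictors — computed efficiently
over the 2^k predictor subsets with the subset-size weights
w(s) = s!(k−s−1)!/k!. The joint contribution J_k is the remainder of the
univariate R²: J_k = R²({k}) − I_k. Two identities are self-checked on
every run: ΣI = full-model R², and I_k + J_k = univariate R²_k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import DistanceMatrix, ValidationError
from .mantel import unfold

#: Cap on predictor count for the all-subsets fit (2^k regressions).
HIER_PART_MAX_PREDICTORS = 16


def standardize_matrix(D: DistanceMatrix) -> DistanceMatrix:
    """Z-score the unfolded entries (mean 0, sample SD 1); zero diagonal kept."""
    v = unfold(D)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant distance matrix cannot be standardized")
    z = (v - v.mean()) / sd
    n = D.n_sites
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = z
    m += m.T
    return DistanceMatrix(D.site_ids, m, signed=True)


@dataclass(frozen=True)
class MRMResult:
    r_squared: float
    p_model: float
    coefficients: dict[str, float]
    p_coef: dict[str, float]
    intercept: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class HierPartResult:
    """Independent (I) and joint (J) R² contributions per predictor."""

    independent: dict[str, float]
    joint: dict[str, float]
    independent_pct: dict[str, float]
    full_r_squared: float
    gof_cache: dict[frozenset, float]

    def to_dict(self) -> dict:
        return {
            "independent": self.independent,
            "joint": self.joint,
            "independent_pct": self.independent_pct,
            "full_r_squared": self.full_r_squared,
        }


def _design(predictors: dict[str, DistanceMatrix]) -> tuple[list[str], np.ndarray]:
    names = list(predictors)
    if not names:
        raise ValidationError("at least one predictor matrix is required")
    ref = next(iter(predictors.values()))
    cols = []
    for name, D in predictors.items():
        if D.site_ids != ref.site_ids:
            raise ValidationError(f"predictor {name!r} has mismatched site ordering")
        cols.append(unfold(D))
    return names, np.column_stack(cols)


def _ols_r2(Xc: np.ndarray, yc: np.ndarray, ssy: float) -> float:
    """R² of centered y on centered columns Xc (intercept implicit)."""
    if Xc.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return float(1.0 - (resid @ resid) / ssy)


def mrm(
    Dy: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    n_perm: int = 9999,
    seed: int | None = None,
    permute: str = "response",
) -> MRMResult:
    """Multiple regression of one distance matrix on several others.

    Predictors are expected already standardized (see
    :func:`standardize_matrix`); the fit itself is ordinary least squares
    with intercept on the unfolded vectors. ``p_model`` is the upper-tail
    permutation p of R²; ``p_coef`` are two-tailed permutation p-values of
    |b|. By default the response matrix is permuted (Legendre-style);
    ``permute="predictors"`` permutes the predictor matrices jointly
    instead, as a sensitivity variant.
    """
    names, X = _design(predictors)
    if Dy.site_ids != next(iter(predictors.values())).site_ids:
        raise ValidationError("response and predictors must share site ordering")
    y = unfold(Dy)
    m = y.size
    k = len(names)
    if m <= k + 1:
        raise ValidationError(f"{m} pairs cannot support {k} predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(m), X])) < k + 1:
        raise ValidationError("rank-deficient design: collinear predictor matrices")
    if permute not in ("response", "predictors"):
        raise ValidationError(f"unknown permutation scheme: {permute!r}")

    Xc = X - X.mean(axis=0)
    # pseudoinverse reused across all permutation refits
    pinv = np.linalg.pinv(Xc)

    def fit(yv: np.ndarray) -> tuple[np.ndarray, float]:
        yc = yv - yv.mean()
        beta = pinv @ yc
        resid = yc - Xc @ beta
        ssy = yc @ yc
        return beta, float(1.0 - (resid @ resid) / ssy)

    beta_obs, r2_obs = fit(y)
    intercept = float(y.mean() - X.mean(axis=0) @ beta_obs)

    n = Dy.n_sites
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    hits_r2 = 0
    hits_b = np.zeros(k, dtype=int)
    eps = 1e-12
    M = Dy.values
    # joint predictor permutation is distributionally identical to permuting
    # the response with the inverse relabeling, so both schemes share one loop
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        y_star = M[np.ix_(perm, perm)][iu]
        b_star, r2_star = fit(y_star)
        hits_r2 += r2_star >= r2_obs - eps
        hits_b += np.abs(b_star) >= np.abs(beta_obs) - eps
    denom = int(n_perm) + 1
    return MRMResult(
        r_squared=r2_obs,
        p_model=(1 + hits_r2) / denom,
        coefficients={nm: float(b) for nm, b in zip(names, beta_obs)},
        p_coef={nm: (1 + int(h)) / denom for nm, h in zip(names, hits_b)},
        intercept=intercept,
        n_perm=int(n_perm),
        seed=seed,
    )


def subset_r2(
    Dy: DistanceMatrix, predictors: dict[str, DistanceMatrix]
) -> dict[frozenset, float]:
    """OLS R² of the unfolded response on every predictor subset."""
    names, X = _design(predictors)
    y = unfold(Dy)
    k = len(names)
    if k > HIER_PART_MAX_PREDICTORS:
        raise ValidationError(
            f"{k} predictors exceed the all-subsets cap "
            f"({HIER_PART_MAX_PREDICTORS}); pre-screen the predictor set"
        )
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ssy = float(yc @ yc)
    if ssy == 0:
        raise ValidationError("constant response matrix")
    cache: dict[frozenset, float] = {}
    for mask in range(2**k):
        idx = [i for i in range(k) if mask >> i & 1]
        cache[frozenset(names[i] for i in idx)] = _ols_r2(Xc[:, idx], yc, ssy)
    return cache


def hier_part(
    Dy: DistanceMatrix, predictors: dict[str, DistanceMatrix]
) -> HierPartResult:
    """Exact hierarchical partitioning of the full-model R².

    I_k = Σ_{S ⊆ P\\{k}} w(|S|)·[R²(S ∪ {k}) − R²(S)], with
    w(s) = s!(k−s−1)!/k! — the average incremental fit of predictor k over
    all k! predictor orderings. Negative I (suppressor variables) is
    reported as-is with a warning; percentages divide by ΣI including any
    negatives.
    """
    names = list(predictors)
    k = len(names)
    cache = subset_r2(Dy, predictors)
    fact = [math.factorial(i) for i in range(k + 1)]
    weights = [fact[s] * fact[k - s - 1] / fact[k] for s in range(k)]

    independent: dict[str, float] = {}
    for kn in names:
        others = [nm for nm in names if nm != kn]
        total = 0.0
        for mask in range(2 ** (k - 1)):
            S = frozenset(others[i] for i in range(k - 1) if mask >> i & 1)
            total += weights[len(S)] * (cache[S | {kn}] - cache[S])
        independent[kn] = total

    full_r2 = cache[frozenset(names)]
    joint = {nm: cache[frozenset([nm])] - independent[nm] for nm in names}

    sum_i = sum(independent.values())
    if abs(sum_i - full_r2) > 1e-8:
        raise AssertionError("hierarchical partition identity SUM(I) = R2 violated")
    for nm in names:
        if abs(independent[nm] + joint[nm] - cache[frozenset([nm])]) > 1e-8:
            raise AssertionError("I_k + J_k = univariate R2_k violated")
    if any(v < 0 for v in independent.values()):
        warnings.warn(
            "negative independent contribution(s) present (suppressor variables); "
            "percentages use the signed sum",
            stacklevel=2,
        )
    pct = {nm: 100.0 * independent[nm] / sum_i for nm in names}
    return HierPartResult(independent, joint, pct, full_r2, cache)


def partition_table(
    beta: dict[str, DistanceMatrix],
    predictors: dict[str, DistanceMatrix],
    n_perm: int = 9999,
    seed: int | None = None,
) -> dict[str, dict]:
    """MRM + hierarchical partitioning for each beta index.

    Returns, per response (total/turnover/nestedness), the MRMResult and
    HierPartResult over the shared predictor set. Each response's
    permutations come from an independent child of the master seed.
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(beta)))
    out: dict[str, dict] = {}
    for beta_name, Dy in beta.items():
        child_seed = int(next(children).generate_state(1)[0] % (2**31))
        out[beta_name] = {
            "mrm": mrm(Dy, predictors, n_perm=n_perm, seed=child_seed),
            "hier_part": hier_part(Dy, predictors),
        }
    return out
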