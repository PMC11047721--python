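"""Pairwise partition of total beta diversity into turnover and nestedness.

Following Baselga's incidence-based decomposition, total pairwise
dissimilarity (Sørensen, βsor) splits additively into a turnover
component (Simpson, βsim) and a nestedness-resultant component (βsne):

    βsor = (b + c) / (2a + b + c)
    βsim = min(b, c) / (a + min(b, c))
    βsne = βsor − βsim = [|b − c| / (2a + b + c)] · [a / (a + min(b, c))]

where a is the number of species shared by the two sites and b, c are the
numbers unique to each. βsim is insensitive to richness differences, so
βsne isolates the dissimilarity caused by ordered species loss (poorer
sites being subsets of richer ones). The ratio βratio = βsne/βsor
classifies which process dominates: below 0.5, turnover; at or above 0.5,
nestedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DistanceMatrix, OccurrenceMatrix, ValidationError

_EQ3_ATOL = 1e-12  # difference vs. direct form of the nestedness component


class DegeneratePairError(ValueError):
    """A pair involving an empty site reached the partition stage."""


@dataclass(frozen=True)
class PairCounts:
    """Shared (a) and one-sided (b, c) species counts for a site pair."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValidationError("pair counts must be non-negative")
        if self.a + self.b < 1 or self.a + self.c < 1:
            raise DegeneratePairError(
                "a site with zero richness reached beta computation; "
                "run drop_empty_sites first"
            )


@dataclass(frozen=True)
class BetaPair:
    beta_sor: float
    beta_sim: float
    beta_sne: float


@dataclass(frozen=True)
class BetaSummary:
    """Pairwise mean ± SD of the three indices and of βratio.

    SDs are sample standard deviations (n−1) over the n(n−1)/2 unordered
    site pairs. Pairs with βsor = 0 (identical communities) contribute to
    the index means but are excluded from βratio, whose denominator
    vanishes there; their count is reported in ``n_ratio_excluded``.
    """

    mean_sor: float
    sd_sor: float
    mean_sim: float
    sd_sim: float
    mean_sne: float
    sd_sne: float
    mean_ratio: float
    sd_ratio: float
    n_pairs: int
    n_ratio_excluded: int
    dominant_component: str
    ratio_of_means: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def pair_counts(row_i: np.ndarray, row_j: np.ndarray) -> PairCounts:
    """Count shared and unique species between two incidence rows."""
    ri = np.asarray(row_i, dtype=bool)
    rj = np.asarray(row_j, dtype=bool)
    if ri.shape != rj.shape:
        raise ValidationError("incidence rows must have equal length")
    a = int(np.count_nonzero(ri & rj))
    b = int(np.count_nonzero(ri & ~rj))
    c = int(np.count_nonzero(~ri & rj))
    return PairCounts(a, b, c)


def beta_pair(pc: PairCounts) -> BetaPair:
    """Evaluate the three pairwise indices from shared/unique counts.

    βsne is computed from its direct product form and cross-checked
    against the difference βsor − βsim to 1e-12; disagreement would
    indicate a numerical fault, not a data property.
    """
    a, b, c = pc.a, pc.b, pc.c
    m = min(b, c)
    if a == 0 and m == 0:
        # only reachable from an empty site, which preconditions exclude
        raise DegeneratePairError("a = 0 with min(b, c) = 0: empty site in pair")
    beta_sor = (b + c) / (2 * a + b + c)
    beta_sim = m / (a + m)
    beta_sne = (abs(b - c) / (2 * a + b + c)) * (a / (a + m))
    if abs(beta_sne - (beta_sor - beta_sim)) > _EQ3_ATOL:
        raise AssertionError("nestedness identity violated beyond tolerance")
    return BetaPair(beta_sor, beta_sim, beta_sne)


def beta_matrices(
    occ: OccurrenceMatrix,
) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """All-pairs βsor, βsim, βsne as three aligned distance matrices."""
    n = occ.n_sites
    if n < 2:
        raise ValidationError("need at least 2 sites for pairwise dissimilarity")
    if (occ.richness() == 0).any():
        raise DegeneratePairError("empty sites present; run drop_empty_sites first")
    inc = occ.incidence.astype(bool)
    sor = np.zeros((n, n))
    sim = np.zeros((n, n))
    sne = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            bp = beta_pair(pair_counts(inc[i], inc[j]))
            sor[i, j] = sor[j, i] = bp.beta_sor
            sim[i, j] = sim[j, i] = bp.beta_sim
            sne[i, j] = sne[j, i] = bp.beta_sne
    ids = occ.site_ids
    return DistanceMatrix(ids, sor), DistanceMatrix(ids, sim), DistanceMatrix(ids, sne)


def beta_summary(
    D_sor: DistanceMatrix, D_sim: DistanceMatrix, D_sne: DistanceMatrix
) -> BetaSummary:
    """Pairwise means ± SDs and the βratio classification.

    βratio is computed per pair and then averaged (the per-pair
    distribution is what gives it a spread); the ratio of the two means is
    reported alongside as ``ratio_of_means`` for comparison.
    """
    if not (D_sor.site_ids == D_sim.site_ids == D_sne.site_ids):
        raise ValidationError("beta matrices must share site ordering")
    iu = np.triu_indices(D_sor.n_sites, k=1)
    sor = D_sor.values[iu]
    sim = D_sim.values[iu]
    sne = D_sne.values[iu]
    nonzero = sor > 0
    n_excluded = int((~nonzero).sum())
    if not nonzero.any():
        raise ValidationError("all pairs identical (beta_sor = 0): ratio undefined")
    if n_excluded:
        warnings.warn(
            f"{n_excluded} identical pair(s) (beta_sor = 0) excluded from "
            "beta_ratio statistics",
            stacklevel=2,
        )
    ratio = sne[nonzero] / sor[nonzero]
    mean_ratio = float(ratio.mean())

    def _sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if x.size > 1 else 0.0

    return BetaSummary(
        mean_sor=float(sor.mean()),
        sd_sor=_sd(sor),
        mean_sim=float(sim.mean()),
        sd_sim=_sd(sim),
        mean_sne=float(sne.mean()),
        sd_sne=_sd(sne),
        mean_ratio=mean_ratio,
        sd_ratio=_sd(ratio),
        n_pairs=int(sor.size),
        n_ratio_excluded=n_excluded,
        dominant_component="turnover" if mean_ratio < 0.5 else "nestedness",
        ratio_of_means=float(sne.mean() / sor.mean()),
    )
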