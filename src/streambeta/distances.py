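"""Explanatory distance matrices and environmental-variable screening.

Three predictor families drive the inference stages: great-circle
geographic distance from transect coordinates, elevational distance as
absolute differences in metres, and Euclidean environmental distance over
z-scored microhabitat variables. Before pooling, variables are screened
for collinearity with pairwise Spearman rank correlations; of each highly
correlated pair the variable lower on a priority list is dropped (in the
montane-stream setting this removes water temperature, which tracks
elevation closely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import shapiro, spearmanr

from .io import DistanceMatrix, EnvTable, TransectMeta, ValidationError

#: Equatorial sphere radius (m) used for great-circle distances, matching
#: the default of the geosphere tool family.
EARTH_RADIUS_M = 6_378_137.0

#: Column-name prefix grouping the substrate composition proportions.
SUBSTRATE_PREFIX = "substrate_"


def geographic_distance(meta: TransectMeta) -> DistanceMatrix:
    """Pairwise haversine (great-circle) distance in metres."""
    lat = np.radians(meta.table["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta.table["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # symmetrize away floating round-off
    return DistanceMatrix(meta.site_ids, d)


def elevational_distance(meta: TransectMeta) -> DistanceMatrix:
    """Pairwise absolute elevation difference in metres."""
    e = meta.table["elevation"].to_numpy(dtype=float)
    return DistanceMatrix(meta.site_ids, np.abs(e[:, None] - e[None, :]))


def standardize(env: EnvTable) -> EnvTable:
    """Z-score every column to mean 0 and sample SD 1."""
    df = env.table.astype(float)
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValidationError(f"constant column(s) cannot be standardized: {constant}")
    return EnvTable((df - df.mean()) / sd)


def environmental_distance(env: EnvTable, standardized: bool = False) -> DistanceMatrix:
    """Euclidean distance over (z-scored) environmental variables."""
    z = env if standardized else standardize(env)
    d = squareform(pdist(z.table.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(env.site_ids, d)


def substrate_columns(env: EnvTable) -> list[str]:
    return [c for c in env.variables if c.startswith(SUBSTRATE_PREFIX)]


def single_variable_distance(
    env: EnvTable,
    var: str,
    standardized: bool = False,
    substrate_encoding: str = "proportions",
) -> DistanceMatrix:
    """Pairwise distance for one predictor variable.

    Scalar variables give |x_i − x_j| on the (z-scored) column. The
    substrate composition is a 4-part proportion vector (sand, gravel,
    rock, humus); ``var="substrate"`` returns either the Euclidean
    distance between the raw proportion vectors (default) or a 0/1
    dominant-category mismatch (``substrate_encoding="dominant"``).
    """
    if var == "substrate":
        cols = substrate_columns(env)
        if not cols:
            raise ValidationError("no substrate_* proportion columns present")
        props = env.table[cols].to_numpy(dtype=float)
        if substrate_encoding == "proportions":
            d = squareform(pdist(props, metric="euclidean"))
        elif substrate_encoding == "dominant":
            dom = props.argmax(axis=1)
            d = (dom[:, None] != dom[None, :]).astype(float)
        else:
            raise ValidationError(f"unknown substrate encoding: {substrate_encoding!r}")
        return DistanceMatrix(env.site_ids, d)
    if var not in env.variables:
        raise ValidationError(f"unknown variable: {var!r}")
    col = env.table[[var]]
    z = col.astype(float) if standardized else standardize(EnvTable(col)).table
    x = z[var].to_numpy(dtype=float)
    return DistanceMatrix(env.site_ids, np.abs(x[:, None] - x[None, :]))


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of the normality and collinearity screen.

    ``normality_p`` holds Shapiro–Wilk p-values per variable; they are
    informational (no transformation is applied on their basis).
    ``flagged_pairs`` lists variable pairs whose |Spearman rho| reached
    the threshold, with the measured rho; ``removed`` are the variables
    dropped, each the lower-priority member of a flagged pair.
    """

    normality_p: dict[str, float]
    spearman_rho: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    removed: list[str]
    kept: list[str]
    threshold: float
    priority: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "normality_p": self.normality_p,
            "flagged_pairs": [
                {"var_a": a, "var_b": b, "rho": r} for a, b, r in self.flagged_pairs
            ],
            "removed": self.removed,
            "kept": self.kept,
            "threshold": self.threshold,
            "priority": self.priority,
        }


def screen_variables(
    env: EnvTable,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> ScreeningReport:
    """Collinearity screen over all variable pairs.

    Spearman rank correlations (tie-corrected) are computed for every
    variable pair; pairs with |rho| >= ``threshold`` are flagged and, for
    each, the variable ranked lower in ``priority`` (then later in column
    order) is removed. Pairs are resolved in order of decreasing |rho| so
    the outcome is deterministic. Shapiro–Wilk normality p-values are
    reported per variable but drive no exclusion.
    """
    if not 0 < threshold < 1:
        raise ValidationError("collinearity threshold must lie in (0, 1)")
    df = env.table.astype(float)
    if len(df) < 4:
        raise ValidationError("need at least 4 sites for the normality screen")
    priority = list(priority or [])
    cols = list(df.columns)

    normality = {c: float(shapiro(df[c].to_numpy()).pvalue) for c in cols}

    if len(cols) == 1:
        rho = pd.DataFrame([[1.0]], index=cols, columns=cols)
    elif len(cols) == 2:
        r = float(spearmanr(df.iloc[:, 0], df.iloc[:, 1]).statistic)
        rho = pd.DataFrame([[1.0, r], [r, 1.0]], index=cols, columns=cols)
    else:
        r, _ = spearmanr(df.to_numpy())
        rho = pd.DataFrame(r, index=cols, columns=cols)

    def rank(v: str) -> int:
        return priority.index(v) if v in priority else len(priority) + cols.index(v)

    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if abs(rho.loc[a, b]) >= threshold:
                flagged.append((a, b, float(rho.loc[a, b])))
    flagged.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))

    removed: list[str] = []
    for a, b, _r in flagged:
        if a in removed or b in removed:
            continue
        removed.append(b if rank(a) < rank(b) else a)
    kept = [c for c in cols if c not in removed]
    return ScreeningReport(
        normality_p=normality,
        spearman_rho=rho,
        flagged_pairs=flagged,
        removed=removed,
        kept=kept,
        threshold=threshold,
        priority=priority,
    )
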