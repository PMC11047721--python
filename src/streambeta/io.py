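"""Data model and readers/writers for site-by-species surveys.

The analysis chain works on three aligned tables — a binary occurrence
matrix (transects x species), per-transect coordinates/elevation, and a
per-transect table of numeric microhabitat variables — plus a shared
symmetric ``DistanceMatrix`` carrier that every downstream stage consumes.
All tables are plain CSV/TSV with a header row and a leading site-id
column; the delimiter is sniffed and can be overridden.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary incidence of species across sites (1 = recorded).

    ``incidence`` has one row per site and one column per species; every
    pairwise dissimilarity in the chain is computed from these rows.
    """

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=np.int8)
        if inc.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if inc.size and not np.isin(inc, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        _check_unique(self.site_ids, "site")
        _check_unique(self.species_ids, "species")
        object.__setattr__(self, "incidence", inc)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> np.ndarray:
        """Species count per site, in site order."""
        return self.incidence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=list(self.site_ids), columns=list(self.species_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceMatrix":
        return cls(
            site_ids=tuple(str(i) for i in df.index),
            species_ids=tuple(str(c) for c in df.columns),
            incidence=df.to_numpy(),
        )

    def subset_sites(self, keep: Sequence[str]) -> "OccurrenceMatrix":
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise ValidationError(f"unknown site ids: {missing}")
        rows = [index[s] for s in keep]
        return OccurrenceMatrix(tuple(keep), self.species_ids, self.incidence[rows])


@dataclass(frozen=True)
class TransectMeta:
    """Per-site WGS84 coordinates (decimal degrees) and elevation (m)."""

    table: pd.DataFrame  # index: site_id; columns: latitude, longitude, elevation

    def __post_init__(self) -> None:
        df = self.table
        required = {"latitude", "longitude", "elevation"}
        if not required.issubset(df.columns):
            raise ValidationError(f"metadata must have columns {sorted(required)}")
        _check_unique([str(i) for i in df.index], "site")
        if not np.isfinite(df[list(required)].to_numpy(dtype=float)).all():
            raise ValidationError("metadata values must be finite")
        if (df["latitude"].abs() > 90).any():
            raise ValidationError("latitude out of [-90, 90]")
        if (df["longitude"].abs() > 180).any():
            raise ValidationError("longitude out of [-180, 180]")

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.table.index)

    def subset_sites(self, keep: Sequence[str]) -> "TransectMeta":
        return TransectMeta(self.table.loc[list(keep)])


@dataclass(frozen=True)
class EnvTable:
    """Per-site numeric environmental variables (one row per transect)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        _check_unique([str(i) for i in df.index], "site")
        _check_unique([str(c) for c in df.columns], "variable")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
            raise ValidationError(f"non-numeric environment columns: {bad}")
        if not np.isfinite(values.astype(float)).all():
            raise ValidationError("environment values must be finite")

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.table.index)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.table.columns)

    def subset_sites(self, keep: Sequence[str]) -> "EnvTable":
        return EnvTable(self.table.loc[list(keep)])

    def subset_variables(self, keep: Sequence[str]) -> "EnvTable":
        return EnvTable(self.table[list(keep)])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise distance/dissimilarity carrier.

    ``signed=True`` marks a z-scored matrix, whose off-diagonal entries may
    be negative; plain distances are validated as non-negative.
    """

    site_ids: tuple[str, ...]
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValidationError("distance matrix entries must be finite")
        if not self.signed and (v < 0).any():
            raise ValidationError("distance matrix entries must be >= 0")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        _check_unique(self.site_ids, "site")
        object.__setattr__(self, "values", v)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.site_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override is not None:
        return override
    sample = Path(path).read_text().splitlines()[0] if Path(path).stat().st_size else ","
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_occurrence(path: str | Path, delimiter: str | None = None) -> OccurrenceMatrix:
    """Read a site-by-species table; counts are binarized (>0 -> 1).

    All downstream statistics are incidence-based, so abundance input is
    accepted and reduced to presence/absence on read. Row and column order
    are preserved from the file.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                x = float(raw[i, j])
                if not np.isfinite(x) or x < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValidationError(
                    f"malformed cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
                    f"{raw[i, j]!r}"
                ) from None
            values[i, j] = 1 if x > 0 else 0
    return OccurrenceMatrix(
        tuple(str(i) for i in df.index), tuple(str(c) for c in df.columns), values
    )


def write_occurrence(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index_label="site_id")


def read_meta(path: str | Path, delimiter: str | None = None) -> TransectMeta:
    sep = _sniff_delimiter(Path(path), delimiter)
    return TransectMeta(pd.read_csv(path, sep=sep, index_col=0))


def write_meta(meta: TransectMeta, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="site_id")


def read_env(path: str | Path, delimiter: str | None = None) -> EnvTable:
    sep = _sniff_delimiter(Path(path), delimiter)
    return EnvTable(pd.read_csv(path, sep=sep, index_col=0))


def write_env(env: EnvTable, path: str | Path) -> None:
    env.table.to_csv(path, index_label="site_id")


def write_distance(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path, index_label="site_id")


def read_distance(path: str | Path, delimiter: str | None = None) -> DistanceMatrix:
    sep = _sniff_delimiter(Path(path), delimiter)
    return DistanceMatrix.from_frame(pd.read_csv(path, sep=sep, index_col=0))


def merge_surveys(surveys: Iterable[OccurrenceMatrix]) -> OccurrenceMatrix:
    """Union incidence across repeated surveys of the same sites.

    A species is present at a site if it was recorded there in any survey
    (logical-or semantics); the merged species set is the union, ordered by
    first appearance across surveys.
    """
    surveys = list(surveys)
    if not surveys:
        raise ValidationError("merge_surveys needs at least one survey")
    ref_sites = surveys[0].site_ids
    for s in surveys[1:]:
        if set(s.site_ids) != set(ref_sites):
            raise ValidationError(
                "surveys must share the same site set; "
                f"mismatch: {sorted(set(s.site_ids) ^ set(ref_sites))}"
            )
    species: list[str] = []
    for s in surveys:
        for sp in s.species_ids:
            if sp not in species:
                species.append(sp)
    merged = np.zeros((len(ref_sites), len(species)), dtype=np.int8)
    col = {sp: j for j, sp in enumerate(species)}
    for s in surveys:
        rows = [s.site_ids.index(site) for site in ref_sites]
        for j, sp in enumerate(s.species_ids):
            merged[:, col[sp]] |= s.incidence[rows, j]
    return OccurrenceMatrix(ref_sites, tuple(species), merged)


def drop_empty_sites(occ: OccurrenceMatrix) -> tuple[OccurrenceMatrix, list[str]]:
    """Remove sites where no species was recorded.

    Surveys can yield transects with no captures; these carry no pairwise
    information (every beta index is undefined against an empty site) and
    are excluded before any dissimilarity is computed. Returns the retained
    matrix and the list of removed site ids, so callers can subset their
    metadata/environment tables and log the exclusion.
    """
    sums = occ.richness()
    keep = [s for s, n in zip(occ.site_ids, sums) if n > 0]
    removed = [s for s, n in zip(occ.site_ids, sums) if n == 0]
    if not keep:
        raise ValidationError("all sites are empty; nothing to analyze")
    return occ.subset_sites(keep), removed


@dataclass
class RunManifest:
    """JSON-serializable record of a pipeline run's provenance."""

    inputs: dict = field(default_factory=dict)
    seed: int | None = None
    excluded_sites: list[str] = field(default_factory=list)
    removed_variables: list[str] = field(default_factory=list)
    decisions: dict = field(default_factory=dict)
    software_version: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
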