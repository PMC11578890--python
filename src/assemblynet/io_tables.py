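"""Tables of species traits and presence/absence occurrence.

This module owns the two tabular inputs of the pipeline — a species × trait
table with mixed column kinds (numeric, ordinal, categorical, binary) and a
binary species × unit incidence matrix, where a "unit" is whatever the
community scale dictates: a biogeographic region, a sampling site, a host
species or a host individual.  It also implements the community-selection
filters used to assemble component communities (host species pooling at
least ``min_fleas`` parasite species across a region) and infracommunities
(conspecific host individuals from one site and time).

Field data arrive as count matrices; counts are coerced to presence with a
warning because incidence is the quantity the downstream similarity uses.
Missing trait cells are tolerated (the Gower similarity handles them by
pairwise deletion); the permissive NA dialect is ``{"NA", "", "na", "NaN"}``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("assemblynet")

TRAIT_KINDS = frozenset({"numeric", "ordinal", "categorical", "binary"})

#: Community scales, from coarsest (species pooled over a whole realm) to
#: finest (fleas on individual hosts).
SCALES = (
    "realm_regions",
    "realm_hosts",
    "region_sites",
    "region_hosts",
    "component_sites",
    "infra_host_individuals",
)

NA_TOKENS = frozenset({"NA", "", "na", "NaN"})

#: Column layout of the per-community result report.
REPORT_COLUMNS = (
    "label",
    "scale",
    "n_species",
    "M",
    "WS",
    "BS",
    "n_func_modules",
    "n_cooc_modules",
    "DgM",
    "p",
    "process",
)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitTable:
    """Species × trait records with per-trait kind metadata.

    Parameters
    ----------
    data
        DataFrame indexed by species id.  numeric/ordinal columns are float
        (NaN = missing); categorical/binary columns are object dtype with
        NaN marking missing cells.
    kinds
        Mapping from trait name to one of :data:`TRAIT_KINDS`.
    """

    data: pd.DataFrame
    kinds: Mapping[str, str]

    def __post_init__(self) -> None:
        idx = self.data.index
        dups = idx[idx.duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate species ids: {dups}")
        if idx.isna().any() or (idx.astype(str) == "").any():
            raise ValueError("species ids must be non-empty")
        if self.data.shape[1] == 0:
            raise ValueError("trait table needs at least one trait column")
        unknown = set(self.kinds.values()) - TRAIT_KINDS
        if unknown:
            raise ValueError(f"unknown trait kinds: {sorted(unknown)}")
        missing = [c for c in self.data.columns if c not in self.kinds]
        if missing:
            raise ValueError(f"traits without a declared kind: {missing}")
        for col in self.data.columns:
            if self.kinds[col] in ("numeric", "ordinal"):
                vals = pd.to_numeric(self.data[col], errors="raise").to_numpy(float)
                ok = np.isnan(vals) | np.isfinite(vals)
                if not ok.all():
                    raise ValueError(f"non-finite value in numeric trait {col!r}")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a trait value is missing."""
        return self.data.isna()

    def subset(self, species: Sequence[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species absent from trait table: {missing}")
        return TraitTable(self.data.loc[list(species)], dict(self.kinds))


def read_trait_table(
    path: str | Path,
    kinds: Mapping[str, str],
    *,
    delimiter: str | None = None,
) -> TraitTable:
    """Read a delimited trait table (first column = species id).

    ``kinds`` declares every trait column's kind.  NA tokens and unparseable
    numeric cells become missing values.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    dups = raw.index[raw.index.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate species ids in {path.name}: {dups}")
    cols: dict[str, object] = {}
    for col in raw.columns:
        if col not in kinds:
            raise ValueError(f"trait {col!r} missing from schema")
        kind = kinds[col]
        if kind not in TRAIT_KINDS:
            raise ValueError(f"unknown trait kind {kind!r} for trait {col!r}")
        cells = raw[col].where(~raw[col].isin(NA_TOKENS), other=np.nan)
        if kind in ("numeric", "ordinal"):
            vals = pd.to_numeric(cells, errors="coerce")
            n_bad = int(cells.notna().sum() - vals.notna().sum())
            if n_bad:
                warnings.warn(
                    f"{n_bad} unparseable numeric cell(s) in trait {col!r} "
                    "treated as missing",
                    stacklevel=2,
                )
            cols[col] = vals.astype(float)
        else:
            cols[col] = cells.astype(object)
    data = pd.DataFrame(cols, index=raw.index)
    return TraitTable(data, dict(kinds))


def write_trait_table(
    table: TraitTable, path: str | Path, *, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    table.data.to_csv(path, sep=sep, na_rep="NA", index_label="species_id")


# ---------------------------------------------------------------------------
# Occurrence matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary species × unit incidence with a community-scale tag."""

    data: pd.DataFrame  # index species, columns units, values in {0, 1}
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        for axis, name in ((self.data.index, "species"), (self.data.columns, "unit")):
            dups = axis[axis.duplicated()].unique().tolist()
            if dups:
                raise ValueError(f"duplicate {name} ids: {dups}")
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occurrence cells must be 0 or 1")
        empty = self.data.index[vals.sum(axis=1) == 0].tolist()
        if empty:
            raise ValueError(f"species with no occurrences: {empty}")
        if self.data.dtypes.ne(np.int8).any():
            object.__setattr__(self, "data", self.data.astype(np.int8))

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def units(self) -> list[str]:
        return [str(u) for u in self.data.columns]

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)


def _binarize(df: pd.DataFrame, source: str) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError(f"negative count in {source}")
    n_counts = int(((vals > 0) & (vals != 1)).sum())
    if n_counts:
        warnings.warn(
            f"{n_counts} count cell(s) in {source} coerced to presence (1)",
            stacklevel=3,
        )
    return pd.DataFrame(
        (vals > 0).astype(np.int8), index=df.index, columns=df.columns
    )


def _drop_empty_species(df: pd.DataFrame, source: str) -> pd.DataFrame:
    empty = df.index[df.to_numpy().sum(axis=1) == 0].tolist()
    if empty:
        warnings.warn(
            f"dropping {len(empty)} species with no occurrences in {source}: "
            f"{empty}",
            stacklevel=3,
        )
        df = df.drop(index=empty)
    return df


def occurrence_from_counts(
    df: pd.DataFrame, scale: str, *, source: str = "matrix"
) -> OccurrenceMatrix:
    """Validate a raw (possibly count-valued) incidence frame.

    Counts are coerced to presence and species observed nowhere are dropped,
    both with warnings; empty units are retained (they carry no pairwise
    co-occurrence signal) but logged.
    """
    df = _binarize(df, source)
    df = _drop_empty_species(df, source)
    empty_units = df.columns[df.to_numpy().sum(axis=0) == 0].tolist()
    if empty_units:
        logger.info("%s: %d unit(s) with no species retained: %s",
                    source, len(empty_units), empty_units)
    return OccurrenceMatrix(df, scale)


def read_occurrence_matrix(
    path: str | Path, scale: str, *, delimiter: str | None = None
) -> OccurrenceMatrix:
    """Read a delimited species × unit matrix (rows species, columns units)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[vals.isna()].tolist()
        if bad:
            raise ValueError(
                f"non-numeric cell(s) in {path.name}, column {col!r}, rows {bad}"
            )
        num[col] = vals
    return occurrence_from_counts(num, scale, source=path.name)


def write_occurrence_matrix(
    occ: OccurrenceMatrix, path: str | Path, *, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    occ.data.to_csv(path, sep=sep, index_label="species_id")


# ---------------------------------------------------------------------------
# Community construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunitySet:
    """One community (at any scale) bound to the trait data of its species."""

    label: str
    occurrence: OccurrenceMatrix
    traits: TraitTable

    def __post_init__(self) -> None:
        missing = set(self.occurrence.species) - set(self.traits.species)
        if missing:
            raise ValueError(
                f"community {self.label!r}: species missing from trait table: "
                f"{sorted(missing)}"
            )

    @classmethod
    def from_global(
        cls, label: str, occurrence: OccurrenceMatrix, global_traits: TraitTable
    ) -> "CommunitySet":
        """Bind a community to the global trait table, subsetting its rows.

        A species present in the occurrence matrix but absent from the trait
        table is a hard error: silently dropping it would bias the
        within/between-module similarity summaries.
        """
        missing = [s for s in occurrence.species if s not in set(global_traits.species)]
        if missing:
            raise ValueError(
                f"community {label!r}: species missing from trait table: {missing}"
            )
        return cls(label, occurrence, global_traits.subset(occurrence.species))


def select_component_communities(
    host_matrices: Mapping[str, OccurrenceMatrix],
    global_traits: TraitTable,
    min_fleas: int = 8,
) -> list[CommunitySet]:
    """Retain host species whose pooled parasite richness is >= ``min_fleas``.

    ``host_matrices`` maps a host species label to its species × sampling-site
    incidence within one region.  Pooled regional richness is the number of
    parasite species occurring at any of the host's sites.
    """
    out = []
    for host in sorted(host_matrices):
        occ = host_matrices[host]
        if occ.n_species >= min_fleas:
            out.append(CommunitySet.from_global(host, occ, global_traits))
    return out


def select_infracommunities(
    group_matrices: Mapping[tuple, OccurrenceMatrix],
    global_traits: TraitTable,
    min_fleas: int = 6,
) -> list[CommunitySet]:
    """Retain (host species, site[, time]) groups with richness >= ``min_fleas``.

    Each group's matrix is parasite species × host individuals for
    conspecific hosts captured at the same site at the same time.
    """
    out = []
    for key in sorted(group_matrices):
        occ = group_matrices[key]
        if occ.n_species >= min_fleas:
            label = "/".join(str(k) for k in key)
            out.append(CommunitySet.from_global(label, occ, global_traits))
    return out


# ---------------------------------------------------------------------------
# Result report
# ---------------------------------------------------------------------------


def results_to_frame(rows: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Assemble per-community result rows into the flat report layout."""
    frame = pd.DataFrame(list(rows))
    missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"result rows lack report columns: {missing}")
    return frame.loc[:, list(REPORT_COLUMNS)]


def write_report(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    results_to_frame(rows).to_csv(Path(path), index=False, na_rep="NA")
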