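"""Species × species similarity matrices weighting the two networks.

Functional similarity is 1 − Gower distance over mixed-type traits: numeric
and ordinal traits contribute range-normalized absolute differences,
categorical and binary traits contribute a 0/1 mismatch, and a trait missing
in either species of a pair is skipped (pairwise deletion).  Ordinal traits
are rank-transformed before range normalization.

Co-occurrence similarity is 1 − binary Bray–Curtis (Sørensen) dissimilarity:
for a species pair sharing a units, with b and c units exclusive to each,
similarity = 2a / (2a + b + c).

Both matrices live in [0, 1], are symmetric with unit diagonal, and their
entries become the edge weights of the functional and co-occurrence
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io_tables import OccurrenceMatrix, TraitTable

SIM_KINDS = ("functional", "cooccurrence")


@dataclass(frozen=True)
class SimilarityMatrix:
    species: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SIM_KINDS:
            raise ValueError(f"kind must be one of {SIM_KINDS}")
        v = self.values
        n = len(self.species)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match species")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        if not (np.diag(v) == 1.0).all():
            raise ValueError("similarity diagonal must be exactly 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index_label="species_id")


def _trait_columns(table: TraitTable) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Per trait: (values, missing mask, is_categorical).

    Numeric traits are passed through; ordinal traits are replaced by average
    ranks of their non-missing values so that only the ordering matters.
    """
    cols = []
    for name in table.traits:
        kind = table.kinds[name]
        col = table.data[name]
        miss = col.isna().to_numpy()
        if kind in ("numeric", "ordinal"):
            x = col.to_numpy(dtype=float)
            if kind == "ordinal" and (~miss).any():
                r = np.full(x.shape, np.nan)
                r[~miss] = rankdata(x[~miss], method="average")
                x = r
            cols.append((x, miss, False))
        else:
            cols.append((col.to_numpy(dtype=object), miss, True))
    return cols


def gower_similarity(table: TraitTable) -> SimilarityMatrix:
    """Gower similarity (1 − Gower distance) over a mixed trait table.

    The Gower distance of a species pair is the mean, over traits non-missing
    in both species, of the per-trait dissimilarity: |x_i − x_j| / range for
    numeric/ordinal traits (a zero-range trait contributes 0), and a 0/1
    mismatch for categorical/binary traits.  A pair sharing no non-missing
    trait is a hard error.
    """
    n = table.n_species
    if n < 2:
        raise ValueError("need at least 2 species for Gower similarity")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for x, miss, is_cat in _trait_columns(table):
        avail = np.outer(~miss, ~miss)
        if is_cat:
            xo = x.astype(object)
            diff = (xo[:, None] != xo[None, :]).astype(float)
        else:
            rng = np.nanmax(x) - np.nanmin(x) if (~miss).any() else 0.0
            if rng > 0:
                with np.errstate(invalid="ignore"):
                    diff = np.abs(x[:, None] - x[None, :]) / rng
            else:
                diff = np.zeros((n, n))
        num += np.where(avail, np.nan_to_num(diff), 0.0)
        den += avail
    bad = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            "species pair with no shared non-missing trait: "
            f"({table.species[i]!r}, {table.species[j]!r})"
        )
    np.fill_diagonal(den, 1.0)  # diagonal distance is 0 regardless
    np.fill_diagonal(num, 0.0)
    sim = 1.0 - num / den
    sim = np.clip(sim, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(tuple(table.species), sim, "functional")


def gower_distance(table: TraitTable) -> np.ndarray:
    """Gower distance matrix (1 − similarity); convenience for simulators."""
    return 1.0 - gower_similarity(table).values


def cooccurrence_similarity(occ: OccurrenceMatrix) -> SimilarityMatrix:
    """Sørensen similarity 2a/(2a+b+c) between species' unit sets.

    Equals 1 − binary Bray–Curtis dissimilarity.  Species with no
    occurrences must have been removed upstream (OccurrenceMatrix enforces
    this), so the denominator is always positive.
    """
    if occ.n_species < 2:
        raise ValueError("need at least 2 species for co-occurrence similarity")
    x = occ.values().astype(bool)
    if (~x.any(axis=1)).any():
        raise ValueError("occurrence matrix contains an all-zero species row")
    # Dice dissimilarity is exactly (b + c) / (2a + b + c)
    dist = squareform(pdist(x, metric="dice"))
    sim = 1.0 - dist
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(tuple(occ.species), sim, "cooccurrence")
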