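"""Functional group detection by best partitioning of trait space.

Each species' row of the functional similarity matrix is treated as its
coordinate vector.  A Ward-linkage hierarchical clustering of these rows is
cut at every candidate number of groups k, each cut is scored by a panel of
internal cluster-validity indices, and the k winning the majority vote is
returned (ties broken toward smaller k).  The detected clusters are the
functional modules ("functional groups"); the partition is computed once on
the full species pool and then *restricted* to each community's species,
never re-fitted per community.

Two Ward variants are supported: ``"ward_d2"`` runs scipy's Ward linkage on
Euclidean distances directly (R hclust's ward.D2), while the default
``"ward_d"`` runs the same linkage on square-root-transformed distances,
which reproduces the merge tree of hclust's ward.D applied to the raw
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .similarity import SimilarityMatrix

PARTITION_KINDS = ("functional", "cooccurrence")

#: Default validity-index panel for the majority vote.
DEFAULT_INDICES = ("silhouette", "calinski_harabasz", "davies_bouldin", "dunn", "c_index")


@dataclass(frozen=True)
class Partition:
    """Assignment of species to modules.

    Module labels are contiguous integers 0..n_modules-1, numbered by first
    appearance in the species order.  ``modularity`` is set only for
    co-occurrence partitions (the Louvain Q value).
    """

    assignment: Mapping[str, int]
    kind: str

    modularity: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PARTITION_KINDS:
            raise ValueError(f"kind must be one of {PARTITION_KINDS}")
        if not self.assignment:
            raise ValueError("empty partition")
        labels = sorted(set(self.assignment.values()))
        if labels != list(range(len(labels))):
            raise ValueError("module labels must be contiguous 0..k-1")

    @property
    def species(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_species(self) -> int:
        return len(self.assignment)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, species: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[s] for s in species], dtype=int)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sp, m in self.assignment.items():
            out.setdefault(m, []).append(sp)
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species_id": list(self.assignment), "module": list(self.assignment.values())}
        ).to_csv(Path(path), index=False)


def _contiguous(species: Sequence[str], raw_labels: Sequence[int]) -> dict[str, int]:
    remap: dict[int, int] = {}
    out = {}
    for sp, lab in zip(species, raw_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[sp] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# Validity indices (higher_is_better flag per index)
# ---------------------------------------------------------------------------


def _dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    ks = np.unique(labels)
    max_diam = 0.0
    for k in ks:
        members = labels == k
        if members.sum() > 1:
            max_diam = max(max_diam, dist[np.ix_(members, members)].max())
    min_sep = np.inf
    for i, a in enumerate(ks):
        for b in ks[i + 1 :]:
            min_sep = min(min_sep, dist[np.ix_(labels == a, labels == b)].min())
    if max_diam == 0.0:
        return np.inf  # perfectly compact clusters
    return min_sep / max_diam


def _c_index(cum: np.ndarray, dist: np.ndarray, labels: np.ndarray) -> float:
    within = labels[:, None] == labels[None, :]
    iu = np.triu_indices_from(dist, k=1)
    mask = within[iu]
    n_w = int(mask.sum())
    if n_w == 0:
        return np.nan
    s = dist[iu][mask].sum()
    s_min = cum[n_w - 1]
    s_max = cum[-1] - (cum[-1 - n_w] if n_w < len(cum) else 0.0)
    if s_max == s_min:
        return np.nan
    return (s - s_min) / (s_max - s_min)


_HIGHER_BETTER = {
    "silhouette": True,
    "calinski_harabasz": True,
    "davies_bouldin": False,
    "dunn": True,
    "c_index": False,
}


def best_partition_traits(
    fsim: SimilarityMatrix,
    k_range: Sequence[int] | None = None,
    indices: Sequence[str] = DEFAULT_INDICES,
    *,
    linkage_variant: str = "ward_d",
) -> Partition:
    """Cluster trait space and pick the number of groups by majority vote.

    Each validity index votes for the k it scores best (per-index ties go to
    the smaller k); the k with the most votes wins, overall ties again
    resolved toward smaller k.  Degenerate input (all species identical)
    yields a single module with a warning.
    """
    if fsim.kind != "functional":
        raise ValueError("best_partition_traits expects a functional similarity matrix")
    n = fsim.n_species
    if n < 3:
        raise ValueError("too few species to partition (need >= 3)")
    unknown = set(indices) - set(_HIGHER_BETTER)
    if unknown:
        raise ValueError(f"unknown validity indices: {sorted(unknown)}")

    coords = fsim.values
    cond = pdist(coords, metric="euclidean")
    if not cond.any():
        warnings.warn("all species have identical trait profiles; single module",
                      stacklevel=2)
        return Partition({s: 0 for s in fsim.species}, "functional")
    if linkage_variant == "ward_d":
        link_input = np.sqrt(cond)
    elif linkage_variant == "ward_d2":
        link_input = cond
    else:
        raise ValueError("linkage_variant must be 'ward_d' or 'ward_d2'")
    Z = linkage(link_input, method="ward")

    ks = list(k_range) if k_range is not None else list(range(2, min(25, n - 1) + 1))
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k (need 2 <= k <= n-1)")

    dist = squareform(cond)
    dsorted = np.sort(cond)
    cum = np.cumsum(dsorted)

    labels_by_k = {k: cut_tree(Z, n_clusters=k).ravel() for k in ks}
    scores = {name: {} for name in indices}
    for k in ks:
        lab = labels_by_k[k]
        for name in indices:
            if name == "silhouette":
                val = silhouette_score(coords, lab, metric="euclidean")
            elif name == "calinski_harabasz":
                val = calinski_harabasz_score(coords, lab)
            elif name == "davies_bouldin":
                val = davies_bouldin_score(coords, lab)
            elif name == "dunn":
                val = _dunn_index(dist, lab)
            else:
                val = _c_index(cum, dist, lab)
            scores[name][k] = val

    votes: dict[int, int] = {k: 0 for k in ks}
    for name in indices:
        vals = scores[name]
        valid = {k: v for k, v in vals.items() if not np.isnan(v)}
        if not valid:
            continue  # index uninformative on this dataset
        best = (max if _HIGHER_BETTER[name] else min)(valid.values())
        k_best = min(k for k, v in valid.items() if v == best)
        votes[k_best] += 1
    top = max(votes.values())
    k_win = min(k for k, v in votes.items() if v == top)
    return Partition(_contiguous(fsim.species, labels_by_k[k_win]), "functional")


# ---------------------------------------------------------------------------
# Module similarity summaries and restriction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleSimilaritySummary:
    """Mean pairwise functional similarity within (WS) and between (BS) modules.

    A component with no contributing pairs (WS for all-singleton partitions,
    BS for a single module) is NaN, never silently zero.
    """

    ws: float
    bs: float


def within_between_similarity(
    partition: Partition, fsim: SimilarityMatrix
) -> ModuleSimilaritySummary:
    if set(partition.species) != set(fsim.species):
        raise ValueError("partition and similarity matrix cover different species")
    lab = partition.labels_for(fsim.species)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(fsim.n_species, k=1)
    vals = fsim.values[iu]
    mask = same[iu]
    ws = float(vals[mask].mean()) if mask.any() else float("nan")
    bs = float(vals[~mask].mean()) if (~mask).any() else float("nan")
    return ModuleSimilaritySummary(ws=ws, bs=bs)


def restrict_partition(partition: Partition, species: Sequence[str]) -> Partition:
    """Restrict a global partition to a community's species.

    Only modules containing at least one community species survive; labels
    are recompacted but co-membership is preserved.
    """
    missing = [s for s in species if s not in partition.assignment]
    if missing:
        raise KeyError(f"species not in global partition: {missing}")
    raw = [partition.assignment[s] for s in species]
    return Partition(_contiguous(species, raw), partition.kind)
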