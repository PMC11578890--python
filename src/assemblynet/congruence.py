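"""Congruence between functional and co-occurrence partitions (Dg_M).

For each functional group g with n_g >= 2 species, the diversity of its
members' co-occurrence-module memberships is the normalized Shannon entropy

    Dg = -sum_k (n_gk / n_g) ln(n_gk / n_g) / ln(n_g)

where n_gk counts group members in co-occurrence module k.  Dg is 0 when
all members share one co-occurrence module and 1 when every member sits in
a different one.  Dg_M is the mean of Dg over non-singleton functional
groups (singletons are vacuously concentrated and would bias the average
toward filtering; they can be included as zeros for sensitivity analysis).

Significance comes from a constrained null model: the functional partition
and the co-occurrence module-size vector are held fixed while species are
randomly permuted among co-occurrence modules; Dg_M is recomputed for each
of n_null (default 999) replicates.  With p = (# null values strictly below
the observed Dg_M) / n_null, the inferred assembly process is
environmental/host-associated filtering when p < 0.05, limiting
similarity/competition when p > 0.95, and stochastic (or no clear dominance
of either deterministic process) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cooccurrence_modules import build_graph, louvain_modules
from .functional_modules import (
    Partition,
    best_partition_traits,
    restrict_partition,
    within_between_similarity,
)
from .io_tables import CommunitySet
from .similarity import cooccurrence_similarity, gower_similarity

PROCESSES = ("filtering", "limiting_similarity", "stochastic", "undefined")


def _aligned_labels(func: Partition, cooc: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(func.species) != set(cooc.species):
        raise ValueError("partitions cover different species sets")
    species = func.species
    return func.labels_for(species), cooc.labels_for(species)


def _dgm_from_labels(
    f: np.ndarray, c: np.ndarray, n_f: int, n_c: int, include_singletons: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-group Dg, group sizes, and their mean; NaN mean if no group counts."""
    counts = np.bincount(f * n_c + c, minlength=n_f * n_c).reshape(n_f, n_c)
    ng = counts.sum(axis=1)
    # H = ln(ng) - sum(n_gk ln n_gk)/ng; exact 0 / ln(ng) at the boundaries
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = np.where(counts > 0, counts * np.log(counts), 0.0).sum(axis=1)
        log_ng = np.log(np.maximum(ng, 1))
        h = log_ng - inner / np.maximum(ng, 1)
        dg = np.where(ng > 1, h / np.where(log_ng > 0, log_ng, 1.0), 0.0)
    use = ng >= 1 if include_singletons else ng >= 2
    if not use.any():
        return dg, ng, float("nan")
    return dg, ng, float(dg[use].mean())


def module_diversity(
    func: Partition,
    cooc: Partition,
    *,
    include_singletons: bool = False,
) -> tuple[dict[int, float], float]:
    """Per-functional-group Dg values and their average Dg_M.

    Groups of a single species are excluded from the average by default
    (``include_singletons=True`` counts them as Dg = 0).  If every group is
    a singleton the result is NaN — undefined, not zero.
    """
    f, c = _aligned_labels(func, cooc)
    dg, ng, dgm = _dgm_from_labels(
        f, c, func.n_modules, cooc.n_modules, include_singletons
    )
    per_group = {g: float(dg[g]) for g in range(func.n_modules) if ng[g] >= 2}
    return per_group, dgm


def null_distribution(
    func: Partition,
    cooc: Partition,
    n_null: int = 999,
    seed: int = 0,
    *,
    include_singletons: bool = False,
) -> np.ndarray:
    """Null Dg_M sample under random species placement among co-occurrence modules.

    Each replicate permutes the species labels against the fixed
    co-occurrence module-size vector (the functional partition is untouched)
    and recomputes Dg_M.  Replicate r draws from its own seed-derived stream,
    so values do not depend on evaluation order.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    f, c = _aligned_labels(func, cooc)
    n = len(f)
    out = np.empty(n_null)
    children = np.random.SeedSequence(seed).spawn(n_null)
    for r in range(n_null):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(n)
        _, _, out[r] = _dgm_from_labels(
            f, c[perm], func.n_modules, cooc.n_modules, include_singletons
        )
    return out


def infer_process(
    observed: float,
    null_values: Sequence[float],
    lower: float = 0.05,
    upper: float = 0.95,
) -> tuple[float, str]:
    """One-sided rank of the observed Dg_M in the null sample, and the verdict.

    p is the proportion of null values *strictly* below the observed value.
    p < ``lower`` → filtering (co-occurring species more trait-similar than
    chance); p > ``upper`` → limiting similarity; otherwise stochastic.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null sample")
    if math.isnan(observed):
        return float("nan"), "undefined"
    p = float(np.mean(null_values < observed))
    if p < lower:
        process = "filtering"
    elif p > upper:
        process = "limiting_similarity"
    else:
        process = "stochastic"
    return p, process


# ---------------------------------------------------------------------------
# Per-community pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CongruenceResult:
    """One community's row of the congruence report."""

    label: str
    scale: str
    n_species: int
    modularity: float
    ws: float
    bs: float
    n_func_modules: int
    n_cooc_modules: int
    dgm: float
    p: float
    process: str
    dg_per_group: dict[int, float] = field(default_factory=dict, repr=False)
    null_values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_row(self) -> dict[str, object]:
        return {
            "label": self.label,
            "scale": self.scale,
            "n_species": self.n_species,
            "M": self.modularity,
            "WS": self.ws,
            "BS": self.bs,
            "n_func_modules": self.n_func_modules,
            "n_cooc_modules": self.n_cooc_modules,
            "DgM": self.dgm,
            "p": self.p,
            "process": self.process,
        }


def analyze_community(
    community: CommunitySet,
    global_functional: Partition,
    *,
    seed: int = 0,
    n_null: int = 999,
    restarts: int = 10,
    lower: float = 0.05,
    upper: float = 0.95,
    include_singletons: bool = False,
) -> CongruenceResult:
    """Full congruence analysis of one community.

    The community's co-occurrence network is built and partitioned by
    Louvain; the supplied global functional partition is restricted to the
    community's species (modules without community members are dropped);
    Dg_M, its null distribution, p and the inferred process follow.
    WS/BS are computed on the functional similarity of the community's own
    trait rows.
    """
    occ = community.occurrence
    csim = cooccurrence_similarity(occ)
    g = build_graph(csim)
    cooc = louvain_modules(g, seed=seed, restarts=restarts)
    func = restrict_partition(global_functional, occ.species)
    fsim = gower_similarity(community.traits)
    summary = within_between_similarity(func, fsim)
    per_group, dgm = module_diversity(func, cooc, include_singletons=include_singletons)
    nulls = null_distribution(
        func, cooc, n_null=n_null, seed=seed, include_singletons=include_singletons
    )
    p, process = infer_process(dgm, nulls, lower=lower, upper=upper)
    return CongruenceResult(
        label=community.label,
        scale=occ.scale,
        n_species=occ.n_species,
        modularity=cooc.modularity,
        ws=summary.ws,
        bs=summary.bs,
        n_func_modules=func.n_modules,
        n_cooc_modules=cooc.n_modules,
        dgm=dgm,
        p=p,
        process=process,
        dg_per_group=per_group,
        null_values=nulls,
    )


def analyze_standalone(
    community: CommunitySet,
    *,
    seed: int = 0,
    n_null: int = 999,
    restarts: int = 10,
    k_range: Sequence[int] | None = None,
    lower: float = 0.05,
    upper: float = 0.95,
) -> CongruenceResult:
    """Analyze a community whose species pool *is* the whole dataset.

    Fits the functional partition on the community's own trait table (no
    wider species pool to restrict from) and then proceeds as
    :func:`analyze_community`.
    """
    fsim = gower_similarity(community.traits)
    func = best_partition_traits(fsim, k_range=k_range)
    return analyze_community(
        community,
        func,
        seed=seed,
        n_null=n_null,
        restarts=restarts,
        lower=lower,
        upper=upper,
    )
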