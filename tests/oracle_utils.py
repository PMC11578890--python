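"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from the defining formulas with
plain Python loops, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np


def gower_oracle(
    columns: Sequence[tuple[list, str]],
) -> np.ndarray:
    """Gower distance matrix from (values, kind) columns; None marks missing.

    Ordinal columns are converted to average ranks of non-missing values
    first; numeric/ordinal contributions are |x_i - x_j| / range over the
    whole column (0 for a zero-range column), categorical/binary a 0/1
    mismatch.  Traits missing in either member of a pair are skipped.
    """
    prepared = []
    for values, kind in columns:
        if kind == "ordinal":
            present = sorted((v, i) for i, v in enumerate(values) if v is not None)
            ranks: dict[int, float] = {}
            i = 0
            while i < len(present):
                j = i
                while j < len(present) and present[j][0] == present[i][0]:
                    j += 1
                avg = (i + 1 + j) / 2.0  # average of ranks i+1 .. j
                for _, idx in present[i:j]:
                    ranks[idx] = avg
                i = j
            values = [ranks.get(i) for i in range(len(values))]
            kind = "numeric"
        prepared.append((values, kind))

    n = len(prepared[0][0])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total, used = 0.0, 0
            for values, kind in prepared:
                vi, vj = values[i], values[j]
                if vi is None or vj is None:
                    continue
                used += 1
                if kind in ("numeric",):
                    obs = [v for v in values if v is not None]
                    rng = max(obs) - min(obs)
                    total += abs(vi - vj) / rng if rng > 0 else 0.0
                else:
                    total += 0.0 if vi == vj else 1.0
            if used == 0:
                raise ValueError(f"pair ({i}, {j}) shares no trait")
            dist[i, j] = dist[j, i] = total / used
    return dist


def sorensen_oracle(x: np.ndarray) -> np.ndarray:
    """Similarity 2a/(2a+b+c) from explicit per-pair set counts."""
    n = x.shape[0]
    sim = np.eye(n)
    sets = [set(np.flatnonzero(row)) for row in np.asarray(x, dtype=bool)]
    for i in range(n):
        for j in range(i + 1, n):
            a = len(sets[i] & sets[j])
            b = len(sets[i] - sets[j])
            c = len(sets[j] - sets[i])
            sim[i, j] = sim[j, i] = 2 * a / (2 * a + b + c)
    return sim


def modularity_oracle(weights: np.ndarray, labels: Sequence[int]) -> float:
    """Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j), full double sum."""
    a = np.asarray(weights, dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(n: int) -> Iterator[list[int]]:
    """All partitions of n items as restricted-growth label strings."""
    labels = [0] * n

    def rec(i: int, used_max: int) -> Iterator[list[int]]:
        if i == n:
            yield list(labels)
            return
        for lab in range(used_max + 2):
            labels[i] = lab
            yield from rec(i + 1, max(used_max, lab))

    if n == 0:
        yield []
    else:
        yield from rec(1, 0)


def exhaustive_best_modularity(weights: np.ndarray) -> float:
    """Maximum Q over all partitions of the nodes (feasible for n <= 8)."""
    best = -math.inf
    for labels in set_partitions(weights.shape[0]):
        best = max(best, modularity_oracle(weights, labels))
    return best


def dgm_oracle(func_labels: Sequence[int], cooc_labels: Sequence[int]) -> float:
    """Mean normalized Shannon diversity over non-singleton functional groups."""
    groups: dict[int, list[int]] = {}
    for f, c in zip(func_labels, cooc_labels):
        groups.setdefault(f, []).append(c)
    dgs = []
    for members in groups.values():
        ng = len(members)
        if ng < 2:
            continue
        counts: dict[int, int] = {}
        for c in members:
            counts[c] = counts.get(c, 0) + 1
        h = -sum((m / ng) * math.log(m / ng) for m in counts.values())
        dgs.append(h / math.log(ng))
    if not dgs:
        return float("nan")
    return sum(dgs) / len(dgs)
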