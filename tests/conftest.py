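import numpy as np
import pandas as pd
import pytest

from assemblynet import OccurrenceMatrix, TraitTable


@pytest.fixture
def small_traits() -> TraitTable:
    data = pd.DataFrame(
        {
            "bodysize": [2.0, 7.0, 4.5],
            "microhabitat": ["hair", "hair", "nest"],
        },
        index=["spA", "spB", "spC"],
    )
    return TraitTable(data, {"bodysize": "numeric", "microhabitat": "categorical"})


@pytest.fixture
def small_occurrence() -> OccurrenceMatrix:
    data = pd.DataFrame(
        [[1, 1, 1, 0], [0, 1, 1, 1], [1, 0, 0, 0], [0, 0, 1, 1]],
        index=["spA", "spB", "spC", "spD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return OccurrenceMatrix(data, "component_sites")


def make_blob_traits(
    n_per_blob: int, n_blobs: int = 2, noise: float = 0.2, seed: int = 0
) -> TraitTable:
    """Well-separated trait blobs: numeric traits near per-blob centres plus a
    blob-specific categorical level; ground truth is the blob label."""
    rng = np.random.default_rng(seed)
    rows, idx = [], []
    for b in range(n_blobs):
        centre = 10.0 * b
        for i in range(n_per_blob):
            rows.append(
                {
                    "x": centre + rng.normal(0, noise),
                    "y": centre + rng.normal(0, noise),
                    "habitat": f"h{b}",
                }
            )
            idx.append(f"b{b}_{i}")
    data = pd.DataFrame(rows, index=idx)
    return TraitTable(
        data, {"x": "numeric", "y": "numeric", "habitat": "categorical"}
    )


def random_trait_table(rng: np.random.Generator, n: int = 8) -> TraitTable:
    """Random mixed-type table with missing cells; first column fully observed
    so every pair shares at least one trait."""
    data = pd.DataFrame(
        {
            "num1": rng.normal(size=n) * rng.uniform(0.5, 20),
            "num2": rng.uniform(-5, 5, size=n),
            "ordn": rng.integers(0, 4, size=n).astype(float),
            "cat": pd.array(rng.choice(list("abc"), size=n), dtype=object),
            "bin": pd.array(rng.choice(["0", "1"], size=n), dtype=object),
        },
        index=[f"s{i}" for i in range(n)],
    )
    kinds = {
        "num1": "numeric",
        "num2": "numeric",
        "ordn": "ordinal",
        "cat": "categorical",
        "bin": "binary",
    }
    for col in ("num2", "ordn", "cat", "bin"):
        mask = rng.random(n) < 0.15
        data.loc[mask, col] = np.nan
    return TraitTable(data, kinds)


def random_occurrence(rng: np.random.Generator, n: int = 6, u: int = 8) -> OccurrenceMatrix:
    while True:
        x = (rng.random((n, u)) < 0.4).astype(np.int8)
        if (x.sum(axis=1) > 0).all():
            break
    data = pd.DataFrame(
        x, index=[f"s{i}" for i in range(n)], columns=[f"u{j}" for j in range(u)]
    )
    return OccurrenceMatrix(data, "component_sites")
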