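"""Independent brute-force average-linkage oracle for the clustering tests.

Pure-Python recomputation of greedy average-linkage agglomeration with the
unmergeable-pair constraint: at every step all cluster-pair average distances
are recomputed from the raw matrix with explicit loops; a pair containing any
unlinked (infinite-distance) genome pair is never merged. Ties break on the
lexicographically smallest member ids. Shares no code with the package's
implementation.
"""

import itertools
import math

import numpy as np
import pandas as pd


def oracle_average_linkage(dist_df: pd.DataFrame, cut: float) -> set[frozenset[str]]:
    clusters = [frozenset([g]) for g in dist_df.index]
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(clusters, 2):
            vals = [float(dist_df.loc[x, y]) for x in a for y in b]
            if any(math.isinf(v) for v in vals):
                continue
            d = sum(vals) / len(vals)
            if d <= cut:
                lo, hi = sorted([min(a), min(b)])
                candidates.append((d, lo, hi, a, b))
        if not candidates:
            break
        _, _, _, a, b = min(candidates, key=lambda t: t[:3])
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return set(clusters)


def random_small_matrix(seed: int):
    """A simulator-style random ANI matrix of <= 8 genomes, with occasional
    unlinked pairs (aligned fraction dropped below the filter)."""
    from scdispense import simulate_ani_matrix

    rng = np.random.default_rng(seed)
    n_lineages = int(rng.integers(1, 5))
    sizes = [int(rng.integers(1, 4)) for _ in range(n_lineages)]
    while sum(sizes) > 8:
        sizes[np.argmax(sizes)] -= 1
    sim = simulate_ani_matrix(
        n_lineages,
        sizes,
        within_ani_low=float(rng.uniform(99.9, 99.98)),
        between_ani=float(rng.uniform(95.0, 98.7)),
        between_ani_jitter=float(rng.uniform(0.0, 0.5)),
        aligned_fraction=float(rng.uniform(80.0, 95.0)),
        seed=int(rng.integers(2**31)),
        lineages_per_strain=int(rng.integers(1, 3)),
    )
    # knock a few pairs below the aligned-fraction filter
    ids = sim.genome_ids
    for _ in range(int(rng.integers(0, 4))):
        i, j = rng.integers(0, len(ids), size=2)
        if i != j:
            sim.aligned_fraction.iloc[i, j] = 40.0
            sim.aligned_fraction.iloc[j, i] = 40.0
    return sim
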