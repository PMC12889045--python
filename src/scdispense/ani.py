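"""Strain- and lineage-level clustering of isolate genomes by ANI.

Pairwise average-nucleotide-identity (ANI) and aligned-fraction tables, as
produced upstream by whole-genome aligners (nucmer/dnadiff-style output), are
filtered and clustered:

* genomes with contamination > 90% or completeness < 50% are dropped;
* pairs whose aligned fraction falls below a minimum (75% for isolate-vs-
  isolate comparisons) are treated as *unlinked* — their ANI is considered
  spurious and the pair can never be merged, at any threshold;
* the remaining genomes are agglomerated with average linkage on the
  distance 100 - ANI, cut at 99% ANI for strain-level groups and at 99.9%
  ANI for lineage-level groups (a pair at exactly the threshold merges);
* each lineage is called *novel* when its best qualifying reference ANI
  (aligned fraction >= 50%) is below 99%.

Asymmetric input ANI is symmetrized by averaging the two directions. The
unlinked constraint is propagated through the agglomeration: a candidate
merge is forbidden if *any* member pair across the two clusters is unlinked,
rather than entering an arbitrary large distance into the averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNLINKED = math.inf

STRAIN_ANI = 99.0
LINEAGE_ANI = 99.9
SELF_MIN_ALIGNED_FRACTION = 75.0
REF_MIN_ALIGNED_FRACTION = 50.0
CONTAMINATION_MAX = 90.0
COMPLETENESS_MIN = 50.0


def qc_filter(
    quality: pd.DataFrame,
    contamination_max: float = CONTAMINATION_MAX,
    completeness_min: float = COMPLETENESS_MIN,
) -> tuple[list[str], list[str]]:
    """Drop genomes with contamination > 90% or completeness < 50%.

    ``quality`` needs columns ``genome_id, completeness, contamination``
    (percent). Boundary values are kept — the thresholds are strict
    inequalities. Returns ``(kept_ids, dropped_ids)`` in input order.
    """
    needed = {"genome_id", "completeness", "contamination"}
    missing = needed - set(quality.columns)
    if missing:
        raise ValueError(f"quality table missing columns: {sorted(missing)}")
    if quality["genome_id"].duplicated().any():
        dupes = quality.loc[quality["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome ids in quality table: {dupes}")
    bad = (quality["contamination"] > contamination_max) | (
        quality["completeness"] < completeness_min
    )
    return (
        quality.loc[~bad, "genome_id"].tolist(),
        quality.loc[bad, "genome_id"].tolist(),
    )


def _as_square(df: pd.DataFrame, ids: list[str], what: str) -> np.ndarray:
    missing = set(ids) - set(df.index)
    if missing:
        raise ValueError(f"genomes absent from {what} matrix: {sorted(missing)}")
    return df.loc[ids, ids].to_numpy(dtype=float)


def build_distance(
    ani: pd.DataFrame,
    aligned_fraction: pd.DataFrame,
    genome_ids: list[str] | None = None,
    min_aligned_fraction: float = SELF_MIN_ALIGNED_FRACTION,
) -> pd.DataFrame:
    """Symmetric distance matrix ``100 - ANI`` with an unlinked sentinel.

    ANI and aligned fraction are symmetrized by averaging the two directions
    of the (possibly asymmetric) input. Pairs whose symmetrized aligned
    fraction falls below ``min_aligned_fraction`` get distance ``inf``
    (unlinked: never merged at any cut). The diagonal is 0.
    """
    ids = sorted(genome_ids if genome_ids is not None else ani.index)
    a = _as_square(ani, ids, "ANI")
    f = _as_square(aligned_fraction, ids, "aligned-fraction")
    if np.isnan(a).any() or np.isnan(f).any():
        raise ValueError("missing pairwise values in ANI/aligned-fraction input")
    a_sym = (a + a.T) / 2.0
    f_sym = (f + f.T) / 2.0
    dist = 100.0 - a_sym
    dist[f_sym < min_aligned_fraction] = UNLINKED
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=ids, columns=ids)


def cluster(distance: pd.DataFrame, ani_threshold: float) -> list[frozenset[str]]:
    """Average-linkage agglomeration cut at ``100 - ani_threshold``.

    Clusters merge while the average pairwise distance between them is at
    most the cut (a pair at exactly the threshold ANI merges). Any candidate
    merge containing an unlinked member pair is forbidden. Ties are broken
    deterministically by the lexicographically smallest genome ids of the two
    clusters, so the result is invariant to input order.

    Returns the partition as a list of frozensets, ordered by each cluster's
    smallest member.
    """
    cut = 100.0 - ani_threshold
    ids = sorted(distance.index)
    n = len(ids)
    d = distance.loc[ids, ids].to_numpy(dtype=float)
    if not np.allclose(
        np.where(np.isinf(d), -1.0, d), np.where(np.isinf(d.T), -1.0, d.T)
    ):
        raise ValueError("distance matrix must be symmetric")

    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                block = d[np.ix_(clusters[a], clusters[b])]
                if np.isinf(block).any():
                    continue  # unlinked pair somewhere: unmergeable
                avg = float(block.mean())
                if avg > cut:
                    continue
                key = (avg, ids[clusters[a][0]], ids[clusters[b][0]])
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    out = [frozenset(ids[i] for i in c) for c in clusters]
    return sorted(out, key=lambda s: min(s))


def novelty_call(
    best_ref_ani: float | None,
    threshold: float = STRAIN_ANI,
) -> str:
    """Novelty of a lineage given its best qualifying reference ANI.

    Returns ``"novel"`` when the best reference ANI is strictly below the
    threshold, ``"known"`` at or above it, and ``"no_reference"`` when no
    qualifying reference comparison exists.
    """
    if best_ref_ani is None or (isinstance(best_ref_ani, float) and math.isnan(best_ref_ani)):
        return "no_reference"
    return "novel" if best_ref_ani < threshold else "known"


@dataclass(frozen=True)
class ClusterAssignment:
    """Strain/lineage labels per genome plus per-lineage novelty calls.

    ``assignments`` has one row per genome: ``genome_id, strain_id,
    lineage_id, best_ref_ani, novelty``. The lineage partition refines the
    strain partition.
    """

    assignments: pd.DataFrame
    n_strains: int
    n_lineages: int
    dropped_genomes: list[str]
    refinement_splits: int = 0

    @property
    def n_novel(self) -> int:
        per_lineage = self.assignments.drop_duplicates("lineage_id")
        return int((per_lineage["novelty"] == "novel").sum())

    def lineage_members(self) -> dict[str, list[str]]:
        return {
            lid: sorted(sub["genome_id"])
            for lid, sub in self.assignments.groupby("lineage_id")
        }

    def summary(self) -> str:
        lines = [
            "ANI strain/lineage clustering",
            "=" * 29,
            f"genomes clustered:  {len(self.assignments)}"
            + (f" ({len(self.dropped_genomes)} dropped by QC)" if self.dropped_genomes else ""),
            f"strains  (ANI >= {STRAIN_ANI}%):  {self.n_strains}",
            f"lineages (ANI >= {LINEAGE_ANI}%): {self.n_lineages}",
            f"novel lineages (best ref ANI < {STRAIN_ANI}%): {self.n_novel}",
        ]
        if self.refinement_splits:
            lines.append(
                f"note: {self.refinement_splits} lineages split to restore refinement"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_genomes": len(self.assignments),
            "n_strains": self.n_strains,
            "n_lineages": self.n_lineages,
            "n_novel": self.n_novel,
            "dropped_genomes": list(self.dropped_genomes),
        }


class StrainLineageModel:
    """Two-level ANI clustering of isolate genomes.

    Parameters
    ----------
    ani, aligned_fraction
        Square percent matrices indexed by genome id (possibly asymmetric;
        symmetrized by averaging).
    quality
        Optional genome-quality table for the QC filter.
    references
        Optional long table ``genome_id, ref_id, ani_pct,
        aligned_fraction_pct`` of comparisons against reference genomes,
        used for per-lineage novelty calls.
    """

    def __init__(
        self,
        ani: pd.DataFrame,
        aligned_fraction: pd.DataFrame,
        quality: pd.DataFrame | None = None,
        references: pd.DataFrame | None = None,
        min_aligned_fraction: float = SELF_MIN_ALIGNED_FRACTION,
        ref_min_aligned_fraction: float = REF_MIN_ALIGNED_FRACTION,
    ):
        self.ani = ani
        self.aligned_fraction = aligned_fraction
        self.quality = quality
        self.references = references
        self.min_aligned_fraction = min_aligned_fraction
        self.ref_min_aligned_fraction = ref_min_aligned_fraction

    def fit(
        self,
        strain_ani: float = STRAIN_ANI,
        lineage_ani: float = LINEAGE_ANI,
    ) -> ClusterAssignment:
        if lineage_ani < strain_ani:
            raise ValueError("lineage threshold must be >= strain threshold")
        dropped: list[str] = []
        ids = sorted(self.ani.index)
        if self.quality is not None:
            kept, dropped = qc_filter(self.quality)
            ids = [g for g in ids if g in set(kept)]
        if not ids:
            raise ValueError("no genomes left after QC filtering")
        dist = build_distance(
            self.ani, self.aligned_fraction, ids, self.min_aligned_fraction
        )
        strains = cluster(dist, strain_ani)
        lineages = cluster(dist, lineage_ani)
        lineages, n_splits = _enforce_refinement(lineages, strains)

        strain_of = {g: k for k, c in enumerate(strains) for g in c}
        lineage_of = {g: k for k, c in enumerate(lineages) for g in c}
        width_s = max(2, len(str(len(strains))))
        width_l = max(2, len(str(len(lineages))))
        rows = [
            {
                "genome_id": g,
                "strain_id": f"S{strain_of[g] + 1:0{width_s}d}",
                "lineage_id": f"L{lineage_of[g] + 1:0{width_l}d}",
            }
            for g in ids
        ]
        out = pd.DataFrame(rows)
        best = _best_reference_ani(
            out, self.references, self.ref_min_aligned_fraction
        )
        out["best_ref_ani"] = out["lineage_id"].map(best)
        out["novelty"] = out["best_ref_ani"].map(novelty_call)
        return ClusterAssignment(
            assignments=out,
            n_strains=len(strains),
            n_lineages=len(lineages),
            dropped_genomes=dropped,
            refinement_splits=n_splits,
        )


def strain_and_lineage(
    ani: pd.DataFrame,
    aligned_fraction: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    references: pd.DataFrame | None = None,
) -> ClusterAssignment:
    """Cluster at 99% (strain) and 99.9% (lineage) ANI (shorthand)."""
    return StrainLineageModel(ani, aligned_fraction, quality, references).fit()


def _enforce_refinement(
    lineages: list[frozenset[str]], strains: list[frozenset[str]]
) -> tuple[list[frozenset[str]], int]:
    """Split any lineage spanning several strains so the lineage partition
    refines the strain partition. With a deterministic monotone linkage this
    is a no-op; it guards degenerate inputs."""
    strain_of = {g: k for k, c in enumerate(strains) for g in c}
    out: list[frozenset[str]] = []
    n_splits = 0
    for lin in lineages:
        by_strain: dict[int, set[str]] = {}
        for g in lin:
            by_strain.setdefault(strain_of[g], set()).add(g)
        if len(by_strain) > 1:
            n_splits += 1
        out.extend(frozenset(s) for s in by_strain.values())
    return sorted(out, key=lambda s: min(s)), n_splits


def _best_reference_ani(
    assignments: pd.DataFrame,
    references: pd.DataFrame | None,
    min_af: float,
) -> dict[str, float]:
    """Best qualifying reference ANI per lineage (NaN when none)."""
    lineage_ids = assignments["lineage_id"].unique()
    if references is None or references.empty:
        return {lid: math.nan for lid in lineage_ids}
    needed = {"genome_id", "ref_id", "ani_pct", "aligned_fraction_pct"}
    missing = needed - set(references.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    ok = references[references["aligned_fraction_pct"] >= min_af]
    merged = ok.merge(
        assignments[["genome_id", "lineage_id"]], on="genome_id", how="inner"
    )
    best = merged.groupby("lineage_id")["ani_pct"].max()
    return {lid: float(best.get(lid, math.nan)) for lid in lineage_ids}
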