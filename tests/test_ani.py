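"""QC filtering, distance construction and strain/lineage clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from cluster_oracle import oracle_average_linkage, random_small_matrix
from scdispense import (
    StrainLineageModel,
    build_distance,
    cluster,
    novelty_call,
    qc_filter,
    simulate_ani_matrix,
    strain_and_lineage,
)


def make_quality(n_good=94, bad=((95.0, 80.0), (1.0, 30.0))):
    """Quality table: n_good clean genomes plus (contamination, completeness)
    offenders."""
    rows = [
        {"genome_id": f"G{i:03d}", "completeness": 99.0, "contamination": 1.0}
        for i in range(n_good)
    ]
    for k, (cont, comp) in enumerate(bad):
        rows.append(
            {"genome_id": f"BAD{k}", "completeness": comp, "contamination": cont}
        )
    return pd.DataFrame(rows, columns=["genome_id", "completeness", "contamination"])


class TestQCFilter:
    def test_two_of_96_removed(self):
        quality = make_quality()
        kept, dropped = qc_filter(quality)
        assert len(quality) == 96
        assert len(kept) == 94
        assert sorted(dropped) == ["BAD0", "BAD1"]

    def test_boundary_values_kept(self):
        quality = pd.DataFrame(
            [{"genome_id": "edge", "completeness": 50.0, "contamination": 90.0}]
        )
        kept, dropped = qc_filter(quality)
        assert kept == ["edge"] and dropped == []

    def test_empty_table(self):
        quality = make_quality(n_good=0, bad=())
        kept, dropped = qc_filter(quality)
        assert kept == [] and dropped == []

    def test_duplicate_ids_rejected(self):
        quality = pd.DataFrame(
            [
                {"genome_id": "a", "completeness": 99, "contamination": 1},
                {"genome_id": "a", "completeness": 98, "contamination": 2},
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            qc_filter(quality)


class TestBuildDistance:
    def test_asymmetric_input_averaged(self):
        ani = pd.DataFrame(
            [[100.0, 99.4], [99.6, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        af = pd.DataFrame(
            [[100.0, 80.0], [80.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        dist = build_distance(ani, af)
        assert dist.loc["a", "b"] == pytest.approx(0.5)
        assert dist.loc["b", "a"] == pytest.approx(0.5)
        assert dist.loc["a", "a"] == 0.0

    def test_low_aligned_fraction_unlinks(self):
        ani = pd.DataFrame(
            [[100.0, 99.95], [99.95, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        af = pd.DataFrame(
            [[100.0, 60.0], [60.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        dist = build_distance(ani, af, min_aligned_fraction=75.0)
        assert math.isinf(dist.loc["a", "b"])
        # and the unlinked pair never merges, even at a permissive threshold
        assert len(cluster(dist, 90.0)) == 2

    def test_missing_pair_is_error(self):
        ani = pd.DataFrame(
            [[100.0, np.nan], [99.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        af = pd.DataFrame(
            [[100.0, 80.0], [80.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="missing"):
            build_distance(ani, af)


def _dist(ani_values, ids):
    ani = pd.DataFrame(ani_values, index=ids, columns=ids)
    af = pd.DataFrame(90.0, index=ids, columns=ids)
    return build_distance(ani, af)


class TestCluster:
    def test_all_identical_single_cluster(self):
        dist = _dist(np.full((4, 4), 100.0), list("abcd"))
        assert cluster(dist, 99.9) == [frozenset("abcd")]

    def test_threshold_boundary_inclusive(self):
        # a pair at exactly the threshold ANI merges
        dist = _dist([[100.0, 99.5], [99.5, 100.0]], ["a", "b"])
        assert len(cluster(dist, 99.0)) == 1
        assert len(cluster(dist, 99.5)) == 1
        assert len(cluster(dist, 99.9)) == 2

    def test_matches_scipy_on_linked_matrices(self):
        # no unlinked pairs: the constrained agglomeration must coincide with
        # standard average linkage cut at the same height
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 9))
            vals = rng.uniform(98.0, 100.0, size=(n, n))
            sym = (vals + vals.T) / 2
            np.fill_diagonal(sym, 100.0)
            ids = [f"g{i}" for i in range(n)]
            dist = _dist(sym, ids)
            for thr in (99.0, 99.9):
                ours = {frozenset(c) for c in cluster(dist, thr)}
                z = linkage(squareform(dist.to_numpy()), method="average")
                flat = fcluster(z, t=100.0 - thr, criterion="distance")
                scipy_parts = {
                    frozenset(np.array(ids)[flat == k]) for k in set(flat)
                }
                assert ours == scipy_parts, f"seed={seed} thr={thr}"

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        sim = random_small_matrix(seed)
        dist = build_distance(sim.ani, sim.aligned_fraction)
        for thr in (99.0, 99.9):
            ours = set(cluster(dist, thr))
            assert ours == oracle_average_linkage(dist, 100.0 - thr)

    def test_input_order_invariance(self):
        sim = random_small_matrix(123)
        dist = build_distance(sim.ani, sim.aligned_fraction)
        base = set(cluster(dist, 99.9))
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(rng.permutation(dist.index))
            shuffled = dist.loc[perm, perm]
            assert set(cluster(shuffled, 99.9)) == base

    def test_threshold_monotonicity(self):
        for seed in range(10):
            sim = random_small_matrix(seed + 500)
            dist = build_distance(sim.ani, sim.aligned_fraction)
            n_prev = None
            for thr in (98.0, 99.0, 99.5, 99.9, 99.99):
                n = len(cluster(dist, thr))
                if n_prev is not None:
                    assert n >= n_prev
                n_prev = n


class TestStrainLineage:
    def test_two_strains_three_lineages(self):
        # 3 lineages packed into 2 strains by construction
        sim = simulate_ani_matrix(
            3, 3, between_ani=97.0, seed=4, lineages_per_strain=2
        )
        res = strain_and_lineage(sim.ani, sim.aligned_fraction)
        assert res.n_strains == 2
        assert res.n_lineages == 3
        assert res.refinement_splits == 0

    def test_single_genome(self):
        ani = pd.DataFrame([[100.0]], index=["a"], columns=["a"])
        af = pd.DataFrame([[100.0]], index=["a"], columns=["a"])
        res = strain_and_lineage(ani, af)
        assert res.n_strains == 1 and res.n_lineages == 1

    def test_unlinked_pair_two_of_each(self):
        ani = pd.DataFrame(
            [[100.0, 99.99], [99.99, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        af = pd.DataFrame(
            [[100.0, 10.0], [10.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        res = strain_and_lineage(ani, af)
        assert res.n_strains == 2 and res.n_lineages == 2

    @pytest.mark.parametrize("seed", range(15))
    def test_lineages_refine_strains(self, seed):
        sim = random_small_matrix(seed + 900)
        res = strain_and_lineage(sim.ani, sim.aligned_fraction)
        by_lineage = res.assignments.groupby("lineage_id")["strain_id"].nunique()
        assert (by_lineage == 1).all()
        assert res.n_lineages >= res.n_strains

    def test_qc_filter_applied_before_clustering(self):
        sim = simulate_ani_matrix(2, 2, between_ani=97.0, seed=6)
        quality = pd.DataFrame(
            {
                "genome_id": sim.genome_ids,
                "completeness": [99.0, 99.0, 99.0, 20.0],
                "contamination": [1.0, 1.0, 1.0, 1.0],
            }
        )
        res = StrainLineageModel(sim.ani, sim.aligned_fraction, quality=quality).fit()
        assert res.dropped_genomes == [sim.genome_ids[-1]]
        assert len(res.assignments) == 3


class TestNovelty:
    @pytest.mark.parametrize(
        "best,expected",
        [(98.7, "novel"), (99.0, "known"), (99.5, "known"), (None, "no_reference"),
         (math.nan, "no_reference")],
    )
    def test_boundary_semantics(self, best, expected):
        assert novelty_call(best) == expected

    def test_reference_aligned_fraction_filter(self):
        sim = simulate_ani_matrix(2, 2, between_ani=97.0, seed=8)
        refs = pd.DataFrame(
            [
                # lineage of G00: qualifying hit above threshold -> known
                {"genome_id": "L00G00", "ref_id": "ref1", "ani_pct": 99.4,
                 "aligned_fraction_pct": 70.0},
                # lineage of L01: only a disqualified (low-AF) hit -> no_reference
                {"genome_id": "L01G00", "ref_id": "ref2", "ani_pct": 99.8,
                 "aligned_fraction_pct": 30.0},
            ]
        )
        res = strain_and_lineage(sim.ani, sim.aligned_fraction, references=refs)
        by_genome = res.assignments.set_index("genome_id")
        assert by_genome.loc["L00G00", "novelty"] == "known"
        assert by_genome.loc["L01G00", "novelty"] == "no_reference"
        # novelty is a per-lineage property shared by all members
        assert by_genome.loc["L00G01", "novelty"] == "known"

    def test_novel_count(self):
        sim = simulate_ani_matrix(3, 2, between_ani=97.0, seed=9)
        refs = pd.DataFrame(
            [
                {"genome_id": "L00G00", "ref_id": "r", "ani_pct": 98.0,
                 "aligned_fraction_pct": 80.0},
                {"genome_id": "L01G00", "ref_id": "r", "ani_pct": 99.6,
                 "aligned_fraction_pct": 80.0},
                {"genome_id": "L02G00", "ref_id": "r", "ani_pct": 95.0,
                 "aligned_fraction_pct": 80.0},
            ]
        )
        res = strain_and_lineage(sim.ani, sim.aligned_fraction, references=refs)
        assert res.n_novel == 2
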