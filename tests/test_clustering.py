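"""Threshold clustering, partition agreement and the threshold sweep."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from taxopan import (
    DdhRecord,
    DistanceMatrix,
    Partition,
    cluster_at_threshold,
    flag_synonyms,
    mri,
    read_partition,
    species_partition,
    sweep_thresholds,
    write_partition,
)

from conftest import block_matrix


def square(labels, entries):
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------- references


def naive_cluster(dm: DistanceMatrix, t: float, f: float) -> frozenset[frozenset[str]]:
    """Reference implementation: recompute every cross-pair statistic from
    the raw matrix at each step instead of maintaining incremental sums."""
    idx = {l: i for i, l in enumerate(dm.labels)}
    clusters = [frozenset([l]) for l in dm.labels]
    while len(clusters) > 1:
        best = None
        for A, B in itertools.combinations(clusters, 2):
            cross = [dm.values[idx[a], idx[b]] for a in A for b in B]
            if sum(c <= t for c in cross) / len(cross) >= f:
                key = (float(np.mean(cross)), tuple(sorted((min(A), min(B)))))
                if best is None or key < best[0]:
                    best = (key, A, B)
        if best is None:
            break
        _, A, B = best
        clusters = [c for c in clusters if c not in (A, B)] + [A | B]
    return frozenset(clusters)


def all_merge_orders(dm: DistanceMatrix, t: float, f: float) -> set[frozenset[frozenset[str]]]:
    """Every partition reachable by merging mergeable pairs in any order."""
    idx = {l: i for i, l in enumerate(dm.labels)}
    start = frozenset(frozenset([l]) for l in dm.labels)
    terminals, seen, stack = set(), set(), [start]
    while stack:
        state = stack.pop()
        if state in seen:
            continue
        seen.add(state)
        pairs = []
        for A, B in itertools.combinations(list(state), 2):
            cross = [dm.values[idx[a], idx[b]] for a in A for b in B]
            if sum(c <= t for c in cross) / len(cross) >= f:
                pairs.append((A, B))
        if not pairs:
            terminals.add(state)
            continue
        for A, B in pairs:
            stack.append(frozenset((state - {A, B}) | {A | B}))
    return terminals


# -------------------------------------------------------- cluster_at_threshold


def test_two_tight_pairs_separate():
    dm = square(
        ["a", "b", "c", "d"],
        {("a", "b"): 0.01, ("c", "d"): 0.02, ("a", "c"): 0.3, ("a", "d"): 0.3,
         ("b", "c"): 0.3, ("b", "d"): 0.3},
    )
    part = cluster_at_threshold(dm, 0.05, 0.5)
    assert set(part.clusters()) == {frozenset("ab"), frozenset("cd")}
    assert part.t_used == 0.05 and part.f_used == 0.5


def test_zero_threshold_gives_singletons():
    rng = np.random.default_rng(0)
    dm, _ = block_matrix(rng, [2, 3], within=(0.01, 0.1))
    part = cluster_at_threshold(dm, 0.0, 0.5)
    assert part.n_clusters == dm.n


def test_threshold_above_max_gives_one_cluster():
    rng = np.random.default_rng(1)
    dm, _ = block_matrix(rng, [2, 2, 2])
    part = cluster_at_threshold(dm, 1.0, 0.5)
    assert part.n_clusters == 1


def test_negative_threshold_rejected():
    dm = square(["a", "b"], {("a", "b"): 0.1})
    with pytest.raises(ValueError):
        cluster_at_threshold(dm, -0.1, 0.5)
    with pytest.raises(ValueError):
        cluster_at_threshold(dm, 0.1, 1.5)


def test_cluster_count_monotone_in_threshold():
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = int(rng.integers(4, 10))
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0, 1, len(iu[0]))
        dm = DistanceMatrix(tuple(f"g{i}" for i in range(n)), d + d.T)
        counts = [
            cluster_at_threshold(dm, t, 0.5).n_clusters
            for t in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_incremental_matches_naive_reference():
    """The optimized implementation must equal a from-scratch recompute."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = int(rng.integers(3, 8))
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0, 1, len(iu[0]))
        dm = DistanceMatrix(tuple(chr(97 + i) for i in range(n)), d + d.T)
        t = float(rng.uniform(0.1, 0.9))
        got = frozenset(cluster_at_threshold(dm, t, 0.5).clusters())
        assert got == naive_cluster(dm, t, 0.5)


def test_merge_order_equivalence_on_gap_structured_matrices():
    """With a clean distance gap, every merge order reaches the same
    partition, and it is the generating block partition."""
    rng = np.random.default_rng(13)
    for _ in range(15):
        sizes = rng.integers(1, 4, int(rng.integers(2, 4)))
        dm, block = block_matrix(rng, sizes)
        truth = frozenset(
            frozenset(l for l, b in zip(dm.labels, block) if b == bb)
            for bb in range(len(sizes))
        )
        terminals = all_merge_orders(dm, 0.2, 0.5)
        assert terminals == {truth}
        assert frozenset(cluster_at_threshold(dm, 0.2, 0.5).clusters()) == truth


def test_greedy_result_is_reachable_on_arbitrary_matrices():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(3, 7))
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0, 1, len(iu[0]))
        dm = DistanceMatrix(tuple(chr(97 + i) for i in range(n)), d + d.T)
        t = float(rng.uniform(0.2, 0.8))
        greedy = frozenset(cluster_at_threshold(dm, t, 0.5).clusters())
        assert greedy in all_merge_orders(dm, t, 0.5)


# ------------------------------------------------------------------------ mri


def test_mri_identity():
    p = Partition({"a": 0, "b": 0, "c": 1})
    assert mri(p, p) == 1.0


def test_mri_zero_example():
    p = Partition.from_clusters([["1", "2"], ["3"]])
    q = Partition.from_clusters([["1"], ["2"], ["3"]])
    assert mri(p, q) == pytest.approx(0.0)


def test_mri_negative_example():
    p = Partition.from_clusters([["1", "2"], ["3", "4"]])
    q = Partition.from_clusters([["1", "3"], ["2", "4"]])
    assert mri(p, q) == pytest.approx(-0.5)


def test_mri_relabeling_invariance_and_symmetry():
    p = Partition({"a": 5, "b": 5, "c": 9, "d": 2})
    q = Partition({"a": 0, "b": 1, "c": 1, "d": 0})
    r = Partition({"a": 100, "b": 200, "c": 200, "d": 100})  # q relabeled
    assert mri(p, q) == mri(q, p) == mri(p, r)


def test_mri_matches_sklearn_on_random_partitions():
    rng = np.random.default_rng(3)
    labels = [f"g{i}" for i in range(30)]
    for _ in range(20):
        a = rng.integers(0, 5, len(labels))
        b = rng.integers(0, 5, len(labels))
        p = Partition(dict(zip(labels, map(int, a))))
        q = Partition(dict(zip(labels, map(int, b))))
        order = sorted(labels)
        expected = adjusted_rand_score(
            [p.assignment[l] for l in order], [q.assignment[l] for l in order]
        )
        assert mri(p, q) == pytest.approx(expected, abs=1e-12)


def test_mri_label_mismatch_names_offenders():
    p = Partition({"a": 0, "b": 0})
    q = Partition({"a": 0, "c": 0})
    with pytest.raises(ValueError, match="c"):
        mri(p, q)


# ------------------------------------------------------------ sweep & species


def test_sweep_default_grid_has_401_points(small_collection):
    dm = small_collection.distances
    res = sweep_thresholds(dm, small_collection.truth_groups)
    assert res.grid.size == 401
    assert res.grid[0] == 0.0 and res.grid[-1] == pytest.approx(0.2)


def test_sweep_plateau_covers_group_gap(small_collection):
    res = sweep_thresholds(
        small_collection.distances, small_collection.truth_groups
    )
    assert res.optimal_mri == 1.0
    lo, hi = res.optimal_range
    assert lo < 0.14 < hi  # generating gap is (0.12, 0.17)
    # every threshold strictly inside the gap attains agreement 1
    grid_inside = (res.grid > 0.125) & (res.grid < 0.165)
    assert np.all(res.mri[grid_inside] == 1.0)


def test_sweep_all_singletons_reference():
    rng = np.random.default_rng(5)
    dm, _ = block_matrix(rng, [2, 2], within=(0.05, 0.1))
    ref = Partition({l: i for i, l in enumerate(dm.labels)})
    res = sweep_thresholds(dm, ref, 0.0, 0.1, 0.01)
    below = res.grid < 0.05
    assert np.all(res.mri[below] == 1.0)


def test_species_partition_boundary():
    one = square(["a", "b"], {("a", "b"): 0.035})
    two = square(["a", "b"], {("a", "b"): 0.037})
    assert species_partition(one).n_clusters == 1
    assert species_partition(two).n_clusters == 2
    assert species_partition(one).t_used == 0.036


def test_species_partition_recovers_truth(small_collection):
    part = species_partition(small_collection.distances)
    assert mri(part, small_collection.truth_species) == 1.0


# ------------------------------------------------------------- dDDH synonyms


def test_flag_synonyms_reported_pairs():
    records = [
        DdhRecord("R. imtechensis RKJ300", "R. opacus ATCC 51882", 80.2, 77.3, 82.9, 90.77),
        DdhRecord("WAY2", "S2-17", 70.2, 67.2, 73.0, 78.63),
        DdhRecord("x", "y", 30.5, 25.0, 36.0, 1.0),
    ]
    flagged = flag_synonyms(records, 70.0)
    assert [f.record.genome_a for f in flagged] == ["R. imtechensis RKJ300", "WAY2"]
    assert flagged[0].ci_entirely_above is True
    assert flagged[1].ci_entirely_above is False


def test_ddh_record_validation():
    with pytest.raises(ValueError):
        DdhRecord("a", "b", 50.0, 60.0, 70.0, 10.0)  # ci_lo above estimate


# -------------------------------------------------------------- partition IO


def test_partition_round_trip(tmp_path):
    p = Partition({"g1": 0, "g2": 0, "g3": 1})
    path = tmp_path / "part.tsv"
    write_partition(p, path)
    assert read_partition(path) == p


def test_partition_duplicate_label_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("genome\tcluster\ng1\t0\ng1\t1\n")
    with pytest.raises(ValueError, match="g1"):
        read_partition(path)
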