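"""Partition set algebra, rarefaction and greedy clustering."""

import itertools

import numpy as np
import pytest

from evorescue.pangenome import (
    PresenceMatrix,
    cluster_sequences,
    exclusive_accessory_summary,
    partition_pangenome,
    rarefaction,
)


def toy_matrix():
    """Hand-built 6-genome, 8-cluster matrix with a known partition."""
    genomes = ("a1", "a2", "a3", "b1", "b2", "b3")
    groups = {g: g[0].upper() for g in genomes}
    clusters = tuple(f"c{i}" for i in range(1, 9))
    rows = np.array([
        [1, 1, 1, 1, 1, 1],  # c1 global core
        [1, 1, 1, 1, 1, 1],  # c2 global core
        [1, 1, 1, 0, 1, 1],  # c3 A-core, in B pan -> shared accessory
        [1, 0, 1, 1, 0, 0],  # c4 shared accessory
        [1, 1, 0, 0, 0, 0],  # c5 exclusive A
        [0, 0, 1, 0, 0, 0],  # c6 exclusive A
        [0, 0, 0, 1, 1, 1],  # c7 B-core, absent from A -> exclusive B
        [0, 0, 0, 0, 1, 0],  # c8 exclusive B
    ], dtype=bool)
    return PresenceMatrix(genome_ids=genomes, groups=groups, cluster_ids=clusters, matrix=rows)


def brute_partition(matrix: PresenceMatrix):
    """Exhaustive set-algebra oracle on small matrices."""
    groups = sorted(set(matrix.groups.values()))
    present = {
        grp: {
            c for ci, c in enumerate(matrix.cluster_ids)
            if any(matrix.matrix[ci, gi] for gi, g in enumerate(matrix.genome_ids)
                   if matrix.groups[g] == grp)
        } for grp in groups
    }
    global_core = {
        c for ci, c in enumerate(matrix.cluster_ids) if matrix.matrix[ci].all()
    }
    shared = set.intersection(*present.values()) - global_core
    exclusive = {grp: present[grp] - set.union(*(present[o] for o in groups if o != grp))
                 for grp in groups}
    return global_core, shared, exclusive


def test_toy_partition_matches_hand_enumeration():
    m = toy_matrix()
    part = partition_pangenome(m)
    core, shared, excl = brute_partition(m)
    assert set(part.global_core) == core == {"c1", "c2"}
    assert set(part.shared_accessory) == shared == {"c3", "c4"}
    assert {g: set(s) for g, s in part.exclusive_accessory.items()} == excl
    assert excl == {"A": {"c5", "c6"}, "B": {"c7", "c8"}}


def test_partition_is_disjoint_and_exhaustive_per_group():
    m = toy_matrix()
    part = partition_pangenome(m)
    for grp, pan in part.group_pan.items():
        pieces = [part.global_core, part.shared_accessory, part.exclusive_accessory[grp]]
        assert frozenset.union(*[frozenset(p) & pan for p in pieces]) == pan
        for x, y in itertools.combinations(pieces, 2):
            assert not (frozenset(x) & frozenset(y))


def test_all_core_matrix_has_empty_accessory():
    genomes = ("a1", "a2", "b1")
    m = PresenceMatrix(genome_ids=genomes, groups={"a1": "A", "a2": "A", "b1": "B"},
                       cluster_ids=("c1", "c2"), matrix=np.ones((2, 3), dtype=bool))
    part = partition_pangenome(m)
    assert len(part.shared_accessory) == 0
    assert all(len(s) == 0 for s in part.exclusive_accessory.values())


def test_partition_requires_grouped_genomes():
    with pytest.raises(ValueError):
        PresenceMatrix(genome_ids=("x",), groups={}, cluster_ids=("c",),
                       matrix=np.ones((1, 1), dtype=bool))


# exclusive accessory summary ----------------------------------------------


def test_exclusive_summary_reproduces_published_arithmetic():
    """374/218 exclusive clusters with 104/80 annotated give the printed rates."""
    genomes = tuple(f"a{i}" for i in range(5)) + tuple(f"b{i}" for i in range(7))
    groups = {g: ("2003" if g.startswith("a") else "2015") for g in genomes}
    n_a, n_b = 374, 218
    clusters, rows, annotations = [], [], {}
    for i in range(n_a):
        cid = f"xa{i}"
        clusters.append(cid)
        rows.append([1] * 5 + [0] * 7)
        annotations[cid] = (i < 104, "misc")
    for i in range(n_b):
        cid = f"xb{i}"
        clusters.append(cid)
        rows.append([0] * 5 + [1] * 7)
        annotations[cid] = (i < 80, "misc")
    m = PresenceMatrix(genome_ids=genomes, groups=groups, cluster_ids=tuple(clusters),
                       matrix=np.array(rows, dtype=bool))
    part = partition_pangenome(m)
    summary = exclusive_accessory_summary(part, annotations, order=["2003", "2015"])
    g03, g15 = summary["groups"]["2003"], summary["groups"]["2015"]
    assert g03["exclusive_size"] == 374 and g15["exclusive_size"] == 218
    assert g03["annotated_pct"] == pytest.approx(27.8, abs=0.05)
    assert g15["annotated_pct"] == pytest.approx(36.7, abs=0.05)
    assert summary["net_change"]["count"] == -156
    assert summary["net_change"]["pct_of_earlier"] == pytest.approx(-41.7, abs=0.05)


def test_exclusive_summary_identical_sets_zero_change():
    m = toy_matrix()
    part = partition_pangenome(m)
    part.exclusive_accessory["B"] = part.exclusive_accessory["A"]
    s = exclusive_accessory_summary(part, order=["A", "B"])
    assert s["net_change"]["count"] == 0


def test_category_percent_change_arithmetic():
    m = toy_matrix()
    part = partition_pangenome(m)
    ann = {"c5": (True, "transport"), "c6": (True, "transport"),
           "c7": (True, "transport"), "c8": (True, "regulation")}
    s = exclusive_accessory_summary(part, ann, order=["A", "B"])
    tr = s["net_change"]["categories"]["transport"]
    assert tr["count_a"] == 2 and tr["count_b"] == 1
    assert tr["pct_change"] == pytest.approx(-50.0)


# rarefaction ---------------------------------------------------------------


def test_rarefaction_single_genome_curve():
    m = PresenceMatrix(genome_ids=("g1",), groups={"g1": "A"},
                       cluster_ids=("c1", "c2", "c3"), matrix=np.ones((3, 1), dtype=bool))
    cur = rarefaction(m, permutations=10, seed=0)
    assert cur.mean.tolist() == [3.0]


def test_rarefaction_identical_genomes_flat_after_first():
    m = PresenceMatrix(genome_ids=("g1", "g2", "g3"), groups={g: "A" for g in ("g1", "g2", "g3")},
                       cluster_ids=("c1", "c2"), matrix=np.ones((2, 3), dtype=bool))
    cur = rarefaction(m, permutations=20, seed=1)
    assert cur.mean.tolist() == [2.0, 2.0, 2.0]


def test_rarefaction_step2_matches_exhaustive_average():
    m = toy_matrix().restrict("A")  # 3 genomes
    cur = rarefaction(m, permutations=4000, seed=2)
    # exhaustive mean over all ordered pairs of distinct genomes
    vals = []
    cols = {g: i for i, g in enumerate(m.genome_ids)}
    for g1, g2 in itertools.permutations(m.genome_ids, 2):
        union = m.matrix[:, cols[g1]] | m.matrix[:, cols[g2]]
        vals.append(union.sum())
    assert cur.mean[1] == pytest.approx(np.mean(vals), abs=0.1)
    # endpoint is permutation-invariant and equals the pan-genome size
    assert cur.lo[-1] == cur.hi[-1] == cur.mean[-1] == m.matrix.any(axis=1).sum()
    assert np.all(np.diff(cur.mean) >= -1e-12)


# clustering ----------------------------------------------------------------


def _mutate(seq: str, k: int, rng) -> str:
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def test_identical_copies_form_one_cluster_per_family(rng):
    fam1 = "".join(rng.choice(list("ACGT"), 300))
    fam2 = "".join(rng.choice(list("ACGT"), 240))
    genes = {f"g{i}": [("f1", fam1), ("f2", fam2)] for i in range(4)}
    m = cluster_sequences(genes)
    assert len(m.cluster_ids) == 2
    assert m.matrix.all()


def test_distant_families_stay_separate(rng):
    fam1 = "".join(rng.choice(list("ACGT"), 200))
    fam2 = _mutate(fam1, 100, rng)  # 50% identity
    m = cluster_sequences({"g1": [("a", fam1)], "g2": [("b", fam2)]}, identity=0.9)
    assert len(m.cluster_ids) == 2


def test_clustering_recovers_simulated_families(rng):
    # families far apart; copies carry light mutations (>=95% identity)
    families = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(12)]
    genes = {}
    for g in range(6):
        present = [(f"fam{fi}", _mutate(fam, int(rng.integers(0, 8)), rng))
                   for fi, fam in enumerate(families) if rng.random() < 0.8]
        genes[f"genome{g}"] = present or [("fam0", families[0])]
    m = cluster_sequences(genes, identity=0.9)
    truth = {}
    for genome, items in genes.items():
        for fid, _ in items:
            truth.setdefault(fid, set()).add(genome)
    assert len(m.cluster_ids) == len(truth)
    found = {frozenset(np.array(m.genome_ids)[m.matrix[ci]]) for ci in range(len(m.cluster_ids))}
    expected = {frozenset(v) for v in truth.values()}
    assert found == expected


def test_clustering_deterministic(rng):
    fam = "".join(rng.choice(list("ACGT"), 150))
    genes = {"g1": [("x", fam)], "g2": [("y", _mutate(fam, 3, rng))]}
    m1 = cluster_sequences(genes)
    m2 = cluster_sequences(genes)
    assert m1.cluster_ids == m2.cluster_ids
    assert np.array_equal(m1.matrix, m2.matrix)


def test_clustering_rejects_empty_input():
    with pytest.raises(ValueError):
        cluster_sequences({})
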