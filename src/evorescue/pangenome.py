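"""Pan-genome partitioning, exclusive-accessory summaries and rarefaction.

The partition follows the usual two-sampling decomposition of a bacterial
pan-genome: for each sampling group, pan = global core (clusters in every
genome) + shared accessory (in both groups' pan-genomes but not the global
core) + exclusive accessory (confined to that group's pan-genome).  The
three parts are disjoint and exhaustive per group by construction, and that
invariant is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "PartitionResult",
    "RarefactionCurve",
    "cluster_sequences",
    "partition_pangenome",
    "exclusive_accessory_summary",
    "rarefaction",
]


@dataclass
class PresenceMatrix:
    """Boolean clusters x genomes membership with group labels."""

    genome_ids: tuple
    groups: dict            # genome id -> group label
    cluster_ids: tuple
    matrix: np.ndarray      # (clusters, genomes) bool
    categories: dict = field(default_factory=dict)  # cluster -> (annotated, category)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.cluster_ids), len(self.genome_ids)):
            raise ValueError("matrix shape must be (clusters, genomes)")
        if self.matrix.size and not self.matrix.any(axis=1).all():
            raise ValueError("empty clusters are not allowed")
        missing = [g for g in self.genome_ids if g not in self.groups]
        if missing:
            raise ValueError(f"genomes without a group label: {missing}")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.genome_ids) if self.groups[g] == group])

    def restrict(self, group: str) -> "PresenceMatrix":
        cols = self.group_columns(group)
        sub = self.matrix[:, cols]
        keep = sub.any(axis=1)
        return PresenceMatrix(
            genome_ids=tuple(self.genome_ids[i] for i in cols),
            groups={self.genome_ids[i]: group for i in cols},
            cluster_ids=tuple(c for c, k in zip(self.cluster_ids, keep) if k),
            matrix=sub[keep],
            categories=self.categories,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.astype(int), index=list(self.cluster_ids),
                            columns=list(self.genome_ids))


@dataclass
class PartitionResult:
    global_core: frozenset
    group_core: dict        # group -> frozenset
    group_pan: dict
    shared_accessory: frozenset
    exclusive_accessory: dict

    def counts(self) -> dict:
        return {
            "global_core": len(self.global_core),
            "shared_accessory": len(self.shared_accessory),
            "group_core": {g: len(s) for g, s in self.group_core.items()},
            "group_pan": {g: len(s) for g, s in self.group_pan.items()},
            "exclusive_accessory": {g: len(s) for g, s in self.exclusive_accessory.items()},
        }


@dataclass
class RarefactionCurve:
    steps: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    permutations: int


# ---------------------------------------------------------------------------
# clustering


def _kmer_set(seq: str, k: int = 8) -> set:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def cluster_sequences(genes_per_genome: dict, identity: float = 0.9,
                      coverage: float = 0.75, groups: dict | None = None) -> PresenceMatrix:
    """Greedy centroid clustering of gene sequences into a presence matrix.

    ``genes_per_genome`` maps genome id -> iterable of (gene id, sequence).
    Genes are sorted by length (descending, then by id for determinism); a
    gene joins the first centroid reaching both the identity and coverage
    thresholds (global edit-distance identity, k-mer pre-screen), otherwise
    it seeds a new cluster.
    """
    import edlib

    if not genes_per_genome or all(not list(v) for v in genes_per_genome.values()):
        raise ValueError("at least one genome with one gene is required")
    genome_ids = tuple(sorted(genes_per_genome))
    entries = []
    for genome in genome_ids:
        for gene_id, seq in genes_per_genome[genome]:
            entries.append((len(seq), genome, str(gene_id), seq.upper()))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))

    centroids: list = []           # (sequence, kmer set)
    membership: list = []          # list of sets of genome indices
    gidx = {g: i for i, g in enumerate(genome_ids)}
    for length, genome, gene_id, seq in entries:
        kmers = _kmer_set(seq)
        placed = False
        for ci, (cseq, ckmers) in enumerate(centroids):
            if min(length, len(cseq)) / max(length, len(cseq)) < coverage:
                continue
            if not (kmers & ckmers):
                continue
            res = edlib.align(seq, cseq, mode="NW", task="distance")
            ident = 1.0 - res["editDistance"] / max(length, len(cseq))
            if ident >= identity:
                membership[ci].add(gidx[genome])
                placed = True
                break
        if not placed:
            centroids.append((seq, kmers))
            membership.append({gidx[genome]})
    matrix = np.zeros((len(centroids), len(genome_ids)), dtype=bool)
    for ci, members in enumerate(membership):
        matrix[ci, sorted(members)] = True
    cluster_ids = tuple(f"cluster{ci + 1:05d}" for ci in range(len(centroids)))
    groups = groups or {g: "all" for g in genome_ids}
    return PresenceMatrix(genome_ids=genome_ids, groups=dict(groups),
                          cluster_ids=cluster_ids, matrix=matrix)


# ---------------------------------------------------------------------------
# partitioning


def partition_pangenome(matrix: PresenceMatrix, groups: list | None = None) -> PartitionResult:
    """Set-algebra partition into global core / shared / exclusive accessory."""
    groups = groups or sorted(set(matrix.groups.values()))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to partition")
    ids = np.array(matrix.cluster_ids)
    pan, core = {}, {}
    for grp in groups:
        cols = matrix.group_columns(grp)
        if cols.size == 0:
            raise ValueError(f"group {grp!r} has no genomes")
        sub = matrix.matrix[:, cols]
        pan[grp] = frozenset(ids[sub.any(axis=1)])
        core[grp] = frozenset(ids[sub.all(axis=1)])
    global_core = frozenset(ids[matrix.matrix.all(axis=1)])
    in_all_pans = frozenset.intersection(*pan.values())
    shared_acc = in_all_pans - global_core
    union_others = {grp: frozenset.union(*(pan[o] for o in groups if o != grp)) for grp in groups}
    exclusive = {grp: pan[grp] - union_others[grp] for grp in groups}
    result = PartitionResult(global_core=global_core, group_core=core, group_pan=pan,
                             shared_accessory=shared_acc, exclusive_accessory=exclusive)
    # disjoint + exhaustive invariant, asserted on every run
    for grp in groups:
        parts = [global_core & pan[grp], shared_acc & pan[grp], exclusive[grp]]
        assert sum(len(p) for p in parts) == len(pan[grp]), "partition not exhaustive"
        assert global_core <= core[grp], "global core must lie inside each group core"
        # note: shared_acc is common to all pans, so shared_acc & pan == shared_acc
    return result


def exclusive_accessory_summary(partition: PartitionResult,
                                annotations: dict | None = None,
                                order: list | None = None) -> dict:
    """Exclusive-accessory sizes, annotation rates and between-group change.

    ``annotations`` maps cluster id -> (annotated flag, category label).
    ``order`` gives the chronological group order (earlier first); the net
    change is expressed as a percentage of the earlier group's exclusive
    size.  Category tallies report per-category counts and percent change.
    """
    annotations = annotations or {}
    groups = order or sorted(partition.exclusive_accessory)
    per_group = {}
    for grp in groups:
        clusters = partition.exclusive_accessory[grp]
        ann = [c for c in clusters if annotations.get(c, (False, None))[0]]
        cats: dict = {}
        for c in clusters:
            flag, cat = annotations.get(c, (False, None))
            if flag and cat is not None:
                cats[cat] = cats.get(cat, 0) + 1
        per_group[grp] = {
            "exclusive_size": len(clusters),
            "annotated": len(ann),
            "annotated_pct": 100.0 * len(ann) / len(clusters) if clusters else float("nan"),
            "categories": dict(sorted(cats.items())),
        }
    out = {"groups": per_group}
    if len(groups) == 2:
        a, b = groups
        na, nb = per_group[a]["exclusive_size"], per_group[b]["exclusive_size"]
        cats = sorted(set(per_group[a]["categories"]) | set(per_group[b]["categories"]))
        cat_changes = {}
        for cat in cats:
            ca = per_group[a]["categories"].get(cat, 0)
            cb = per_group[b]["categories"].get(cat, 0)
            cat_changes[cat] = {
                "count_a": ca, "count_b": cb, "change": cb - ca,
                "pct_change": 100.0 * (cb - ca) / ca if ca else float("nan"),
            }
        out["net_change"] = {
            "count": nb - na,
            "pct_of_earlier": 100.0 * (nb - na) / na if na else float("nan"),
            "categories": cat_changes,
        }
    return out


# ---------------------------------------------------------------------------
# rarefaction


def rarefaction(matrix: PresenceMatrix, permutations: int = 1000, seed: int = 0,
                quantiles: tuple = (0.025, 0.975)) -> RarefactionCurve:
    """Permutation rarefaction of cumulative distinct clusters per genome added."""
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    m = matrix.matrix
    n_genomes = m.shape[1]
    curves = np.empty((permutations, n_genomes))
    for p in range(permutations):
        order = rng.permutation(n_genomes)
        seen = np.zeros(m.shape[0], dtype=bool)
        for step, col in enumerate(order):
            seen |= m[:, col]
            curves[p, step] = seen.sum()
    return RarefactionCurve(
        steps=np.arange(1, n_genomes + 1),
        mean=curves.mean(axis=0),
        lo=np.quantile(curves, quantiles[0], axis=0),
        hi=np.quantile(curves, quantiles[1], axis=0),
        permutations=permutations,
    )
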