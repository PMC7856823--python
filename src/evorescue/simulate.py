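"""Synthetic ground-truth data: genealogies, alignments, imports, pan-genomes.

Every generator is a pure function of its inputs and a seed.  The coalescent
uses haploid scaling (rate k(k-1)/(2N(t))) with N(t) from a
:class:`~evorescue.scenario.DemographicScenario`; mutation is neutral
infinite-sites within each gene with an A->C substitution convention (the
ancestral base is A everywhere; each mutation toggles A<->C at a private
site).  Recombination imports are laid on branches as Poisson initiations
with geometric tract lengths and elevated within-tract divergence, mirroring
the parameterisation (R/theta, delta, nu) estimated downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coalescent import (
    CoalescentDraws,
    SizeHistory,
    fold_spectrum,
    rescaled_interval_durations,
)
from .diversity import FoldedSFS, GeneAlignment
from .scenario import DemographicScenario

__all__ = [
    "ImportModel",
    "PanGenomeModel",
    "TruthRecord",
    "GeneGenealogy",
    "SimulatedDataset",
    "SfsSimulation",
    "simulate_folded_sfs",
    "simulate_alignments",
    "apply_imports",
    "simulate_pangenome",
    "DEFAULT_MU",
]

#: Default per-site per-generation mutation rate (non-mutator pseudomonad).
DEFAULT_MU = 2.5e-8


@dataclass(frozen=True)
class ImportModel:
    """Recombination-import parameters.

    rel_rate
        Import-initiation rate relative to mutation (R/theta, dimensionless).
    mean_tract
        Mean import tract length delta in bp (tract lengths are geometric).
    divergence
        Per-site substitution probability nu inside an imported tract.
    """

    rel_rate: float
    mean_tract: float
    divergence: float

    def __post_init__(self) -> None:
        if self.rel_rate < 0:
            raise ValueError("rel_rate must be >= 0")
        if self.mean_tract < 1:
            raise ValueError("mean_tract must be >= 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


DEFAULT_CATEGORIES = {
    "transport": 0.10,
    "biosynthesis": 0.15,
    "regulation": 0.10,
    "small_molecule_metabolism": 0.20,
    "phosphorylation": 0.05,
    "dna_recombination": 0.05,
    "signal_transduction": 0.05,
    "unknown": 0.30,
}


@dataclass(frozen=True)
class PanGenomeModel:
    """Structure of a two-sampling synthetic pan-genome.

    ``exclusive_counts`` maps group label -> number of clusters confined to
    that group's pan-genome.  ``categories`` maps functional-category label
    -> proportion (must sum to 1); clusters labelled "unknown" count as
    unannotated.  ``noise`` is a per-cell presence flip probability applied
    after the structured matrix is built (truth counts are recorded first).
    """

    core_count: int
    shared_accessory_count: int
    exclusive_counts: dict
    categories: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    noise: float = 0.0

    def __post_init__(self) -> None:
        if min(self.core_count, self.shared_accessory_count, *self.exclusive_counts.values()) < 0:
            raise ValueError("all cluster counts must be >= 0")
        if abs(sum(self.categories.values()) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a probability")


@dataclass
class TruthRecord:
    """Ground truth written alongside every simulated dataset."""

    scenario_code: str
    anchor_times: tuple
    anchor_sizes_backward: tuple
    mu: float
    n: int
    locus_lengths: tuple
    seed: int
    import_model: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# folded SFS simulation


@dataclass
class SfsSimulation:
    n: int
    expected_proportions: np.ndarray  # folded, classes 1..n//2
    sfs: FoldedSFS                    # sampled counts over L loci
    reps: int


def simulate_folded_sfs(
    scenario: DemographicScenario,
    n: int,
    L: int = 1000,
    theta_per_locus: float = 1.0,
    reps: int = 10_000,
    seed: int = 0,
    draws: CoalescentDraws | None = None,
) -> SfsSimulation:
    """Monte-Carlo folded SFS under the scenario's size history.

    ``theta_per_locus`` is the scaled mutation parameter 2*N0*mu*l with N0
    the size at the sampling anchor, so the per-locus per-generation
    mutation intensity is theta_per_locus / (2*N0).  Expected class
    proportions come from ``reps`` replicate genealogies' branch lengths;
    sampled counts from Poisson mutation on ``L`` further replicates.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if reps < 1 or L < 0:
        raise ValueError("reps >= 1 and L >= 0 required")
    rng = np.random.default_rng(seed)
    hist = SizeHistory.from_scenario(scenario)
    if draws is None or draws.n != n:
        draws = CoalescentDraws(n, reps, rng)
    durations = rescaled_interval_durations(hist, n, draws.exp)
    unfolded = np.tensordot(durations, draws.classes, axes=([0, 1], [0, 1])) / draws.reps
    expected = fold_spectrum(unfolded)
    expected = expected / expected.sum()

    mu_locus = theta_per_locus / (2.0 * scenario.anchor_sizes[0])
    counts = np.zeros(n // 2)
    if L > 0:
        loc = CoalescentDraws(n, L, rng)
        dur = rescaled_interval_durations(hist, n, loc.exp)
        w = np.einsum("rk,rki->ri", dur, loc.classes)  # per-locus unfolded branch lengths
        muts = rng.poisson(mu_locus * w)
        counts = fold_spectrum(muts.sum(axis=0).astype(float))
    return SfsSimulation(n=n, expected_proportions=expected, sfs=FoldedSFS(n=n, counts=counts), reps=reps)


# ---------------------------------------------------------------------------
# gene alignments


@dataclass
class GeneGenealogy:
    """One gene's coalescent tree with per-branch substitution events.

    Nodes 0..n-1 are tips; the branch of node v runs to ``parent[v]``
    (root parent = -1).  ``clonal_sites[v]`` / ``import_sites[v]`` list the
    0-based alignment columns toggled (A<->C) on that branch.
    """

    gene_id: str
    n: int
    parent: np.ndarray
    time: np.ndarray
    clonal_sites: list
    import_sites: list

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return 0.0 if p < 0 else float(self.time[p] - self.time[v])

    def path_to_root(self, v: int):
        while v >= 0:
            yield v
            v = self.parent[v]

    def node_sequence(self, v: int, length: int) -> np.ndarray:
        """Materialise a node's sequence (0 = A, 1 = C) from root-path toggles."""
        seq = np.zeros(length, dtype=np.uint8)
        for u in self.path_to_root(v):
            for s in self.clonal_sites[u]:
                seq[s] ^= 1
            for s in self.import_sites[u]:
                seq[s] ^= 1
        return seq

    def newick(self, ids, lengths_scale: float = 1.0) -> str:
        def rec(v: int) -> str:
            kids = [u for u in range(len(self.parent)) if self.parent[u] == v]
            bl = self.branch_length(v) * lengths_scale
            if not kids:
                return f"{ids[v]}:{bl:.8g}"
            inner = ",".join(rec(u) for u in kids)
            return f"({inner}):{bl:.8g}" if self.parent[v] >= 0 else f"({inner});"
        root = int(np.where(self.parent < 0)[0][0])
        return rec(root)


@dataclass
class SimulatedDataset:
    """Per-gene alignments + true genealogies + truth record."""

    scenario: DemographicScenario
    n: int
    mu: float
    locus_len: int
    sample_ids: tuple
    genealogies: list
    seed: int
    import_model: ImportModel | None = None

    def alignments(self) -> list:
        out = []
        for g in self.genealogies:
            seqs = []
            for tip in range(self.n):
                arr = g.node_sequence(tip, self.locus_len)
                seqs.append("".join("AC"[b] for b in arr))
            out.append(GeneAlignment.from_sequences(g.gene_id, self.sample_ids, seqs))
        return out

    def truth_record(self) -> TruthRecord:
        return TruthRecord(
            scenario_code=self.scenario.code,
            anchor_times=tuple(self.scenario.anchor_times),
            anchor_sizes_backward=tuple(self.scenario.anchor_sizes),
            mu=self.mu,
            n=self.n,
            locus_lengths=tuple(self.locus_len for _ in self.genealogies),
            seed=self.seed,
            import_model=dataclasses.asdict(self.import_model) if self.import_model else None,
        )

    def tip_parent_sequences(self) -> dict:
        """True parent (ancestral) sequence of each tip's terminal branch."""
        out = {}
        for g in self.genealogies:
            for tip in range(self.n):
                p = int(g.parent[tip])
                out.setdefault(self.sample_ids[tip], []).append(g.node_sequence(p, self.locus_len))
        return {k: np.concatenate(v) for k, v in out.items()}


def _simulate_topology(n: int, coal_times: np.ndarray, rng: np.random.Generator):
    """Random-join Kingman topology with supplied coalescence times."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    live = list(range(n))
    for step in range(n - 1):
        i, j = rng.choice(len(live), size=2, replace=False)
        a, b = live[i], live[j]
        new = n + step
        parent[a] = parent[b] = new
        time[new] = coal_times[step]
        live = [v for v in live if v not in (a, b)] + [new]
    return parent, time


def simulate_alignments(
    scenario: DemographicScenario,
    n: int,
    genes: int,
    locus_len: int = 900,
    mu: float = DEFAULT_MU,
    seed: int = 0,
    sample_prefix: str = "s",
) -> SimulatedDataset:
    """One independent genealogy per gene; infinite-sites mutations on branches."""
    if genes < 1 or locus_len < 1:
        raise ValueError("genes >= 1 and locus_len >= 1 required")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    hist = SizeHistory.from_scenario(scenario)
    exp_draws = rng.exponential(size=(genes, n - 1))
    durations = rescaled_interval_durations(hist, n, exp_draws)
    coal_times = np.cumsum(durations, axis=1)
    sample_ids = tuple(f"{sample_prefix}{i + 1}" for i in range(n))
    # infinite-sites sanity check on the *expected* mutation load per gene
    mean_tree_len = float(np.sum(durations * np.arange(n, 1, -1), axis=1).mean())
    if mu * locus_len * mean_tree_len > locus_len:
        raise ValueError(
            "expected mutations per gene exceed gene length; "
            "reduce mu * locus_len (infinite-sites assumption broken)"
        )
    genealogies = []
    for g in range(genes):
        parent, time = _simulate_topology(n, coal_times[g], rng)
        n_mut = np.array([rng.poisson(mu * locus_len * (time[parent[v]] - time[v]))
                          for v in range(2 * n - 2)])
        total = int(n_mut.sum())
        if total > locus_len:
            raise ValueError("realised mutations exceed gene length; reduce mu * locus_len")
        sites = rng.choice(locus_len, size=total, replace=False)
        clonal: list = [[] for _ in range(2 * n - 1)]
        pos = 0
        for v in range(2 * n - 2):
            clonal[v] = sorted(int(s) for s in sites[pos: pos + n_mut[v]])
            pos += n_mut[v]
        genealogies.append(GeneGenealogy(
            gene_id=f"gene{g + 1:05d}", n=n, parent=parent, time=time,
            clonal_sites=clonal, import_sites=[[] for _ in range(2 * n - 1)],
        ))
    return SimulatedDataset(
        scenario=scenario, n=n, mu=mu, locus_len=locus_len,
        sample_ids=sample_ids, genealogies=genealogies, seed=seed,
    )


def apply_imports(dataset: SimulatedDataset, model: ImportModel, seed: int = 0):
    """Overlay recombination imports on every branch of every genealogy.

    Import initiations on a branch are Poisson with mean
    rel_rate * (expected clonal mutations on the branch); tract lengths are
    geometric with mean ``mean_tract`` (truncated at the gene end); each
    tract site substitutes independently with probability ``divergence``.

    Returns a new dataset plus a tract table with 0-based half-open
    coordinates and realised substitution counts.
    """
    rng = np.random.default_rng(seed)
    records = []
    new_genealogies = []
    L = dataset.locus_len
    for g in dataset.genealogies:
        imports: list = [[] for _ in range(2 * dataset.n - 1)]
        for v in range(2 * dataset.n - 2):
            bl = g.branch_length(v)
            mean_inits = model.rel_rate * dataset.mu * L * bl
            n_tracts = rng.poisson(mean_inits)
            for _ in range(n_tracts):
                start = int(rng.integers(0, L))
                tract_len = int(rng.geometric(1.0 / model.mean_tract))
                end = min(start + tract_len, L)
                hit = np.nonzero(rng.random(end - start) < model.divergence)[0] + start
                imports[v].extend(int(s) for s in hit)
                records.append({
                    "gene": g.gene_id, "branch": v, "start": start, "end": end,
                    "drawn_length": tract_len, "n_substitutions": int(hit.size),
                })
        new_genealogies.append(GeneGenealogy(
            gene_id=g.gene_id, n=g.n, parent=g.parent, time=g.time,
            clonal_sites=g.clonal_sites, import_sites=[sorted(s) for s in imports],
        ))
    tracts = pd.DataFrame(records, columns=["gene", "branch", "start", "end",
                                            "drawn_length", "n_substitutions"])
    out = dataclasses.replace(dataset, genealogies=new_genealogies, import_model=model)
    return out, tracts


# ---------------------------------------------------------------------------
# pan-genome


def simulate_pangenome(group_sizes: dict, model: PanGenomeModel, seed: int = 0):
    """Presence/absence matrix with configured core / shared / exclusive parts.

    Returns an :class:`evorescue.pangenome.PresenceMatrix`; its ``truth``
    attribute records the pre-noise counts.
    """
    from .pangenome import PresenceMatrix

    if min(group_sizes.values()) < 1:
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    groups = sorted(group_sizes)
    genome_ids, genome_group = [], {}
    for grp in groups:
        for i in range(group_sizes[grp]):
            gid = f"{grp}_g{i + 1}"
            genome_ids.append(gid)
            genome_group[gid] = grp
    idx_of_group = {grp: [i for i, gid in enumerate(genome_ids) if genome_group[gid] == grp]
                    for grp in groups}

    cats = sorted(model.categories)
    probs = np.array([model.categories[c] for c in cats])

    rows, cluster_ids, categories = [], [], {}
    counter = 0

    def _add(pattern: np.ndarray, kind: str) -> None:
        nonlocal counter
        counter += 1
        cid = f"{kind}{counter:05d}"
        cluster_ids.append(cid)
        rows.append(pattern)
        cat = cats[int(rng.choice(len(cats), p=probs))]
        categories[cid] = (cat != "unknown", cat)

    n_total = len(genome_ids)
    for _ in range(model.core_count):
        _add(np.ones(n_total, dtype=bool), "core")
    for _ in range(model.shared_accessory_count):
        while True:
            pattern = np.zeros(n_total, dtype=bool)
            for grp in groups:
                members = idx_of_group[grp]
                k = int(rng.integers(1, len(members) + 1))
                pattern[rng.choice(members, size=k, replace=False)] = True
            if not pattern.all():  # must stay accessory
                break
        _add(pattern, "shac")
    for grp in groups:
        members = idx_of_group[grp]
        for _ in range(model.exclusive_counts.get(grp, 0)):
            pattern = np.zeros(n_total, dtype=bool)
            k = int(rng.integers(1, len(members) + 1))
            pattern[rng.choice(members, size=k, replace=False)] = True
            _add(pattern, f"ex{grp}")

    matrix = np.array(rows, dtype=bool) if rows else np.zeros((0, n_total), dtype=bool)
    truth = {
        "core": model.core_count,
        "shared_accessory": model.shared_accessory_count,
        "exclusive": dict(model.exclusive_counts),
    }
    if model.noise > 0:
        flip = rng.random(matrix.shape) < model.noise
        matrix = matrix ^ flip
        keep = matrix.any(axis=1)
        matrix = matrix[keep]
        cluster_ids = [c for c, k in zip(cluster_ids, keep) if k]
    return PresenceMatrix(
        genome_ids=tuple(genome_ids),
        groups={g: genome_group[g] for g in genome_ids},
        cluster_ids=tuple(cluster_ids),
        matrix=matrix,
        categories=categories,
        truth=truth,
    )
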