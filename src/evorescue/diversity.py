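"""Per-gene diversity statistics and between-sampling shift tests.

Implements the classical summaries of within-population variation on gene
alignments of haploid sequences: segregating sites S, nucleotide diversity
pi (mean pairwise difference per compared site), Watterson's theta and
Tajima's D, plus the folded site-frequency spectrum and the paired Wilcoxon /
Levene / Brown-Forsythe tests used to compare two sampling time points.

Missing data policy (gaps and N): pairwise deletion for pi; a column counts
as segregating only if it shows >= 2 distinct non-missing bases among >= 2
non-missing calls.  Genes with S = 0 have undefined Tajima's D and are
excluded from D group summaries, but contribute pi = 0 to pi summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GeneAlignment",
    "FoldedSFS",
    "ShiftTestResult",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajima_constants",
    "folded_sfs_from_calls",
    "paired_wilcoxon",
    "variance_equality_test",
    "diversity_summary",
    "diversity_shift_report",
]

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 255, "-": 255}


@dataclass(frozen=True)
class GeneAlignment:
    """Equal-length haploid sequences for one gene (cluster)."""

    gene_id: str
    ids: tuple[str, ...]
    matrix: np.ndarray  # (n, L) uint8; 0..3 = ACGT, 255 = missing

    @classmethod
    def from_sequences(cls, gene_id: str, ids, seqs) -> "GeneAlignment":
        seqs = [s.upper() for s in seqs]
        if len(seqs) < 2:
            raise ValueError("an alignment needs >= 2 sequences")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences must be equal length")
        mat = np.empty((len(seqs), len(seqs[0])), dtype=np.uint8)
        for i, s in enumerate(seqs):
            try:
                mat[i] = [_CODE[c] for c in s]
            except KeyError as exc:  # pragma: no cover - defensive
                raise ValueError(f"unsupported base {exc} in {gene_id}") from None
        return cls(gene_id, tuple(ids), mat)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FoldedSFS:
    """Minor-allele-count spectrum for n haploid samples (classes 1..n//2)."""

    n: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n // 2,):
            raise ValueError(f"folded SFS for n={self.n} needs {self.n // 2} classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def s_total(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else np.zeros_like(self.counts)


@dataclass
class ShiftTestResult:
    statistic_name: str
    statistic: float
    p_value: float
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# per-gene statistics


def segregating_sites(aln: GeneAlignment) -> int:
    """Columns with >= 2 distinct non-missing bases (missing = N or gap)."""
    mat = aln.matrix.astype(np.int16)  # avoid unsigned wrap-around of fills
    valid = mat != 255
    enough = valid.sum(axis=0) >= 2
    # a column segregates if max and min of the valid calls differ
    hi = np.where(valid, mat, -1).max(axis=0)
    lo = np.where(valid, mat, 256).min(axis=0)
    return int(np.sum(enough & (hi != lo)))


def _pairwise_diff_stats(aln: GeneAlignment) -> tuple[float, float]:
    """(mean pairwise difference count, mean per-site pairwise diversity)."""
    mat, valid = aln.matrix, aln.matrix != 255
    n = aln.n
    tot_diffs = 0.0
    tot_persite = 0.0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        comp = int(both.sum())
        diffs = int(np.sum((mat[i] != mat[j]) & both))
        tot_diffs += diffs
        tot_persite += diffs / comp if comp > 0 else 0.0
        pairs += 1
    return tot_diffs / pairs, tot_persite / pairs


def nucleotide_diversity(aln: GeneAlignment) -> float:
    """pi per site: mean over unordered pairs of (differences / compared sites)."""
    return _pairwise_diff_stats(aln)[1]


def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalising constants a1, a2, b1, b2, c1, c2, e1, e2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def watterson_theta(aln: GeneAlignment, per_site: bool = True) -> float:
    """Watterson's estimator S / a1, optionally per site."""
    s = segregating_sites(aln)
    theta = s / tajima_constants(aln.n)["a1"]
    return theta / aln.length if per_site else theta


def tajimas_d(aln: GeneAlignment) -> float:
    """Tajima's D; ``nan`` when S = 0 (undefined, excluded from summaries)."""
    s = segregating_sites(aln)
    if s == 0:
        return float("nan")
    k = tajima_constants(aln.n)
    pi_total = _pairwise_diff_stats(aln)[0]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return (pi_total - s / k["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# folded SFS


def folded_sfs_from_calls(genotypes: np.ndarray, n: int | None = None) -> FoldedSFS:
    """Fold biallelic haploid calls into minor-allele-count classes.

    Parameters
    ----------
    genotypes:
        (sites, samples) array of 0/1 alternate-allele calls; negative values
        mark missing calls.  Each polymorphic site adds 1 to class
        min(k, n-k); monomorphic sites (class 0) are dropped.  Sites where
        missingness leaves < 2 calls are skipped and counted in the log.
    """
    gt = np.asarray(genotypes)
    if gt.ndim != 2:
        raise ValueError("genotypes must be 2-d (sites x samples)")
    n = gt.shape[1] if n is None else int(n)
    counts = np.zeros(n // 2, dtype=float)
    skipped = 0
    for row in gt:
        called = row >= 0
        m = int(called.sum())
        if m < 2:
            skipped += 1
            continue
        if np.any(row[called] > 1):
            skipped += 1  # non-biallelic coding
            continue
        k = int(row[called].sum())
        minor = min(k, m - k)
        if minor == 0:
            continue
        # frequency class measured against the full sample size n
        cls = min(k, n - k) if m == n else minor
        counts[min(cls, n // 2) - 1] += 1
    if skipped:
        logger.info("folded_sfs_from_calls: skipped %d sites (missing/non-biallelic)", skipped)
    return FoldedSFS(n=n, counts=counts)


def folded_sfs_from_alignments(alignments) -> FoldedSFS:
    """Folded SFS pooled over gene alignments (biallelic columns only)."""
    alignments = list(alignments)
    n = alignments[0].n
    counts = np.zeros(n // 2, dtype=float)
    skipped = 0
    for aln in alignments:
        mat, valid = aln.matrix, aln.matrix != 255
        for col in range(aln.length):
            calls = mat[valid[:, col], col]
            if calls.size < 2:
                continue
            alleles, ac = np.unique(calls, return_counts=True)
            if alleles.size < 2:
                continue
            if alleles.size > 2:
                skipped += 1
                continue
            counts[min(int(ac[0]), int(ac[1]), n // 2) - 1] += 1
    if skipped:
        logger.info("folded_sfs_from_alignments: skipped %d non-biallelic columns", skipped)
    return FoldedSFS(n=n, counts=counts)


# ---------------------------------------------------------------------------
# shift tests


def paired_wilcoxon(x, y) -> ShiftTestResult:
    """Two-sided paired Wilcoxon signed-rank test, R-style V statistic.

    V is the sum of the ranks of the positive differences after dropping
    zero differences (classic Wilcoxon convention) and average-ranking ties.
    The p-value uses the exact null distribution when there are no ties and
    at most 25 informative pairs, otherwise a normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return ShiftTestResult("wilcoxon_V", 0.0, 1.0, {"n_pairs_used": 0, "warning": "all differences zero"})
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    ties = np.unique(np.abs(d), return_counts=True)[1]
    has_ties = np.any(ties > 1)
    if m <= 25 and not has_ties:
        # exact distribution of V by dynamic programming over rank subsets
        dist = np.zeros(m * (m + 1) // 2 + 1)
        dist[0] = 1.0
        for r in range(1, m + 1):
            dist[r:] += dist[:-r].copy()
        dist /= dist.sum()
        mu = m * (m + 1) / 4.0
        lo = min(v, 2 * mu - v)
        p = float(min(1.0, 2.0 * dist[: int(lo) + 1].sum()))
    else:
        mu = m * (m + 1) / 4.0
        sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
        z = (v - mu) / math.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return ShiftTestResult("wilcoxon_V", v, p, {"n_pairs_used": int(m)})


def variance_equality_test(x, y, center: str = "median") -> ShiftTestResult:
    """Levene (center='mean') / Brown-Forsythe (center='median') F test.

    One-way ANOVA on absolute deviations from the group center; reports
    F(1, n1 + n2 - 2).
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    zx = np.abs(x - (np.mean(x) if center == "mean" else np.median(x)))
    zy = np.abs(y - (np.mean(y) if center == "mean" else np.median(y)))
    if np.allclose(zx, zx[0]) and np.allclose(zy, zy[0]) and np.isclose(zx[0], zy[0]):
        raise ValueError("zero within-group deviation everywhere; F undefined")
    f, p = sps.levene(x, y, center=center)
    name = "levene_F" if center == "mean" else "brown_forsythe_F"
    return ShiftTestResult(name, float(f), float(p), {
        "df1": 1, "df2": int(x.size + y.size - 2), "center": center,
        "var_x": float(np.var(x, ddof=1)), "var_y": float(np.var(y, ddof=1)),
    })


# ---------------------------------------------------------------------------
# summaries


def diversity_summary(alignments) -> pd.DataFrame:
    """Per-gene S, pi, Watterson theta and Tajima's D as a DataFrame."""
    rows = []
    for aln in alignments:
        s = segregating_sites(aln)
        rows.append({
            "gene_id": aln.gene_id,
            "n": aln.n,
            "length": aln.length,
            "S": s,
            "pi": nucleotide_diversity(aln),
            "theta_w": watterson_theta(aln),
            "tajimas_d": tajimas_d(aln),
        })
    return pd.DataFrame(rows)


def _pct(before: float, after: float) -> float:
    return 100.0 * (after - before) / before if before != 0 else float("nan")


def diversity_shift_report(alignments_a, alignments_b) -> dict:
    """Compare per-gene diversity between two samplings of the same gene set.

    Genes are matched by cluster id.  pi summaries use every shared gene
    (invariant genes contribute pi = 0); D summaries use only genes with
    S > 0 in the respective group.  Mean shifts are tested with the paired
    Wilcoxon; variance shifts with Levene (center=mean) on D and
    Brown-Forsythe (center=median) on pi.
    """
    ta = diversity_summary(alignments_a).set_index("gene_id")
    tb = diversity_summary(alignments_b).set_index("gene_id")
    shared = ta.index.intersection(tb.index)
    if shared.empty:
        raise ValueError("no shared gene ids between the two samplings")
    ta, tb = ta.loc[shared], tb.loc[shared]

    def _block(col: str, drop_nan: bool) -> dict:
        va, vb = ta[col].to_numpy(), tb[col].to_numpy()
        if drop_nan:
            ka, kb = va[~np.isnan(va)], vb[~np.isnan(vb)]
        else:
            ka, kb = va, vb
        return {
            "mean_a": float(np.mean(ka)), "mean_b": float(np.mean(kb)),
            "var_a": float(np.var(ka, ddof=1)), "var_b": float(np.var(kb, ddof=1)),
            "pct_change_mean": _pct(float(np.mean(ka)), float(np.mean(kb))),
            "n_genes_used_a": int(ka.size), "n_genes_used_b": int(kb.size),
        }

    pi_block = _block("pi", drop_nan=False)
    d_block = _block("tajimas_d", drop_nan=True)

    w_pi = paired_wilcoxon(ta["pi"], tb["pi"])
    both_d = (~ta["tajimas_d"].isna()) & (~tb["tajimas_d"].isna())
    w_d = paired_wilcoxon(ta.loc[both_d, "tajimas_d"], tb.loc[both_d, "tajimas_d"])
    bf_pi = variance_equality_test(ta["pi"], tb["pi"], center="median")
    da = ta["tajimas_d"].dropna().to_numpy()
    db = tb["tajimas_d"].dropna().to_numpy()
    lev_d = variance_equality_test(da, db, center="mean")

    excluded = sorted(shared[(ta["S"] == 0) | (tb["S"] == 0)].tolist())
    return {
        "n_shared_genes": int(shared.size),
        "pi": pi_block,
        "tajimas_d": d_block,
        "tests": {
            "wilcoxon_pi": w_pi.__dict__,
            "wilcoxon_d": w_d.__dict__,
            "brown_forsythe_pi": bf_pi.__dict__,
            "levene_d": lev_d.__dict__,
        },
        "genes_excluded_from_d": excluded,
    }
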