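"""Diversity statistics against independent brute-force recomputations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from evorescue.diversity import (
    FoldedSFS,
    GeneAlignment,
    folded_sfs_from_alignments,
    folded_sfs_from_calls,
    nucleotide_diversity,
    paired_wilcoxon,
    segregating_sites,
    tajima_constants,
    tajimas_d,
    variance_equality_test,
    watterson_theta,
)

from conftest import random_alignment


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-implementations)


def brute_segregating(aln: GeneAlignment) -> int:
    s = 0
    for col in range(aln.length):
        calls = {int(b) for b in aln.matrix[:, col] if b != 255}
        if len(aln.matrix[:, col][aln.matrix[:, col] != 255]) >= 2 and len(calls) >= 2:
            s += 1
    return s


def brute_pi(aln: GeneAlignment) -> float:
    vals = []
    for i, j in itertools.combinations(range(aln.n), 2):
        diffs = comp = 0
        for col in range(aln.length):
            a, b = aln.matrix[i, col], aln.matrix[j, col]
            if a != 255 and b != 255:
                comp += 1
                diffs += a != b
        vals.append(diffs / comp if comp else 0.0)
    return sum(vals) / len(vals)


def brute_tajimas_d(aln: GeneAlignment) -> float:
    n = aln.n
    s = brute_segregating(aln)
    if s == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    # mean pairwise difference in counts
    tot, pairs = 0.0, 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        for col in range(aln.length):
            a, b = aln.matrix[i, col], aln.matrix[j, col]
            if a != 255 and b != 255 and a != b:
                tot += 1
    pi_total = tot / pairs
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def brute_wilcoxon_v(x, y) -> float:
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    ad = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * len(d)
    k = 0
    while k < len(ad):
        m = k
        while m < len(ad) and ad[m][0] == ad[k][0]:
            m += 1
        avg = (k + 1 + m) / 2.0
        for t in range(k, m):
            ranks[ad[t][1]] = avg
        k = m
    return sum(r for r, v in zip(ranks, d) if v > 0)


def brute_levene_f(x, y, center):
    cx = np.mean(x) if center == "mean" else np.median(x)
    cy = np.mean(y) if center == "mean" else np.median(y)
    zx, zy = np.abs(np.asarray(x) - cx), np.abs(np.asarray(y) - cy)
    z = np.concatenate([zx, zy])
    k, n = 2, z.size
    zbar = z.mean()
    between = zx.size * (zx.mean() - zbar) ** 2 + zy.size * (zy.mean() - zbar) ** 2
    within = ((zx - zx.mean()) ** 2).sum() + ((zy - zy.mean()) ** 2).sum()
    return ((n - k) / (k - 1)) * between / within


# ---------------------------------------------------------------------------


def test_identical_sequences_have_no_variation():
    aln = GeneAlignment.from_sequences("g", ["a", "b", "c"], ["ACGT" * 5] * 3)
    assert segregating_sites(aln) == 0
    assert nucleotide_diversity(aln) == 0.0
    assert math.isnan(tajimas_d(aln))


def test_single_mismatch_pair():
    aln = GeneAlignment.from_sequences("g", ["a", "b"], ["AAAAAAAAAA", "AAAAACAAAA"])
    assert segregating_sites(aln) == 1
    assert nucleotide_diversity(aln) == pytest.approx(0.1)


def test_statistics_match_brute_force_on_random_alignments(rng):
    for rep in range(100):
        aln = random_alignment(rng, n=int(rng.integers(4, 8)), length=int(rng.integers(20, 40)),
                               missing_rate=0.05 if rep % 3 == 0 else 0.0)
        assert segregating_sites(aln) == brute_segregating(aln)
        assert nucleotide_diversity(aln) == pytest.approx(brute_pi(aln), abs=1e-10)
        d, bd = tajimas_d(aln), brute_tajimas_d(aln)
        if math.isnan(bd):
            assert math.isnan(d)
        else:
            assert d == pytest.approx(bd, abs=1e-10)


def test_singleton_only_alignment_gives_negative_d():
    # every segregating site is a singleton: excess of rare variants
    seqs = ["AAAAAAAA", "CAAAAAAA", "ACAAAAAA", "AACAAAAA"]
    aln = GeneAlignment.from_sequences("g", list("abcd"), seqs)
    assert tajimas_d(aln) < 0


def test_watterson_theta_definition(rng):
    aln = random_alignment(rng, 6, 30)
    s = segregating_sites(aln)
    a1 = tajima_constants(6)["a1"]
    assert watterson_theta(aln, per_site=False) == pytest.approx(s / a1)


# folded SFS ----------------------------------------------------------------


def test_folded_sfs_single_site_counts():
    gt = np.array([[0, 1, 1, 1]])  # one site, allele counts 1/3
    sfs = folded_sfs_from_calls(gt)
    assert sfs.n == 4
    assert sfs.counts.tolist() == [1.0, 0.0]


def test_folded_sfs_invariant_data_is_empty():
    gt = np.zeros((5, 6), dtype=int)
    sfs = folded_sfs_from_calls(gt)
    assert sfs.s_total == 0


def test_folded_sfs_total_equals_segregating_sites(rng):
    from evorescue.scenario import make_scenario
    from evorescue.simulate import simulate_alignments

    scen = make_scenario("CCC", (1500,) * 4, (0, 900, 1200, 3600))
    ds = simulate_alignments(scen, 6, genes=40, locus_len=500, mu=1e-5, seed=7)
    alns = ds.alignments()
    sfs = folded_sfs_from_alignments(alns)
    assert sfs.s_total == sum(segregating_sites(a) for a in alns)


# Wilcoxon ------------------------------------------------------------------


def test_wilcoxon_identical_pairs():
    r = paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_wilcoxon_all_positive_differences():
    r = paired_wilcoxon([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert r.statistic == 6.0  # ranks 1+2+3


def test_wilcoxon_matches_brute_force_ranking(rng):
    for _ in range(30):
        n = int(rng.integers(5, 51))
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.5, size=n)
        v = paired_wilcoxon(x, y).statistic
        assert v == pytest.approx(brute_wilcoxon_v(x, y), abs=1e-10)


def test_wilcoxon_exact_p_matches_scipy_small_sample(rng):
    x = rng.normal(size=12)
    y = x + rng.normal(scale=0.7, size=12)
    ours = paired_wilcoxon(x, y)
    ref = sps.wilcoxon(x, y, mode="exact")
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
                min_size=3, max_size=40),
       st.integers(-500, 500))
def test_wilcoxon_v_invariant_under_paired_shift(pairs, shift):
    # integer-valued data keeps the paired differences exact under the shift
    x = [float(a) for a, _ in pairs]
    y = [float(b) for _, b in pairs]
    v0 = paired_wilcoxon(x, y).statistic
    v1 = paired_wilcoxon([a + shift for a in x], [b + shift for b in y]).statistic
    assert v0 == v1


# variance tests ------------------------------------------------------------


def test_levene_zero_for_identical_groups():
    x = [1.0, 2.0, 3.0, 4.0]
    assert variance_equality_test(x, list(x), center="mean").statistic == pytest.approx(0.0)


@pytest.mark.parametrize("center", ["mean", "median"])
def test_variance_test_matches_direct_anova(center, rng):
    for _ in range(20):
        x = rng.normal(size=20)
        y = rng.normal(scale=2.0, size=20)
        ours = variance_equality_test(x, y, center=center)
        assert ours.statistic == pytest.approx(brute_levene_f(x, y, center), abs=1e-10)
        assert ours.detail["df2"] == 38


def test_variance_test_rejects_degenerate_input():
    with pytest.raises(ValueError):
        variance_equality_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], center="mean")
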