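# evorescue

Population-genomic detection of **evolutionary rescue** — the escape of a
crashing population from extinction through rapid adaptation — in clonal
bacterial lineages sampled before and after an environmental perturbation.
The package is aimed at microbial population geneticists who have (or can
simulate) per-gene alignments, SNP calls, a clonal genealogy and gene
presence/absence tables for two sampling time points, and want the four
analyses that together diagnose a rescue event:

1. **Demographic model selection.** All 27 three-interval
   contraction/expansion/constant (K/E/C) population-size models anchored at
   the perturbation dates are fitted to the folded site-frequency spectrum
   by simulation-based composite likelihood
   (lnL = Σᵢ mᵢ ln pᵢ over minor-allele classes, optionally plus a Poisson
   term on total S) and ranked by Akaike weights
   wAIC = 100·e^(−Δᵢ/2)/Σⱼe^(−Δⱼ/2).  A rescue event appears as a U-shaped
   (K-then-E) trajectory winning the ranking.
2. **Diversity shifts.** Per-gene S, π, Watterson's θ and Tajima's
   D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1)), with paired Wilcoxon (V) tests for
   mean shifts and Levene / Brown–Forsythe F tests for variance shifts
   between samplings.  Post-expansion populations show falling π with
   rising D.
3. **Pan-genome partition.** Global core / shared accessory / per-sampling
   exclusive accessory decomposition of a presence matrix, exclusive-gene
   turnover with functional-category tallies, and permutation rarefaction
   curves.
4. **Recombination imports.** A per-branch two-state HMM over substitution
   tracks estimates R/θ (import initiation relative to mutation), δ (mean
   tract length), ν (import divergence), and the derived δν and
   r/m = (R/θ)·δ·ν, with block-bootstrap confidence intervals.

A first-class synthetic-data generator (coalescent genealogies under
piecewise-exponential demography, infinite-sites mutation, geometric import
tracts, structured pan-genomes) provides ground truth for every stage, so
the whole pipeline is verifiable at desk scale without the original
sequencing data.

## Worked example

Simulate an undisturbed population and a post-rescue one (a >99% crash at
the first perturbation followed by a 1,000-fold re-expansion), then compare
their core-gene diversity:

```python
from evorescue import make_scenario, simulate_alignments, diversity_shift_report
from evorescue.scenario import default_anchor_times

anchors = default_anchor_times()              # (0, 863, 1184, 3600) generations
before = make_scenario("CCC", (2000, 2000, 2000, 2000), anchors)
after = make_scenario("KEK", (2000, 20, 20000, 5000), anchors)
ds_a = simulate_alignments(before, n=5, genes=200, locus_len=900, mu=1e-5, seed=1)
ds_b = simulate_alignments(after, n=7, genes=200, locus_len=900, mu=1e-5, seed=2)

rep = diversity_shift_report(ds_a.alignments(), ds_b.alignments())
pi, d = rep["pi"], rep["tajimas_d"]
print(f"pi: {pi['mean_a']:.4f} -> {pi['mean_b']:.4f}  ({pi['pct_change_mean']:+.1f}%)")
print(f"D:  {d['mean_a']:+.3f} -> {d['mean_b']:+.3f}")
w = rep["tests"]["wilcoxon_pi"]
print(f"Wilcoxon V = {w['statistic']:.0f}, p = {w['p_value']:.3g}")
```

prints

```
pi: 0.0416 -> 0.0205  (-50.6%)
D:  -0.037 -> -1.124
Wilcoxon V = 18621, p = 1.35e-25
```

— the bottlenecked-and-recovered sample has lost half its nucleotide
diversity (paired Wilcoxon on the 200 shared genes is decisive), and its
strongly negative mean Tajima's D is the excess-singleton signature of the
explosive re-expansion out of the bottleneck.  The same objects drive the
other stages (`folded_sfs_from_alignments` → `fit_model`/`compare_models`
for the 27-model wAIC table, `partition_pangenome`,
`estimate_recombination`); `evorescue run-all --outdir out --seed 1`
executes everything end-to-end and writes a consolidated `report.json`.
One honest caveat, demonstrated by the package's own experiments and
documented in `docs/methods.md`: folded spectra alias across K/E/C codes
for bottleneck-recovery histories, so single-dataset wAIC rankings of the
27 codes are descriptive rather than reliable regime recovery.

A command-line layer mirrors the stages: `evorescue simulate | stats | sfs |
demography | pangenome | recombination | report | run-all`
(`--preset desk|paper` switches between scaled-down and original simulation
budgets).

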