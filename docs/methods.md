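# Methods

`evorescue` implements the population-genomic workflow used to diagnose an
evolutionary-rescue event in a clonal (haploid) bacterial lineage sampled at
two time points spanning a series of environmental perturbations: coalescent
demographic model selection on the folded site-frequency spectrum (SFS),
per-gene diversity-shift statistics, pan-genome partitioning with
rarefaction, and recombination-import estimation with a per-branch hidden
Markov model.  Every stage can run on fully synthetic data with known ground
truth, which is how the package verifies itself at desk scale.

## Demographic scenarios and the coalescent engine

A `DemographicScenario` is a piecewise-exponential effective-size trajectory
anchored at four events — the original sampling, two intermediate
perturbations, and the final sampling — with a three-letter code over
{K (contraction), E (expansion), C (constant)} read forward in time.  Anchor
times are measured in generations before the final sampling; the default
spacing (0, 863, 1184, 3600) distributes a 3,600-generation study window
proportionally to the calendar gaps between the four event dates (35, 13 and
98 months).  The division-rate conversion helper uses 0.04 h⁻¹ by default
and exposes a scaling knob; the nominal rate corresponds to ≈4,270
generations over the window, inside the published 2,100–6,300 envelope whose
ends the knob reaches at scalings of 0.49 and 1.48.

Between anchors the size changes exponentially (log-linear); a C interval
forces a zero growth rate exactly.  The haploid Kingman coalescent with k
lineages coalesces at rate k(k−1)/(2N(t)).  Genealogies are simulated by
time rescaling: cumulative intensity Λ(t) = ∫dt′/N(t′) has a closed form per
exponential piece, and standard-exponential waiting draws are mapped through
its exact inverse.  Replicate topologies (uniform random joins) and waiting
draws are independent of the demography, so one draw set is generated per
fitting session and re-used for every candidate model — common random
numbers that make likelihood surfaces smooth and model comparisons
noise-matched.  The expected unfolded SFS is accumulated from branch lengths
classified by the number of subtended tips; mutation enters only when
sampled spectra or sequences are required.

## Synthetic data

* **Alignments** (`simulate_alignments`): one independent genealogy per
  gene; infinite-sites mutation within a gene at per-site rate μ (default
  2.5×10⁻⁸ for a non-mutator pseudomonad; desk-scale runs use inflated μ so
  that short loci carry realistic SNP counts at small N).  The ancestral
  base is A at every site and a mutation toggles A↔C, so alignments,
  haploid VCF and newick genealogies round-trip exactly.  The generator
  refuses parameter combinations whose expected per-gene mutation load
  exceeds the gene length (infinite-sites violation).
* **Recombination imports** (`apply_imports`): on each branch, import
  initiations are Poisson with mean R/θ × (expected clonal mutations on the
  branch); tract lengths are geometric with mean δ; within a tract each site
  substitutes independently with probability ν.  The realised tract table
  (0-based half-open, drawn length, substitution count) is the ground truth
  for estimator validation.
* **Pan-genome** (`simulate_pangenome`): a presence/absence matrix with a
  configured number of global-core, shared-accessory and per-group exclusive
  clusters, functional-category labels drawn from a fixed proportion table
  (clusters labelled "unknown" count as unannotated), and an optional
  per-cell flip noise applied after truth counts are recorded.

What the generator does **not** emulate: linkage between genes (gene trees
are independent), within-gene recombination of the clonal background,
selection, gene gain/loss dynamics along the genealogy, sequencing error,
and alignment artefacts.  Passing tests therefore demonstrate correctness of
the inference machinery under its own model assumptions, not robustness to
real-data violations of them.

## Diversity statistics

S, π, Watterson's θ and Tajima's D follow the classical definitions with a
DnaSP-style missing-data policy: pairwise deletion for π; a column is
segregating only if ≥2 distinct non-missing bases remain among ≥2 calls.
Genes with S = 0 have undefined D and are excluded from D summaries but
contribute π = 0 to π summaries (the two published gene counts, 3,503 of
3,682, differ for exactly this reason).  The paired Wilcoxon test reports
the R-style V statistic (sum of positive-difference ranks, zeros dropped,
average ranks for ties) with an exact-distribution p-value for ≤25 tie-free
pairs and a tie-corrected normal approximation otherwise.  Variance shifts
use the Levene (center = mean, applied to D) and Brown–Forsythe
(center = median, applied to π) one-way ANOVA on absolute deviations,
delegated to `scipy.stats.levene` and verified in the tests against a direct
two-step computation.

## Demographic model selection

All 3³ = 27 K/E/C codes are enumerated with epoch boundaries fixed at the
perturbation dates; free parameters are the log₁₀ anchor sizes, and each C
letter ties two anchors (k = 4 − #C).  The expected folded spectrum under a
candidate parameter vector is a Monte-Carlo average (default 5,000
replicates per evaluation at desk scale; 500,000 mirrors the original
study's budget), floored at 1/(10·sims) and renormalised so the composite
log-likelihood Σᵢ mᵢ ln pᵢ over polymorphic classes never sees a zero.

Class proportions alone carry no information about the absolute size of a
constant history, so `fit_model` optionally adds a Poisson log-likelihood
term on the total segregating-site count, with expectation
n_loci × μℓ × E[total tree length]; this is the same absolute-SFS
information simulation-based composite-likelihood tools rely on, and it is
what anchors size recovery in the tests.  Optimisation is cyclic coordinate
search: per cycle, each free parameter is refined by bounded golden-section
search with the ordering constraints of the code enforced as moving bounds
against neighbouring anchors; multi-start (default 5) guards local optima
and the search stops early once a full cycle yields no improvement.
AIC = 2k − 2lnL̂ with natural-log likelihoods applied uniformly; Akaike
weights wAIC = 100·exp(−Δᵢ/2)/Σ exp(−Δⱼ/2) sum to 100 within 1e-9 by
construction.  Parametric bootstrap resimulates the observed S budget from
the fitted class proportions (multinomial), refits, and reports percentile
95% intervals per parameter plus a per-generation trajectory band.

A structural caveat the synthetic experiments make explicit: the folded
spectrum identifies K/E/C codes only weakly.  At n = 7 it has three
classes, so with the S total there are at most four observables and some
2–3-parameter code can almost always match any reachable observation,
out-competing a 4-parameter truth on parsimony.  Enlarging the synthetic
sample (n = 20, ten classes) does not rescue identifiability either: for a
strong crash/re-expansion/contraction truth, other 4-parameter codes (e.g.
expansion in the final interval instead of contraction) reproduce the
truth's expected spectrum essentially exactly, and multinomial sampling
noise decides which alias tops the wAIC ranking in any one replicate.
`rescue_recovery_experiment` therefore *measures* the top-rank behaviour of
the true code across replicates rather than assuming it is recoverable, and
the package treats single-dataset wAIC rankings over this model family as
descriptive, not as reliable recovery of the generating regime.  The
high-precision re-evaluation of fitted optima on a shared large draw set
(``eval_draws``) is essential even for that: without it, flexible codes
additionally profit from chasing search-time Monte-Carlo noise.

## Pan-genome partition

For groups A and B with pan-genomes pan(A), pan(B): global core = clusters
in every genome; shared accessory = (pan(A) ∩ pan(B)) − global core;
exclusive accessory of a group = its pan minus the other group's pan,
regardless of within-group frequency.  These three parts are disjoint and
exhaustive for each group's pan-genome, which is asserted on every run.
Per-group cores (clusters in every genome of the group) are reported
separately.  Rarefaction permutes genome order (default 1,000 permutations)
and reports the mean and 2.5/97.5% band of cumulative distinct clusters; the
final point is permutation-invariant and equals the group pan-genome size.
Greedy centroid clustering (sort by length descending, join the first
centroid passing identity ≥0.9 and length-coverage ≥0.75, k-mer pre-screen,
global edit-distance identity via edlib) replaces the original three-way
clustering consensus, whose internals are not reproducible; it is exact on
the synthetic families the tests generate.

## Recombination-import HMM

Each terminal branch of the clonal genealogy yields a binary substitution
track against a clonal reference — the column majority excluding the focal
tip ("consensus" mode), or the true parent sequence in simulations ("truth"
mode).  The two-state chain {Unimported, Imported} uses the exponential
link for all probabilities: p(U→I) = 1−exp(−(R/θ)·ℓ), p(I→U) = 1−exp(−1/δ),
p(sub|U) = 1−exp(−ℓ), p(sub|I) = ν, with the stationary distribution as the
initial law.  The forward pass is evaluated exactly on run-length segments
of the track using closed-form powers of the 2×2 step matrix (eigenvalue
form, with binary powering as the near-defective fallback) and per-segment
renormalisation — no underflow at genome scale and cost proportional to the
number of substitutions rather than sites.  Branch lengths come from the
input tree and are held fixed.  Maximisation over (R/θ, δ, ν) is bounded
multi-start L-BFGS-B on log₁₀ parameters; δν and r/m = (R/θ)·δ·ν follow by
definition.  On import-free data the surface has a degenerate ridge at
δ → 1 where single-site "imports" absorb ordinary clonal substitutions at
an arbitrary R/θ, so the fit is accepted only if it beats the clonal
Bernoulli null by more than the AIC cost of its three parameters;
otherwise R/θ is reported as zero.  Confidence intervals use a block bootstrap over alignment
columns (default block 100 bp, respecting tract autocorrelation).
Posterior decoding (forward–backward) emits per-site import probabilities
and BED-like tracts at a 0.5 threshold.

## Numerical and reproducibility choices

* Growth rates |g| < 1e-14 are treated as zero; intensity inversion guards
  its logarithm argument; C-coded intervals store exactly zero growth.
* Wilcoxon exact p-values only for ≤25 tie-free pairs (DP over rank sums);
  otherwise normal approximation with tie correction.
* Every stochastic routine takes an explicit integer seed and is a pure
  function of (inputs, seed); the pipeline fans one master seed out to
  stages via `numpy.random.SeedSequence.spawn` in a fixed order, and report
  JSON contains no timestamps, making reruns byte-identical.
* Desk-scale defaults (5,000 sims/evaluation, 10 cycles, B = 100, 200
  permutations) are the package's standard verification conditions; the
  `paper` preset restores the original budgets (500,000 / 40 / 1,000 /
  1,000).

## Known limitations

* The composite likelihood treats SNPs as independent; linkage within genes
  is ignored, so model-selection confidence is overstated on real data.
* The per-branch HMM analyses terminal branches against a consensus rather
  than jointly reconstructing ancestral states; shared imports on internal
  branches are attributed to multiple tips.
* The clusterer is a single greedy pass; it is deterministic and exact on
  well-separated synthetic families but is not a substitute for orthology
  inference on real annotations.
* Published headline values that depend on the twelve sequenced genomes
  (e.g. the real-data wAIC table, π = 0.0075→0.0058) are out of reach by
  design; the package reproduces the printed arithmetic and recovers known
  ground truth on synthetic data instead.
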