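# Methods

`slmdesign` models, designs and analyses short developmental enhancers of the
*Drosophila* blastoderm — elements like the minimal *even-skipped* stripe 2
enhancer (MSE2), which reads anterior–posterior (AP) gradients of maternal and
gap transcription factors (Bicoid, Hunchback, Krüppel, Giant, Knirps, Zelda,
Stat92E, …) and drives a stripe of expression near 40% embryo length (% EL).
This note records the models implemented, the parameters that matter, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Motif annotation

A binding motif is a position probability matrix over {A,C,G,T}. A window `w`
of the motif's length is scored by the natural-log likelihood ratio against a
fixed genomic background,

    LLR(w) = Σ_j log( p_j(w_j) / p_bg(w_j) ),

with the *Drosophila* genomic composition `p_bg(A) = p_bg(T) = 0.297`,
`p_bg(C) = p_bg(G) = 0.203` as the default background. A window is called a
binding site when `LLR > 0`, strictly; both strands are scanned by default and
reverse-strand hits are reported in forward, 0-based half-open coordinates.
Scores are often expressed as a fraction of the motif's maximum attainable LLR
(the consensus score). The log base is irrelevant to every rule built on the
score (sign thresholds and fractions of the maximum are base-invariant);
natural log is used throughout. Count matrices get a pseudocount of 0.5 per
nucleotide so probabilities are strictly positive.

## The thermodynamic sequence-level model

Expression is predicted independently for each AP bin from that bin's factor
concentrations. The modelled region is 35.5–92.5% EL at 1% resolution (58
bins). A bound site carries the statistical weight

    w = K_factor · [TF] · e^LLR ,

and a configuration is any subset of annotated sites whose footprints do not
overlap (steric competition). Its weight is the product of the site weights
times a cooperativity bonus (strength ≥ 1) for each *consecutively bound* pair
covered by a cooperativity rule with gap ≤ `max_gap` — the standard linear-chain
formulation, which makes the partition function and all marginal occupancies
exactly computable by a forward/backward dynamic programme over sites in
position order (`f[i] = w_i(1 + Σ_{j<i, compatible} c_{ji} f[j])`,
`h[i] = 1 + Σ_{j>i, compatible} c_{ij} w_j h[j]`, occupancy
`= f[i]·h[i]/Z`). Brute-force enumeration over all `2^n` configurations is used
as the test oracle for `n ≤ 12`.

Occupancies become transcription through the documented rule set:

* an **activator** site contributes `activation_strength × occupancy`;
* a **coactivatable repressor** (Hunchback) contributes as an activator in
  proportion to the probability that at least one coactivating partner
  (Bicoid) is bound within `coactivation.range` bp (independent approximation
  over partner sites), and as a repressor with the remaining probability;
* each **short-range repressor** multiplies the contribution of activator
  sites within `quench_range` bp by the survival factor
  `1 − quench_efficiency × occupancy`, aggregated multiplicatively over
  repressors (order-independent); repressors may additionally subtract
  `direct_repression_strength × occupancy` from the net activation;
* net activation `A` maps to output through a saturating logistic response
  `R_max / (1 + exp(−steepness (A − midpoint)))`, clipped to the 0–255 display
  scale.

Seven parameter sets (ids 1–7) are shipped in
`src/slmdesign/data/parameter_sets.yaml`. They are synthetic defaults authored
for this package — a documented member of this model family, not a re-fit: the
binding scales are set so a consensus site at peak factor concentration has a
weight of order 1–10 (occupancy 0.5–0.9) while near-threshold sites are weakly
bound; response midpoints (3.8–4.5 activation units) and the Bicoid gradient
length scale (12% EL in the fixture atlas) were fixed, once, so that the
reference arrangement of sites yields a single contiguous stripe peaking at
41.5% EL under every set, and were not revisited afterwards. Set 7 declares
Zelda as a uniformly expressed activator at a constant concentration of 100.
Knirps is included as a central-posterior repressor: without it the Bicoid
tail drives a spurious expression dome at 60–69% EL in the gap between the
Krüppel and posterior Giant domains, which is precisely the region Knirps
occupies in the embryo.

## Sequence design

The designer minimises, by simulated annealing over single-nucleotide
substitutions with Metropolis acceptance and geometric cooling,

    E = Σ_i (x_i − y_i)² + β·o ,

where `x` is the predicted profile, `y` the target, and `o` the number of
unordered pairs of called sites whose footprints overlap or lie within 5 bp of
each other end-to-end (inclusive; same-factor and cross-factor pairs both
count). The default `β` is 1% of the maximum possible sum-of-squares score,
`0.01 × n_bins × 255²` (the overlap term cannot be bounded without a sequence,
so the maximum is read as the SSE ceiling); it is a named, overridable value.
Consensus design over `k` parameter sets minimises the arithmetic mean of the
per-set costs. The proposal kernel is substitution-only — design length is
fixed by the initial sequence; length changes belong to the edit-path module.
Runs are reproducible from a single seed recorded in all outputs.

## Neutral paths

The minimal edit script between two sequences is computed by the unit-cost
Levenshtein dynamic programme with a deterministic backtrace (substitution
preferred over deletion over insertion, edits emitted leftmost-first). Edits
are anchored to columns of the source–target alignment, not to mutable
sequence offsets, so applying them in any order is well defined, always ends
at the target, and changes the sequence by exactly one edit per step.

Each intermediate `x` is scored against the reference profile `y` by

    F = Σ_i ( x_i / max x − y_i / max y )² × Penalty ,
    Penalty = max y / max x  if max x < max y, else 1 ,

implemented exactly as defined. Note the penalty multiplies the standardised
SSE, so when two shapes are identical it is inert (a construct at half the
reference amplitude but the same shape scores 0); a silent construct
(`max x = 0`) scores +inf. The path objective is the sum of F over every
intermediate and every scoring parameter set. Ordering is greedy (apply the
remaining edit whose resulting sequence scores best; ties break to the lowest
alignment column, so score-neutral scripts come out left-to-right), optionally
refined by seeded Metropolis swaps over the permutation; exhaustive search is
available for scripts of ≤ 8 edits and anchors the ≤1%-of-optimum test. Step
scoring uses model predictions only, never measured data.

The full-length synthetic bundle paths (251 and 272 edits, below) use a fixed
deterministic order — greedy ordering is quadratic in script length times a
full model evaluation and is demonstrated and verified on short scripts, where
the exhaustive optimum is computable.

## Binding-site turnover

Two sequences are aligned globally (Needleman–Wunsch via Biopython's
`PairwiseAligner`; defaults match +2, mismatch −1, gap open −5, gap extend −1,
config-exposed) and sites are called independently on both at `LLR > 0`. A
reference site is *maintained* if a same-factor site on the other sequence
starts within 3 alignment columns (inclusive) of it, else *lost*; unmatched
sites on the other sequence are *gained*. Matching is per-factor, one-to-one,
greedy nearest-first, and strand-agnostic (a site that flips strand in place
confers the same affinity). Maintained + lost always equals the reference
census; maintained counts are nondecreasing in the tolerance.

## Expression variability

Per-nucleus fluorescence tables (embryo, nucleus, AP%, fluorescence, line) are
first corrected for between-embryo brightness: one multiplicative scale per
embryo minimises the sum of squared pairwise differences between per-embryo
bin means in 1% AP bins, subject to the scales summing to the number of
embryos. This constrained quadratic is solved exactly through its KKT linear
system (least-squares solve, constraint re-imposed to machine precision); a
black-box SLSQP optimiser is the test oracle. Bins are half-open `[k, k+1)` %.

On the scaled, pooled nuclei the package computes: an OLS regression (with
intercept) of per-bin SD on per-bin mean, population-SD convention (`ddof=0`,
switchable); and mean-normalised values (each value divided by its 1%-bin
mean) within an AP window, default 60–80% EL, requiring every window bin
populated.

The comparison distribution is the steady state of the two-state (telegraph)
promoter: the transcript count and the ON/OFF promoter state are coupled
random variables with ON-state synthesis rate `N` (in units of the mRNA
degradation rate), ON probability `p`, and switching parameter `b = 4` by
default, mapped to rate constants as `k_on = b·p`, `k_off = b·(1−p)` (so
`k_on/(k_on+k_off) = p` and the total switching rate is `b` in degradation
units — this mapping is an assumption of the implementation and is stated
here). The distribution is obtained numerically as the stationary vector of
the truncated master-equation generator over states (promoter, n), n ≤ n_max
(required ≥ 5N; mass above 1e−6 at the boundary raises an error). The OFF and
ON components α_n and β_n are returned alongside their sum φ_n. Validation:
normalisation, the closed-form mean μ = N·p, the Poisson(N) limit as p → 1,
and agreement with a long exact-stochastic (Gillespie) trajectory. At fixed
mean, variance falls monotonically with `p` — the mechanism by which a
chromatin-opening activator (high p, lower N) drives quieter expression than
a strong but nucleosome-competing one (low p, higher N).

Variance homogeneity between two mean-normalised samples is tested with the
Fligner–Killeen statistic implemented from its definition — absolute
deviations from each sample's median, joint average ranks, one-sided normal
scores `Φ⁻¹(1/2 + r/(2(n+1)))`, and a χ² statistic on the group score means —
and cross-checked against an independent library implementation. Its type-I
error is calibrated by simulation in the test suite.

## Synthetic data: what it emulates, and what it does not

No measured data ship with the package. The `fixtures` module generates:

* **Atlas** — stylised AP profiles on 35.5–92.5% EL: Bicoid exponential
  anterior gradient (length scale 12% EL), Hunchback anterior sigmoid, Giant
  anterior + posterior domes, Krüppel central dome, Knirps central-posterior
  dome, uniform Zelda, broad central Stat92E plateau. Shapes are designed, not
  fitted to an imaging atlas; model acceptance is therefore qualitative
  (stripe position and contiguity), never a bit-target against in vivo
  profiles.
* **PWMs** — synthetic sharp-consensus count matrices (97/100 counts on the
  consensus base) built on field-standard consensus motifs. The sharpness was
  chosen so the 480 bp reference element carries a census of a few tens of
  `LLR > 0` sites for the four gap factors, the regime such elements show in
  practice.
* **Reference bundle** — a 480 bp stripe-2-like element with a planted
  activator/repressor site layout (including a head-to-head Bicoid pair);
  design targets at exactly 251 (same length) and 272 edits (shrinking to
  319 bp); path intermediates sampled along both edit series, with the s-path
  ordered so its last 22 edits are substitutions and its step-250 intermediate
  is already 319 bp (its distance to the reference is then exactly 250 by the
  triangle inequality); a 40-record construct catalogue including homotypic
  6-motif lines; and an averaged-expression table whose amplitudes encode the
  qualitative outcomes the designs are meant to probe, including a >10-fold
  peak ratio between the strong short element and the reference. Exact-edit
  targets are grown one accepted edit at a time (a move is kept only if the
  edit distance, tracked with edlib, rises by exactly one), with substitutions
  biased toward bases under-represented in the reference — random equal-length
  sequences plateau near 0.52n edits, so deeply diverged targets are
  necessarily composition-skewed, as designed motif-dense sequences are.
* **Embryos** — per-nucleus tables: counts drawn from the telegraph
  distribution, scaled so bin means track a supplied profile, times a
  per-embryo lognormal scale (sd 0.15 by default; 6 embryos × 20 nuclei/bin
  default, 4 × 60 in the faster analysis runs).

Passing tests on these fixtures demonstrate that the machinery is correct and
the study's analysis regime is reproducible end-to-end; they do not validate
the model against real imaging data, which the package does not ship. The
generator does not emulate imaging noise, segmentation error, dorsoventral
structure, or nuclear-cycle time classes.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (one generator per run,
echoed in output headers); same seed, same inputs ⇒ byte-identical outputs.
Default analysis sizes — 58-bin profiles, 480 bp reference, ≤ 12-site
enumeration oracles, 1,000-replicate test calibrations, ~10⁵-event stochastic
simulation checks — were chosen so a full verification pass runs in seconds to
a few minutes on one core.

## Known limitations

* The kinetic parameter sets are authored defaults, not fits; absolute output
  levels and the stripe's exact width carry no quantitative meaning.
* Cooperativity acts between consecutively bound sites only; arbitrary-pair
  interaction graphs would require a different (exponential or transfer-matrix)
  treatment.
* The shape-cost penalty is inert for shape-identical profiles (see above);
  this is faithful to the cost's definition, and flagged here because users
  sometimes expect under-expression to be penalised even at identical shape.
* The turnover module is pairwise only; no multiple alignment across a whole
  path, no phylogenetic footprinting.
* No inference of (N, p, b) from data — distributions are compared by summary
  statistics and tests, not by likelihood fitting.
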