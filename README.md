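# slmdesign

Thermodynamic sequence-level modelling and in silico compensatory design of
developmental enhancers.

Enhancers of the early *Drosophila* embryo — the minimal *even-skipped*
stripe 2 element is the canonical example — convert smooth anterior–posterior
gradients of transcription factors (Bicoid, Hunchback, Krüppel, Giant,
Knirps, Zelda, Stat92E, …) into sharp stripes of gene expression. `slmdesign`
is a toolkit for studying how far a mechanistic model of that conversion can
be pushed: it predicts expression from sequence, designs new enhancers
against a target pattern, mutates one enhancer into another along "neutral
paths" that conserve the predicted pattern at every single-nucleotide step,
quantifies binding-site turnover between sequences, and analyses
within-embryo expression variability with a stochastic promoter model. It is
aimed at computational biologists working on cis-regulatory logic and
synthetic enhancer design.

## The models

**Occupancy.** Binding sites are motif matches with a positive
log-likelihood ratio, LLR(w) = Σ_j log(p_j(w_j)/p_bg(w_j)), against the
*Drosophila* genomic background (P_bg(A) = P_bg(T) = 0.297,
P_bg(C) = P_bg(G) = 0.203). A bound site has statistical weight
w = K·[TF]·e^LLR; configurations of non-overlapping bound sites (steric
competition), with multiplicative cooperativity between consecutively bound
partner sites, define a partition function solved exactly by dynamic
programming. Marginal occupancies feed a rule set with short-range quenching,
direct repression, and coactivation of Hunchback by nearby Bicoid; net
activation passes through a saturating response scaled to a 0–255 display
range. Seven kinetic parameter sets (synthetic defaults spanning the model
vocabulary) ship with the package.

**Design.** Simulated annealing over single-base substitutions minimises
E = Σ_i (x_i − y_i)² + β·o, where o counts motif pairs closer than 5 bp
end-to-end and β defaults to 1% of the maximum possible score
(0.01·n_bins·255²); consensus design averages E over several parameter sets.

**Neutral paths.** The Levenshtein edits between two sequences are anchored
to alignment columns and re-ordered — greedily, with optional annealing —
to minimise Σ_steps F, with
F = Σ_i (x_i/max x − y_i/max y)² × Penalty and Penalty = max y / max x
whenever the model maximum falls below the reference maximum.

**Turnover.** Sites called at LLR > 0 on two globally aligned sequences are
classified maintained / gained / lost with a 3 bp alignment tolerance,
matched per-factor, one-to-one, strand-agnostically.

**Variability.** Per-embryo scale factors (sum constrained to the number of
embryos) remove between-embryo brightness differences; per-1%-bin mean–SD
regression and mean-normalised distributions are compared with the
steady-state mRNA distribution φ_n = α_n + β_n of the two-state (telegraph)
promoter with ON-strength N, ON-probability p, switching parameter b = 4, and
mean μ = N·p; variance homogeneity is tested with a from-definition
Fligner–Killeen statistic.

No measured data ship with the package: the `fixtures` module generates a
synthetic TF atlas, synthetic PWMs, per-nucleus embryo tables, and a
synthetic 480 bp reference element with designed edit targets at 251 and 272
edits (the latter shrinking to a 319 bp element), so every stage is testable
end-to-end.

## Worked example

```python
import numpy as np
import slmdesign as sd

bundle = sd.build_reference_bundle(seed=0)           # synthetic reference data
ps = sd.load_parameter_set(id=1)                     # one of the 7 shipped sets

# predict the stripe driven by the 480 bp reference element
profile = sd.predict_expression(bundle.reference, bundle.atlas, ps, bundle.catalogue)
print(f"peak {profile.peak:.1f} at {profile.peak_position:.1f}% EL")

# binding-site turnover after 60 edits along the compensatory path
report = sd.compare_sequences(bundle.reference, bundle.constructs["e60"],
                              bundle.catalogue, ["bcd", "hb", "Kr", "gt"])
print(f"{report.total_maintained} maintained ({report.percent_maintained:.0f}%), "
      f"{report.total_gained} gained, {report.total_lost} lost")

# the strong short element: 250 edits away, 319 bp long
script = sd.levenshtein_script(bundle.reference, bundle.constructs["s250"])
print(f"{script.distance} edits; short element {len(bundle.constructs['s250'])} bp")

# telegraph promoter model at N=20, p=0.5, b=4
from slmdesign.variability import TelegraphParams, telegraph_pmf
dist = telegraph_pmf(TelegraphParams(N=20, p=0.5, b=4), n_max=140)
print(f"telegraph mean {dist.mean:.2f} (N*p = 10), CV {np.sqrt(dist.variance)/dist.mean:.2f}")
```

prints

```
peak 250.9 at 41.5% EL
28 maintained (64%), 2 gained, 16 lost
250 edits; short element 319 bp
telegraph mean 10.00 (N*p = 10), CV 0.55
```

The element drives a single stripe peaking at 41.5% embryo length under every
parameter set; a majority of gap-factor binding sites survive 60 compensatory
edits; the designed short element sits 250 edits from the reference at two
thirds of its length; and the telegraph distribution reproduces its
closed-form mean μ = N·p.

A command-line interface mirrors the library —
`slmdesign scan | predict | design | path | turnover | variability | telegraph | fixtures`
— reading FASTA, JASPAR-style PWM files and TSV tables, and writing TSV with
provenance headers. `slmdesign fixtures bundle --seed 0 --out bundle/` writes
the full synthetic reference bundle to disk.

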