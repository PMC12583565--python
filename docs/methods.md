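# Methods

## Study design the package models

Episignature studies for rare monogenic disorders share a structure:
a small discovery group of confirmed variant carriers (here 14) against
an excess of unaffected controls, additional carriers held out for
validation, a screening pool of unresolved cases, VUS carriers whose
classification the signature should inform, mosaic carriers whose blood
carries the variant in only a fraction of cells, and a background of
other-disorder cohorts against which specificity must hold. `episig`
implements the analysis for this design and ships a generator that
reproduces its statistical structure with known ground truth, because
the raw patient data behind such studies are generally not shareable.

## Differential methylation

Statistics are computed on M-values, $M = \log_2(\beta/(1-\beta))$ with
$\beta$ clipped to $[\varepsilon, 1-\varepsilon]$, $\varepsilon =
10^{-6}$: the logit transform stabilizes variance across the
methylation range, which matters for linear modeling; effect sizes are
reported on the beta scale because methylation differences are
conventionally read as fractions.

Per probe $g$, an ordinary least-squares fit of
$M \sim \text{intercept} + \text{group} (+ \text{covariates})$ yields
the group coefficient (case-minus-control M difference) and residual
variance $s_g^2$ with $d_g = n - p$ degrees of freedom. The
empirical-Bayes prior $(d_0, s_0^2)$ is estimated by moment-matching on
$z_g = \log s_g^2$: with $e_g = z_g - \psi(d_g/2) + \log(d_g/2)$,

- the excess spread $\operatorname{var}(e) - \psi'(d_g/2)$ determines
  $d_0$ via the inverse trigamma (Newton iteration);
- $s_0^2 = \exp\{\bar e + \psi(d_0/2) - \log(d_0/2)\}$.

When the observed log-variance spread does not exceed what sampling
alone produces, $d_0 = \infty$ and $s_0^2$ is the pooled
(arithmetic-mean) variance; in the fully degenerate case of identical
sample variances this reduces the moderated t to the ordinary
two-sample t exactly. Posterior variances are
$\tilde s_g^2 = (d_0 s_0^2 + d_g s_g^2)/(d_0 + d_g)$, the moderated t
is the group coefficient over $\tilde s_g \cdot \mathrm{SE}$, and
p-values use $d_0 + d_g$ degrees of freedom (normal in the infinite
limit). The implementation is cross-checked in the test suite against
an independently coded per-probe evaluation of these formulas (inverse
trigamma by bracketed root search) and against the limma reference
implementation on a shared M matrix.

Multiple testing uses Benjamini–Hochberg step-up (delegated to
statsmodels; an exhaustive brute-force oracle over short vectors guards
the call). NA policy: probes with any missing beta among the analysis
samples are dropped before testing.

## Probe selection

Defaults $q_{\max} = 0.01$, $\delta_{\min} = 0.05$, cap 1000, ranking
by $|t|$ with lexicographic probe-id tie-breaks for reproducibility.
Published signature sizes (a few hundred probes) are data-dependent
outcomes, not targets; with the generator defaults the selection lands
near the planted 200.

## Classifier and MVP score

A linear-kernel SVM (C = 1) on the beta values of the signature probes,
cases versus everything else in the training partition. All cases
train; controls and each other-disorder cohort are split 75/25
stratified by cohort label so specificity is measured on held-out
background. The high-dimension/low-n regime argues for the linear
kernel; hyperparameters are exposed. Decision values are calibrated
with Platt's sigmoid $P = 1/(1+e^{Ad+B})$ fitted by maximum likelihood
with Platt's smoothed targets $(N_+ + 1)/(N_+ + 2)$ and $1/(N_- + 2)$,
which keeps scores off the 0/1 boundary even for separable training
sets. The resulting MVP score is the calibrated probability that a
sample carries the episignature; the screening call threshold defaults
to 0.5. Leave-one-case-out validation re-runs selection and training
without the held-out case and reports its score and its branch at a
two-cluster cut of the Ward dendrogram.

## Clustering and embedding

Heatmap-style structure uses Ward linkage on Euclidean distances over
signature-probe betas (betas, not M, matching how such heatmaps are
drawn); samples are sorted by id before linkage so dendrograms are
order-invariant. The MDS is classical Torgerson scaling — double-center
the squared-distance matrix, take top eigenvectors scaled by root
eigenvalues — which reproduces intrinsically low-dimensional Euclidean
configurations exactly; axis signs are fixed (first nonzero loading
positive) for stable plots and tests.

## DMR calling

Published episignature studies typically call DMRs with kernel-based
tools whose parameters are rarely fully specified; `episig` instead
defines a transparent run-based caller: genomically sorted probes with
$q \le 0.05$ are grown into runs while consecutive significant probes
stay within 1 kb and keep one direction; runs of ≥ 3 probes become
regions spanning [first probe, last probe + 1). The region statistic is
an equal-weight Stouffer combination of member probes' one-sided,
direction-aligned z-scores (mixed-direction regions are impossible by
construction); region p-values are BH-adjusted across candidate
regions. Counts such as "12 hypermethylated DMRs" in the recovery tests
are properties of the planted simulation, not reconstructions of any
real genome.

## Genomic context

Coordinates are 0-based half-open throughout (BED convention); the
probe position is the C of the CpG. CpG categories: island (inside),
shore (≤ 2 kb from an island boundary, measured as `start − pos` on the
left flank and `pos − end` on the right), shelf (≤ 4 kb), inter-CGI.
Gene categories with strand-aware upstream distance: promoter (0–1 kb
upstream of a TSS), promoter+ (1–5 kb), CDS, intergenic, with
precedence promoter > promoter+ > CDS since the categories must be
disjoint and promoter context is the biologically loaded one. DMRs are
annotated at their midpoint. Category percentages are integer-rounded
(half away from zero) with the remainder assigned to the largest
category so summaries total exactly 100. The vectorized annotator is
tested for exact agreement with a naive linear-scan oracle.

## Synthetic cohorts

Per-probe background means are drawn from an equal mixture of
Uniform(0.1, 0.4) and Uniform(0.6, 0.9) — methylation arrays are
dominated by mostly-unmethylated and mostly-methylated CpGs. Sample
betas follow Beta(μ·φ, (1−μ)·φ) with precision φ = 50, giving
within-group standard deviations of 0.04–0.07, a realistic array noise
level. Case effects are planted on the mean scale: signature-probe
means shift by ±Δβ (default 0.15 for the fixture; 90% upward to mirror
a predominantly hypermethylated profile), clipped to [0.02, 0.98] with
a warning. Mosaic samples are mean-scale mixtures
$f\,\mu_{case} + (1-f)\,\mu_{control}$. Batch effects, when enabled,
add N(0, σ) on the logit-mean scale. All draws descend from one seed
through fixed-order substreams (one per sample), so subsets are
reproducible and adding samples does not perturb earlier ones.

For DMR recovery the generator has a clustered-signature mode that
plants the signature as genomic runs of adjacent probes (the manifest
lays probes out in island-anchored units whose intra-island spacing is
~100–180 bp, so such runs exist by construction).

What the generator does **not** emulate: probe cross-reactivity,
SNP-affected probes, cell-composition heterogeneity, age/sex
methylation drift, and chip/position batch structure beyond the single
additive term. Passing recovery and separation tests therefore
demonstrates correctness of the algorithms under the stated noise
model, not expected performance on real arrays, where confounder
handling dominates difficulty.

Other-disorder cohorts draw a configurable fraction (fixture: 25%) of
their signature probes from the case signature, so cross-cohort overlap
analysis has planted shared biology to detect.

## Clinical prevalence

Features are tri-state (present / absent / unknown); unknowns never
enter denominators. Percent = 100·affected/responders, rounded half
away from zero to the nearest integer except exact half-integers, which
keep one decimal (87.5 stays 87.5). Published tables of this kind
occasionally round inconsistently (e.g. printing 83 where 36/43 rounds
to 84); the package applies the stated rule uniformly and its tests
assert only rows where the rule reproduces the printed value. The
bundled 53-individual example cohort encodes per-individual states
deterministically from published aggregate counts — the counts, not the
synthetic individual assignments, are the contract.

## Problem sizes and numerical choices

Default analyses and tests run at 10,000 probes and ~50–90 samples,
sizes at which every stage is sub-second except leave-one-out (14
re-discoveries, under a second total); the full test suite runs in
under a minute. Tolerances: oracle equivalences at 1e-10 (absolute),
limma cross-check at 1e-6 (relative), MDS exactness at 1e-9,
determinism of retraining at 1e-8. Ties are broken lexicographically
(probe selection) or by sorted sample ids (clustering). Degenerate
inputs: zero-variance probes get finite moderated statistics through
shrinkage; empty selections warn rather than raise; empty DMR lists
serialize as header-only tables; cohorts with fewer than two samples go
wholly to the training split with a warning.

## Known limitations

- No surrogate-variable or cell-type deconvolution adjustments;
  covariates enter only additively.
- The multi-signature classification board of production systems is
  reduced to one binary classifier per signature; cross-signature
  responses are observable by scoring but not modeled.
- The DMR caller is a deliberately simple stand-in for kernel-based
  callers and is not tuned to reproduce any published region list.
- Real-data quantities that depend on proprietary databases or
  unavailable raw data (printed signature sizes, DMR coordinates,
  cross-cohort overlap percentages) are out of reach by design; the
  package validates the machinery on planted truth instead.
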