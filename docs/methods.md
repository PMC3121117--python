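# Methods

This note documents the models and procedures implemented in `glycolink`,
the parameters that matter, the synthetic study conditions, and the design
choices made where the design was genuinely open.

## Expression preprocessing

**Background correction.** Raw one-color intensities are corrected per
array under the convolution model `X = S + B`, with true signal
`S ~ Exp(alpha)` and noise `B ~ N(mu, sigma^2)`, applied to net
intensities (foreground − background). Parameters are fit per array by
tail moments: `mu` is the mode of a kernel density estimate of the net
intensities, `sigma` the root-mean-square spread of the lower tail below
the mode (dominated by noise), and `alpha` the mean excess above the mode
(dominated by signal). Raw second/third-moment matching was rejected
because the skewness estimator destabilizes whenever the signal scale
exceeds the noise scale — the common case on real arrays. Each probe is
replaced by the posterior mean

```
E[S | X = x] = mu_sx + sigma * phi(mu_sx/sigma) / Phi(mu_sx/sigma),
mu_sx = x − mu − sigma^2 / alpha,
```

evaluated in log space to stay finite deep in the lower tail, and the
output is `log2(corrected + offset)`. The offset (default 16, the usual
order of magnitude for this correction; the appropriate value depends on
the scanner and is configurable) damps the variance of log-ratios near
zero. Degenerate arrays (empty tails or non-positive moment estimates)
fall back to `max(net, offset/2)` with a logged warning. The corrected
output is monotone in net intensity for fixed parameters.

**Clustering / correlation / LOOCV.** Hierarchical clustering uses
Euclidean distance with complete or Ward linkage (scipy). Sample
similarity is the Pearson correlation of expression profiles. The
leave-one-out nearest-neighbor classifier assigns each sample the class of
its nearest other sample under distance `1 − r`; ties resolve to the
lowest sample index for determinism.

**Differential testing.** Per lineage, iPSC vs SC samples are compared
gene-wise with the pooled-variance (Student) two-sided *t*-test — Student
rather than Welch because the equal-variance form is the classical choice
for these designs — with `df = nA + nB − 2`. Zero-pooled-variance genes
get `p = 1` when the means agree, else `p = 0` (exact constant offset),
with a warning. BH step-up q-values are computed within each lineage
(statsmodels). A gene passes at `q < 0.05` (strict) and fold change
`>= 2.0`. The fold-change cut defaults to the log scale
(`|Δlog2| ≥ log2(2.0)`), because the data are log intensities; a
linear-scale variant (ratio of linear-scale group means) is available via
`fc_scale`, since "a 2.0-fold change in average values" is ambiguous
between the two. The signature intersects the per-lineage lists,
requiring the same sign of change everywhere; discordant genes are
dropped and logged. Per member the *minimum* fold-change magnitude and
*maximum* q across lineages are reported — the conservative summary.

## Network screening

**Reference networks.** For each functional gene set `F`, the candidate
targets are the measured genes bound by at least one TF and contained in
`F`; edges run TF → target for every binding TF. TFs are never targets,
so the graphs are bipartite and acyclic by construction (self-regulatory
TF→TF edges are excluded; allowing them could create 2-cycles from
reciprocal binding). Networks without targets, or whose targets miss the
expression signature entirely, are dropped.

**Enrichment.** Hypergeometric upper tail `P[X ≥ k]` of signature genes
among the network's target genes; regulator nodes are excluded from the
draw. The universe defaults to the number of measured genes and is
configurable.

**Gaussian network likelihood.** The DAG's joint density factorizes into
per-node conditionals. Under the linear-Gaussian model each node
contributes the maximized log-likelihood of an OLS regression (with
intercept, no regularization) of the node on its parents; root nodes use
the marginal variance. All regressions for a data set are solved from one
centered cross-product (Gram) matrix, which makes scoring thousands of
null networks cheap. Residual variances are floored at 1e-12; an
in-degree ≥ n−1 is an error.

**GCP.** Null networks keep the node set and edge count and randomize the
structure: a uniform random node permutation is drawn as topological
order and edges are sampled uniformly without replacement from all
order-respecting pairs — exact acyclicity with full support over
order-respecting edge sets (the sampler is a design choice; a switch to
restrict regulator identity is out of scope). The GCP is the plus-one
upper-tail estimator `(1 + #{ll_null ≥ ll_obs}) / (1 + n_random)`; the
upper tail because the screen selects *for* structures that fit the data
better than random ones, and plus-one so no network gets an exactly-zero
empirical p. Consistency is declared at GCP < 0.05 with `n_random = 2000`
by default (tests use fewer). Scoring defaults to iPSC samples only
(`sample_scope_for_gcp`), since the screen targets networks activated in
the reprogrammed state; `all` is available. GCP is computed only for
networks that already passed enrichment (the cheaper test runs first,
matching the screening step order). Regulator nodes contribute marginal
terms in both observed and null scoring so node sets — and hence
likelihoods — are comparable across null draws.

Calibration: on structure-free i.i.d. data the GCP rejection rate at 0.05
stays within the binomial band around the nominal level (slightly below,
from plus-one conservatism). Power: with planted coefficients 0.8 and
residual sd 0.5 on 10-node/9-edge DAGs and 20 samples, detection is
essentially certain (see `scripts/acceptance.py`).

## Glycan stage

Replicate spots are averaged, the per-(lectin, sample) background is
subtracted, and the result is floored at `lectin_floor` (default 1.0
fluorescence unit) so log transforms are defined; flooring events are
counted. Lectin differential tests and lectin–enzyme correlations run on
log2 signals by default (intensities are multiplicative; a linear-scale
switch exists). The lectin test pools all lineages into one iPSC-vs-SC
contrast, mirroring the two-class split of the array design; BH-FDR is
applied across lectins. Correlation significance uses the *t* transform
`t = r sqrt((n−2)/(1−r^2))` with `n−2` df (the standard exact null for
bivariate-normal data); pairs with fewer than 4 shared samples are
skipped. The glycan signature keeps lectins that pass the differential
test and map (via the curated lectin–glycan–enzyme table) to at least one
expression-signature enzyme.

## Integration

Candidates are the union of (a) network-signature genes restricted to the
known enzyme universe — the enzymes named in the curated map plus an
optional explicit list, making the narrative "glycan-related" filter
reproducible; heparan-sulfate genes are excluded from the default union —
and (b) the glycan-signature enzymes, with evidence tags
`network`/`glycan`/`both`. A shipped curated table annotates candidates
with function class and glycan structure; unannotated genes are flagged
`Unknown`. The candidate count always satisfies inclusion–exclusion over
the two sides.

## Synthetic study conditions

The generator emulates the study shape: 4 lineages (AM, PAE, UtE, MRC),
one parental SC line with 3 samples and 3 iPSC lines × 3 passages per
lineage (48 samples; the real study's lineages carried 1–3 iPSC lines
each — the generator default sits at the top of that range to keep
per-lineage group sizes realistic), 2,000 genes (a deliberate scale-down
of the ~16,000-gene array for fast tests; fractions, not counts, are the
contract), baselines `N(8, 1.5)` log2 units, a shared iPSC-vs-SC
component on 10% of genes at ±2.0 log2 with lineage-specific effects on
5% per lineage, and i.i.d. `N(0, 0.5)` noise. Networks (40; 8–15 nodes;
1–4 regulators; star topology) alternate data-consistent — targets
regenerated inside the GCP scope as `0.8 × parent + N(0, 0.5)`, recentred
to keep their original scope mean so the planted differential structure
survives — and inconsistent (same topology class, targets untouched).
Consistent networks draw 90% of targets from the planted common genes
(the "consistent and enriched" condition); regulators come from
undifferential genes, which is immaterial to enrichment because regulator
nodes are excluded from the draw. Lectins (43; half coupled) have true
signals `2^(slope × log2-expression + intercept)` with triplicate spots
at 5% CV and backgrounds `N(100, 10)` truncated at 0; uncoupled lectins
are log-normal noise. A separate constructed fixture pins the glycan
stage's bookkeeping: 16 lectins coupled to 12 planted enzymes (with
redundant many-to-one relations), 4 differential decoys mapped only to
undifferential genes, and 23 noise lectins — at effect size 4.0 so the
expected 16/12 outcome is unambiguous rather than power-limited.

What the synthetic conditions do *not* emulate: probe-level artifacts,
spatial array effects, dye chemistry, correlated noise between genes,
batch effects, and heavy-tailed intensity distributions. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated Gaussian model, not robustness to real-array pathologies.

Every generator is a pure function of (design, seed); sub-stage streams
are derived from the seed and the stage name, and the full pipeline is
byte-reproducible for a fixed seed.

## Numerical choices and limitations

- Gene identifiers are opaque, case-sensitive strings; no alias
  harmonization (OCT3/4 vs POU5F1 must be resolved upstream).
- TSV everywhere (UTF-8, `#` comments, floats at 9 significant digits so
  write→parse round-trips are identity up to formatting).
- Under the stated per-lineage group sizes (9 iPSC vs 3 SC), per-lineage
  differential sensitivity on planted genes is ≈ 0.98, so the four-way
  intersection retains ≈ 0.93 of the shared planted genes — the
  compounding of four independent ~0.98 selections, not an implementation
  loss; `scripts/acceptance.py` reports both numbers.
- The GCP null distribution is re-sampled per network with seeds spawned
  deterministically from the run seed; results are reproducible for a
  fixed seed and reference order.
- `n_random_networks ≥ 100` is recommended for reported runs; the
  plus-one estimator bounds the smallest attainable GCP at
  `1/(1 + n_random)`.
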