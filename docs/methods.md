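# Methods

## Model and assumptions

The screen treats a chemical–chemical and a protein–chemical interaction
table as the only evidence. Both carry integer evidence-channel scores on
the STITCH 0–1000 scale; a link *exists* iff its combined score is strictly
positive, and the other channels (similarity/experimental/database/
textmining for chemicals; experimental/prediction/database/textmining for
proteins) are used only by the feature encoder. Links are undirected; both
orientations of a pair are merged on parsing, and a duplicate pair with
conflicting scores keeps the record with the larger combined score (maximal
evidence) with a warning.

The method assumes guilt by association: functional similarity is carried
by direct interaction, never by two-hop paths or pathway expansion. Genes
enter only through their mapped proteins; the gene→protein mapping is an
explicit input file because no inference from gene symbols to protein
accessions is attempted. A gene with several proteins contributes each
linked protein once (set semantics, no multiplicity).

## Rating scores and the permutation null

The rating score of compound *c* against a reference set is the mean
combined score of the links that exist between *c* and the set, and 0 when
none exists. Note what this is *not*: it does not reward the number of
links, only their average strength, so the permutation test asks whether
*c*'s links into the disease set are *stronger* than its links into random
sets of equal size — not more numerous.

The empirical P-value is W/n over n random reference sets (default 1,000)
drawn without replacement, where W counts sets whose rating score strictly
exceeds the observed one; ties do not count, so a compound whose scores are
exchangeable with the universe has P near 0.5 rather than 1. The sampling
frame is the full interaction universe (all compound ids in the chemical
table for the chemical channel; all protein ids in the protein table for
the gene channel) minus the assessed compound. The gene-channel reference
size is the number of distinct proteins mapped from the disease gene set,
since scoring operates at the protein level. Sets are drawn from
per-compound substreams of one seeded generator, so results are
reproducible and independent of assessment order; a `share_sets` option
reuses one sequence of sets across compounds instead. An `exhaustive` mode
enumerates every subset on small universes and is the test oracle for the
Monte-Carlo path.

Thresholds are the per-channel maxima of the approved drugs' own P-values,
computed by running the identical assessment on the drugs (drugs failing
the association test drop out of this cohort and out of the clustering
reference). Comparisons are inclusive (≤).

## Feature encoding

Fifteen features per compound: five chemical channels versus the approved
drugs, five versus the disease chemicals, five protein channels versus the
disease proteins. Each channel is averaged over exactly the partners with a
strictly positive score *in that channel* (per-channel support), 0 on empty
support — so a partner missing one evidence type does not drag that
channel's mean down. No scaling is applied before clustering; the
clusterer's per-dimension variances absorb scale.

## EM clustering

A diagonal-covariance Gaussian mixture, fitted by EM: E-step computes
posterior responsibilities, M-step the weighted MLE of mixing weights,
means and per-dimension variances. Initialization is farthest-point seeding
from a seeded RNG followed by 10 k-means iterations; deterministic
tie-breaks (lowest index) everywhere. Defaults: tol 1e-6 on the
log-likelihood improvement, max 100 iterations, variance floor 1e-6 × the
per-dimension data variance (with a 1e-12 absolute floor), all
configurable. The floor keeps degenerate inputs (identical rows, singleton
components) well-posed; on all-identical data the components collapse onto
one effective cluster.

The component count is selected by 10-fold cross-validated held-out
log-likelihood: k grows from 1 while the mean held-out per-datum
log-likelihood strictly improves, and the last improving k wins (capped at
`k_max` and at the smallest training-fold size). This emulates clustering
toolkits that auto-select the class number by CV likelihood. BIC/AIC
variants are deliberately absent.

Candidates in the drugs' component are retained. The default policy is
`plurality` (the component holding the most drugs, ties to the lower
index), which tolerates a heterogeneous drug cohort; policy `all` demands
every drug in one component and raises an error carrying the drug partition
otherwise. Refinement re-encodes the survivors with the drugs and repeats
selection for up to two rounds by default — a fixed small round count rather
than a convergence criterion, stopping early when the set stops shrinking
or empties. During refinement the fold count is clamped to the cohort size
so small surviving sets remain clusterable. Because CV-likelihood selection
needs a subpopulation of a few points at minimum to justify a second
component, one or two stray candidates may remain in the drugs' component
(k=1): co-clustering is a coarse filter, and conversely a borderline
candidate is occasionally split off in a late round.

## Synthetic fixtures: what they emulate and what they do not

The generator emits the five input files with planted fates. Link scores
are integers in [150, 999] (150 being the customary evidence floor), with
30% per-channel dropout on non-combined channels so per-channel feature
supports differ. Sizes default to 200 compounds, 10 drugs, 30 disease
chemicals, 15 genes (1–2 proteins each, plus 60 background proteins),
12 planted positives and 8 decoys of each class — large enough for the
permutation and clustering stages to behave, small enough to screen in
about a second.

Design choices that make the planted fates near-deterministic:

* **Drug cohort heterogeneity.** Six *strong* drugs have strongly enriched
  disease links (combined ~700–950 vs background ~150–500); three *weak*
  drugs are only mildly enriched (~350–750 disease vs ~300–700 background),
  so their moderate P-values anchor the drug-derived thresholds well above
  the positives' P-values, mirroring the wide threshold spread seen in real
  screens; one *inert* drug has no disease links and drops out at the
  association test, exercising drug-cohort attrition.
* **Positives mimic the strong drugs** (same score distributions, links to
  three drugs), so they pass the permutation test with P ≈ 0 and co-cluster
  with the drugs.
* **No-drug and no-gene decoys** fail their stage deterministically (no
  drug link; no disease-protein link).
* **Nonspecific decoys** link promiscuously to ~30% of the universe. Their
  disease-set links are drawn at universe-average strength (~300–600) while
  their promiscuous background links are modestly stronger (~450–750),
  placing the observed rating score at or below the compound's own
  permutation-null mean and hence the P-value at ~0.5 or above. If the two
  distributions were identical the P-value would be uniform-ish around 0.5
  (observed and null rating scores have comparable sampling variance) and a
  material fraction of decoys would slip under drug-derived thresholds by
  chance; the mild anti-enrichment makes the planted fate testable while
  keeping the decoy the textbook promiscuous binder the permutation test
  exists to reject. The EM stage remains a backstop for any leak.

What the fixtures do **not** emulate: realistic chemistry or network
topology (degree distributions, score correlations between channels,
transitivity of STITCH similarity scores), identifier aliasing, or the
scale of real interaction databases. Passing on fixtures demonstrates that
each stage implements its contract and rejects its decoy class — not that
the method's discoveries on a real network are correct, and published
headline compound counts obtained on specific database releases are not
reproduction targets. Background compounds carry no guaranteed fate; a few
may legitimately survive the screen.

The mixture-data generator (`generate_gmm_data`) plants unit-variance
diagonal Gaussian components whose means are `separation` within-component
standard deviations apart (Euclidean distance between adjacent centers).
At the 5σ benchmark separation in 15 dimensions with n=300, a
maximum-likelihood diagonal-GMM fit recovers the partition with adjusted
Rand index typically 0.93–1.0: per-component variance estimates in the 14
noise dimensions wobble the decision boundary, so a fitted model
misassigns a handful more points than the Bayes rule on unlucky draws.
This is a property of ML estimation at that sample size (an independent
mixture implementation reaches the same optimum and the same ARI), not of
the EM iteration.

## Numerical and degenerate-input choices

* P-values are exact multiples of 1/n by construction; fixed seeds make
  them bit-reproducible.
* Random sets producing no interaction score 0, consistent with the rating
  score's zero convention.
* The Monte-Carlo sampler materializes permutations in chunks capped at
  ~20M entries to bound memory on large universes.
* Empty stages end the pipeline cleanly with the report filled up to that
  stage; an empty drug set, reference set larger than the universe, k
  exceeding the row count, and fewer rows than folds are configuration
  errors.
* Problem sizes used by the test suite and the acceptance script (50-
  compound oracle tables, 12-chemical exhaustive universes, n=300
  mixtures, 200-compound pipeline fixtures over 5 seeds) were chosen so
  each check is statistically meaningful at desk scale.

## Known limitations

* Interaction existence is a hard combined>0 cut; no weighting by score
  magnitude at the screening stage beyond the rating-score means.
* The permutation null samples uniformly from the universe, ignoring
  degree structure; hub compounds therefore have conservative nulls.
* Diagonal covariance cannot capture correlated feature channels (e.g.
  textmining co-varying with combined); full covariance is out of scope.
* Exactly two refinement rounds is a convention, not a convergence
  criterion.
* Single-organism runs only; no identifier resolution beyond CID prefix
  normalization.
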