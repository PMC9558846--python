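# Methods

## The question and the statistics

Morphological character matrices carry dependencies among characters:
anatomical entities are related by development and structure, and those
relations are formalized in anatomy ontologies.  This package asks whether
that ontological structure is reflected in the *phylogenetic information*
carried by groups of characters — whether characters annotated to
semantically similar ontology terms produce similar posterior distributions
over tree topologies.

All statistics are defined on distributions over fully resolved unrooted
topologies for a fixed taxon set of size *n*.  With a discrete uniform
prior over the (2n−5)!! topologies:

- **Bayesian phylogenetic information (BPI).**
  I = H_prior − H_posterior, with H_prior = ln (2n−5)!! and H the Shannon
  entropy in nats.  Reported as a percentage of H_prior, so 0% means the
  posterior is as diffuse as the prior and 100% means a point mass.
- **Posterior coverage (φ).**  The total estimated posterior probability of
  the distinct topologies actually present in the MCMC sample.  Low
  coverage means the sample represents only a small part of the posterior
  and entropy estimates are unreliable.
- **Phylogenetic dissonance (D).**  For K posteriors,
  D = H(mean distribution) − mean(H_k), a Jensen–Shannon-type divergence:
  0 when all posteriors coincide, at most ln K for mutually disjoint
  posteriors.  Reported as a percentage of a configurable maximum (below).

## Posterior estimators

Two estimators of the topology posterior from a finite sample are
implemented:

- **Plug-in**: relative frequencies of distinct sampled topologies.  It is
  simple and unbiased over its support, and serves as the independent
  baseline in the test suite.
- **Conditional clade distribution (CCD, the default)**: every sampled
  tree is rooted at the canonically first taxon; for each observed clade
  the frequencies of its observed child splits are treated as independent
  conditional distributions.  The induced probability of a topology is the
  product of its conditional split frequencies, which extends mass to
  unsampled combinations of sampled splits and markedly reduces the bias
  of entropy estimates for diffuse posteriors.

CCD entropy is computed without enumerating topologies by the recursion
H = Σ_c m(c) · H(q(·|c)), where m(c) is the CCD marginal probability of
clade c (propagated top-down from the root clade) and q(·|c) the
conditional split distribution.  The test suite verifies this recursion
exactly against −Σ p ln p enumerated over all topologies for n ≤ 6.

The analytic prior is itself a CCD: a clade of s leaves splits into given
child clades of sizes (a, b) with probability R(a)·R(b)/R(s), where
R(k) = (2k−3)!! counts rooted resolved topologies on k leaves.  Every
resolved topology then receives exactly 1/(2n−5)!!.

**Clade-specific information components.**  Because the uniform prior and
the CCD posterior factorize over the same conditional clade distributions,
I = KL(posterior ‖ prior) decomposes exactly per clade:
component(c) = m(c) · Σ_s q(s|c) ln [q(s|c)/q₀(s|c)], with q₀ the analytic
prior conditional.  Components sum to the total information to machine
precision (an enforced contract), and attribute BPI to individual clades
of a reference species tree.

**Merging posteriors.**  The equal-weight average of K sample-based
posteriors is estimated by pooling the raw samples before building the
CCD — pooling is exactly what concatenating equally sized runs does.
For plug-in distributions the explicit mixture is used, for which the
identity H(merged) = mean(H) + D holds to machine precision.

**Dissonance percentage denominator.**  The reference scale for D% is
configurable: the merged entropy (default), the mean entropy, or ln K.
Published per-subset tables only state "percentage of maximum" and the
exact normalization cannot be back-calculated unambiguously, so the scale
is explicit in every result object.

## The Mk+Γ sampler

A lightweight Bayesian sampler makes the pipeline runnable end-to-end
without external software; posterior samples produced by MrBayes (`.t`
files with translate tables) are imported through the same interface and
are the intended route for full-scale analyses.

- **Model.**  k-state symmetric Mk with rates normalized to one expected
  change per unit branch length: P(same) = 1/k + (k−1)/k·e^(−kβt),
  β = 1/(k−1).  Per-character k comes from the character's declared
  alphabet.  Among-character rate variation: discrete gamma with 4
  equal-probability categories (mean of each quantile slice).  The
  `variable` coding bias divides each character's likelihood by one minus
  the summed likelihood of constant patterns (ascertainment correction);
  the suite checks that corrected likelihoods of all variable patterns on
  a fixed tree sum to 1.
- **Priors.**  Uniform on resolved topologies; Exponential(10) on branch
  lengths; Exponential(1) on the gamma shape; symmetric state frequencies.
- **Moves.**  Single-chain Metropolis–Hastings per run: NNI on a uniformly
  chosen internal edge (50%), branch-length multiplier (35%), gamma-shape
  multiplier (15%).  The NNI proposal is symmetric and enumerates each
  neighbor exactly once, so prior-only runs (no data) sample the uniform
  topology distribution — verified by chi-square against all 15 five-taxon
  topologies.  Metropolis coupling is deliberately omitted: at ≤ 12 taxa a
  single well-mixed chain suffices, and the external import path covers
  larger analyses.
- **Constraints.**  Clade bitmasks that must be present in every sampled
  topology are enforced by auto-rejection (used for reference trees that
  enforce a focal grouping, e.g. a monophyletic set of miniature taxa).
- **Likelihood.**  Felsenstein pruning vectorized over characters grouped
  by state count, exploiting the rank-one structure of the symmetric Mk
  transition matrix.  Verified against exhaustive summation over internal
  state assignments on all 15 five-taxon topologies.

Burn-in follows the convention of dropping the first ⌈fraction·N⌉ samples
(default 25%), retained in files and flagged for downstream removal.

## Ontology semantics

OBO flat files are parsed (via `obonet`) into a typed relation graph;
closures are taken over a configurable relation set, default
{is_a, part_of}, because mixing subsumption and parthood is the common
practice yet filtering them apart is scientifically informative — relation
choice is a first-class argument throughout.

- **Jaccard** similarity: |anc(t₁) ∩ anc(t₂)| / |anc(t₁) ∪ anc(t₂)| over
  reflexive ancestor closures.
- **Resnik** similarity: the information content −ln(n_a/N) of the most
  informative common ancestor, with the character-annotation table itself
  as corpus (n_a counts characters annotated to a term or any descendant).
  Using the annotation corpus keeps the analysis self-contained and
  reproducible.

Similarities convert to distances d = 1 − s/s_max (s_max = 1 for Jaccard,
the maximum observed IC for Resnik) and are clustered by UPGMA (average
linkage, the default; configurable), with labels sorted first so ties
break deterministically.  The same clustering applied to the pairwise
dissonance matrix gives the dissonance dendrogram; congruence between the
two dendrograms is the operational meaning of *semantic signal*.

## Study-level analyses

- **ALL subsets**: one subset per annotated term with at least `min_chars`
  characters (default 3 — one or two characters yield near-prior
  posteriors and inflate noise; no published minimum exists, so it is
  explicit and configurable).  Annotation propagation along the ontology
  is off by default (subsets mean "characters annotated to this term") and
  available for part-of rollups such as grouping all dermatocranium bones.
- **PROFILE subsets**: curated groups of preferred terms; the profile
  table reports per-subset rows plus per-run merged-information and
  among-subset dissonance rows and their mean, in the familiar layout.
- **Node maps**: for each internal node of a dendrogram, the merged
  posterior BPI and among-subset dissonance of the subtended subsets,
  plus values relative to the across-node mean (relative values average
  to 1 by construction).
- **Clade support**: posterior probability of each reference-tree clade
  under each subset; "supporting proportion" uses a 0.95 posterior
  probability threshold by default (no published value; configurable).
- **Resampling**: for a term with m characters, random size-m subsets
  drawn without replacement within a replicate, independently across
  replicates, give the null distribution of BPI/dissonance against which
  the ontology-based subset is compared (reported relative to the
  resampled median).

## The synthetic-data generator

`make_fixture_study` emulates the concerted-convergence scenario: a toy
anatomy ontology (jaw bones under "dermatocranium", fins under "paired
fin"), a species tree, and an alternative tree sharing no splits with it.
Jaw-term character blocks evolve on the species tree; fin-term blocks
jointly evolve on the alternative tree, mimicking traits responding to a
shared ecological factor rather than phylogeny.  Defaults: 8 taxa, 20
binary characters per term, branch length 0.05 expected changes — chosen
so per-subset information lands in the range observed for real
morphological subsets (roughly 30–80% of prior entropy) under the
Exponential(10) branch-length prior scale.  Characters are filtered to
variable ones, pairing with the `variable` coding bias.

What the generator does *not* emulate: multistate and ordered characters
beyond a shared alphabet, among-character correlation within a term block
beyond the shared tree, missing data and polymorphism patterns of real
matrices, and rate heterogeneity across blocks.  Passing tests therefore
demonstrate that the statistics and the pipeline behave correctly under
the intended generating mechanisms, not that any particular empirical
data set will show semantic signal.

## Numerical choices

- Entropies in nats throughout; percentages make the base irrelevant.
- Posterior entropy may exceed prior entropy by at most 1e−9 relative
  (floating-point slack, clipped); larger overshoot raises an error since
  it signals estimator failure.
- Dissonance percentages are clamped to [0, 100]; a zero denominator
  yields 0%.
- Topology identity: splits stored as bitmasks normalized to the side
  containing the lexicographically first taxon, sorted, then hashed
  (BLAKE2b, 12 bytes).  Invariant to rotation, rooting, and branch
  lengths.
- Polytomies are rejected by default (the information measures assume
  resolved topologies); an opt-in flag accepts multifurcating inputs for
  plumbing purposes.
- Random-number streams: a single integer seed fans out to named
  substreams (per-run MCMC via `(seed, run)` seed sequences, fixture
  generation, resampling), so components are independently reproducible.

## Problem sizes used in tests

The bundled tests and the acceptance script run at desk scale: 5–10 taxa,
20–500 characters, 10⁴–1.5×10⁵ MCMC generations, chosen as the package's
own defaults for synthetic studies.  Full-scale reproductions (10⁷
generations, MrBayes, published matrices) are supported through the
import path rather than rerun here.

## Known limitations

- No formal significance test for BPI or dissonance differences is
  provided, mirroring the framework's descriptive intent.
- The CCD assigns probability zero to topologies containing unobserved
  splits; coverage quantifies, but does not correct, sample
  incompleteness.
- The built-in sampler is not Metropolis-coupled and is not intended for
  matrices beyond ~15 taxa.
- BPI comparisons across data sets require identical taxon sets (the
  prior depends only on n, so subsets of one matrix are always
  comparable).
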