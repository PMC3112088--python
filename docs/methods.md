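# Methods

## Scientific setting

Ribosomal RNA genes (18S–5.8S–28S units) form tandem clusters — nucleolar
organizer regions — on one to many chromosome pairs, usually adjacent to a
centromere or telomere. In the genus *Mus* their chromosomal distribution is
exceptionally labile, and the question the package addresses is whether that
lability is linked to karyotype reshuffling: do rDNA clusters co-evolve with
centromeres, and do chromosomal breakpoints preferentially fall where both
structures sit?

The analysis has three stages, all operating on a rooted reference phylogeny
of 23 taxa (21 *Mus* taxa, *Rattus rattus* and *Apodemus sylvaticus* as
outgroups) and a character matrix over the 30 orthologous segments of the
ancestral *Mus* karyotype:

1. **Ancestral reconstruction.** Each segment is a 3-state character
   (0 absent, 1 pericentromeric cluster, 2 distal cluster) evolving under a
   continuous-time Markov chain with all six ordered transition rates free
   (the ARD model). Rates are fitted by maximum likelihood with Felsenstein
   pruning; marginal posterior state probabilities are computed at every node
   and a state is *called* where its posterior reaches 75% (inclusive).
   Cluster insertions and deletions are read off branches whose endpoints
   have determinate, different presence status.
2. **Correlated evolution.** For each segment, centromere presence and
   cluster presence (states 1/2 collapsed to 1) form a pair of binary traits
   modelled jointly on four combined states. The independent model gives each
   trait gain/loss rates that ignore the other trait (4 parameters); the
   dependent model conditions every flip rate on the other trait's current
   state (8 parameters); simultaneous double flips have rate zero in both.
   Twice the log-likelihood gain of the dependent model is referred to
   χ² with 4 degrees of freedom. Segments on which a cluster is never
   observed, or observed only at the telomeric position, are excluded
   (28 of 30 remain).
3. **Breakpoint co-occurrence.** Each of 42 breakpoints sits on a (segment,
   branch) pair. Its cluster context is the called ancestral state at the
   branch's **parent** node — the state in place when the rearrangement
   happened; its centromere context is a transcribed annotation. Categories:
   *undetermined* (cluster call unknown), *neither*, *cluster_and_centromere*
   (with sub-position and centromere-fate detail), *other*. The headline
   statistic is 100 × n_both / (total − n_undetermined).

## Likelihood machinery and numerical choices

* Transition probabilities are exp(Qt). For a whole tree they are computed
  for all branches at once through the eigendecomposition of Q when its
  eigenvector matrix is well conditioned (condition number < 1e8), falling
  back to scipy's scaling-and-squaring `expm` per distinct branch length
  otherwise — ARD generators need not be symmetric or even diagonalizable.
* Pruning uses per-node rescaling of partial likelihoods (rescale when the
  row maximum drops below 1e-250, accumulating log factors), so long trees
  cannot underflow.
* Marginal (empirical-Bayes) posteriors use the exact two-pass up/down
  algorithm; they agree with brute-force enumeration over all internal-node
  assignments to 1e-8 (tested on trees up to 6 tips, 2–4 states). This is a
  *true* marginal reconstruction; historical implementations that report
  scaled conditional likelihoods differ at non-root nodes.
* The root prior is uniform by default (matching common `ace` behaviour and
  keeping nested-model comparisons well defined); the stationary distribution
  of the fitted Q is available as an alternative.
* Optimization: L-BFGS-B on log-rates, bounds [1e-8, 100] after rescaling
  the tree to unit height (rates are reported per original branch-length
  unit), one fixed start plus seeded random restarts (5 by default for the
  ARD fit). ARD surfaces are multimodal for sparse characters, hence the
  restarts. The dependent pair model is warm-started from the independent
  MLE plus jittered restarts, which keeps fits nested up to optimizer
  tolerance; a likelihood-ratio statistic within 2e-6 below zero is clamped
  to 0, anything lower raises as an optimizer failure.
* Flat-likelihood tie-break: after optimization each rate is shrunk to the
  lower bound when that leaves the likelihood unchanged (within 1e-9). Rates
  the data carry no information about — e.g. the loss rate of a state never
  observed — are otherwise left at arbitrary values by any optimizer and
  would smear ancestral posteriors.
* Invariant characters: under a flat root prior the MLE drives the decay
  rates *out of* unobserved states to the upper bound (the data are then
  certain regardless of the root draw), so every node below the root is
  reconstructed at the observed state with probability ~1 while the root
  posterior stays uniform. `ape::ace` behaves identically; this is a
  property of ML with a flat root prior, not an implementation artifact.
* Threshold calls require the threshold in (0.5, 1] so at most one state can
  qualify; 0.75 is the default. Raising the threshold can only increase the
  number of unknown nodes.
* Event calling: by default an event is attributed to the deepest
  determinate ancestor–descendant pair, skipping intervening unknown-call
  nodes; a flag restricts to strictly adjacent determinate pairs. The
  reported support is the posterior of the new presence status at the
  event's reporting node, as a percentage.

## The packaged study fixture

The karyotype table (which chromosome pairs carry clusters, and where) is a
transcription of the published observations; cluster-pair counts, the
sites = 2 × pairs identity, and the per-taxon chromosome lists are its
validation surface. Robertsonian metacentrics noted `a.b` score the cluster
on both arms; the *M. terricolor* clusters lying between centromere and
telomere are coded proximal (state 1) by default with a switch to code them
distal; the *M. caroli* X-linked cluster is recorded in the karyotype but
excluded from the 30 autosomal segments; the two segments of house-mouse
chromosome 1 are coded `?` for *A. sylvaticus*, whose chromosome-1 homology
is unresolved.

Four fixture components are **synthetic stand-ins**, clearly marked in their
file headers, because the originals were never published:

* **Branch lengths** of the reference tree. The topology honours the stated
  constraints (*Coelomys* diverging first, *Nannomys* sister to
  *Mus*+*Pyromys*, three clades within subgenus *Mus*, *M. cypriacus* sister
  to *M. macedonicus*); lengths are ultrametric with node depths
  proportional to clade nesting, total height 1.
* **The homology map** for taxa outside subgenus *Mus* (whose own labels are
  already house-mouse nomenclature). It is an editable TSV; any total map
  consistent with the chromosome lists gives the same structural counts.
  The 30th segment — the one whose only cluster is telomeric, excluded
  together with the cluster-free 10d to leave 28 for the correlated-
  evolution screen — is labelled 12d here and realised by the
  *A. sylvaticus* chromosome-12 subtelomeric cluster; its true identity is
  not recoverable from the published material.
* **Centromere annotations** per taxon × segment: proximal/unsplit segments
  carry a centromere in all taxa; distal blocks only where a lineage's
  fissioned chromosomes make them independent centromere-bearing elements;
  junior arms of Robertsonian fusions lose theirs; segment 19's centromere
  is restricted to subgenus *Mus* (echoing its reported origin at that
  ancestor).
* **Breakpoint placements** (42 records). Branch placements were selected
  against this package's deterministic reconstruction so that the published
  count surface — 9 undetermined, 13 neither, 8 flanking a
  cluster-plus-centromere (2 at the cluster's distal end with both
  structures lost, 6 between centromere and cluster with 4 centromeres
  reacquired) — is reproduced; only branches whose parent call is decisive
  (max posterior ≥ 0.85, or ≤ 0.70 for the undetermined class) were used so
  numerical drift cannot flip a category.

Because branch lengths are synthetic, node-level quantities that depend on
them — absolute per-segment log-likelihoods, the global fraction of
determinate nodes, insertion/deletion totals — are reported for this fixture
but are not expected to equal the originally published values; the
structural counts (30 segments, 29 reconstructed, 28 tested, 42/9/13/8
breakpoints, the 24% flanking share, the LRT arithmetic) are.

On this fixture several scattered characters (17p among them) land in the
high-rate regime where every internal node's posterior hovers near the
stationary frequencies and no state reaches 75% — the same phenomenon the
original analysis reported for four of its segments. Their breakpoints fall
in the undetermined class.

## The simulators

`simulate_tree` draws Yule (pure-birth) trees: per-lineage birth rate 1 by
default, one extra exponential waiting time after the last split so terminal
branches have positive length. `simulate_character` evolves a discrete
character by exact Gillespie simulation along each branch (exponential
waiting times, logged transition history); `simulate_pair` wraps the 4-state
combined chain for binary trait pairs. Every call derives its own numpy
Generator from (seed, operation-code), so runs are bit-reproducible and
sub-simulations independent. Empirical end-state frequencies on a single
branch agree with the matrix exponential (χ² goodness-of-fit over 10,000
draws).

What the simulators do *not* emulate: rate heterogeneity across segments,
rearrangement processes themselves (breakpoints are annotations, not
simulated events), correlated sampling error in FISH scoring, or
phylogenetic uncertainty. Passing simulation tests therefore demonstrate
correctness of the inference machinery under its own model, not robustness
to model violation on real data.

## Simulation-study design (sizes and conditions)

* **Oracle equivalence**: 200 random trees with ≤ 6 tips, 2–4 states, random
  rates in [0, 2.5], ~10% missing tips; pruning lnL and marginals vs
  exhaustive enumeration at 1e-8.
* **Parameter recovery**: 50 replicates, 200-tip Yule trees scaled by 0.4
  (root-to-tip height ≈ 2 expected events per rate-0.5 channel), all six
  true rates 0.5. These conditions keep each ordered transition observable
  (~13 expected events per channel) while avoiding saturation; the check is
  that the median relative error of every rate stays below 50%. Single-site
  ARD estimation is intrinsically noisy — individual replicates can collapse
  poorly-informed rates to the bound — which is why the median, not the
  mean, is the summary.
* **LRT calibration**: 200 independent-model replicates (all four rates 0.8)
  on 100-tip Yule trees, one optimizer restart per fit; the rejection rate
  at α = 0.05 is required to lie in [0.005, 0.10] — the χ²₄ reference is
  conservative near rate boundaries, so a band, not a point, is asserted.
  **Power**: 40 replicates under a strongly dependent generator (trait 2
  gained only while trait 1 is present: gain₂|₁₌₀ = 0, gain₂|₁₌₁ = 2,
  loss₂|₁₌₀ = 2, loss₂|₁₌₁ = 0.1), requiring rejection in ≥ 80%.

## Known limitations

* The correlated-evolution screen reports raw p-values at α = 0.05 across 28
  segments, as the original analysis did; a Holm correction is available
  behind a flag but off by default.
* Binary-pair models treat the centromere annotation as data of the same
  standing as the FISH observations, though it is a transcription of a
  chromosomal phylogeny rather than a direct observation.
* Marginal calls at different nodes are not jointly consistent (no joint
  MAP reconstruction is attempted), and no Bayesian treatment of rate
  uncertainty is offered.
* The event caller's "deepest determinate pair" attribution can assign one
  biological event to a single branch pair even when multiple equally
  parsimonious placements exist along a chain of unknown-call nodes.
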