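# Methods

## Scope and data model

`coevnet` scores candidate protein-pair interfaces against a template family
of interacting complexes. The family is a `FamilySeed`: one or more seed
complexes as aligned sequence pairs in shared alignment coordinates, an
inter-protein contact map over 1-based alignment columns, and one
position-specific profile per partner protein. Upstream stages — template
search/threading and multi-interface alignment — are consumed as input, not
performed here: seed interfaces are assumed pre-aligned, and query pairs
arrive with their per-protein alignment features already computed.

The per-family "profile" of each partner is a gapless position-specific
log-odds table (log₂ of column probability over background) rather than a
full profile HMM. Every sequence the package ever scores is already in
alignment coordinates — the co-evolution sampler preserves the alignment and
never introduces indels — so insert/delete states would be dead weight. The
scoring entry point (`profile_score`) is the seam where a full profile HMM
could be substituted. Column probabilities are `(count + κ·bg_r)/(n_nongap +
κ)` with pseudocount κ = 1 and a uniform background by default (any strictly
positive 20-vector can be supplied); all-gap columns fall back to the
background with a logged warning. Gap columns in a scored sequence contribute
a fixed penalty, default −4 bits, configurable — the choice is conventional
(a gap is "worse than any bad residue" on the log-odds scale) and only
offsets scores additively for a fixed gap pattern.

Contact maps built from coordinates use a representative-atom Euclidean
cutoff, default 8.0 Å (configurable; co-evolutionary signal has been reported
out to 10–12 Å, but contacts only drive the mutation proposal — longer-range
correlations are captured by the tree model, not the contact set).

## Simulated co-evolution (MCMC)

One Markov chain per seed complex, started at that seed. Each step:

- **Contacts.** ⌈f·C⌉ of the C contacts are selected uniformly without
  replacement (f = 0.05 by default). For each, a fair coin fixes one side;
  the other side is resampled from the family contact-pair conditional given
  the fixed residue. The contact-pair distribution is the pseudocounted
  empirical joint over all seed contacts, `(count+κ)/(total+400κ)`, κ = 1; an
  arbitrary 20×20 matrix can be loaded instead.
- **Non-contacts.** ⌈f·M⌉ of the M non-interface, non-gap positions per
  protein are resampled from a BLOSUM62-derived substitution conditional
  P(b|a) ∝ bg_b·2^{S(a,b)/2}, row-normalized with uniform background (the
  standard inversion of a half-bit log-odds matrix).
- **Selection.** The whole proposed pair is accepted with probability
  min(1, exp(Δfitness/T)), fitness being the sum of the two profile scores in
  bits and T = 1 by default. Acceptance is per step (whole pair), not per
  mutation.

Gap positions are immutable and never created. The 5% fractions use ceilings
so small interfaces still mutate at least one position.

The plain acceptance mirrors the described procedure and is deliberately
*not* corrected for the asymmetry of conditional resampling; the resulting
stationary law retains proposal-induced contact correlations, which is the
point of the simulation. `MCMCParams(hastings=True)` enables the exact
Metropolis–Hastings acceptance with the proposal-ratio correction; in that
mode the chain provably targets exp(fitness/T), which the test suite verifies
by total-variation comparison against an exactly enumerated 16-state toy
chain (TV ≈ 0.01 at 30,000 samples).

Sampling protocol: burn-in 500 steps, thinning 10 (unspecified upstream;
chosen so small families decorrelate between emitted samples), then 1,000
samples per seed complex, or 2,500 when the family has a single seed. Chains
from multiple seeds are pooled before tree learning — one profile per
family. Convergence is monitored by window-mean stability
(|mean(last w) − mean(previous w)| ≤ tol·pooled sd, w = 200, tol = 0.5); a
failing check sets a flag on the `SampleSet` rather than raising, because a
drifting trace can still carry usable late samples and the caller should
decide.

Reproducibility: all chain randomness derives from one integer seed through
`numpy.random.SeedSequence.spawn`, one stream per chain; identical seeds give
bit-identical sample sets.

## Tree interface profiles

Nodes are the union of both proteins' interface columns, tagged A/B. The
alphabet has 21 states (20 residues + gap) so gapped query interfaces remain
scorable. Structure is the maximum-weight spanning tree under pairwise
mutual information of the pseudocounted joints — the Chow–Liu tree, i.e. the
maximum-likelihood tree-structured distribution. Determinism is part of the
contract: candidate edges are sorted by (−MI, node pair) lexicographically
before Kruskal extraction, the root is the smallest node id, and learning is
invariant to sample order. Parameters are pseudocounted (0.5 per cell by
default): a root marginal and per-edge conditional tables P(child|parent).
Log-likelihood of an assignment is log₂ of the root marginal plus the sum of
log₂ CPT entries along the edges; pseudocounts keep every assignment finite,
including all-gap ones.

The negative ("background") tree is learned from the same samples with
B-halves permuted by a derangement. This choice preserves both marginal
sequence distributions exactly while destroying every inter-protein
dependency — including the chain-identity correlations that pooling several
chains introduces at *all* column pairs — so the L⁺−L⁻ contrast isolates
inter-protein interface signal. Whether the original background model was
built from shuffled simulated sequences or from non-interacting natural
pairs is not documented upstream; the derangement is this package's
documented default, not an inference of intent.

L⁺ and L⁻ are passed to the classifier as raw (not length-normalized)
log-likelihoods; the fitted weights absorb scale.

## Confidence classifier

Features per query pair: per-protein alignment features (sequence score,
secondary-structure score, length — opaque reals/integers supplied by the
upstream threading stage), interface size Yᵢ (node count of the family
profile), and the scalar tree scores L⁺, L⁻. The model is logistic:
log p/(1−p) = α + β₁ᵀX₁ + β₂ᵀX₂ + βᵢYᵢ + β₊L⁺ + β₋L⁻. L⁺/L⁻ enter as
scalars with scalar coefficients (one tree each); the feature container is
extensible if per-subtree scores are added later.

Fitting is L2-penalized maximum likelihood (strength 1.0 by default) on
standardized features with an unpenalized intercept; a penalty is always
applied because L⁺ and L⁻ are nearly collinear on realistic data. The stored
model carries its standardization, so prediction is self-contained, and
coefficients are reported on both standardized and original scales. With
all-constant features the fit reduces exactly to α = logit(class
prevalence).

The high-confidence cutoff defaults to 0.6, boundary inclusive (p = 0.6 is
high confidence); on synthetic data a cutoff can be re-derived by Youden's J
from the ROC. ROC curves sweep every distinct score as an inclusive
threshold (ties collapse), report sensitivity TP/(TP+FN) and specificity
TN/(TN+FP), and integrate AUC by the trapezoidal rule; the AUC equals the
normalized Mann–Whitney U statistic (test-verified to 1e-9).
Cross-validation is stratified k-fold (default 5), deterministic given the
seed, optionally repeated; association with reference labels uses Fisher's
exact test with Haldane-corrected odds ratios for empty cells.

## The synthetic generator

The generator emulates the statistical structure the interface model
assumes, with closed-form oracles:

- Background columns are i.i.d. uniform over the first k letters of the
  amino-acid alphabet (k = 20 by default).
- At each of the n_contacts contact column pairs, with probability c
  (`coupling_strength`) the B residue is σ(a) for a fixed random permutation
  σ; otherwise it is drawn independently. One σ is shared by all contacts of
  a family — a family-wide co-evolution code, matching the single
  family-wide contact-pair distribution the sampler estimates. The mixture's
  per-contact mutual information has the closed form
  MI = log₂k − H(c + (1−c)/k, (1−c)/k, …), used as an analytic oracle.
- Families default to 5 seed complexes (a typical small structural family)
  and 50-sequence profile MSAs drawn from the same model.

The labeled benchmark (default 100 interacting / 100 non-interacting pairs
over a 30+30-column family with 8 contacts at coupling 0.9 — small enough
for desk-scale runs) is featurized through the *real* pipeline: sampler →
tree learning → interface scoring. Alignment features are profile scores and
a standard-normal secondary-structure placeholder with identical
distributions in both classes, so any discrimination must come from the
interface features. With coupling 0 the two classes are distributionally
identical and cross-validated AUC sits at 0.5.

What the generator does *not* emulate: phylogenetic relatedness among family
members, realistic residue composition and substitution structure,
indel variation, multi-domain architecture, or the geometry of real
interfaces. Passing tests therefore demonstrate the statistical machinery —
that genuine inter-protein coupling is captured, scored and converted into
calibrated-looking confidences, and that no signal is invented when none
exists — not performance on any real interactome.

## Numerical and design notes

- All sequence data are encoded as int8 over a fixed 21-symbol alphabet;
  chains run on integer arrays with incremental profile-score updates.
- MI estimation uses the plug-in estimator on pseudocounted joints. Its
  finite-sample bias, ≈(k−1)²/(2N ln 2) bits, and the mixture artifact of
  uniform smoothing over the full 21×21 table when data occupy a
  sub-alphabet are real effects; tests that assert "MI ≈ 0" therefore use
  small pseudocounts and, where a closed form is compared, Miller–Madow
  correction.
- Pooled multi-chain samples carry chain-identity correlations at every
  column pair (each chain hovers near its own seed). These are background
  correlations in the model's own sense and are absorbed by the negative
  tree; they are why contact-vs-background MI contrasts are only meaningful
  on single, well-mixed chains.
- The stationarity acceptance check averages the null benchmark over 10
  independently seeded replicates of the AUC estimate, whose per-replicate
  sd (~0.05 at 200 rows) would otherwise dominate the comparison; the
  signal benchmark is a single run at the stated conditions.
- Tie-breaking is deterministic everywhere randomness is not explicit
  (edge sorting, root choice, stable sorts in the ROC sweep), so every
  pipeline output is bit-identical across reruns with the same seed.
- Degenerate inputs: empty MSAs, single-class training data, single-sample
  derangements, contact maps with zero interface columns and out-of-range
  contacts all raise typed errors naming the offender; all-gap MSA columns
  and non-converged chains warn instead of raising.

## Problem sizes used in checks

Enumeration checks run on ≤3-node trees (21³ = 9,261 assignments) and a
16-state toy family; structure recovery uses 100 replicates of 5,000 samples
from a 6-node chain; the sampler contract runs at its real defaults
(1,000/2,500 samples) on 6+6-column families; the benchmark runs at its
default 200 pairs. These sizes keep the full check suite within a few
minutes on one CPU while exercising every stage at the sizes the contracts
name.
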