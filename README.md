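# coevnet

Confidence scores for predicted protein–protein interactions from interface
co-evolution.

High-throughput interaction screens (yeast-two-hybrid and friends) are noisy,
and threading-based structural predictions of an interaction need a
quantitative confidence. `coevnet` implements the scoring core of a
structure-based interaction predictor: given a template family of interacting
complexes, it builds a statistical profile of the family's binding interface
by *simulating co-evolution*, and converts a candidate pair's fit to that
profile into a probability that the pair really interacts. It is a library
first (see `examples/`), with a thin `coevnet` command-line wrapper for the
pipeline stages.

## The model

For a template family (seed complexes with aligned interfaces and an
inter-protein contact map):

1. **Simulated co-evolution.** Artificial interacting homolog pairs are
   generated by a Markov chain: per step, 5% of interface contacts are
   re-drawn from a family-wide 20×20 contact-pair distribution (one side of
   the contact fixed by a fair coin, the other resampled from the conditional
   given the fixed residue), 5% of non-contact positions per protein are
   re-drawn from a BLOSUM62-derived substitution conditional, and the whole
   proposed pair is accepted stochastically on its joint profile fitness
   (Metropolis; an exact Metropolis–Hastings mode with the proposal-ratio
   correction is available). 1,000 samples are kept per seed complex, 2,500
   for single-seed families.
2. **Tree interface profiles.** Over the interface columns of both proteins,
   two spanning-tree graphical models are learned by maximum-MI (Chow–Liu)
   structure selection with pseudocounted marginals/CPTs on the 21-symbol
   alphabet (20 residues + gap): a *positive* tree from the simulated
   interacting pairs and a *negative* tree from the same samples with
   partner assignments deranged (background correlations only). A candidate
   interface x gets log-likelihoods L⁺ = log₂ P₊(x) and L⁻ = log₂ P₋(x).
3. **Confidence.** Alignment features of the two partners (sequence score,
   secondary-structure score, length: X₁, X₂), the interface size Yᵢ and the
   tree scores enter a logistic model

   log p/(1−p) = α + β₁ᵀX₁ + β₂ᵀX₂ + βᵢYᵢ + β₊L⁺ + β₋L⁻

   fitted by L2-penalized maximum likelihood on standardized features.
   Predictions with p ≥ 0.6 are called high-confidence. Evaluation is by
   ROC curves (sensitivity TP/(TP+FN) against specificity TN/(TN+FP)) under
   stratified 5-fold cross-validation, plus Fisher's exact test for
   association with reference labels.

A synthetic-data module generates families and labeled benchmarks with known
ground truth (tunable contact coupling with closed-form mutual information),
so the whole pipeline is testable without any external data.

## Worked example

```bash
python examples/02_tree_profiles_and_scoring.py
```

```
learned trees over 16 interface nodes; positive edges: 15
co-evolved pair    mean L+ - L- =  +7.89 bits (positive favors genuinely co-evolved interfaces)
independent pair   mean L+ - L- =  +0.94 bits (positive favors genuinely co-evolved interfaces)
```

A synthetic family (30+30 alignment columns, 8 contacts, coupling 0.9) is
simulated, the two trees are learned, and 50 query pairs per class are
scored: genuinely co-evolved pairs sit ~7 bits above independent pairs on the
L⁺−L⁻ contrast — that contrast is what the classifier converts into
confidence. `examples/03_confidence_classifier.py` continues to the logistic
stage and prints a 5-fold CV AUC of 0.949 with per-specificity sensitivities;
`examples/01_simulate_coevolution.py` shows the sampler itself (selection
pressure and contact MI in the samples).

The same stages are available as shell commands: `coevnet simulate-fixture`,
`simulate`, `build-profile`, `score`, `train`, `predict`, `evaluate` and
`pipeline` (YAML-configured, end to end); every command is deterministic
given `--seed`.

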