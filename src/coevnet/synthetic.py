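"""Synthetic families and labeled benchmarks with known ground truth.

The generator emulates the statistical structure the co-evolution model
assumes: designated interface columns whose inter-protein residue pairs are
correlated with tunable strength, independent background columns, and labeled
interacting / non-interacting pair sets.  Contact coupling is a mixture of a
copy channel and independence: with probability ``coupling_strength`` the
B-side residue is a fixed alphabet permutation of the A-side residue,
otherwise it is drawn independently.  One permutation is shared by all
contacts of a family — a family-wide co-evolution code, matching the single
family-wide contact-pair distribution the sampler estimates.  The mixture's
mutual information has a closed form, giving analytic oracles.

Everything is reproducible bit-for-bit from ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import decode
from .classifier import (
    AlignmentFeatures,
    FeatureVector,
    LabeledDataset,
)
from .interface import (
    AlignedSequencePair,
    ContactMap,
    FamilySeed,
    InterfaceAssignment,
    build_profile,
)
from .mcmc import MCMCParams, run_mcmc
from .tree import InterfaceProfilePair, build_negative_samples, learn_tree, score_interface


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic family / benchmark generator."""

    n_cols_a: int = 30
    n_cols_b: int = 30
    n_contacts: int = 8
    coupling_strength: float = 0.9
    alphabet_size: int = 20
    n_seed_pairs: int = 5
    n_msa_sequences: int = 50
    n_positive_pairs: int = 100
    n_negative_pairs: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contacts > min(self.n_cols_a, self.n_cols_b):
            raise ValueError("n_contacts cannot exceed the shorter alignment")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must be in [0, 1]")
        if not (2 <= self.alphabet_size <= 20):
            raise ValueError("alphabet_size must be between 2 and 20")
        if self.n_seed_pairs < 1:
            raise ValueError("need at least one seed pair")
        if self.n_msa_sequences < 2:
            raise ValueError("need at least two MSA sequences for profiles")
        if self.n_positive_pairs < 0 or self.n_negative_pairs < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used — for oracles in tests."""

    contacts: tuple[tuple[int, int], ...]
    permutation: tuple[int, ...]  # sigma over alphabet indices: b = sigma[a]
    coupling_strength: float
    alphabet_size: int
    analytic_mi_bits: float  # per contact
    spec: GeneratorSpec


def analytic_contact_mi(coupling_strength: float, alphabet_size: int) -> float:
    """MI (bits) of the uniform copy-channel/independence mixture.

    Joint: P(a, b) = (1/k) * [c * 1{b = sigma(a)} + (1 - c)/k].
    """
    k = alphabet_size
    c = coupling_strength
    p_match = c + (1.0 - c) / k
    p_other = (1.0 - c) / k
    h_b_given_a = 0.0
    if p_match > 0:
        h_b_given_a -= p_match * math.log2(p_match)
    if p_other > 0:
        h_b_given_a -= (k - 1) * p_other * math.log2(p_other)
    return math.log2(k) - h_b_given_a


def _draw_pair_arrays(
    gt_contacts: np.ndarray,
    permutation: np.ndarray,
    coupling: float,
    n_cols_a: int,
    n_cols_b: int,
    alphabet_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One aligned pair from the generating model (int8 arrays)."""
    a = rng.integers(0, alphabet_size, size=n_cols_a).astype(np.int8)
    b = rng.integers(0, alphabet_size, size=n_cols_b).astype(np.int8)
    for i, j in gt_contacts:
        if rng.random() < coupling:
            b[j - 1] = permutation[a[i - 1]]
    return a, b


def draw_pair(
    ground_truth: GroundTruth, coupled: bool, rng: np.random.Generator
) -> AlignedSequencePair:
    """Draw a query pair from the coupled model or the independence model."""
    spec = ground_truth.spec
    coupling = ground_truth.coupling_strength if coupled else 0.0
    a, b = _draw_pair_arrays(
        np.asarray(ground_truth.contacts, dtype=int),
        np.asarray(ground_truth.permutation, dtype=int),
        coupling,
        spec.n_cols_a,
        spec.n_cols_b,
        spec.alphabet_size,
        rng,
    )
    return AlignedSequencePair(decode(a), decode(b))


def generate_family(
    spec: GeneratorSpec, return_msas: bool = False
) -> tuple[FamilySeed, GroundTruth] | tuple[FamilySeed, GroundTruth, tuple[list[str], list[str]]]:
    """Build a synthetic family seed bundle plus its ground truth.

    Contact columns are drawn without replacement in each protein; seed pairs
    and the profile MSAs are drawn from the generating model itself, so the
    profiles describe the family's (uniform-over-alphabet) column statistics.
    """
    rng = np.random.default_rng(spec.rng_seed)
    cols_a = np.sort(rng.choice(spec.n_cols_a, size=spec.n_contacts, replace=False)) + 1
    cols_b = np.sort(rng.choice(spec.n_cols_b, size=spec.n_contacts, replace=False)) + 1
    contacts = tuple((int(i), int(j)) for i, j in zip(cols_a, cols_b))
    permutation = tuple(int(x) for x in rng.permutation(spec.alphabet_size))

    gt_contacts = np.asarray(contacts, dtype=int)
    perm_arr = np.asarray(permutation, dtype=int)

    def pair() -> tuple[np.ndarray, np.ndarray]:
        return _draw_pair_arrays(
            gt_contacts,
            perm_arr,
            spec.coupling_strength,
            spec.n_cols_a,
            spec.n_cols_b,
            spec.alphabet_size,
            rng,
        )

    seed_pairs = []
    for _ in range(spec.n_seed_pairs):
        a, b = pair()
        seed_pairs.append(AlignedSequencePair(decode(a), decode(b)))

    msa_a, msa_b = [], []
    for _ in range(spec.n_msa_sequences):
        a, b = pair()
        msa_a.append(decode(a))
        msa_b.append(decode(b))

    family = FamilySeed(
        seed_pairs=seed_pairs,
        contact_map=ContactMap(
            frozenset(contacts), length_a=spec.n_cols_a, length_b=spec.n_cols_b
        ),
        profile_a=build_profile(msa_a, pseudocount=1.0),
        profile_b=build_profile(msa_b, pseudocount=1.0),
        family_id=f"synthetic_seed{spec.rng_seed}",
    )
    truth = GroundTruth(
        contacts=contacts,
        permutation=permutation,
        coupling_strength=spec.coupling_strength,
        alphabet_size=spec.alphabet_size,
        analytic_mi_bits=analytic_contact_mi(spec.coupling_strength, spec.alphabet_size),
        spec=spec,
    )
    if return_msas:
        return family, truth, (msa_a, msa_b)
    return family, truth


def build_profile_pair(
    family: FamilySeed,
    params: MCMCParams | None = None,
    tree_pseudocount: float = 0.5,
) -> InterfaceProfilePair:
    """Run the sampler and learn the positive/negative tree profile pair."""
    params = params or MCMCParams()
    sample_set = run_mcmc(family, params)
    rng = np.random.default_rng(params.rng_seed + 1)
    positive = learn_tree(sample_set, family.contact_map, tree_pseudocount)
    negatives = build_negative_samples(sample_set, rng)
    negative = learn_tree(negatives, family.contact_map, tree_pseudocount)
    return InterfaceProfilePair(positive, negative, family_id=family.family_id)


def sample_labeled_benchmark(
    spec: GeneratorSpec,
    params: MCMCParams | None = None,
) -> LabeledDataset:
    """Labeled benchmark: features computed through the real pipeline.

    One synthetic family is generated; the sampler and tree learner build its
    interface profile pair; positives are query pairs drawn from the coupled
    model and negatives from the independence model, all featurized with
    the actual interface scorer.  Alignment features (profile scores, a
    secondary-structure placeholder score, lengths) follow the same
    distribution in both classes, so discrimination can only come from the
    interface features.
    """
    if spec.n_positive_pairs == 0 and spec.n_negative_pairs == 0:
        return LabeledDataset.from_rows([], [], [])
    family, truth = generate_family(spec)
    params = params or MCMCParams(rng_seed=spec.rng_seed)
    profile_pair = build_profile_pair(family, params)

    from .interface import profile_score  # local import to avoid cycle at module load

    rng = np.random.default_rng(spec.rng_seed + 2)
    ids, fvs, labels = [], [], []
    for label, count, tag in (
        (1, spec.n_positive_pairs, "pos"),
        (0, spec.n_negative_pairs, "neg"),
    ):
        for k in range(count):
            pair = draw_pair(truth, coupled=(label == 1), rng=rng)
            assignment = InterfaceAssignment.from_pair(pair, family.contact_map)
            l_plus, l_minus = score_interface(assignment, profile_pair)
            fv = FeatureVector(
                x1=AlignmentFeatures(
                    seq_score=profile_score(pair.seq_a, family.profile_a),
                    ss_score=float(rng.normal()),
                    length=spec.n_cols_a,
                ),
                x2=AlignmentFeatures(
                    seq_score=profile_score(pair.seq_b, family.profile_b),
                    ss_score=float(rng.normal()),
                    length=spec.n_cols_b,
                ),
                yi=family.contact_map.interface_size,
                l_plus=l_plus,
                l_minus=l_minus,
            )
            ids.append(f"{tag}_{k:04d}")
            fvs.append(fv)
            labels.append(label)
    return LabeledDataset.from_rows(ids, fvs, labels)
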