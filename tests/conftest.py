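"""Shared fixtures: tiny families built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from coevnet import (
    AlignedSequencePair,
    ContactMap,
    FamilySeed,
    PairDistribution,
    build_profile,
)
from coevnet.alphabet import AMINO_ACIDS, N_AA

A_IDX = AMINO_ACIDS.index("A")
V_IDX = AMINO_ACIDS.index("V")


def make_restricted_conditional(p_stay: float = 0.7) -> np.ndarray:
    """Row-stochastic 20x20 substitution matrix supported on {A, V} for A/V rows."""
    sub = np.full((N_AA, N_AA), 1.0 / N_AA)
    for i in (A_IDX, V_IDX):
        sub[i] = 0.0
        sub[i, i] = p_stay
        sub[i, V_IDX if i == A_IDX else A_IDX] = 1.0 - p_stay
    return sub


def make_toy_pair_distribution(p_match: float = 0.35) -> PairDistribution:
    """Joint supported on {A, V} x {A, V}: diagonal mass p_match each."""
    joint = np.zeros((N_AA, N_AA))
    off = (1.0 - 2 * p_match) / 2.0
    joint[A_IDX, A_IDX] = p_match
    joint[V_IDX, V_IDX] = p_match
    joint[A_IDX, V_IDX] = off
    joint[V_IDX, A_IDX] = off
    return PairDistribution(joint)


@pytest.fixture
def toy_family() -> FamilySeed:
    """Two columns per protein, one contact, alphabet restricted to {A, V}.

    The profiles favor A in every column, making the fitness landscape over
    the 16 reachable states non-uniform.
    """
    profile_a = build_profile(["AA", "AA", "AA", "AV", "VA"], pseudocount=1.0)
    profile_b = build_profile(["AA", "AA", "AV", "VV", "AA"], pseudocount=1.0)
    return FamilySeed(
        seed_pairs=[AlignedSequencePair("AA", "AA")],
        contact_map=ContactMap(frozenset({(1, 1)}), length_a=2, length_b=2),
        profile_a=profile_a,
        profile_b=profile_b,
        family_id="toy",
    )


@pytest.fixture
def small_family() -> FamilySeed:
    """A 6+6 column family with two contacts and two seed complexes."""
    rng = np.random.default_rng(42)
    letters = "ACDEFGHIKL"

    def seq(n):
        return "".join(rng.choice(list(letters), size=n))

    msa_a = [seq(6) for _ in range(20)]
    msa_b = [seq(6) for _ in range(20)]
    return FamilySeed(
        seed_pairs=[
            AlignedSequencePair(seq(6), seq(6)),
            AlignedSequencePair(seq(6), seq(6)),
        ],
        contact_map=ContactMap(frozenset({(1, 2), (3, 5)}), length_a=6, length_b=6),
        profile_a=build_profile(msa_a),
        profile_b=build_profile(msa_b),
        family_id="small",
    )
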