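"""Simulated interface co-evolution by mutation + stochastic selection.

Artificial interacting homolog pairs are generated from each seed complex by a
Metropolis-style Markov chain: at every step a small fraction of interface
contacts is re-drawn from a family-wide contact-pair distribution (one side of
the contact fixed by a fair coin, the other resampled from the conditional
given the fixed residue), a small fraction of non-contact positions in each
protein is re-drawn from a BLOSUM62-derived substitution distribution, and the
whole proposed pair is accepted or rejected on its joint profile fitness.

The plain mode mirrors the described procedure (no proposal-ratio correction);
``MCMCParams.hastings=True`` enables the exact Metropolis–Hastings acceptance
with the proposal-ratio correction, under which the chain provably targets the
Boltzmann-like distribution ∝ exp(fitness / temperature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, GAP_INDEX, N_AA, decode, encode
from .interface import (
    AlignedSequencePair,
    ContactMap,
    FamilySeed,
    ProfileModel,
    profile_score,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contact-pair distribution
# ---------------------------------------------------------------------------


@dataclass
class PairDistribution:
    """Joint 20x20 distribution over (residue_a, residue_b) at a contact."""

    joint: np.ndarray

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        if self.joint.shape != (N_AA, N_AA):
            raise ValueError("joint must be 20x20")
        if np.any(self.joint < 0):
            raise ValueError("joint entries must be non-negative")
        if not math.isclose(float(self.joint.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("joint must sum to 1")

    @staticmethod
    def _normalize_rows(m: np.ndarray) -> np.ndarray:
        sums = m.sum(axis=1, keepdims=True)
        out = np.where(sums > 0, m / np.where(sums > 0, sums, 1.0), 1.0 / N_AA)
        return out

    @property
    def cond_b_given_a(self) -> np.ndarray:
        """P(b | a): row a of the joint, normalized (uniform for empty rows)."""
        return self._normalize_rows(self.joint)

    @property
    def cond_a_given_b(self) -> np.ndarray:
        """P(a | b): column b of the joint, normalized (uniform for empty columns)."""
        return self._normalize_rows(self.joint.T)

    def save(self, path: str | Path) -> None:
        """Write a 20x20 matrix with amino-acid header row and column."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                fh.write(aa + "\t" + "\t".join(f"{v:.10g}" for v in self.joint[i]) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PairDistribution":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        header = lines[0].split()
        order = [AMINO_ACIDS.index(a) for a in header]
        joint = np.zeros((N_AA, N_AA))
        for ln in lines[1:]:
            parts = ln.split()
            r = AMINO_ACIDS.index(parts[0])
            joint[r, order] = [float(v) for v in parts[1:]]
        return cls(joint)


def estimate_pair_distribution(
    family_seeds: FamilySeed | Sequence[FamilySeed],
    pseudocount: float = 1.0,
) -> PairDistribution:
    """Estimate the contact-pair distribution from seed-complex interfaces.

    ``joint[r, s] = (count(r, s) + pseudocount) / (total + 400 * pseudocount)``
    where counts run over all contacts of all seed pairs of all families.
    Observations where either contact position is a gap are skipped.
    """
    if isinstance(family_seeds, FamilySeed):
        family_seeds = [family_seeds]
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = np.zeros((N_AA, N_AA))
    n_contacts_total = 0
    n_skipped = 0
    for fam in family_seeds:
        if not fam.contact_map.contacts:
            raise ValueError(f"family {fam.family_id!r} has no contacts")
        n_contacts_total += len(fam.contact_map.contacts)
        for pair in fam.seed_pairs:
            a = encode(pair.seq_a)
            b = encode(pair.seq_b)
            for i, j in fam.contact_map.contacts:
                ra, rb = a[i - 1], b[j - 1]
                if ra == GAP_INDEX or rb == GAP_INDEX:
                    n_skipped += 1
                    continue
                counts[ra, rb] += 1
    if n_contacts_total == 0:
        raise ValueError("no contacts in any family seed")
    if n_skipped:
        logger.warning("skipped %d gap-containing contact observations", n_skipped)
    total = counts.sum()
    if pseudocount == 0 and np.any(counts == 0):
        raise ValueError("pseudocount must be > 0 when some contact pair is unobserved")
    joint = (counts + pseudocount) / (total + N_AA * N_AA * pseudocount)
    return PairDistribution(joint)


def blosum62_substitution(background: np.ndarray | None = None) -> np.ndarray:
    """BLOSUM62 inverted to a conditional substitution distribution.

    ``P(b | a) ∝ background_b * 2**(S(a, b) / 2)``, row-normalized over the 20
    residues (the standard inversion of a half-bit log-odds matrix).
    """
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    S = np.empty((N_AA, N_AA))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            S[i, j] = m[a, b]
    bg = np.full(N_AA, 1.0 / N_AA) if background is None else np.asarray(background, float)
    w = bg[None, :] * np.exp2(S / 2.0)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters and sample sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCParams:
    """Knobs of the co-evolution sampler.

    Defaults follow the simulation protocol: 5% of contacts and 5% of
    non-contact positions mutated per step, 1,000 samples per seed complex and
    2,500 for single-seed families.
    """

    contact_mutation_fraction: float = 0.05
    noncontact_mutation_fraction: float = 0.05
    temperature: float = 1.0
    n_samples_per_seed: int = 1000
    n_samples_single_seed: int = 2500
    burn_in: int = 500
    thinning: int = 10
    rng_seed: int = 0
    hastings: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.contact_mutation_fraction <= 1.0):
            raise ValueError("contact_mutation_fraction must be in [0, 1]")
        if not (0.0 <= self.noncontact_mutation_fraction <= 1.0):
            raise ValueError("noncontact_mutation_fraction must be in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_samples_per_seed < 0 or self.n_samples_single_seed < 0:
            raise ValueError("sample counts must be non-negative")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class SampleSet:
    """MCMC-generated artificial interacting homolog pairs."""

    samples: list[AlignedSequencePair]
    fitness_traces: list[np.ndarray]  # one trace per chain, one value per step
    acceptance_rate: float
    params_used: MCMCParams
    converged: bool = True


# ---------------------------------------------------------------------------
# proposal machinery
# ---------------------------------------------------------------------------


def _sample_from_rows(cum: np.ndarray, rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one symbol per row index from row-wise cumulative distributions."""
    u = rng.random(rows.shape[0])
    out = np.empty(rows.shape[0], dtype=np.int8)
    for k, r in enumerate(rows):
        out[k] = min(int(np.searchsorted(cum[r], u[k], side="right")), N_AA - 1)
    return out


@dataclass
class _ProposalContext:
    """Precomputed arrays reused at every MCMC step for one family."""

    contacts: np.ndarray  # (n_contacts, 2) zero-based (col_a, col_b)
    noncontact_a: np.ndarray  # zero-based non-interface columns of A
    noncontact_b: np.ndarray
    cond_ba: np.ndarray  # P(b | a)
    cond_ab: np.ndarray  # P(a | b)
    cum_ba: np.ndarray
    cum_ab: np.ndarray
    sub: np.ndarray  # P(new | old) for background mutations
    sub_cum: np.ndarray

    @classmethod
    def build(
        cls,
        contact_map: ContactMap,
        pair_dist: PairDistribution,
        substitution: np.ndarray | None,
    ) -> "_ProposalContext":
        sub = blosum62_substitution() if substitution is None else np.asarray(substitution, float)
        if sub.shape != (N_AA, N_AA) or not np.allclose(sub.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("substitution must be a row-stochastic 20x20 matrix")
        contacts = np.array(sorted(contact_map.contacts), dtype=np.intp) - 1
        if contacts.size == 0:
            contacts = contacts.reshape(0, 2)
        iface_a = {c - 1 for c in contact_map.interface_cols_a}
        iface_b = {c - 1 for c in contact_map.interface_cols_b}
        noncontact_a = np.array(
            [c for c in range(contact_map.length_a) if c not in iface_a], dtype=np.intp
        )
        noncontact_b = np.array(
            [c for c in range(contact_map.length_b) if c not in iface_b], dtype=np.intp
        )
        cond_ba = pair_dist.cond_b_given_a
        cond_ab = pair_dist.cond_a_given_b
        return cls(
            contacts=contacts,
            noncontact_a=noncontact_a,
            noncontact_b=noncontact_b,
            cond_ba=cond_ba,
            cond_ab=cond_ab,
            cum_ba=np.cumsum(cond_ba, axis=1),
            cum_ab=np.cumsum(cond_ab, axis=1),
            sub=sub,
            sub_cum=np.cumsum(sub, axis=1),
        )


@dataclass
class ProposalDetails:
    """Bookkeeping for one proposal step (positions are 1-based columns)."""

    contact_sites: list[tuple[int, int, str]]  # (col_a, col_b, resampled side)
    noncontact_sites_a: list[int]
    noncontact_sites_b: list[int]
    log_hastings: float


def _propose(
    a: np.ndarray,
    b: np.ndarray,
    ctx: _ProposalContext,
    frac_contact: float,
    frac_noncontact: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, ProposalDetails]:
    """One proposal: returns new arrays (copies) plus bookkeeping.

    Gap positions are immutable: a selected site whose current (or fixing)
    residue is a gap is left unchanged, and proposals never introduce gaps.
    """
    a_new = a.copy()
    b_new = b.copy()
    log_h = 0.0
    contact_sites: list[tuple[int, int, str]] = []
    nc_a: list[int] = []
    nc_b: list[int] = []

    n_contacts = ctx.contacts.shape[0]
    n_mut_c = int(math.ceil(frac_contact * n_contacts)) if n_contacts else 0
    if n_mut_c:
        chosen = rng.choice(n_contacts, size=n_mut_c, replace=False)
        coins = rng.random(n_mut_c) < 0.5  # True: fix A, resample B
        for idx, fix_a in zip(chosen, coins):
            i, j = ctx.contacts[idx]
            ra, rb = a_new[i], b_new[j]
            if ra == GAP_INDEX or rb == GAP_INDEX:
                continue
            if fix_a:
                new = int(_sample_from_rows(ctx.cum_ba, np.array([ra]), rng)[0])
                log_h += math.log(ctx.cond_ba[ra, rb]) - math.log(ctx.cond_ba[ra, new])
                b_new[j] = new
                contact_sites.append((int(i) + 1, int(j) + 1, "B"))
            else:
                new = int(_sample_from_rows(ctx.cum_ab, np.array([rb]), rng)[0])
                log_h += math.log(ctx.cond_ab[rb, ra]) - math.log(ctx.cond_ab[rb, new])
                a_new[i] = new
                contact_sites.append((int(i) + 1, int(j) + 1, "A"))

    for seq, pool, sites in (
        (a_new, ctx.noncontact_a, nc_a),
        (b_new, ctx.noncontact_b, nc_b),
    ):
        mutable = pool[seq[pool] != GAP_INDEX]
        n_mut = int(math.ceil(frac_noncontact * mutable.shape[0])) if mutable.shape[0] else 0
        if not n_mut:
            continue
        chosen = rng.choice(mutable.shape[0], size=n_mut, replace=False)
        for c in mutable[chosen]:
            old = seq[c]
            new = int(_sample_from_rows(ctx.sub_cum, np.array([old]), rng)[0])
            log_h += math.log(ctx.sub[new, old]) - math.log(ctx.sub[old, new])
            seq[c] = new
            sites.append(int(c) + 1)

    return a_new, b_new, ProposalDetails(contact_sites, nc_a, nc_b, log_h)


def propose_mutation(
    pair: AlignedSequencePair,
    contact_map: ContactMap,
    pair_dist: PairDistribution,
    params: MCMCParams,
    rng: np.random.Generator,
    substitution: np.ndarray | None = None,
    with_details: bool = False,
):
    """Propose a mutated pair: contact resampling + background substitutions.

    Exactly ``ceil(fraction * n_contacts)`` contacts are selected uniformly
    without replacement; for each, a fair coin fixes one side and the other is
    resampled from the contact-pair conditional given the fixed residue.
    Independently, ``ceil(fraction * n_noncontact)`` non-contact (non-gap)
    positions per protein are resampled from the substitution distribution
    conditioned on the current residue.
    """
    if pair.length_a != contact_map.length_a or pair.length_b != contact_map.length_b:
        raise ValueError("pair lengths do not match contact map")
    ctx = _ProposalContext.build(contact_map, pair_dist, substitution)
    a_new, b_new, details = _propose(
        encode(pair.seq_a),
        encode(pair.seq_b),
        ctx,
        params.contact_mutation_fraction,
        params.noncontact_mutation_fraction,
        rng,
    )
    new_pair = AlignedSequencePair(decode(a_new), decode(b_new))
    return (new_pair, details) if with_details else new_pair


# ---------------------------------------------------------------------------
# fitness and acceptance
# ---------------------------------------------------------------------------


def joint_fitness(
    pair: AlignedSequencePair, profile_a: ProfileModel, profile_b: ProfileModel
) -> float:
    """Joint fitness = sum of the two profile alignment scores (bits)."""
    return profile_score(pair.seq_a, profile_a) + profile_score(pair.seq_b, profile_b)


def accept(
    fitness_current: float,
    fitness_proposed: float,
    temperature: float,
    rng: np.random.Generator,
    log_hastings: float = 0.0,
) -> bool:
    """Metropolis(-Hastings) acceptance on the joint fitness.

    Accept with probability ``min(1, exp((f_prop - f_cur)/T + log_hastings))``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    log_alpha = (fitness_proposed - fitness_current) / temperature + log_hastings
    if log_alpha >= 0:
        return True
    return bool(rng.random() < math.exp(log_alpha))


def check_convergence(
    fitness_trace: Sequence[float], window: int, tolerance: float
) -> bool:
    """Window-mean stability: |mean(last) - mean(previous)| <= tol * pooled sd."""
    trace = np.asarray(fitness_trace, dtype=float)
    if trace.shape[0] < 2 * window:
        raise ValueError(f"trace of length {trace.shape[0]} shorter than 2*window={2 * window}")
    w2 = trace[-window:]
    w1 = trace[-2 * window : -window]
    pooled_sd = math.sqrt((float(np.var(w1, ddof=1)) + float(np.var(w2, ddof=1))) / 2.0)
    return abs(float(w2.mean()) - float(w1.mean())) <= tolerance * pooled_sd


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


def run_mcmc(
    family_seed: FamilySeed,
    params: MCMCParams | None = None,
    pair_dist: PairDistribution | None = None,
    substitution: np.ndarray | None = None,
    convergence_window: int = 200,
    convergence_tolerance: float = 0.5,
) -> SampleSet:
    """Generate artificial interacting homolog pairs for a family.

    One independent chain is run per seed complex, started at that seed.
    After ``burn_in`` steps, every ``thinning``-th state is emitted until
    ``n_samples_per_seed`` samples are collected per chain
    (``n_samples_single_seed`` when the family has exactly one seed).
    Fully reproducible given ``params.rng_seed``.
    """
    params = params or MCMCParams()
    if pair_dist is None:
        pair_dist = estimate_pair_distribution(family_seed)
    ctx = _ProposalContext.build(family_seed.contact_map, pair_dist, substitution)

    score_a = family_seed.profile_a.score_matrix()
    score_b = family_seed.profile_b.score_matrix()
    n_seeds = len(family_seed.seed_pairs)
    n_target = params.n_samples_single_seed if n_seeds == 1 else params.n_samples_per_seed

    child_seeds = np.random.SeedSequence(params.rng_seed).spawn(n_seeds)
    samples: list[AlignedSequencePair] = []
    traces: list[np.ndarray] = []
    n_accepted = 0
    n_steps = 0
    all_converged = True

    for seed_pair, ss in zip(family_seed.seed_pairs, child_seeds):
        rng = np.random.default_rng(ss)
        a = encode(seed_pair.seq_a)
        b = encode(seed_pair.seq_b)
        cols_a = np.arange(a.shape[0])
        cols_b = np.arange(b.shape[0])
        f = float(score_a[cols_a, a].sum() + score_b[cols_b, b].sum())
        trace: list[float] = []
        emitted = 0
        post_burn = 0
        step = 0
        while emitted < n_target:
            a_new, b_new, details = _propose(
                a,
                b,
                ctx,
                params.contact_mutation_fraction,
                params.noncontact_mutation_fraction,
                rng,
            )
            f_new = float(score_a[cols_a, a_new].sum() + score_b[cols_b, b_new].sum())
            log_h = details.log_hastings if params.hastings else 0.0
            if accept(f, f_new, params.temperature, rng, log_h):
                a, b, f = a_new, b_new, f_new
                n_accepted += 1
            trace.append(f)
            step += 1
            n_steps += 1
            if step > params.burn_in:
                post_burn += 1
                if post_burn % params.thinning == 0:
                    samples.append(AlignedSequencePair(decode(a), decode(b)))
                    emitted += 1
        trace_arr = np.asarray(trace)
        traces.append(trace_arr)
        if trace_arr.shape[0] >= 2 * convergence_window:
            if not check_convergence(trace_arr, convergence_window, convergence_tolerance):
                all_converged = False
                logger.warning(
                    "chain for family %r did not meet the convergence criterion",
                    family_seed.family_id,
                )

    rate = n_accepted / n_steps if n_steps else 0.0
    return SampleSet(
        samples=samples,
        fitness_traces=traces,
        acceptance_rate=rate,
        params_used=params,
        converged=all_converged,
    )


# ---------------------------------------------------------------------------
# sample I/O (interleaved A/B FASTA + trace TSV)
# ---------------------------------------------------------------------------


def write_samples_fasta(samples: Sequence[AlignedSequencePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, pair in enumerate(samples):
            fh.write(f">sample_{k:05d}_A\n{pair.seq_a}\n")
            fh.write(f">sample_{k:05d}_B\n{pair.seq_b}\n")


def read_samples_fasta(path: str | Path) -> list[AlignedSequencePair]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: interleaved A/B FASTA must have an even record count")
    return [
        AlignedSequencePair(str(records[k].seq), str(records[k + 1].seq))
        for k in range(0, len(records), 2)
    ]


def write_trace_tsv(sample_set: SampleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tstep\tfitness\n")
        for c, trace in enumerate(sample_set.fitness_traces):
            for s, f in enumerate(trace):
                fh.write(f"{c}\t{s}\t{f:.6f}\n")
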