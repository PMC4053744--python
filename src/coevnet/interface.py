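"""Domain types for template families of interacting proteins.

A *family* bundles one or more seed complexes (pairs of aligned sequences in
shared alignment coordinates), an inter-protein contact map over alignment
columns, and a per-protein position-specific log-odds profile built from a
multiple sequence alignment.  The family HMM of each partner protein is
represented here as a gapless position-specific profile: only
alignment-coordinate sequences are ever scored (the co-evolution sampler
preserves the alignment), so insert/delete states would never be exercised.
The scoring surface (:func:`profile_score`) is the pluggable point if a full
profile HMM is substituted.

All file formats index columns 1-based.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from scipy.spatial.distance import cdist

from .alphabet import (
    AMINO_ACIDS,
    GAP,
    GAP_INDEX,
    N_AA,
    encode,
    validate_sequence,
)

logger = logging.getLogger(__name__)

#: interface node identifier: ("A" or "B", 1-based alignment column)
Node = tuple[str, int]


class FamilyFormatError(ValueError):
    """A family bundle file violates the expected format."""


class ContactBoundsError(ValueError):
    """A contact refers to an alignment column outside the family lengths."""


def node_str(node: Node) -> str:
    return f"{node[0]}:{node[1]}"


def parse_node(s: str) -> Node:
    tag, col = s.split(":")
    if tag not in ("A", "B"):
        raise ValueError(f"node tag must be 'A' or 'B', got {tag!r}")
    return (tag, int(col))


# ---------------------------------------------------------------------------
# sequences and contacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedSequencePair:
    """Two aligned amino-acid sequences, one per partner protein."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        validate_sequence(self.seq_a)
        validate_sequence(self.seq_b)

    @property
    def length_a(self) -> int:
        return len(self.seq_a)

    @property
    def length_b(self) -> int:
        return len(self.seq_b)


@dataclass(frozen=True)
class ContactMap:
    """Inter-protein residue contacts in 1-based alignment coordinates."""

    contacts: frozenset[tuple[int, int]]
    length_a: int
    length_b: int

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (1 <= i <= self.length_a):
                raise ContactBoundsError(
                    f"contact column {i} outside protein A alignment (1..{self.length_a})"
                )
            if not (1 <= j <= self.length_b):
                raise ContactBoundsError(
                    f"contact column {j} outside protein B alignment (1..{self.length_b})"
                )

    @property
    def interface_cols_a(self) -> tuple[int, ...]:
        return tuple(sorted({i for i, _ in self.contacts}))

    @property
    def interface_cols_b(self) -> tuple[int, ...]:
        return tuple(sorted({j for _, j in self.contacts}))

    @property
    def nodes(self) -> tuple[Node, ...]:
        """Sorted union of both proteins' interface columns."""
        return tuple(
            [("A", c) for c in self.interface_cols_a]
            + [("B", c) for c in self.interface_cols_b]
        )

    @property
    def interface_size(self) -> int:
        """Total interface node count (both proteins)."""
        return len(self.interface_cols_a) + len(self.interface_cols_b)

    def transpose(self) -> "ContactMap":
        return ContactMap(
            frozenset((j, i) for i, j in self.contacts),
            length_a=self.length_b,
            length_b=self.length_a,
        )


def read_contacts_tsv(path: str | Path, length_a: int, length_b: int) -> ContactMap:
    """Read a two-column, 1-based, tab-separated contact list ('#' comments)."""
    contacts: set[tuple[int, int]] = set()
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise FamilyFormatError(
                    f"{path}: row {row_no}: expected two integer columns, got {line!r}"
                )
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FamilyFormatError(
                    f"{path}: row {row_no}: non-integer contact entry"
                ) from exc
            if not (1 <= i <= length_a and 1 <= j <= length_b):
                raise ContactBoundsError(
                    f"{path}: row {row_no}: contact ({i}, {j}) out of range for "
                    f"alignments of length {length_a} and {length_b}"
                )
            contacts.add((i, j))
    return ContactMap(frozenset(contacts), length_a=length_a, length_b=length_b)


def write_contacts_tsv(contact_map: ContactMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# col_a\tcol_b (1-based alignment columns)\n")
        for i, j in sorted(contact_map.contacts):
            fh.write(f"{i}\t{j}\n")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileModel:
    """Position-specific log-odds profile over alignment columns.

    ``log_odds[c, r] = log2(P(r | column c) / background[r])``.  Gap columns in
    a scored sequence contribute a fixed ``gap_penalty`` instead of a lookup.
    """

    log_odds: np.ndarray  # (n_columns, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    gap_penalty: float = -4.0

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != N_AA:
            raise ValueError("log_odds must have shape (n_columns, 20)")
        if self.background.shape != (N_AA,) or np.any(self.background <= 0):
            raise ValueError("background must be a strictly positive 20-vector")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("background must sum to 1")
        probs = self.probabilities
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-column probabilities must sum to 1")

    @property
    def n_columns(self) -> int:
        return self.log_odds.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Per-column residue probabilities recovered from the log-odds."""
        return self.background[None, :] * np.exp2(self.log_odds)

    def score_matrix(self) -> np.ndarray:
        """(n_columns, 21) per-symbol scores with the gap penalty in column 20."""
        m = np.empty((self.n_columns, N_AA + 1))
        m[:, :N_AA] = self.log_odds
        m[:, GAP_INDEX] = self.gap_penalty
        return m

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "background": self.background.tolist(),
            "columns": self.log_odds.tolist(),
            "pseudocount": self.pseudocount,
            "gap_penalty": self.gap_penalty,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProfileModel":
        return cls(
            log_odds=np.asarray(d["columns"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            pseudocount=float(d["pseudocount"]),
            gap_penalty=float(d.get("gap_penalty", -4.0)),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "ProfileModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def uniform_background() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


def build_profile(
    msa: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_penalty: float = -4.0,
) -> ProfileModel:
    """Estimate a log-odds profile from an aligned set of sequences.

    Column probabilities are ``(count_r + pseudocount * background_r) /
    (n_nongap + pseudocount)``; gaps are excluded from the counts.  A column
    consisting only of gaps falls back to the background distribution.
    """
    msa = [str(s) for s in msa]
    if not msa:
        raise ValueError("cannot build a profile from an empty MSA")
    lengths = {len(s) for s in msa}
    if len(lengths) != 1:
        raise FamilyFormatError(f"MSA rows have inconsistent lengths: {sorted(lengths)}")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if np.any(bg <= 0):
        raise ValueError("background must be strictly positive")
    bg = bg / bg.sum()
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")

    codes = np.stack([encode(s) for s in msa])  # (n_seq, n_col)
    n_col = codes.shape[1]
    counts = np.zeros((n_col, N_AA))
    for r in range(N_AA):
        counts[:, r] = (codes == r).sum(axis=0)
    n_eff = counts.sum(axis=1)  # non-gap count per column

    probs = np.empty_like(counts)
    nonempty = n_eff > 0
    if pseudocount == 0 and np.any(counts[nonempty] == 0):
        # log-odds of an unobserved residue would be -inf
        raise ValueError("pseudocount must be > 0 unless every column observes all residues")
    probs[nonempty] = (counts[nonempty] + pseudocount * bg[None, :]) / (
        n_eff[nonempty, None] + pseudocount
    )
    if np.any(~nonempty):
        logger.warning(
            "MSA columns %s contain only gaps; falling back to background",
            np.nonzero(~nonempty)[0] + 1,
        )
        probs[~nonempty] = bg[None, :]
    log_odds = np.log2(probs / bg[None, :])
    return ProfileModel(log_odds, bg, pseudocount, gap_penalty)


def profile_score(sequence: str, profile: ProfileModel) -> float:
    """Sum of per-column log-odds; gap columns contribute the gap penalty."""
    codes = encode(sequence)
    if codes.shape[0] != profile.n_columns:
        raise ValueError(
            f"sequence length {codes.shape[0]} does not match profile with "
            f"{profile.n_columns} columns"
        )
    m = profile.score_matrix()
    return float(m[np.arange(codes.shape[0]), codes].sum())


# ---------------------------------------------------------------------------
# family bundles
# ---------------------------------------------------------------------------


@dataclass
class FamilySeed:
    """Seed complexes of a template family plus its contact map and profiles."""

    seed_pairs: list[AlignedSequencePair]
    contact_map: ContactMap
    profile_a: ProfileModel
    profile_b: ProfileModel
    family_id: str = "family"

    def __post_init__(self) -> None:
        if not self.seed_pairs:
            raise ValueError("a family needs at least one seed pair")
        la, lb = self.contact_map.length_a, self.contact_map.length_b
        for k, pair in enumerate(self.seed_pairs):
            if pair.length_a != la or pair.length_b != lb:
                raise FamilyFormatError(
                    f"seed pair {k} has lengths ({pair.length_a}, {pair.length_b}); "
                    f"family expects ({la}, {lb})"
                )
        if self.profile_a.n_columns != la or self.profile_b.n_columns != lb:
            raise FamilyFormatError("profile column counts do not match family lengths")

    @property
    def length_a(self) -> int:
        return self.contact_map.length_a

    @property
    def length_b(self) -> int:
        return self.contact_map.length_b


def read_msa_fasta(path: str | Path) -> list[str]:
    """Read an aligned FASTA / A2M file; uppercases and maps '.' to '-'."""
    seqs = [
        str(rec.seq).upper().replace(".", GAP) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise FamilyFormatError(f"{path}: no FASTA records")
    return seqs


def read_family_seed(
    fasta_path: str | Path,
    contacts_tsv_path: str | Path,
    msa_paths: tuple[str | Path, str | Path],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_penalty: float = -4.0,
    family_id: str | None = None,
) -> FamilySeed:
    """Assemble a :class:`FamilySeed` from FASTA + contacts TSV + two MSAs.

    The seed FASTA must hold an even number of records ordered A1, B1, A2, B2…
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records or len(records) % 2 != 0:
        raise FamilyFormatError(
            f"{fasta_path}: expected an even, non-zero number of records "
            f"(A1,B1,A2,B2,...), got {len(records)}"
        )
    pairs = []
    length_a = len(records[0].seq)
    length_b = len(records[1].seq)
    for k in range(0, len(records), 2):
        ra, rb = records[k], records[k + 1]
        if len(ra.seq) != length_a:
            raise FamilyFormatError(
                f"{fasta_path}: record {ra.id!r} has length {len(ra.seq)}, expected {length_a}"
            )
        if len(rb.seq) != length_b:
            raise FamilyFormatError(
                f"{fasta_path}: record {rb.id!r} has length {len(rb.seq)}, expected {length_b}"
            )
        pairs.append(AlignedSequencePair(str(ra.seq).upper(), str(rb.seq).upper()))

    contact_map = read_contacts_tsv(contacts_tsv_path, length_a, length_b)

    msa_a = read_msa_fasta(msa_paths[0])
    msa_b = read_msa_fasta(msa_paths[1])
    if len(msa_a[0]) != length_a:
        raise FamilyFormatError(
            f"{msa_paths[0]}: MSA has {len(msa_a[0])} columns, family expects {length_a}"
        )
    if len(msa_b[0]) != length_b:
        raise FamilyFormatError(
            f"{msa_paths[1]}: MSA has {len(msa_b[0])} columns, family expects {length_b}"
        )
    profile_a = build_profile(msa_a, pseudocount, background, gap_penalty)
    profile_b = build_profile(msa_b, pseudocount, background, gap_penalty)
    fid = family_id if family_id is not None else Path(fasta_path).stem
    return FamilySeed(pairs, contact_map, profile_a, profile_b, family_id=fid)


# ---------------------------------------------------------------------------
# contact maps from coordinates
# ---------------------------------------------------------------------------


def build_contact_map_from_coords(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff_angstrom: float = 8.0,
) -> ContactMap:
    """Contacts = residue pairs whose representative atoms lie within *cutoff*.

    ``coords_*`` are (n_residues, 3) arrays of representative-atom coordinates
    in Ångströms, one row per alignment column.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    coords_a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    coords_b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if coords_a.size == 0 or coords_b.size == 0:
        return ContactMap(frozenset(), length_a=coords_a.shape[0], length_b=coords_b.shape[0])
    dist = cdist(coords_a, coords_b)
    ii, jj = np.nonzero(dist <= cutoff_angstrom)
    contacts = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))
    return ContactMap(contacts, length_a=coords_a.shape[0], length_b=coords_b.shape[0])


def read_coordinates_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a per-residue coordinate table: chain, 1-based index, x, y, z."""
    rows: dict[str, dict[int, tuple[float, float, float]]] = {}
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 5:
                raise FamilyFormatError(
                    f"{path}: row {row_no}: expected 'chain index x y z'"
                )
            chain, idx = parts[0], int(parts[1])
            rows.setdefault(chain, {})[idx] = tuple(map(float, parts[2:]))
    out = {}
    for chain, by_idx in rows.items():
        n = max(by_idx)
        arr = np.full((n, 3), np.nan)
        for idx, xyz in by_idx.items():
            arr[idx - 1] = xyz
        out[chain] = arr
    return out


# ---------------------------------------------------------------------------
# interface assignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceAssignment:
    """Residue symbols at every interface node of a family's contact map."""

    residues: Mapping[Node, str]

    def __post_init__(self) -> None:
        for node, sym in self.residues.items():
            if sym not in AMINO_ACIDS + GAP:
                raise ValueError(f"symbol {sym!r} at node {node} outside the alphabet")

    @classmethod
    def from_pair(
        cls, pair: AlignedSequencePair, contact_map: ContactMap
    ) -> "InterfaceAssignment":
        """Extract the interface residues of an aligned pair."""
        residues: dict[Node, str] = {}
        for c in contact_map.interface_cols_a:
            residues[("A", c)] = pair.seq_a[c - 1]
        for c in contact_map.interface_cols_b:
            residues[("B", c)] = pair.seq_b[c - 1]
        return cls(residues)

    def check_nodes(self, nodes: Iterable[Node]) -> None:
        expected = set(nodes)
        got = set(self.residues)
        if got != expected:
            raise ValueError(
                f"assignment nodes differ from expected interface: "
                f"missing {sorted(expected - got)}, extra {sorted(got - expected)}"
            )
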