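"""Enumeration and splicing of theoretical minimal RNA rings.

A minimal RNA ring is a 22-nt circular sequence read in overlapping codons
over three consecutive translation rounds.  Because gcd(3, 22) = 1, the 22
translation codons visit every ring position exactly once, so the codon
multiset equals the multiset of all 22 trinucleotide windows around the
ring.  The coding constraints are: exactly one stop codon, a start AUG
whose open reading frame ends at that stop (which therefore occupies the
three nucleotides immediately 5' of the start), and one codon for each of
the 20 amino acids among the remaining windows.

Three documented constraint readings are exposed through
``constraint_mode``:

``canonical_codons`` (default)
    the ring family shares one fixed codon per amino acid (the assignment
    realized by the published reference ring, AB) plus the AUG start and
    UGA stop; rings are the circular arrangements whose 22 windows realize
    that multiset exactly.  This is the only reading whose solution count
    stays within the published bound of 25 (it yields 24) while containing
    the reference ring.
``coding``
    any codon choices: one stop, start AUG three nucleotides after the
    stop ends, each amino acid exactly once elsewhere (the start
    contributes a second methionine).  1280 rings.
``coding_adjacent``
    as ``coding`` with the additional overlap adjacency seen in the
    reference ring: a second, met-coding AUG overlapping the stop (the
    AUGA motif).  336 rings.

The enumerator is an exhaustive pruned depth-first search over ring
positions with amino-acid-multiset feasibility pruning; ``is_valid_ring``
re-verifies every constraint through independent string operations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_rna_by_id

from .structure_features import canonicalize_sequence

__all__ = [
    "RNARing",
    "SplicedSequence",
    "GeneticCode",
    "RING_LENGTH",
    "REFERENCE_RING_SEQUENCE",
    "standard_code",
    "enumerate_minimal_rings",
    "is_valid_ring",
    "splice_ring",
    "canonical_rotation",
    "rings_to_fasta",
]

RING_LENGTH = 22

#: Ring 25 ("AB"), the published reference ring, in the rotation defining
#: splicing position 1 (T/U-canonicalized, 2-nt circular overhang removed).
REFERENCE_RING_SEQUENCE = "UAUGAAUGGUGCCAUUCAAGAC"


@dataclass(frozen=True)
class GeneticCode:
    """A codon table over an arbitrary alphabet, for real or toy codes."""

    forward: dict[str, str]          # codon -> amino acid symbol
    stops: frozenset[str]
    start: str                       # the start codon
    alphabet: str = "ACGU"

    @property
    def codon_length(self) -> int:
        return len(self.start)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.forward.values())))


def standard_code() -> GeneticCode:
    """The standard genetic code (RNA alphabet) from biopython."""
    tbl = unambiguous_rna_by_id[1]
    return GeneticCode(
        forward=dict(tbl.forward_table),
        stops=frozenset(tbl.stop_codons),
        start="AUG",
    )


@dataclass(frozen=True)
class RNARing:
    """A circular ring stored in canonical (lexicographically smallest) rotation."""

    ring_id: int
    sequence: str
    name: str | None = None
    cognate_aa: str | None = None
    integration_order: int | None = None
    anchor_offset: int = 0
    codons: tuple[str, ...] = field(default=(), compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SplicedSequence:
    """One linearization of a ring; ``position`` is 1-based (1..ring length)."""

    ring_id: int
    position: int
    sequence: str


def canonical_rotation(sequence: str) -> str:
    """Lexicographically smallest rotation: the ring's stored identity."""
    return min(sequence[i:] + sequence[:i] for i in range(len(sequence)))


def _windows(sequence: str, k: int) -> list[str]:
    doubled = sequence + sequence[: k - 1]
    return [doubled[i : i + k] for i in range(len(sequence))]


def ring_codons(sequence: str, k: int = 3) -> tuple[str, ...]:
    """The codons in translation order (step ``k`` around the ring).

    Requires gcd(k, len) = 1 so that the codon starts cover every position.
    """
    n = len(sequence)
    doubled = sequence + sequence
    return tuple(doubled[(k * i) % n : (k * i) % n + k] for i in range(n))


def _reference_multiset(code: GeneticCode) -> Counter:
    return Counter(_windows(REFERENCE_RING_SEQUENCE, 3))


# ---------------------------------------------------------------------------
# checker (independent of the enumerator's pruning logic)


def is_valid_ring(
    sequence: str,
    code: GeneticCode | None = None,
    constraint_mode: str = "canonical_codons",
    length: int | None = None,
) -> tuple[bool, str]:
    """Re-verify the ring constraints from scratch.

    Returns ``(ok, diagnostic)``; the diagnostic names the first violated
    constraint.  Raises ``ValueError`` for symbols outside the code's
    alphabet, identifying the offending position.
    """
    code = code or standard_code()
    sequence = canonicalize_sequence(sequence)
    for pos, ch in enumerate(sequence):
        if ch not in code.alphabet:
            raise ValueError(f"non-alphabet symbol {ch!r} at position {pos + 1}")
    n = length or (RING_LENGTH if code.start == "AUG" else len(sequence))
    if len(sequence) != n:
        return False, f"length {len(sequence)} != {n}"
    k = code.codon_length
    ws = _windows(sequence, k)
    if constraint_mode == "canonical_codons":
        # the fixed codon assignment implies one stop and full coverage
        if Counter(ws) != _reference_multiset(code):
            return False, "codon multiset differs from the canonical assignment"
        return True, "ok"
    if constraint_mode not in ("coding", "coding_adjacent"):
        raise ValueError(f"unknown constraint_mode {constraint_mode!r}")
    stop_idx = [i for i, w in enumerate(ws) if w in code.stops]
    if len(stop_idx) != 1:
        return False, f"{len(stop_idx)} stop codons (need exactly 1)"
    si = stop_idx[0]
    if ws[(si + k) % n] != code.start:
        return False, "start codon is not adjacent 3' of the stop"
    rest = [ws[i] for i in range(n) if i not in (si, (si + k) % n)]
    aa_counts = Counter(code.forward[w] for w in rest)
    expected = Counter(code.amino_acids)
    if aa_counts != expected:
        missing = sorted(set(expected) - set(aa_counts))
        return False, f"amino-acid multiset mismatch (missing: {missing})"
    if constraint_mode == "coding_adjacent" and ws[(si - 1) % n] != code.start:
        return False, "no start codon overlapping the stop (AUGA motif)"
    return True, "ok"


# ---------------------------------------------------------------------------
# enumerator


def _dfs_coding(code: GeneticCode, n: int, require_overlap_start: bool) -> list[str]:
    """Anchored DFS for the ``coding``/``coding_adjacent`` modes.

    The rotation is anchored with the stop codon at window 0 and the start
    at window ``k`` (positions k..2k-1), which every solution admits exactly
    once; pruning tracks the amino-acid multiset as windows complete.
    """
    k = code.codon_length
    sols: list[str] = []
    amino = code.amino_acids
    for stop in sorted(code.stops):
        seq: list[str | None] = [None] * n
        seq[0:k] = list(stop)
        seq[k : 2 * k] = list(code.start)
        counts: Counter = Counter()
        feasible = True
        # windows 1..k-1 straddle the stop/start junction and are already fixed
        for w in range(1, k):
            cod = "".join(seq[w : w + k])  # type: ignore[arg-type]
            if cod in code.stops:
                feasible = False
                break
            counts[code.forward[cod]] += 1
        if not feasible or any(v > 1 for v in counts.values()):
            continue

        def dfs(p: int) -> None:
            if p == n:
                wrap: Counter = Counter()
                for w in range(n - k + 1, n):
                    cod = "".join(seq[(w + i) % n] for i in range(k))  # type: ignore[index]
                    if cod in code.stops:
                        return
                    wrap[code.forward[cod]] += 1
                total = counts + wrap
                if all(total.get(a, 0) == 1 for a in amino):
                    sols.append("".join(seq))  # type: ignore[arg-type]
                return
            for nt in code.alphabet:
                seq[p] = nt
                cod = "".join(seq[p - k + 1 : p + 1])  # type: ignore[arg-type]
                if cod in code.stops:
                    continue
                aa = code.forward[cod]
                if counts[aa] >= 1:
                    continue
                counts[aa] += 1
                dfs(p + 1)
                counts[aa] -= 1
            seq[p] = None

        dfs(2 * k)
    if require_overlap_start:
        sols = [
            s
            for s in sols
            if _windows(s, k)[-1] == code.start  # window n-1 overlaps the stop at 0
        ]
    return sols


def _dfs_multiset(target: Counter, alphabet: str, n: int, k: int) -> list[str]:
    """DFS over circular sequences whose window multiset equals ``target``."""
    anchor = next(c for c in sorted(target) if target[c] == 1)
    seq: list[str | None] = [None] * n
    seq[0:k] = list(anchor)
    avail = Counter(target)
    avail[anchor] -= 1
    sols: list[str] = []

    def dfs(p: int) -> None:
        if p == n:
            wrap: Counter = Counter()
            for w in range(n - k + 1, n):
                cod = "".join(seq[(w + i) % n] for i in range(k))  # type: ignore[index]
                wrap[cod] += 1
            if all(avail[c] >= m for c, m in wrap.items()) and sum(
                avail.values()
            ) == sum(wrap.values()):
                sols.append("".join(seq))  # type: ignore[arg-type]
            return
        for nt in alphabet:
            seq[p] = nt
            cod = "".join(seq[p - k + 1 : p + 1])  # type: ignore[arg-type]
            if avail[cod] > 0:
                avail[cod] -= 1
                dfs(p + 1)
                avail[cod] += 1
        seq[p] = None

    dfs(k)
    return sols


def enumerate_minimal_rings(
    code: GeneticCode | None = None,
    constraint_mode: str = "canonical_codons",
    length: int | None = None,
) -> list[RNARing]:
    """Exhaustively enumerate the rings of ``constraint_mode``.

    Returns one :class:`RNARing` per rotation-equivalence class, sorted by
    canonical sequence, numbered from 1.  An infeasible mode yields an
    empty list (not an exception).
    """
    code = code or standard_code()
    n = length or (RING_LENGTH if code.start == "AUG" else None)
    if n is None:
        raise ValueError("length is required for non-standard codes")
    k = code.codon_length
    if _gcd(k, n) != 1:
        return []  # codon starts would not cover the ring: no valid design
    if constraint_mode == "canonical_codons":
        if code.start != "AUG":
            raise ValueError("canonical_codons mode is defined for the standard code")
        raw = _dfs_multiset(_reference_multiset(code), code.alphabet, n, k)
    elif constraint_mode in ("coding", "coding_adjacent"):
        raw = _dfs_coding(code, n, constraint_mode == "coding_adjacent")
    else:
        raise ValueError(f"unknown constraint_mode {constraint_mode!r}")
    canon = sorted({canonical_rotation(s) for s in raw})
    rings = []
    for i, seq in enumerate(canon, start=1):
        ring = RNARing(ring_id=i, sequence=seq, codons=ring_codons(seq, k))
        if canonical_rotation(REFERENCE_RING_SEQUENCE) == seq:
            ring = RNARing(
                ring_id=i,
                sequence=seq,
                name="AB",
                cognate_aa="G",
                anchor_offset=_rotation_offset(seq, REFERENCE_RING_SEQUENCE),
                codons=ring_codons(seq, k),
            )
        rings.append(ring)
    return rings


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


def _rotation_offset(canonical: str, anchored: str) -> int:
    """Offset such that rotating ``canonical`` by it recovers ``anchored``."""
    n = len(canonical)
    for off in range(n):
        if canonical[off:] + canonical[:off] == anchored:
            return off
    raise ValueError("sequences are not rotations of each other")


# ---------------------------------------------------------------------------
# splicing


def splice_ring(ring: RNARing, position: int) -> SplicedSequence:
    """Linearize a ring at splicing ``position`` (1-based).

    Position 1 starts at the ring's ``anchor_offset`` (the rotation with
    highest homology to an ancestral tRNA, shipped as annotation); each
    further position shifts by one nucleotide.
    """
    n = ring.length
    if not 1 <= position <= n:
        raise ValueError(f"splicing position {position} outside 1..{n}")
    start = (ring.anchor_offset + position - 1) % n
    seq = ring.sequence[start:] + ring.sequence[:start]
    return SplicedSequence(ring.ring_id, position, seq)


def rings_to_fasta(rings: list[RNARing], spliced: bool = False) -> str:
    """FASTA text for rings (anchored rotation) or all their splicings."""
    out = []
    for ring in rings:
        if spliced:
            for pos in range(1, ring.length + 1):
                s = splice_ring(ring, pos)
                out.append(f">ring{ring.ring_id:02d}_sp{pos:02d}\n{s.sequence}")
        else:
            anchored = splice_ring(ring, 1).sequence
            out.append(f">ring{ring.ring_id:02d}\n{anchored}")
    return "\n".join(out) + "\n"
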