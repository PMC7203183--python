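"""Secondary-structure ingestion, folding, and the four-variable featurization.

Every structure is reduced to four percentages:

``pct_stem``
    paired nucleotides among all nucleotides,
``pct_eloop``
    unpaired nucleotides lying in hairpin loops, among all unpaired
    nucleotides,
``pct_gc_stem``
    G+C among paired nucleotides,
``pct_gc_loop``
    G+C among unpaired nucleotides.

Terminology warning: in this analysis "external loop" means a hairpin loop
topping a stem, *not* the exterior loop of standard RNA nomenclature.
Bulges, internal loops, multibranch loops and dangling ends all count as
"internal" unpaired positions.  Only Watson-Crick pairs and the G-U wobble
are retained; any other drawn pair (C-A, U-C, G-A, ...) is masked and both
positions are treated as unpaired.

Coordinates are 0-based half-open internally; CT input/output is 1-based.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

__all__ = [
    "SecondaryStructure",
    "FeatureVector",
    "parse_structure",
    "parse_dot_bracket",
    "parse_ct",
    "write_ct",
    "to_dot_bracket",
    "apply_canonical_mask",
    "classify_loops",
    "extract_features",
    "fold",
    "CANONICAL_PAIRS",
]

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def canonicalize_sequence(sequence: str) -> str:
    """Uppercase and convert to the RNA alphabet (T -> U)."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs over a linear sequence.

    ``pairs`` holds 0-based ``(i, j)`` tuples with ``i < j``; each index
    appears in at most one pair and pairs never cross (no pseudoknots).
    ``provenance`` records which backend or parser produced the structure.
    """

    sequence: str
    pairs: frozenset[tuple[int, int]]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i}, {j}) out of range for length {n}")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair: ({i}, {j})")
            seen.update((i, j))
        sorted_pairs = sorted(self.pairs)
        for a in range(len(sorted_pairs)):
            i, j = sorted_pairs[a]
            for k, l in sorted_pairs[a + 1 :]:
                if k >= j:
                    break
                if l > j:  # i < k < j < l
                    raise ValueError(
                        f"crossing pairs ({i},{j}) and ({k},{l}): pseudoknots unsupported"
                    )

    @property
    def n(self) -> int:
        return len(self.sequence)

    def partner(self) -> list[int | None]:
        """Partner index per position, ``None`` when unpaired."""
        out: list[int | None] = [None] * self.n
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass(frozen=True)
class FeatureVector:
    """The four secondary-structure percentages plus their underlying counts.

    Degenerate denominators (no unpaired or no paired nucleotides) yield 0.0
    for the affected percentages and set the corresponding flag so that
    downstream statistics can exclude rather than fabricate.
    """

    pct_stem: float
    pct_eloop: float
    pct_gc_stem: float
    pct_gc_loop: float
    counts: dict[str, int] = field(default_factory=dict, compare=False)
    degenerate_loop: bool = False
    degenerate_stem: bool = False

    @property
    def values(self) -> tuple[float, float, float, float]:
        return (self.pct_stem, self.pct_eloop, self.pct_gc_stem, self.pct_gc_loop)

    @property
    def is_degenerate(self) -> bool:
        """True when some percentage is a zero-denominator sentinel."""
        return self.degenerate_loop or self.degenerate_stem

    @classmethod
    def from_counts(
        cls,
        n_total: int,
        n_paired: int,
        n_eloop: int,
        n_gc_stem: int,
        n_gc_loop: int,
    ) -> "FeatureVector":
        """Build the four percentages from raw counts.

        The arithmetic is fixed: stem over all nucleotides, hairpin-loop and
        loop-GC percentages over unpaired nucleotides, stem-GC over paired
        nucleotides.
        """
        if n_total <= 0:
            raise ValueError("n_total must be positive")
        n_unpaired = n_total - n_paired
        if n_unpaired < 0:
            raise ValueError("n_paired exceeds n_total")
        deg_loop = n_unpaired == 0
        deg_stem = n_paired == 0
        return cls(
            pct_stem=100.0 * n_paired / n_total,
            pct_eloop=0.0 if deg_loop else 100.0 * n_eloop / n_unpaired,
            pct_gc_stem=0.0 if deg_stem else 100.0 * n_gc_stem / n_paired,
            pct_gc_loop=0.0 if deg_loop else 100.0 * n_gc_loop / n_unpaired,
            counts={
                "n_total": n_total,
                "n_paired": n_paired,
                "n_unpaired": n_unpaired,
                "n_eloop": n_eloop,
                "n_gc_stem": n_gc_stem,
                "n_gc_loop": n_gc_loop,
            },
            degenerate_loop=deg_loop,
            degenerate_stem=deg_stem,
        )


# ---------------------------------------------------------------------------
# parsing


def parse_dot_bracket(sequence: str, structure: str, provenance: str = "dot-bracket") -> SecondaryStructure:
    """Parse a dot-bracket string against its sequence.

    Raises ``ValueError`` on unbalanced brackets or length mismatch.
    """
    sequence = canonicalize_sequence(sequence)
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs = set()
    for idx, ch in enumerate(structure):
        if ch in _BRACKETS:
            stacks[ch].append(idx)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise ValueError(f"unbalanced '{ch}' at position {idx + 1}")
            pairs.add((stacks[opener].pop(), idx))
        elif ch not in ".,-:_":
            raise ValueError(f"unexpected structure character {ch!r} at position {idx + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced '{opener}' at position {stack[-1] + 1}")
    return SecondaryStructure(sequence, frozenset(pairs), provenance)


def parse_ct(text: str, provenance: str = "ct") -> SecondaryStructure:
    """Parse connect (CT) format: per-line ``index base prev next partner id``.

    The partner column is 1-based, 0 meaning unpaired.  Partner asymmetry is
    an error reported with its line number.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty CT input")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise ValueError("CT header must start with the sequence length") from exc
    if len(lines) - 1 < n:
        raise ValueError(f"CT declares {n} nucleotides but has {len(lines) - 1} rows")
    seq = []
    partner = [0] * n
    for lineno, ln in enumerate(lines[1 : n + 1], start=2):
        cols = ln.split()
        if len(cols) < 5:
            raise ValueError(f"CT line {lineno}: expected >=5 columns")
        idx = int(cols[0])
        if idx != len(seq) + 1:
            raise ValueError(f"CT line {lineno}: index {idx} out of order")
        seq.append(cols[1])
        partner[idx - 1] = int(cols[4])
    pairs = set()
    for i, p in enumerate(partner, start=1):
        if p == 0:
            continue
        if not (1 <= p <= n) or partner[p - 1] != i:
            raise ValueError(f"CT line {i + 1}: asymmetric partner {i} -> {p}")
        if i < p:
            pairs.add((i - 1, p - 1))
    return SecondaryStructure(canonicalize_sequence("".join(seq)), frozenset(pairs), provenance)


def parse_structure(text: str, sequence: str | None = None) -> SecondaryStructure:
    """Parse either CT content or a dot-bracket string.

    CT content is recognised by its numeric first column; a bare dot-bracket
    string requires ``sequence``.
    """
    stripped = text.strip()
    first = stripped.splitlines()[0].split() if stripped else []
    if first and first[0].isdigit():
        return parse_ct(text)
    if sequence is None:
        raise ValueError("dot-bracket input needs an accompanying sequence")
    lines = stripped.splitlines()
    if len(lines) == 1:
        return parse_dot_bracket(sequence, lines[0])
    raise ValueError("unrecognised structure format")


def write_ct(structure: SecondaryStructure, title: str = "") -> str:
    partner = structure.partner()
    out = [f"{structure.n} {title}".rstrip()]
    for i, base in enumerate(structure.sequence):
        p = partner[i]
        out.append(
            f"{i + 1} {base} {i} {(i + 2) if i + 1 < structure.n else 0} "
            f"{0 if p is None else p + 1} {i + 1}"
        )
    return "\n".join(out) + "\n"


def to_dot_bracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.n
    for i, j in structure.pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# masking, loop classification, features


def apply_canonical_mask(structure: SecondaryStructure) -> SecondaryStructure:
    """Drop non-canonical pairs; the freed positions become unpaired.

    Watson-Crick pairs and G-U wobble survive; everything else (C-A, U-C,
    G-A, ...) is treated as an internal bulge.
    """
    keep = frozenset(
        (i, j)
        for i, j in structure.pairs
        if (structure.sequence[i], structure.sequence[j]) in CANONICAL_PAIRS
    )
    return SecondaryStructure(structure.sequence, keep, structure.provenance + "+mask")


def classify_loops(structure: SecondaryStructure) -> list[str]:
    """Label every position ``paired``, ``eloop`` or ``other_unpaired``.

    A position is ``eloop`` (hairpin loop) when its nearest paired
    neighbours on both sides form one and the same pair.  Unpaired runs
    against a sequence end, bulges, internal and multibranch loops are all
    ``other_unpaired``.
    """
    partner = structure.partner()
    n = structure.n
    labels = ["other_unpaired"] * n
    for i, p in enumerate(partner):
        if p is not None:
            labels[i] = "paired"
    i = 0
    while i < n:
        if labels[i] == "paired":
            i += 1
            continue
        j = i
        while j < n and labels[j] != "paired":
            j += 1
        # run [i, j) of unpaired positions; flanks i-1 and j
        if i > 0 and j < n and partner[i - 1] == j:
            for k in range(i, j):
                labels[k] = "eloop"
        i = j
    return labels


def extract_features(structure: SecondaryStructure) -> FeatureVector:
    """Compute the four percentages of a canonical-masked structure."""
    labels = classify_loops(structure)
    seq = structure.sequence
    n_total = structure.n
    n_paired = sum(1 for l in labels if l == "paired")
    n_eloop = sum(1 for l in labels if l == "eloop")
    gc = set("GC")
    n_gc_stem = sum(1 for b, l in zip(seq, labels) if l == "paired" and b in gc)
    n_gc_loop = sum(1 for b, l in zip(seq, labels) if l != "paired" and b in gc)
    return FeatureVector.from_counts(n_total, n_paired, n_eloop, n_gc_stem, n_gc_loop)


# ---------------------------------------------------------------------------
# folding backends

MIN_HAIRPIN = 3


def _nussinov_maxpair(sequence: str) -> frozenset[tuple[int, int]]:
    """Maximum canonical pairing with a minimum hairpin of 3 unpaired nt.

    Deterministic traceback: the 5'-most position pairs whenever it can
    participate in an optimal structure, with the smallest admissible
    partner; otherwise it stays unpaired.
    """
    n = len(sequence)
    can = [
        [
            (sequence[i], sequence[j]) in CANONICAL_PAIRS and j - i - 1 >= MIN_HAIRPIN
            for j in range(n)
        ]
        for i in range(n)
    ]
    N = [[0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if can[i][k]:
                    cand = 1 + N[i + 1][k - 1] + (N[k + 1][j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            N[i][j] = best
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = N[i][j]
        if target == 0:
            continue
        paired = False
        for k in range(i + MIN_HAIRPIN + 1, j + 1):  # smallest k first: 5'-most pairing
            if can[i][k]:
                cand = 1 + N[i + 1][k - 1] + (N[k + 1][j] if k + 1 <= j else 0)
                if cand == target:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return frozenset(pairs)


def _rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def _fold_external(sequence: str) -> SecondaryStructure:
    if not _rnafold_available():
        raise RuntimeError(
            "no external MFE folder found on PATH (RNAfold); "
            "use backend='builtin_maxpair' as a reproducible fallback"
        )
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=sequence + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    db = lines[1].split()[0]
    return parse_dot_bracket(sequence, db, provenance="external_mfe:RNAfold@37C")


def fold(sequence: str, backend: str = "builtin_maxpair") -> SecondaryStructure:
    """Predict a secondary structure.

    ``builtin_maxpair``
        maximum canonical pairing (Nussinov-style dynamic programme),
        minimum hairpin 3, deterministic 5'-most traceback; reproducible
        anywhere.
    ``external_mfe``
        minimum-free-energy prediction delegated to an installed RNAfold
        (default parameters, 37 degrees C), recorded in provenance.
    """
    sequence = canonicalize_sequence(sequence)
    if not sequence:
        raise ValueError("empty sequence")
    bad = [i for i, b in enumerate(sequence) if b not in "ACGU"]
    if bad:
        raise ValueError(f"non-ACGU symbol at position {bad[0] + 1}")
    if backend == "builtin_maxpair":
        return SecondaryStructure(sequence, _nussinov_maxpair(sequence), "builtin_maxpair")
    if backend == "external_mfe":
        return _fold_external(sequence)
    raise ValueError(f"unknown folding backend {backend!r}")
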