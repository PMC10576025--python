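"""Alphabet handling, one-hot encoding and dot-bracket utilities.

Sequences are RNA internally (``A C G U``); DNA input is normalised with
``T -> U``.  Secondary structure uses Vienna dot-bracket notation where
matched ``(`` / ``)`` denote paired bases and ``.`` unpaired ones.
"""

from __future__ import annotations

import numpy as np

RNA_ALPHABET = "ACGU"
STRUCT_ALPHABET = "(.)"

#: Watson-Crick plus wobble pairs legal in an RNA helix.
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_SEQ_INDEX = {c: i for i, c in enumerate(RNA_ALPHABET)}
_STRUCT_INDEX = {c: i for i, c in enumerate(STRUCT_ALPHABET)}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA thymine to uracil."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def reverse_complement_dna(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq.upper()))


def one_hot_sequence(seq: str) -> np.ndarray:
    """(d, 4) one-hot over A, C, G, U."""
    seq = normalize_rna(seq)
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, c in enumerate(seq):
        out[i, _SEQ_INDEX[c]] = 1.0
    return out


def one_hot_structure(struct: str) -> np.ndarray:
    """(d, 3) one-hot over '(', '.', ')'."""
    out = np.zeros((len(struct), 3), dtype=np.float64)
    for i, c in enumerate(struct):
        if c not in _STRUCT_INDEX:
            raise ValueError(f"invalid structure symbol {c!r} at position {i}")
        out[i, _STRUCT_INDEX[c]] = 1.0
    return out


def decode_sequence(x_seq: np.ndarray) -> str:
    return "".join(RNA_ALPHABET[i] for i in np.argmax(x_seq, axis=1))


def pair_table(struct: str) -> dict[int, int]:
    """Map position -> partner for every base pair in a dot-bracket string.

    Raises ``ValueError`` on unbalanced brackets.  Both orientations are
    present: if (i, j) pair then table[i] == j and table[j] == i.
    """
    stack: list[int] = []
    table: dict[int, int] = {}
    for i, c in enumerate(struct):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[j] = i
            table[i] = j
        elif c != ".":
            raise ValueError(f"invalid structure symbol {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return table


def wobble_vector(sequence: str, structure: str) -> np.ndarray:
    """Binary indicator of positions participating in a G-U wobble pair.

    Positions i and j of a predicted pair are flagged 1 iff the paired
    bases are {G, U}; Watson-Crick pairs and unpaired positions are 0.
    """
    sequence = normalize_rna(sequence)
    if len(sequence) != len(structure):
        raise ValueError("sequence and structure length mismatch")
    table = pair_table(structure)
    out = np.zeros(len(sequence), dtype=np.float64)
    for i, j in table.items():
        if {sequence[i], sequence[j]} == {"G", "U"}:
            out[i] = 1.0
    return out


def helices(struct: str) -> list[list[tuple[int, int]]]:
    """Decompose a structure into maximal stacked helices.

    A helix is a maximal run of nested pairs (i, j), (i+1, j-1), ...
    Returned in 5' order; each helix is a list of (i, j) pairs.
    """
    table = pair_table(struct)
    opens = sorted(i for i, j in table.items() if i < j)
    seen: set[int] = set()
    out: list[list[tuple[int, int]]] = []
    for i in opens:
        if i in seen:
            continue
        j = table[i]
        helix = [(i, j)]
        seen.add(i)
        while (i + len(helix)) in table and table[i + len(helix)] == j - len(helix):
            nxt = i + len(helix)
            helix.append((nxt, j - len(helix)))
            seen.add(nxt)
        out.append(helix)
    return out
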