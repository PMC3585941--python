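"""RNA secondary-structure prediction by energy minimization.

The bundled engine is a Nussinov-style dynamic program over a simple
additive base-pair energy model (GC -3.0, AU -2.0, GU -1.0 kcal/mol,
minimum hairpin loop of 3 nt, no pseudoknots).  It is deliberately small
and fully specified so that every minimum-free-energy value used by the
hairpin predictor is reproducible to the digit; a nearest-neighbor engine
can be substituted through the ``fold_fn`` hooks taken by the predictor.
"""

from __future__ import annotations

import numpy as np

RNA_ALPHABET = frozenset("ACGU")
MIN_LOOP = 3

# integer deci-kcal scores so the DP is exact
_PAIR_SCORE = {
    ("G", "C"): 30, ("C", "G"): 30,
    ("A", "U"): 20, ("U", "A"): 20,
    ("G", "U"): 10, ("U", "G"): 10,
}


def pair_energy(a: str, b: str) -> float:
    """Stacking-free energy contribution of a single base pair (kcal/mol)."""
    return -_PAIR_SCORE.get((a, b), 0) / 10.0


def _score_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    e = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            e[i, j] = _PAIR_SCORE.get((seq[i], seq[j]), 0)
    return e


def fold(seq: str):
    """Fold an RNA sequence, returning ``(dot_bracket, mfe_kcal_mol)``.

    The DP maximizes total pair score with a 3-nt minimum loop; ties are
    broken deterministically (pairing i..j preferred, then the smallest
    bifurcation point).  Raises ``ValueError`` on non-ACGU characters.
    """
    seq = seq.upper().replace("T", "U")
    if not set(seq) <= RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise ValueError(f"non-RNA characters in sequence: {bad}")
    n = len(seq)
    if n == 0:
        return "", 0.0
    e = _score_matrix(seq)
    m = np.zeros((n, n), dtype=np.int64)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j] if span >= 1 else 0
            if e[i, j] and span > MIN_LOOP:
                v = m[i + 1, j - 1] + e[i, j]
                if v > best:
                    best = v
            # bifurcation covers "i unpaired" (k=i) and "j unpaired" (k=j-1)
            ks = m[i, i:j] + m[i + 1:j + 1, j]
            v = int(ks.max())
            if v > best:
                best = v
            m[i, j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = m[i, j]
        if target == 0:
            continue
        if e[i, j] and j - i > MIN_LOOP and m[i + 1, j - 1] + e[i, j] == target:
            structure[i] = "("
            structure[j] = ")"
            stack.append((i + 1, j - 1))
            continue
        ks = m[i, i:j] + m[i + 1:j + 1, j]
        k = i + int(np.argmax(ks == target))
        stack.append((i, k))
        stack.append((k + 1, j))
    return "".join(structure), -float(m[0, n - 1]) / 10.0 + 0.0


def structure_energy(seq: str, structure: str) -> float:
    """Energy of an explicit dot-bracket structure under the bundled model."""
    seq = seq.upper().replace("T", "U")
    total = 0.0
    for i, j in pair_table(structure).items():
        if i < j:
            total += pair_energy(seq[i], seq[j])
    return total


def pair_table(structure: str) -> dict:
    """Map each paired position to its partner (both directions, 0-based)."""
    stack = []
    table = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            table[i] = j
            table[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return table
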