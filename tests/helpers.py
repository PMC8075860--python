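"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

import random


def local_affine_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -15.0,
    gap_open: float = -36.0,
    gap_extend: float = -0.5,
) -> float:
    """Plain-Python maximal-segment affine-gap alignment score.

    Free end gaps on both sequences; a gap of length k costs
    gap_open + (k - 1) * gap_extend.  Deliberately simple and slow.
    """
    m, n = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng: random.Random, seq: str, n_subs: int) -> str:
    """Apply n_subs distinct substitutions to seq."""
    arr = list(seq)
    for pos in rng.sample(range(len(arr)), n_subs):
        arr[pos] = rng.choice([c for c in "ACGT" if c != arr[pos]])
    return "".join(arr)
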