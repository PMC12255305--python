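"""Independent brute-force oracles used to validate the package.

These are deliberately naive re-derivations from first principles —
full dynamic programming without seeding heuristics, quadratic scans,
atom-by-atom molecule building from textbook ribonucleotide structures —
kept separate from the implementation paths they check.
"""

from __future__ import annotations

from collections import Counter


def smith_waterman_oracle(a, b, score, gap_open, gap_extend):
    """Full affine-gap local alignment by exhaustive Gotoh DP.

    ``score(x, y)`` gives the substitution score.  A gap of length L
    costs gap_open + L * gap_extend, so opening a gap costs
    gap_open + gap_extend and each extension gap_extend.
    Returns the optimal raw score.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to gap)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + score(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return int(best)


def digest_oracle(bases, ribose_methyl_flags, cleave_after):
    """Naive quadratic fragment enumeration.

    Scans every bond, collects cleaved positions, and splits.  Returns
    the list of (start, end) 1-based inclusive coordinate pairs.
    """
    n = len(bases)
    cut_after = []
    for i in range(1, n):  # bond between residue i and i+1
        if bases[i - 1] in cleave_after and not ribose_methyl_flags[i - 1]:
            cut_after.append(i)
    frags = []
    start = 1
    for c in cut_after:
        frags.append((start, c))
        start = c + 1
    frags.append((start, n))
    return frags


# textbook structures: free bases, D-ribose, phosphate group
_BASE_ATOMS = {
    "A": Counter({"C": 5, "H": 5, "N": 5}),          # adenine
    "C": Counter({"C": 4, "H": 5, "N": 3, "O": 1}),  # cytosine
    "G": Counter({"C": 5, "H": 5, "N": 5, "O": 1}),  # guanine
    "U": Counter({"C": 4, "H": 4, "N": 2, "O": 2}),  # uracil
}
_RIBOSE = Counter({"C": 5, "H": 10, "O": 5})
_WATER = Counter({"H": 2, "O": 1})
_HPO3 = Counter({"H": 1, "O": 3, "P": 1})
_CH2 = Counter({"C": 1, "H": 2})


def _sub(total: Counter, minus: Counter, times: int = 1) -> None:
    for el, k in minus.items():
        total[el] -= k * times


def formula_oracle(bases, methyl_counts, five_prime, three_prime):
    """Build an oligonucleotide formula atom-by-atom.

    Each nucleoside is base + ribose - H2O (glycosidic bond); each of
    the n-1 phosphodiester bridges adds HPO3 and removes H2O; terminal
    phosphates add HPO3 (cyclic also removes one H2O, a triphosphate
    adds three HPO3); each methyl modification adds CH2.  Returns a
    plain element -> count dict.
    """
    total: Counter = Counter()
    for b in bases:
        total += _BASE_ATOMS[b] + _RIBOSE
        _sub(total, _WATER)
    bridges = len(bases) - 1
    for _ in range(bridges):
        total += _HPO3
        _sub(total, _WATER)
    if three_prime == "linear_phosphate":
        total += _HPO3
    elif three_prime == "cyclic_phosphate":
        total += _HPO3
        _sub(total, _WATER)
    if five_prime == "monophosphate":
        total += _HPO3
    elif five_prime == "triphosphate":
        total += _HPO3 + _HPO3 + _HPO3
    for _ in range(methyl_counts):
        total += _CH2
    return {el: k for el, k in total.items() if k}
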