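"""Hairpin secondary-structure prediction by maximum base pairing.

The curation criteria only ask *how many* mature-miRNA bases are paired in
the precursor hairpin and where the pairing partners lie, so the folder
maximizes the number of Watson-Crick + G:U wobble pairs over all nested
(pseudoknot-free) structures with a minimum hairpin loop of three unpaired
bases — a Nussinov-style dynamic program with a deterministic traceback.
A thermodynamic folding engine can be plugged in behind the same interface:
anything returning a :class:`HairpinFold` satisfies the downstream contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: minimum number of unpaired bases enclosed by any pair
MIN_LOOP = 3

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble (U treated as T)."""
    a = "T" if a == "U" else a
    b = "T" if b == "U" else b
    return (a, b) in _PAIRS


@dataclass
class HairpinFold:
    """A nested secondary structure of one sequence.

    ``partner[i]`` is the 0-based pairing partner of position ``i`` or -1.
    """

    dotbracket: str
    n_pairs: int
    partner: list[int]

    def __post_init__(self) -> None:
        # symmetry and bracket balance are structural invariants
        for i, j in enumerate(self.partner):
            if j >= 0 and self.partner[j] != i:
                raise ValueError("pairing map not symmetric")
        if self.dotbracket.count("(") != self.dotbracket.count(")"):
            raise ValueError("unbalanced dot-bracket string")

    def paired_in_range(self, start: int, end: int) -> int:
        """Number of paired positions within [start, end)."""
        return sum(1 for i in range(start, end) if self.partner[i] >= 0)


def _pair_matrix(seq: str) -> np.ndarray:
    s = np.frombuffer(seq.replace("U", "T").encode(), dtype=np.uint8)
    a = s[:, None]
    b = s[None, :]
    at = (a == ord("A")) & (b == ord("T"))
    ta = (a == ord("T")) & (b == ord("A"))
    gc = (a == ord("G")) & (b == ord("C"))
    cg = (a == ord("C")) & (b == ord("G"))
    gt = (a == ord("G")) & (b == ord("T"))
    tg = (a == ord("T")) & (b == ord("G"))
    return at | ta | gc | cg | gt | tg


def fold_hairpin(sequence: str) -> HairpinFold:
    """Maximum-pairing nested structure of ``sequence``.

    Deterministic traceback: the 5'-most base is paired whenever a pairing
    achieves the optimum, and among optimal partners the most distal (3')
    one is taken, which reconstructs clean outer stems for hairpins.

    Raises ``ValueError`` for sequences shorter than 10 nt (no meaningful
    hairpin is possible at that length).
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} < 10 nt)")
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-nucleotide characters")

    pm = _pair_matrix(seq)
    # dp padded by one row/col so dp[k+1, j] is always valid (zeros below diag)
    dp = np.zeros((n + 1, n + 1), dtype=np.int16)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            ks = np.nonzero(pm[i, i + MIN_LOOP + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + MIN_LOOP + 1
                vals = dp[i + 1, ks - 1] + 1 + dp[ks + 1, j]
                m = int(vals.max())
                if m > best:
                    best = m
            dp[i, j] = best

    partner = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = dp[i, j]
            if target == 0:
                break
            paired = False
            for k in range(j, i + MIN_LOOP, -1):
                if pm[i, k] and dp[i + 1, k - 1] + 1 + dp[k + 1, j] == target:
                    partner[i] = k
                    partner[k] = i
                    if k + 1 < j:
                        stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    paired = True
                    break
            if not paired:
                i += 1

    db = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(partner)
    )
    return HairpinFold(dotbracket=db, n_pairs=sum(p >= 0 for p in partner) // 2, partner=partner)
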