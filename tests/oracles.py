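"""Independent reference implementations used only to check the package.

These deliberately avoid the implementation's vectorized code paths:
the scanner oracle slides a window character by character and tests the
reverse complement of each window for minus-strand matches; the
hypergeometric oracle enumerates every draw explicitly.
"""

from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _block_mismatches(block: str, consensus: str) -> int:
    return sum(1 for x, y in zip(block, consensus) if x != y)


def brute_force_scan(sequence: str, upstream: str = "TTAAG",
                     downstream: str = "TTAAG", spacers=(6,),
                     max_mismatches: int = 0, circular: bool = False,
                     strands: str = "both"):
    """Every (start, strand, spacer, mm_up, mm_down, window) within budget.

    Minus-strand matches are found by testing the reverse complement of
    each plus-strand window, so coordinates are plus-strand native.
    """
    L = len(sequence)
    out = set()
    for spacer in spacers:
        w = 10 + spacer
        starts = range(L) if circular else range(max(L - w + 1, 0))
        for p in starts:
            if circular and p + w > L:
                window = sequence[p:] + sequence[: p + w - L]
            else:
                window = sequence[p: p + w]
            for strand in ("+", "-"):
                if strands not in (strand, "both"):
                    continue
                view = window if strand == "+" else revcomp(window)
                mm_up = _block_mismatches(view[:5], upstream)
                mm_down = _block_mismatches(view[5 + spacer:], downstream)
                if mm_up + mm_down <= max_mismatches:
                    out.add((p, strand, spacer, mm_up, mm_down, view))
    return out


def hits_as_tuples(hits):
    return {(h.start, h.strand, h.spacer_length, h.mismatch_up,
             h.mismatch_down, h.operator_sequence()) for h in hits}


def hypergeom_upper_tail_by_enumeration(N: int, na: int, nb: int, k: int) -> float:
    """P[|A & B| >= k] over all equally likely size-nb draws B, A fixed."""
    a = set(range(na))
    total = hits = 0
    for b in combinations(range(N), nb):
        total += 1
        if len(a & set(b)) >= k:
            hits += 1
    return hits / total
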