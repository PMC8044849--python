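"""Brute-force reference for PQS scanning, independent of the package.

Every substring of admissible length is tested against an anchored
regex for the default G3-5 L1-5 pattern; scan-mode semantics (shortest
per start, no-overlap walk, containment filter) are re-derived from
that exhaustive set rather than from the implementation's algorithms.
"""

import re

FULL = re.compile("G{3,5}[ACGT]{1,5}G{3,5}[ACGT]{1,5}G{3,5}[ACGT]{1,5}G{3,5}")
MIN_LEN = 4 * 3 + 3 * 1  # 15
MAX_LEN = 4 * 5 + 3 * 5  # 35

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def all_matching_substrings(seq: str) -> list[tuple[int, int]]:
    out = []
    for i in range(len(seq) - MIN_LEN + 1):
        if not seq.startswith("GGG", i):  # every match begins with >=3 G
            continue
        for j in range(i + MIN_LEN, min(i + MAX_LEN, len(seq)) + 1):
            if FULL.fullmatch(seq[i:j]):
                out.append((i, j))
    return out


def shortest_per_start(seq: str) -> list[tuple[int, int]]:
    best: dict[int, int] = {}
    for i, j in all_matching_substrings(seq):
        if i not in best or j < best[i]:
            best[i] = j
    return sorted(best.items())


def oracle_nonoverlapping_strand(seq: str) -> list[tuple[int, int]]:
    """Leftmost-shortest walk: emit the shortest match at the smallest
    admissible start, resume after its end."""
    shortest = shortest_per_start(seq)
    out = []
    pos = 0
    for i, j in shortest:
        if i >= pos:
            out.append((i, j))
            pos = j
    return out


def oracle_minimal_strand(seq: str) -> list[tuple[int, int]]:
    """Shortest per start, minus intervals properly containing another."""
    cand = shortest_per_start(seq)
    kept = []
    for a in cand:
        contains_other = any(
            b != a and a[0] <= b[0] and b[1] <= a[1] for b in cand
        )
        if not contains_other:
            kept.append(a)
    return kept


def _map_both_strands(seq: str, strand_fn) -> set[tuple[int, int, str]]:
    n = len(seq)
    out = {(i, j, "+") for i, j in strand_fn(seq)}
    out |= {(n - j, n - i, "-") for i, j in strand_fn(rc(seq))}
    return out


def oracle_nonoverlapping(seq: str) -> set[tuple[int, int, str]]:
    return _map_both_strands(seq, oracle_nonoverlapping_strand)


def oracle_minimal(seq: str) -> set[tuple[int, int, str]]:
    return _map_both_strands(seq, oracle_minimal_strand)
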