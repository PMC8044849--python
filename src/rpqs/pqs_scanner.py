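"""Regex-based detection of potential G-quadruplex sequences (PQS).

A PQS under the default pattern is four G-runs of 3-5 nt separated by
loops of 1-5 nt (G3-5 L1-5, Quadparser-style).  Two scan modes are
provided:

``scan_nonoverlapping``
    Leftmost-shortest (lazy) matching; scanning resumes after each
    match.  This is the mode used for genome-wide PQS density.

``scan_minimal_overlapping``
    The shortest match is generated at *every* admissible start
    position, then any match whose interval properly contains another
    match on the same strand is discarded.  The surviving "minimal
    PQSs" are the unit of interspersed-repeat discovery.

Both modes scan the forward strand and, independently, the reverse
complement; minus-strand hits are mapped back to forward coordinates.
Loops may contain any of {A,C,G,T} (including G, so long G-runs can
self-match -- see :func:`classify_pqs` for the artifact classes this
implies); windows containing N never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

__all__ = [
    "PqsPattern",
    "PqsMatch",
    "DensityResult",
    "reverse_complement",
    "scan_nonoverlapping",
    "scan_minimal_overlapping",
    "pqs_density",
    "classify_pqs",
    "classify_sequence",
    "CANONICAL",
    "HOMOPOLYMER",
    "TWO_RUN_LONG_G",
    "TANDEM_SIMPLE_REPEAT",
    "PQS_CLASSES",
]

# artifact classes (precedence: homopolymer > two_run_long_g > tandem)
CANONICAL = "canonical"
HOMOPOLYMER = "homopolymer"
TWO_RUN_LONG_G = "two_run_long_g"
TANDEM_SIMPLE_REPEAT = "tandem_simple_repeat"
PQS_CLASSES = (CANONICAL, HOMOPOLYMER, TWO_RUN_LONG_G, TANDEM_SIMPLE_REPEAT)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

# tandem-repeat operationalization: smallest exact period <= _TANDEM_MAX_PERIOD
# matching at >= _TANDEM_MIN_COVER of comparable positions
_TANDEM_MAX_PERIOD = 6
_TANDEM_MIN_COVER = 0.9
_LONG_RUN_MIN = 8  # GnNiGn exclusion requires n > 7


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"invalid symbols for reverse complement: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PqsPattern:
    """G-quadruplex search pattern: ``n_runs`` G-runs of ``run_min..run_max``
    guanines separated by loops of ``loop_min..loop_max`` arbitrary bases."""

    n_runs: int = 4
    run_min: int = 3
    run_max: int = 5
    loop_min: int = 1
    loop_max: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.run_min <= self.run_max):
            raise ValueError("require 1 <= run_min <= run_max")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("require 1 <= loop_min <= loop_max")
        if self.n_runs < 2:
            raise ValueError("require n_runs >= 2")

    @property
    def min_match_len(self) -> int:
        return self.n_runs * self.run_min + (self.n_runs - 1) * self.loop_min

    @property
    def max_match_len(self) -> int:
        return self.n_runs * self.run_max + (self.n_runs - 1) * self.loop_max

    def _unit(self, lazy: bool) -> tuple[str, str]:
        q = "?" if lazy else ""
        run = f"G{{{self.run_min},{self.run_max}}}{q}"
        loop = f"[ACGT]{{{self.loop_min},{self.loop_max}}}{q}"
        return run, loop

    @cached_property
    def _re_lazy(self) -> re.Pattern:
        """Lazy pattern; its leftmost search hit marks the smallest start
        position admitting a match."""
        run, loop = self._unit(lazy=True)
        return re.compile((run + loop) * (self.n_runs - 1) + run)

    @cached_property
    def _re_full(self) -> re.Pattern:
        """Greedy pattern used only for fullmatch language-membership tests."""
        run, loop = self._unit(lazy=False)
        return re.compile((run + loop) * (self.n_runs - 1) + run)

    @cached_property
    def _re_starts(self) -> re.Pattern:
        """Zero-width lookahead enumerating every admissible start position."""
        return re.compile(f"(?={self._re_lazy.pattern})")

    @cached_property
    def _re_groups(self) -> re.Pattern:
        run, loop = self._unit(lazy=False)
        parts = []
        for i in range(self.n_runs - 1):
            parts.append(f"({run})({loop})")
        parts.append(f"({run})")
        return re.compile("".join(parts))

    @cached_property
    def _prefix(self) -> str:
        return "G" * self.run_min

    def shortest_end_at(self, seq: str, start: int) -> Optional[int]:
        """End of the shortest pattern match starting at ``start``, or None."""
        if not seq.startswith(self._prefix, start):
            return None
        full = self._re_full
        hi = min(self.max_match_len, len(seq) - start)
        for length in range(self.min_match_len, hi + 1):
            if full.fullmatch(seq, start, start + length):
                return start + length
        return None

    def fullmatches(self, seq: str) -> bool:
        """True if the whole string is a single pattern match."""
        return self._re_full.fullmatch(seq) is not None

    def decompose(self, seq: str) -> tuple[tuple[tuple[int, int], ...], tuple[str, ...]]:
        """Split a matching sequence into ((run_offset, run_len), ...) and
        loop subsequences (one valid decomposition; greedy runs)."""
        m = self._re_groups.fullmatch(seq)
        if m is None:
            raise ValueError("sequence does not match the PQS pattern")
        runs, loops = [], []
        for g in range(1, 2 * self.n_runs):
            s, e = m.span(g)
            if g % 2 == 1:  # odd groups are G-runs
                runs.append((s, e - s))
            else:
                loops.append(seq[s:e])
        return tuple(runs), tuple(loops)


@dataclass
class PqsMatch:
    """One pattern hit in forward-strand coordinates (0-based half-open).

    ``sequence`` is the matched DNA read 5'->3' on its own strand; for a
    minus-strand hit this is the reverse complement of the forward slice.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str = ""
    runs: tuple = field(default_factory=tuple)
    loops: tuple = field(default_factory=tuple)
    pqs_class: str = CANONICAL

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def interval(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.strand)


@dataclass
class DensityResult:
    """Both-strand PQS hit count normalized per Mb of single-strand length."""

    seq_id: str
    n_hits: int
    genome_length: int
    density: float  # hits per Mb
    gc: float  # fraction, N ignored


# ---------------------------------------------------------------------------
# scanning


def _scan_strand_lazy(seq: str, pattern: PqsPattern) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    search = pattern._re_lazy.search
    i = 0
    while True:
        m = search(seq, i)
        if m is None:
            break
        start = m.start()
        end = pattern.shortest_end_at(seq, start)
        assert end is not None  # the search hit is a witness
        out.append((start, end))
        i = end
    return out


def _scan_strand_minimal(seq: str, pattern: PqsPattern) -> list[tuple[int, int]]:
    shortest = [
        (m.start(), pattern.shortest_end_at(seq, m.start()))
        for m in pattern._re_starts.finditer(seq)
    ]
    # drop any interval properly containing a later-start interval;
    # starts are distinct and each carries its shortest end, so [s1,e1)
    # properly contains [s2,e2) iff s1 < s2 and e2 <= e1
    kept: list[tuple[int, int]] = []
    min_end_after = float("inf")
    for start, end in reversed(shortest):
        if not (min_end_after <= end):
            kept.append((start, end))
        min_end_after = min(min_end_after, end)
    kept.reverse()
    return kept


def _extended_own_strand_seq(seq: str, start: int, end: int, strand: str) -> str:
    """Match sequence with its terminal G-runs extended to their maximal
    genomic extent (on the match's own strand)."""
    n = len(seq)
    base = "G" if strand == "+" else "C"
    while start > 0 and seq[start - 1] == base:
        start -= 1
    while end < n and seq[end] == base:
        end += 1
    s = seq[start:end]
    return s if strand == "+" else reverse_complement(s)


def _build_matches(
    genome, pattern: PqsPattern, intervals: list[tuple[int, int]], strand: str
) -> list[PqsMatch]:
    fwd = genome.sequence
    n = len(fwd)
    out = []
    for s, e in intervals:
        if strand == "+":
            fs, fe = s, e
            sub = fwd[fs:fe]
        else:
            fs, fe = n - e, n - s
            sub = reverse_complement(fwd[fs:fe])
        runs, loops = pattern.decompose(sub)
        cls = classify_sequence(_extended_own_strand_seq(fwd, fs, fe, strand))
        out.append(
            PqsMatch(
                seq_id=genome.seq_id,
                start=fs,
                end=fe,
                strand=strand,
                sequence=sub,
                runs=runs,
                loops=loops,
                pqs_class=cls,
            )
        )
    return out


def scan_nonoverlapping(genome, pattern: PqsPattern = PqsPattern()) -> list[PqsMatch]:
    """Lazy non-overlapping scan of both strands.

    At the smallest start position admitting a match the shortest match
    starting there is emitted and scanning resumes after its end.  The
    reverse complement is scanned independently and mapped back to
    forward coordinates with strand '-'.
    """
    fwd = genome.sequence
    matches = _build_matches(genome, pattern, _scan_strand_lazy(fwd, pattern), "+")
    rc = reverse_complement(fwd)
    matches += _build_matches(genome, pattern, _scan_strand_lazy(rc, pattern), "-")
    matches.sort(key=lambda m: (m.start, m.strand, m.end))
    return matches


def scan_minimal_overlapping(genome, pattern: PqsPattern = PqsPattern()) -> list[PqsMatch]:
    """Overlapping scan keeping only minimal PQSs.

    The shortest match is generated at every admissible start; matches
    properly containing another same-strand match are removed.
    """
    fwd = genome.sequence
    matches = _build_matches(genome, pattern, _scan_strand_minimal(fwd, pattern), "+")
    rc = reverse_complement(fwd)
    matches += _build_matches(genome, pattern, _scan_strand_minimal(rc, pattern), "-")
    matches.sort(key=lambda m: (m.start, m.strand, m.end))
    return matches


def pqs_density(genome, pattern: PqsPattern = PqsPattern()) -> DensityResult:
    """Non-overlapping hit count over both strands per Mb of genome.

    The denominator is the single-strand genome length; GC is computed
    ignoring N.
    """
    if len(genome.sequence) == 0:
        raise ValueError("empty genome")
    seq = genome.sequence
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError(f"{genome.seq_id}: GC undefined (sequence is all N)")
    gc = (seq.count("G") + seq.count("C")) / acgt
    n_hits = len(scan_nonoverlapping(genome, pattern))
    return DensityResult(
        seq_id=genome.seq_id,
        n_hits=n_hits,
        genome_length=len(seq),
        density=n_hits / len(seq) * 1e6,
        gc=gc,
    )


# ---------------------------------------------------------------------------
# artifact classification


def _maximal_g_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end() - m.start()) for m in re.finditer("G+", seq)]


def classify_sequence(seq: str) -> str:
    """Artifact class of a (possibly run-extended) PQS sequence.

    homopolymer
        entirely G.
    two_run_long_g
        exactly two maximal G-runs, each of more than 7 guanines,
        separated by 1-2 non-G nt (the interspersed GnNiGn repeat
        family, n > 7, i = 1 or 2).
    tandem_simple_repeat
        smallest exact period <= 6 nt matching at >= 90% of comparable
        positions (e.g. (GGGCT)n, (GGGAA)n).
    canonical
        everything else.
    """
    if set(seq) == {"G"}:
        return HOMOPOLYMER
    runs = _maximal_g_runs(seq)
    if len(runs) == 2:
        (s1, l1), (s2, l2) = runs
        sep = s2 - (s1 + l1)
        spans_all = s1 == 0 and s2 + l2 == len(seq)
        if spans_all and l1 >= _LONG_RUN_MIN and l2 >= _LONG_RUN_MIN and 1 <= sep <= 2:
            return TWO_RUN_LONG_G
    n = len(seq)
    for p in range(1, _TANDEM_MAX_PERIOD + 1):
        if n <= p:
            break
        hits = sum(1 for i in range(p, n) if seq[i] == seq[i - p])
        if hits / (n - p) >= _TANDEM_MIN_COVER:
            return TANDEM_SIMPLE_REPEAT
    return CANONICAL


def classify_pqs(match: PqsMatch, genome=None) -> str:
    """Artifact class of a match.

    With ``genome`` given, the terminal G-runs of the match are first
    extended to their maximal genomic extent, so that e.g. the minimal
    match inside a G8-TA-G8 repeat (whose own terminal runs are trimmed
    to 7 G) is still recognized as the two-run long-G class.
    """
    if genome is not None:
        seq = _extended_own_strand_seq(genome.sequence, match.start, match.end, match.strand)
    else:
        seq = match.sequence
    return classify_sequence(seq)
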