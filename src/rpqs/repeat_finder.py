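"""Interspersed-repeat discovery over minimal PQSs.

A repetitive PQS (rPQS) is an exact minimal-PQS sequence occurring at
least ``min_copies`` times in a genome, counting both the direct
sequence and its reverse complement.  Occurrences are raw (possibly
overlapping) substring hits, not restricted to minimal-match loci.
Artifact classes (homoguanine runs, GnNiGn two-run repeats, simple
tandem repeats) are filtered out of the main table but kept in a side
inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import AnnotatedGenome, GenomeRecord
from .pqs_scanner import (
    CANONICAL,
    HOMOPOLYMER,
    TANDEM_SIMPLE_REPEAT,
    TWO_RUN_LONG_G,
    PqsMatch,
    PqsPattern,
    reverse_complement,
    scan_minimal_overlapping,
)

__all__ = [
    "RepeatedPqs",
    "DEFAULT_EXCLUDED_CLASSES",
    "canonical_form",
    "count_occurrences",
    "repeat_groups",
    "find_repeated_pqs",
    "cross_genome_repeats",
    "repeats_frame",
]

DEFAULT_EXCLUDED_CLASSES = frozenset(
    {HOMOPOLYMER, TWO_RUN_LONG_G, TANDEM_SIMPLE_REPEAT}
)


def canonical_form(seq: str) -> str:
    """Strand-independent representative: lexicographic minimum of the
    sequence and its reverse complement (idempotent)."""
    return min(seq, reverse_complement(seq))


def _as_genome(genome) -> GenomeRecord:
    return genome.genome if isinstance(genome, AnnotatedGenome) else genome


def _occurrence_positions(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)  # overlapping hits all count
    return out


def count_occurrences(genome, query: str) -> tuple[int, int]:
    """(forward, reverse) counts of exact, possibly overlapping hits of
    ``query`` and its reverse complement on the forward strand string."""
    if not query:
        raise ValueError("empty query")
    if "N" in query:
        raise ValueError("query must not contain N")
    seq = _as_genome(genome).sequence
    fwd = len(_occurrence_positions(seq, query))
    rev = len(_occurrence_positions(seq, reverse_complement(query)))
    return fwd, rev


@dataclass
class RepeatedPqs:
    """One rPQS family: a canonical sequence with all its genomic copies."""

    canonical_sequence: str
    copies: list[PqsMatch] = field(default_factory=list)
    count_forward: int = 0  # occurrences of canonical_sequence
    count_reverse: int = 0  # occurrences of its reverse complement
    pqs_class: str = CANONICAL

    @property
    def total_count(self) -> int:
        return self.count_forward + self.count_reverse

    @property
    def g_rich_sequence(self) -> str:
        """The strand reading that is an actual PQS match (starts with G)."""
        rc = reverse_complement(self.canonical_sequence)
        return self.canonical_sequence if self.canonical_sequence[0] == "G" else rc


def repeat_groups(
    genome,
    pattern: PqsPattern = PqsPattern(),
    min_copies: int = 4,
) -> list[RepeatedPqs]:
    """All minimal-PQS families with >= min_copies total occurrences,
    including artifact classes (no exclusion applied)."""
    gen = _as_genome(genome)
    seq = gen.sequence
    groups: dict[str, dict] = {}
    for m in scan_minimal_overlapping(gen, pattern):
        canon = canonical_form(m.sequence)
        g = groups.setdefault(canon, {"rep": m.sequence, "class": m.pqs_class})
        # class from the first minimal match that founded the group
    out: list[RepeatedPqs] = []
    for canon, info in groups.items():
        rep = info["rep"]  # G-rich reading as matched
        rep_rc = reverse_complement(rep)
        plus = _occurrence_positions(seq, rep)
        minus = _occurrence_positions(seq, rep_rc) if rep_rc != rep else []
        total = len(plus) + len(minus)
        if total < min_copies:
            continue
        runs, loops = pattern.decompose(rep)
        copies = [
            PqsMatch(
                seq_id=gen.seq_id,
                start=p,
                end=p + len(rep),
                strand=strand,
                sequence=rep,
                runs=runs,
                loops=loops,
                pqs_class=info["class"],
            )
            for positions, strand in ((plus, "+"), (minus, "-"))
            for p in positions
        ]
        copies.sort(key=lambda m: (m.start, m.strand))
        cf = len(plus) if canon == rep else len(minus)
        out.append(
            RepeatedPqs(
                canonical_sequence=canon,
                copies=copies,
                count_forward=cf,
                count_reverse=total - cf,
                pqs_class=info["class"],
            )
        )
    out.sort(key=lambda r: (-r.total_count, r.canonical_sequence))
    return out


def find_repeated_pqs(
    genome,
    pattern: PqsPattern = PqsPattern(),
    min_copies: int = 4,
    exclude_classes: frozenset = DEFAULT_EXCLUDED_CLASSES,
) -> list[RepeatedPqs]:
    """rPQS families after dropping artifact classes.

    The dropped groups remain available via :func:`repeat_groups` for
    the excluded-class side table.
    """
    return [
        g
        for g in repeat_groups(genome, pattern, min_copies)
        if g.pqs_class not in exclude_classes
    ]


def cross_genome_repeats(
    genomes: list,
    pattern: PqsPattern = PqsPattern(),
    min_copies: int = 4,
    exclude_classes: frozenset = DEFAULT_EXCLUDED_CLASSES,
) -> pd.DataFrame:
    """rPQS copy-number matrix across genomes.

    Rows are the union of per-genome rPQS canonical sequences; each cell
    is the total (both-strand) occurrence count in that genome, filled
    even where the sequence is not itself an rPQS.  Rows are ordered by
    descending maximum count, then lexicographically.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    recs = [_as_genome(g) for g in genomes]
    ids = [g.seq_id for g in recs]
    families: dict[str, str] = {}
    for g in genomes:
        for fam in find_repeated_pqs(g, pattern, min_copies, exclude_classes):
            families.setdefault(fam.canonical_sequence, fam.g_rich_sequence)
    data = {}
    for canon, rep in families.items():
        data[canon] = [sum(count_occurrences(rec, rep)) for rec in recs]
    df = pd.DataFrame.from_dict(data, orient="index", columns=ids)
    if len(df):
        order = sorted(df.index, key=lambda s: (-df.loc[s].max(), s))
        df = df.loc[order]
    df.index.name = "canonical_sequence"
    return df


def repeats_frame(groups: list[RepeatedPqs]) -> pd.DataFrame:
    """Tabular view of repeat families for TSV export."""
    return pd.DataFrame(
        {
            "canonical_sequence": [g.canonical_sequence for g in groups],
            "g_rich_sequence": [g.g_rich_sequence for g in groups],
            "pqs_class": [g.pqs_class for g in groups],
            "count_forward": [g.count_forward for g in groups],
            "count_reverse": [g.count_reverse for g in groups],
            "total_count": [g.total_count for g in groups],
            "positions": [
                ";".join(f"{c.start}-{c.end}({c.strand})" for c in g.copies)
                for g in groups
            ],
        }
    )
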