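"""Genomic context of rPQS copies relative to the annotated gene model.

Each copy is placed as genic/intergenic by its midpoint, paired with
the nearest CDS on each side (strand-agnostic, as the flanking-gene
statistics are computed regardless of the G-rich strand's orientation),
classified by the flanking pair's orientation (head-to-head /
tail-to-tail / head-to-tail), measured against the facing CDS
boundaries, and probed for the C-rich track (minimal motif C3TC3) in
its 3' flank on the G-rich strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_io import AnnotatedGenome, GeneAnnotation, GenomeRecord
from .pqs_scanner import PqsMatch, reverse_complement

__all__ = [
    "INTERGENIC",
    "GENIC",
    "HEAD_TO_HEAD",
    "TAIL_TO_TAIL",
    "HEAD_TO_TAIL",
    "UNPAIRED",
    "CRichTrack",
    "CdsDistance",
    "ContextRecord",
    "classify_location",
    "classify_orientation",
    "distance_to_cds",
    "extract_flanks",
    "detect_crich_track",
    "build_context_records",
    "summarize_context",
    "oric_distance",
]

INTERGENIC = "intergenic"
GENIC = "genic"
HEAD_TO_HEAD = "head_to_head"
TAIL_TO_TAIL = "tail_to_tail"
HEAD_TO_TAIL = "head_to_tail"
UNPAIRED = "unpaired"

_CRICH_RE = re.compile("C{3,}[ACGT]C{3,}")
_CRICH_WINDOW = 12  # best-window width for the C fraction


@dataclass
class CRichTrack:
    offset: int  # nt from the PQS 3' end to the track start
    length: int
    c_fraction: float  # best 12-nt window C fraction in the search window
    matches_minimal_motif: bool  # separator is T (the C3TC3 family)


@dataclass
class CdsDistance:
    distance: int  # gap between the nearest match boundary and the facing CDS boundary
    boundary: str  # "start" (gene 5' end) or "end" (gene 3' end)
    overlaps: bool = False


@dataclass
class ContextRecord:
    match: PqsMatch
    location_class: str
    left_gene: Optional[GeneAnnotation]
    right_gene: Optional[GeneAnnotation]
    orientation_class: str
    dist_to_nearest_cds_start: Optional[int]
    dist_to_nearest_cds_end: Optional[int]
    flank5: str
    flank3: str
    crich: Optional[CRichTrack]
    ori_distance: Optional[int] = None


# ---------------------------------------------------------------------------


def classify_location(
    match: PqsMatch, genes: list[GeneAnnotation], genome: GenomeRecord
) -> tuple[str, Optional[GeneAnnotation], Optional[GeneAnnotation]]:
    """Genic if the match midpoint lies within any CDS (strand-agnostic);
    otherwise intergenic with the nearest CDS on each side.  For a
    circular genome the neighbor search wraps around the origin."""
    mid = match.midpoint
    left = right = None
    for g in genes:
        if g.start0 <= mid < g.end0:
            return GENIC, None, None
        if g.end0 <= mid and (left is None or g.end0 > left.end0):
            left = g
        if g.start0 > mid and (right is None or g.start0 < right.start0):
            right = g
    if genome.circular and genes:
        if left is None:
            left = max(genes, key=lambda g: g.end0)  # wraps past the origin
        if right is None:
            right = min(genes, key=lambda g: g.start0)
    return INTERGENIC, left, right


def classify_orientation(
    left_gene: Optional[GeneAnnotation], right_gene: Optional[GeneAnnotation]
) -> str:
    """Orientation of the flanking gene pair around an intergenic locus.

    tail_to_tail: both 3' (CDS-end) boundaries face the locus (+,-);
    head_to_head: both 5' boundaries face it (-,+); head_to_tail:
    co-oriented genes.
    """
    if left_gene is None or right_gene is None:
        return UNPAIRED
    ls, rs = left_gene.strand, right_gene.strand
    if ls == "+" and rs == "-":
        return TAIL_TO_TAIL
    if ls == "-" and rs == "+":
        return HEAD_TO_HEAD
    return HEAD_TO_TAIL


def distance_to_cds(
    match: PqsMatch,
    gene: GeneAnnotation,
    genome_length: Optional[int] = None,
    circular: bool = False,
) -> CdsDistance:
    """Gap between the nearest match boundary and the facing CDS boundary.

    The facing boundary is labelled as the gene's CDS start (5' end on
    its own strand) or CDS end (3' end).  Overlap yields distance 0 with
    the overlap flag set.
    """
    gs, ge = gene.start0, gene.end0
    if gs < match.end and match.start < ge:
        # the boundary nearer the match interior is reported
        left_gap = match.start - ge
        boundary = "end" if gene.strand == "+" else "start"
        return CdsDistance(distance=0, boundary=boundary, overlaps=True)
    if ge <= match.start:  # gene on the left; its right edge faces the match
        d = match.start - ge
        boundary = "end" if gene.strand == "+" else "start"
        if circular and genome_length:
            d_wrap = (gs - match.end) % genome_length
            if d_wrap < d:
                d = d_wrap
                boundary = "start" if gene.strand == "+" else "end"
    else:  # gene on the right; its left edge faces the match
        d = gs - match.end
        boundary = "start" if gene.strand == "+" else "end"
        if circular and genome_length:
            d_wrap = (match.start - ge) % genome_length
            if d_wrap < d:
                d = d_wrap
                boundary = "end" if gene.strand == "+" else "start"
    return CdsDistance(distance=d, boundary=boundary)


def extract_flanks(
    match: PqsMatch, genome: GenomeRecord, window: int = 100
) -> tuple[str, str]:
    """(flank5, flank3) read 5'->3' on the G-rich strand of the match.

    For a '-' match flank3 is the reverse complement of the genomic
    sequence upstream of match.start.  Flanks truncate at replicon ends
    for linear genomes and wrap for circular ones.
    """
    seq = genome.sequence
    n = len(seq)

    def slice_(a: int, b: int) -> str:
        if genome.circular:
            return "".join(seq[i % n] for i in range(a, b)) if b - a < n else seq
        return seq[max(0, a) : min(n, b)]

    if match.strand == "+":
        return slice_(match.start - window, match.start), slice_(match.end, match.end + window)
    up = slice_(match.end, match.end + window)
    down = slice_(match.start - window, match.start)
    return reverse_complement(up), reverse_complement(down)


def detect_crich_track(flank3: str, search_window: int = 30) -> Optional[CRichTrack]:
    """Leftmost maximal C{3,}[ACGT]C{3,} segment in the first
    ``search_window`` nt of the 3' flank; minimal-motif (C3TC3 family)
    when the single separator is T.  The C fraction is the best 12-nt
    window within the search region."""
    if not flank3:
        raise ValueError("empty 3' flank")
    region = flank3[:search_window]
    m = _CRICH_RE.search(region)
    if m is None:
        return None
    sep = re.match("C+", region[m.start():]).end() + m.start()
    separator = region[sep]
    w = min(_CRICH_WINDOW, len(region))
    best = max(
        region[i : i + w].count("C") for i in range(0, len(region) - w + 1)
    )
    return CRichTrack(
        offset=m.start(),
        length=m.end() - m.start(),
        c_fraction=best / w,
        matches_minimal_motif=(separator == "T"),
    )


def oric_distance(match: PqsMatch, oric_position: int, genome: GenomeRecord) -> int:
    """Distance from the match midpoint to oriC (minimal circular
    distance on circular replicons)."""
    if not (0 <= oric_position < genome.length):
        raise ValueError("oriC position outside genome")
    d = abs(match.midpoint - oric_position)
    return min(d, genome.length - d) if genome.circular else d


def build_context_records(
    matches: list[PqsMatch],
    annotated: AnnotatedGenome,
    window: int = 100,
    oric_position: Optional[int] = None,
) -> list[ContextRecord]:
    genome = annotated.genome
    out = []
    for m in matches:
        loc, left, right = classify_location(m, annotated.genes, genome)
        orient = classify_orientation(left, right) if loc == INTERGENIC else UNPAIRED
        d_start = d_end = None
        if loc == INTERGENIC:
            for gene in (left, right):
                if gene is None:
                    continue
                cd = distance_to_cds(m, gene, genome.length, genome.circular)
                if cd.boundary == "start":
                    d_start = cd.distance if d_start is None else min(d_start, cd.distance)
                else:
                    d_end = cd.distance if d_end is None else min(d_end, cd.distance)
        flank5, flank3 = extract_flanks(m, genome, window)
        crich = detect_crich_track(flank3) if flank3 else None
        ori = oric_distance(m, oric_position, genome) if oric_position is not None else None
        out.append(
            ContextRecord(
                match=m,
                location_class=loc,
                left_gene=left,
                right_gene=right,
                orientation_class=orient,
                dist_to_nearest_cds_start=d_start,
                dist_to_nearest_cds_end=d_end,
                flank5=flank5,
                flank3=flank3,
                crich=crich,
                ori_distance=ori,
            )
        )
    return out


def summarize_context(records: list[ContextRecord]) -> dict:
    """Aggregate context statistics.

    Orientation fractions use paired intergenic records as denominator
    and are reported as None (absent) when no record is paired.
    """
    if not records:
        raise ValueError("no context records")
    n = len(records)
    intergenic = [r for r in records if r.location_class == INTERGENIC]
    paired = [r for r in records if r.orientation_class != UNPAIRED]
    if paired:
        orientation_fractions = {
            cls: sum(1 for r in paired if r.orientation_class == cls) / len(paired)
            for cls in (TAIL_TO_TAIL, HEAD_TO_HEAD, HEAD_TO_TAIL)
        }
    else:
        orientation_fractions = None
    dists = [
        d
        for r in records
        for d in (r.dist_to_nearest_cds_start, r.dist_to_nearest_cds_end)
        if d is not None
    ]
    dist_stats = None
    if dists:
        arr = np.asarray(dists, dtype=float)
        counts, edges = np.histogram(arr, bins=10)
        dist_stats = {
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "min": int(arr.min()),
            "max": int(arr.max()),
            "histogram_counts": counts.tolist(),
            "histogram_edges": edges.tolist(),
        }
    sense_left = [
        r.match.strand == r.left_gene.strand for r in paired if r.left_gene is not None
    ]
    sense_right = [
        r.match.strand == r.right_gene.strand for r in paired if r.right_gene is not None
    ]
    return {
        "n_records": n,
        "fraction_intergenic": len(intergenic) / n,
        "orientation_fractions": orientation_fractions,
        "distance_stats": dist_stats,
        "fraction_crich": sum(1 for r in records if r.crich is not None) / n,
        "fraction_crich_minimal_motif": sum(
            1 for r in records if r.crich is not None and r.crich.matches_minimal_motif
        )
        / n,
        "fraction_plus_strand": sum(1 for r in records if r.match.strand == "+") / n,
        "fraction_sense_vs_left_gene": (
            sum(sense_left) / len(sense_left) if sense_left else None
        ),
        "fraction_sense_vs_right_gene": (
            sum(sense_right) / len(sense_right) if sense_right else None
        ),
    }
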