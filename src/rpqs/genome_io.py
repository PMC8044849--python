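"""Genome/annotation input and pipeline output in standard text formats.

Coordinate conventions: internal coordinates are 0-based half-open;
GFF3 stays 1-based inclusive at the file boundary; BED output is
0-based half-open.  One conversion layer lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO

from .pqs_scanner import PqsMatch

__all__ = [
    "GenomeRecord",
    "GeneAnnotation",
    "AnnotatedGenome",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_circularity",
    "write_gff3",
    "write_matches_bed",
    "read_matches_bed",
    "gff_to_internal",
    "internal_to_gff",
]

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")


@dataclass
class GenomeRecord:
    """One replicon: uppercase DNA over {A,C,G,T,N}."""

    seq_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"{self.seq_id}: invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(order=True)
class GeneAnnotation:
    """A CDS (or gene) interval, 1-based inclusive as in GFF3."""

    start: int
    end: int
    locus_tag: str
    seq_id: str = field(compare=False)
    strand: str = field(compare=False)
    feature_type: str = field(compare=False, default="CDS")
    product: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.locus_tag}: require 1 <= start <= end")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be + or -")

    @property
    def start0(self) -> int:
        """0-based inclusive start (internal convention)."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end (internal convention)."""
        return self.end


@dataclass
class AnnotatedGenome:
    genome: GenomeRecord
    genes: list[GeneAnnotation]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.seq_id != self.genome.seq_id:
                raise ValueError(
                    f"gene {g.locus_tag} references {g.seq_id}, "
                    f"genome is {self.genome.seq_id}"
                )
            if g.end > self.genome.length:
                raise ValueError(f"gene {g.locus_tag} extends past genome end")
        # sorted by start, ties broken by end then locus_tag
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.locus_tag))


def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA


def _normalize(seq: str, seq_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        logger.warning("%s: mapping non-ACGTN symbols %s to N", seq_id, sorted(bad))
        s = s.translate({ord(c): "N" for c in bad})
    return s


def read_fasta(path, circular: bool = False) -> list[GenomeRecord]:
    """Read FASTA; lowercase -> uppercase, U -> T, other symbols -> N."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA header at line 1: {first.strip()!r}")
    records = [
        GenomeRecord(rec.id, _normalize(str(rec.seq), rec.id), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path, feature_filter: Sequence[str] = ("CDS",)) -> list[GeneAnnotation]:
    """Read GFF3 features of the requested types as GeneAnnotation.

    locus_tag is taken from the ``locus_tag`` attribute, else ``ID``;
    ``product`` if present.  Coordinates outside a declared
    ##sequence-region raise a validation error; strand must be + or -.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    regions: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            regions[parts[1]] = int(parts[3])
    wanted = set(feature_filter)
    out: list[GeneAnnotation] = []
    for feat in db.all_features(order_by=("seqid", "start", "end")):
        if feat.featuretype not in wanted:
            continue
        if feat.strand not in "+-":
            raise ValueError(
                f"{path}: feature {feat.id or feat.featuretype} at "
                f"{feat.seqid}:{feat.start}-{feat.end} has degenerate strand "
                f"{feat.strand!r}"
            )
        if feat.seqid in regions and feat.end > regions[feat.seqid]:
            raise ValueError(
                f"{path}: feature {feat.id or feat.featuretype} end {feat.end} "
                f"outside declared sequence-region of {feat.seqid} "
                f"({regions[feat.seqid]} nt)"
            )
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", [""]))[0]
        product = feat.attributes.get("product", [""])[0]
        out.append(
            GeneAnnotation(
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                feature_type=feat.featuretype,
                locus_tag=locus,
                product=product,
            )
        )
    return out


def read_circularity(path) -> dict[str, bool]:
    """seq_id -> Is_circular from GFF3 region features (default False)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, bool] = {}
    for feat in db.all_features():
        if feat.featuretype == "region":
            val = feat.attributes.get("Is_circular", ["false"])[0]
            out[feat.seqid] = val.lower() == "true"
    return out


def write_gff3(
    annotated: AnnotatedGenome, path, source: str = "rpqs"
) -> None:
    """Write the gene model as GFF3 (CDS rows, 1-based inclusive)."""
    genome = annotated.genome
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.seq_id} 1 {genome.length}\n")
        circ = "true" if genome.circular else "false"
        fh.write(
            f"{genome.seq_id}\t{source}\tregion\t1\t{genome.length}\t.\t+\t.\t"
            f"ID=region_{genome.seq_id};Is_circular={circ}\n"
        )
        for i, g in enumerate(annotated.genes):
            attrs = f"ID=cds_{i};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.seq_id}\t{source}\t{g.feature_type}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED6

_BED_HEADER = "# BED6: chrom start end name(pqs_class) score strand\n"


def write_matches_bed(matches: Iterable[PqsMatch], path) -> None:
    """BED6, 0-based half-open; name column carries the artifact class.

    Rows are sorted by (seq_id, start, strand) so output is deterministic;
    '-' sorts after '+' at equal start.
    """
    rows = sorted(matches, key=lambda m: (m.seq_id, m.start, m.strand, m.end))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER)
        for m in rows:
            fh.write(f"{m.seq_id}\t{m.start}\t{m.end}\t{m.pqs_class}\t0\t{m.strand}\n")


def read_matches_bed(path) -> list[PqsMatch]:
    """Re-read a BED6 match file (coordinates, strand and class only)."""
    out: list[PqsMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED columns")
            out.append(
                PqsMatch(
                    seq_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                    pqs_class=parts[3],
                )
            )
    return out
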