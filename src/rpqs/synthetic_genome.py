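"""Synthetic annotated genomes with planted rPQS copies and ground truth.

The generator emulates the layout the pipeline is designed to detect: a
circular genome of configurable length and GC content carrying N copies
of an rPQS template, each followed on its own strand by a C-rich tail,
placed intergenically between a dedicated pair of CDSs whose strands
realize a requested orientation class at a fixed spacer distance from
the PQS match boundaries.  In scrub mode, background windows that
accidentally match the PQS pattern (either strand) are re-rolled until
the planted copies are the only matches, which makes exact
precision/recall checks possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .genome_io import AnnotatedGenome, GeneAnnotation, GenomeRecord
from .null_model import random_dna
from .pqs_scanner import PqsPattern, reverse_complement, scan_minimal_overlapping
from .context_annotator import HEAD_TO_HEAD, HEAD_TO_TAIL, TAIL_TO_TAIL

__all__ = [
    "GCA_CORE",
    "GCA_TAIL",
    "TemplateSpec",
    "SiteLayout",
    "SyntheticSpec",
    "PlantedSite",
    "GroundTruth",
    "generate_synthetic_genome",
    "write_synthetic",
    "validate_ground_truth",
]

# default template: the most abundant rPQS variant (GCA central loop)
# with its natural 3' C-rich tail
GCA_CORE = "CTGGGGGGTGGGGGCAGGGGAGGGGGCTC"
GCA_TAIL = "GCCCCCTCCCCGCA"

_ORIENTATION_MIX = {TAIL_TO_TAIL: 0.50, HEAD_TO_HEAD: 0.11, HEAD_TO_TAIL: 0.39}
_ORIENT_STRANDS = {
    TAIL_TO_TAIL: ("+", "-"),
    HEAD_TO_HEAD: ("-", "+"),
    HEAD_TO_TAIL: ("+", "+"),
}
_MAX_SCRUB_ROUNDS = 100


@dataclass(frozen=True)
class TemplateSpec:
    """A plantable rPQS: core sequence (must contain exactly one minimal
    PQS), optional 3' tail, copy number, and forward-strand fraction."""

    core: str = GCA_CORE
    tail: str = GCA_TAIL
    n_copies: int = 12
    strand_mix: float = 0.5


@dataclass(frozen=True)
class SiteLayout:
    orientation: str = TAIL_TO_TAIL
    spacer: int = 300  # nt between the PQS match boundary and each CDS


@dataclass
class SyntheticSpec:
    length: int = 500_000
    gc: float = 0.55
    circular: bool = True
    templates: list[TemplateSpec] = field(default_factory=lambda: [TemplateSpec()])
    gene_layout: Optional[list[SiteLayout]] = None  # one per planted site
    gene_length: int = 600
    intersite_gap: int = 500
    leading_gap: int = 1000
    scrub_background: bool = True
    seed: int = 0
    seq_id: str = "synthetic_1"


@dataclass
class PlantedSite:
    seq_id: str
    template_index: int
    strand: str
    insert_start: int
    insert_end: int
    match_start: int  # forward-strand coords of the PQS match
    match_end: int
    tail_start: int
    tail_end: int
    orientation: str
    spacer: int
    left_locus: str
    right_locus: str


@dataclass
class GroundTruth:
    seq_id: str
    length: int
    circular: bool
    gc: float
    seed: int
    background_scrubbed: bool
    planted: list[PlantedSite]
    genes: list[GeneAnnotation]

    def to_dict(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "length": self.length,
            "circular": self.circular,
            "gc": self.gc,
            "seed": self.seed,
            "background_scrubbed": self.background_scrubbed,
            "planted": [asdict(p) for p in self.planted],
            "genes": [asdict(g) for g in self.genes],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seq_id=d["seq_id"],
            length=d["length"],
            circular=d["circular"],
            gc=d["gc"],
            seed=d["seed"],
            background_scrubbed=d["background_scrubbed"],
            planted=[PlantedSite(**p) for p in d["planted"]],
            genes=[GeneAnnotation(**g) for g in d["genes"]],
        )


def _default_layout(n_sites: int, rng: np.random.Generator) -> list[SiteLayout]:
    """Orientation quotas by largest remainder over the default mix,
    shuffled so classes are not positionally correlated."""
    exact = {k: v * n_sites for k, v in _ORIENTATION_MIX.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n_sites - sum(counts.values())
    by_remainder = sorted(exact, key=lambda k: exact[k] - counts[k], reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    classes = [k for k, c in counts.items() for _ in range(c)]
    rng.shuffle(classes)
    return [SiteLayout(orientation=c) for c in classes]


def _template_match_span(template: TemplateSpec, pattern: PqsPattern) -> tuple[int, int]:
    """Offsets of the single minimal PQS match within core+tail."""
    insert = template.core + template.tail
    probe = GenomeRecord(seq_id="_template", sequence=insert)
    hits = [m for m in scan_minimal_overlapping(probe, pattern) if m.strand == "+"]
    minus = [m for m in scan_minimal_overlapping(probe, pattern) if m.strand == "-"]
    if len(hits) != 1 or minus:
        raise ValueError(
            f"template must contain exactly one minimal PQS on the forward "
            f"strand (found {len(hits)} forward, {len(minus)} reverse)"
        )
    return hits[0].start, hits[0].end


def generate_synthetic_genome(
    spec: SyntheticSpec, pattern: PqsPattern = PqsPattern()
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Build the annotated genome and its machine-readable ground truth.

    Deterministic: identical spec (including seed) gives byte-identical
    sequence, annotation and truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    # per-template geometry
    spans = [_template_match_span(t, pattern) for t in spec.templates]

    # site order: template blocks in order, orientations per layout
    site_templates = [
        ti for ti, t in enumerate(spec.templates) for _ in range(t.n_copies)
    ]
    n_sites = len(site_templates)
    layout = spec.gene_layout
    if layout is None:
        layout = _default_layout(n_sites, rng)
    if len(layout) != n_sites:
        raise ValueError(
            f"gene_layout has {len(layout)} entries for {n_sites} planted sites"
        )
    strands = [
        "+" if rng.random() < spec.templates[ti].strand_mix else "-"
        for ti in site_templates
    ]

    arr = np.frombuffer(
        random_dna(rng, spec.length, spec.gc).encode("ascii"), dtype="S1"
    ).copy()
    protected = np.zeros(spec.length, dtype=bool)

    genes: list[GeneAnnotation] = []
    planted: list[PlantedSite] = []
    pos = spec.leading_gap
    for si, (ti, site, strand) in enumerate(zip(site_templates, layout, strands)):
        t = spec.templates[ti]
        insert = t.core + t.tail
        m0, m1 = spans[ti]
        if strand == "+":
            g0, g1 = m0, m1  # match offsets within the genomic insert
            ins_seq = insert
        else:
            g0, g1 = len(insert) - m1, len(insert) - m0
            ins_seq = reverse_complement(insert)
        left_gap = site.spacer - g0
        right_gap = site.spacer - (len(insert) - g1)
        if left_gap < 0 or right_gap < 0:
            raise ValueError(
                f"site {si}: spacer {site.spacer} shorter than the template "
                f"overhang around the PQS match"
            )
        ls, rs = _ORIENT_STRANDS[site.orientation]
        left_tag, right_tag = f"SYN_{2 * si:04d}", f"SYN_{2 * si + 1:04d}"
        genes.append(
            GeneAnnotation(
                seq_id=spec.seq_id, start=pos + 1, end=pos + spec.gene_length,
                strand=ls, locus_tag=left_tag, product="hypothetical protein",
            )
        )
        pos += spec.gene_length + left_gap
        ins_start = pos
        ins_end = pos + len(insert)
        if ins_end > spec.length:
            raise ValueError("planted sites exceed genome length; enlarge length")
        arr[ins_start:ins_end] = np.frombuffer(ins_seq.encode("ascii"), dtype="S1")
        protected[ins_start:ins_end] = True
        if strand == "+":
            tail_iv = (ins_start + len(t.core), ins_end)
        else:
            tail_iv = (ins_start, ins_start + len(t.tail))
        planted.append(
            PlantedSite(
                seq_id=spec.seq_id,
                template_index=ti,
                strand=strand,
                insert_start=ins_start,
                insert_end=ins_end,
                match_start=ins_start + g0,
                match_end=ins_start + g1,
                tail_start=tail_iv[0],
                tail_end=tail_iv[1],
                orientation=site.orientation,
                spacer=site.spacer,
                left_locus=left_tag,
                right_locus=right_tag,
            )
        )
        pos = ins_end + right_gap
        genes.append(
            GeneAnnotation(
                seq_id=spec.seq_id, start=pos + 1, end=pos + spec.gene_length,
                strand=rs, locus_tag=right_tag, product="hypothetical protein",
            )
        )
        pos += spec.gene_length + spec.intersite_gap
    if pos > spec.length:
        raise ValueError("planted sites exceed genome length; enlarge length")

    if spec.scrub_background:
        _scrub(arr, protected, planted, spec, pattern, rng)

    genome = GenomeRecord(
        seq_id=spec.seq_id, sequence=arr.tobytes().decode("ascii"),
        circular=spec.circular,
    )
    annotated = AnnotatedGenome(genome=genome, genes=genes)
    for p in planted:  # planted inserts never touch a CDS by construction
        for g in genes:
            assert p.insert_end <= g.start0 or g.end0 <= p.insert_start
    truth = GroundTruth(
        seq_id=spec.seq_id,
        length=spec.length,
        circular=spec.circular,
        gc=spec.gc,
        seed=spec.seed,
        background_scrubbed=spec.scrub_background,
        planted=planted,
        genes=annotated.genes,
    )
    return annotated, truth


def _scrub(arr, protected, planted, spec, pattern, rng) -> None:
    """Re-roll background positions inside accidental PQS matches until
    the planted matches are the only ones (bounded retry loop)."""
    wanted = {(p.match_start, p.match_end, p.strand) for p in planted}
    for _ in range(_MAX_SCRUB_ROUNDS):
        genome = GenomeRecord(
            seq_id=spec.seq_id, sequence=arr.tobytes().decode("ascii")
        )
        offending = [
            m
            for m in scan_minimal_overlapping(genome, pattern)
            if m.interval() not in wanted
        ]
        if not offending:
            return
        for m in offending:
            idx = np.arange(m.start, m.end)
            idx = idx[~protected[idx]]
            if idx.size == 0:
                raise RuntimeError(
                    f"accidental PQS at {m.start}-{m.end}({m.strand}) lies "
                    "entirely inside a planted insert; change the template"
                )
            repl = random_dna(rng, idx.size, spec.gc)
            arr[idx] = np.frombuffer(repl.encode("ascii"), dtype="S1")
    raise RuntimeError(f"background not clean after {_MAX_SCRUB_ROUNDS} scrub rounds")


def write_synthetic(
    annotated: AnnotatedGenome, truth: GroundTruth, out_prefix
) -> dict[str, str]:
    """Emit <prefix>.fasta, <prefix>.gff3 and <prefix>.truth.json."""
    from .genome_io import write_fasta, write_gff3

    prefix = str(out_prefix)
    paths = {
        "fasta": prefix + ".fasta",
        "gff3": prefix + ".gff3",
        "truth": prefix + ".truth.json",
    }
    write_fasta([annotated.genome], paths["fasta"])
    write_gff3(annotated, paths["gff3"])
    truth.to_json(paths["truth"])
    return paths


def validate_ground_truth(
    truth: GroundTruth,
    matches=None,
    repeats=None,
    contexts=None,
) -> dict:
    """Recovery report of pipeline outputs against the planted truth.

    In scrub mode every figure is expected to be exact (precision and
    recall 1.0, counts equal, orientation confusion diagonal, C-track
    detected everywhere).
    """
    report: dict = {"seq_id": truth.seq_id, "n_planted": len(truth.planted)}
    truth_set = {(p.match_start, p.match_end, p.strand) for p in truth.planted}
    if matches is not None:
        for m in matches:
            if m.seq_id != truth.seq_id:
                raise ValueError(
                    f"match seq_id {m.seq_id!r} does not belong to truth "
                    f"{truth.seq_id!r}"
                )
        found = {m.interval() for m in matches}
        tp = len(found & truth_set)
        report["match_precision"] = tp / len(found) if found else 0.0
        report["match_recall"] = tp / len(truth_set) if truth_set else 1.0
        loci_truth = {(s, e): st for s, e, st in truth_set}
        strand_ok = [
            st == loci_truth[(s, e)]
            for (s, e, st) in found
            if (s, e) in loci_truth
        ]
        report["strand_accuracy"] = (
            sum(strand_ok) / len(strand_ok) if strand_ok else 0.0
        )
        report["background_hits"] = sorted(found - truth_set)
    if repeats is not None:
        expected: dict[int, int] = {}
        for p in truth.planted:
            expected[p.template_index] = expected.get(p.template_index, 0) + 1
        report["n_families_found"] = len(repeats)
        report["n_templates_planted"] = len(expected)
        found_counts = {r.canonical_sequence: r.total_count for r in repeats}
        report["family_counts"] = found_counts
        report["repeat_counts_exact"] = (
            sorted(found_counts.values()) == sorted(expected.values())
        )
    if contexts is not None:
        by_locus = {(r.match.start, r.match.end): r for r in contexts}
        confusion: dict[str, dict[str, int]] = {}
        crich_hits = 0
        matched_sites = 0
        for p in truth.planted:
            r = by_locus.get((p.match_start, p.match_end))
            if r is None:
                continue
            matched_sites += 1
            confusion.setdefault(p.orientation, {}).setdefault(
                r.orientation_class, 0
            )
            confusion[p.orientation][r.orientation_class] += 1
            if r.crich is not None and r.crich.matches_minimal_motif:
                crich_hits += 1
        report["orientation_confusion"] = confusion
        report["crich_detection_rate"] = (
            crich_hits / matched_sites if matched_sites else 0.0
        )
    return report
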