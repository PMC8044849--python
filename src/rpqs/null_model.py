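"""GC-content null model for PQS density.

Random i.i.d. sequences at fixed GC (G and C equiprobable, likewise A
and T) give the expected PQS density as a function of base composition
alone; the observed genome densities are compared against this curve
and against GC by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeRecord
from .pqs_scanner import PqsPattern, pqs_density

__all__ = [
    "RandomSeqParams",
    "NullCurvePoint",
    "random_dna",
    "generate_random_sequence",
    "null_density_curve",
    "curve_frame",
    "write_curve_tsv",
    "spearman_rank_correlation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RandomSeqParams:
    length: int
    gc: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class NullCurvePoint:
    gc: float
    mean_density: float
    sd_density: float
    n_replicates: int


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. DNA with p(G)=p(C)=gc/2 and p(A)=p(T)=(1-gc)/2."""
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def generate_random_sequence(params: RandomSeqParams) -> GenomeRecord:
    """Seeded random genome; identical params give identical sequence."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    seq = random_dna(rng, params.length, params.gc)
    return GenomeRecord(seq_id=f"random_gc{params.gc:g}_seed{params.seed}", sequence=seq)


def null_density_curve(
    gc_grid,
    length: int = 1_000_000,
    n_replicates: int = 5,
    base_seed: int = 0,
    pattern: PqsPattern = PqsPattern(),
) -> list[NullCurvePoint]:
    """Mean +/- sample SD of PQS density over replicate random sequences.

    Replicate streams derive from SeedSequence(base_seed, spawn_key=
    (grid_index, replicate_index)), so the curve is fully reproducible
    from base_seed and collision-free across grid points.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for the SD to be defined")
    points = []
    for gi, gc in enumerate(gc_grid):
        densities = []
        for ri in range(n_replicates):
            ss = np.random.SeedSequence(base_seed, spawn_key=(gi, ri))
            rng = np.random.default_rng(ss)
            genome = GenomeRecord(
                seq_id=f"null_gc{gc:g}_rep{ri}", sequence=random_dna(rng, length, gc)
            )
            densities.append(pqs_density(genome, pattern).density)
        arr = np.asarray(densities)
        points.append(
            NullCurvePoint(
                gc=float(gc),
                mean_density=float(arr.mean()),
                sd_density=float(arr.std(ddof=1)),
                n_replicates=n_replicates,
            )
        )
    return points


def curve_frame(points: list[NullCurvePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gc": [p.gc for p in points],
            "mean_density": [p.mean_density for p in points],
            "sd_density": [p.sd_density for p in points],
            "n": [p.n_replicates for p in points],
        }
    )


def write_curve_tsv(points: list[NullCurvePoint], path) -> None:
    curve_frame(points).to_csv(path, sep="\t", index=False, float_format="%.6f")


def spearman_rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties; p from the large-sample
    t approximation (as implemented in scipy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
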