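"""Composition-matched random genomes and false-positive estimation.

The scanner's specificity is estimated by running it on genomes drawn
i.i.d. from the base composition of a real assembly: any candidate on
such a sequence is a false positive, and the false-positive rate (FPR)
is the mean per-genome candidate count expressed as a percentage of the
count predicted in the real genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .errors import DomainError, EmptyInputError
from .scanner import ScanParameters, SequenceRecord, find_3prime_termini

__all__ = [
    "CompositionSpec",
    "CompositionCount",
    "count_composition",
    "random_genome",
    "estimate_fpr",
]

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


@dataclass(frozen=True)
class CompositionSpec:
    """Base frequencies (A, T, G, C), length and seed of a random genome.

    Frequencies may sum to slightly less than 1 when taken from an
    assembly containing N bases; they are renormalized proportionally.
    """

    freq_a: float
    freq_t: float
    freq_g: float
    freq_c: float
    length: int
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.array([self.freq_a, self.freq_t, self.freq_g, self.freq_c])
        if (f < 0).any():
            raise DomainError("frequencies must be non-negative")
        if not 0.99 <= f.sum() <= 1.0 + 1e-9:
            raise DomainError("frequencies must sum to ~1")
        if self.length <= 0:
            raise DomainError("length must be positive")

    @property
    def probabilities(self) -> np.ndarray:
        f = np.array([self.freq_a, self.freq_t, self.freq_g, self.freq_c])
        return f / f.sum()


class CompositionCount(NamedTuple):
    """Measured composition: frequencies are None when only N was seen."""

    freq_a: float | None
    freq_t: float | None
    freq_g: float | None
    freq_c: float | None
    length: int


def count_composition(records: Iterable[SequenceRecord]) -> CompositionCount:
    """A/T/G/C frequencies and total length over all records.

    N bases count toward the length but are excluded from the frequency
    denominator; an input of only N yields undefined (None) frequencies.
    """
    counts = np.zeros(256, dtype=np.int64)
    total = 0
    seen = False
    for rec in records:
        seen = True
        arr = np.frombuffer(rec.seq.upper().encode("ascii"), dtype=np.uint8)
        counts += np.bincount(arr, minlength=256)
        total += arr.size
    if not seen:
        raise EmptyInputError("count_composition received no records")
    acgt = np.array([counts[ord(b)] for b in "ATGC"], dtype=float)
    denom = acgt.sum()
    if denom == 0:
        return CompositionCount(None, None, None, None, total)
    f = acgt / denom
    return CompositionCount(f[0], f[1], f[2], f[3], total)


def random_genome(spec: CompositionSpec) -> SequenceRecord:
    """I.i.d. random sequence at the given composition; same seed, same
    sequence."""
    rng = np.random.default_rng(spec.seed)
    codes = rng.choice(_BASES, size=spec.length, p=spec.probabilities)
    return SequenceRecord(
        id=f"random_seed{spec.seed}", seq=codes.tobytes().decode("ascii")
    )


class FprResult(NamedTuple):
    fpr_percent: float
    counts: list[int]
    seeds: list[int]


def estimate_fpr(
    spec: CompositionSpec,
    n_genomes: int,
    p: ScanParameters | None = None,
    reference_count: int = 665,
) -> FprResult:
    """Scanner false-positive rate on ``n_genomes`` random genomes.

    Genome ``i`` uses seed ``spec.seed + i``.  FPR(%) = 100 x (mean
    candidate count over the random genomes) / ``reference_count``,
    where the reference is the count predicted in the real genome the
    composition was measured from.  Per-genome counts are returned for
    inspection; only 3' termini are counted, so 5'-end search is
    skipped.
    """
    if n_genomes < 1:
        raise DomainError("n_genomes must be at least 1")
    if reference_count <= 0:
        raise DomainError("reference_count must be positive")
    p = p or ScanParameters()
    counts: list[int] = []
    seeds: list[int] = []
    for i in range(n_genomes):
        g = random_genome(
            CompositionSpec(
                spec.freq_a, spec.freq_t, spec.freq_g, spec.freq_c,
                spec.length, spec.seed + i,
            )
        )
        counts.append(len(find_3prime_termini(g, p)))
        seeds.append(spec.seed + i)
    fpr = 100.0 * float(np.mean(counts)) / reference_count
    return FprResult(fpr, counts, seeds)
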