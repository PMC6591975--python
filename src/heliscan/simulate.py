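"""Deterministic synthetic data: planted Helitron cassettes, toy gene
annotations and ecotype/phenotype matrices.

The planted-genome generator writes canonical Helitron cassettes

    A | TC ...filler... [arm][loop][revcomp(arm)] [spacer] CTAG | T

into a background drawn from a configurable composition.  With the
default A/T-only background the flanks cannot form GC-rich hairpin arms
or CTAG motifs, so the planted termini are provably the only detectable
signal and scanner recovery can be checked exactly against the returned
truth table.  Arms are drawn from {G, C} only, loops and spacers are
poly-A, and each cassette is framed by the AT target-site bases so the
target-site flag is exercised.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .errors import CapacityError, ConstraintError
from .rules import TransactionSet
from .scanner import SequenceRecord, reverse_complement

__all__ = [
    "PlantSpec",
    "make_planted_genome",
    "make_toy_annotation",
    "make_ecotype_matrix",
]


@dataclass(frozen=True)
class PlantSpec:
    """Layout of a synthetic genome with planted Helitron termini."""

    n_cassettes: int = 5
    background_length: int = 10_000
    background_freqs: tuple[float, float, float, float] = (0.5, 0.5, 0.0, 0.0)
    arm_len: int = 8
    loop_len: int = 4
    spacer_len: int = 3
    leader_len: int = 120  # bases between the 5' TC and the hairpin
    include_five_prime: bool = True
    seed: int = 0
    seq_id: str = "synth1"


def _cassette(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, dict]:
    arm = "".join(rng.choice(["G", "C"], size=spec.arm_len))
    loop = "A" * spec.loop_len
    spacer = "A" * spec.spacer_len
    filler = "".join(rng.choice(["A", "T"], size=spec.leader_len - 1)) + "A"
    head = "A" + "TC" + filler if spec.include_five_prime else ""
    body = arm + loop + reverse_complement(arm) + spacer + "CTAG" + "T"
    offsets = {
        "five_offset": 1 if spec.include_five_prime else None,  # 0-based T
        "hairpin_left_offset": len(head),
        "hairpin_right_end_offset": len(head) + 2 * spec.arm_len + spec.loop_len,
        "end3_offset": len(head) + len(body) - 2,  # 0-based G of CTAG
    }
    return head + body, offsets


def make_planted_genome(spec: PlantSpec) -> tuple[SequenceRecord, pd.DataFrame]:
    """Synthetic genome plus a truth table of planted coordinates.

    The truth table has one row per cassette with 1-based
    ``five_prime_pos`` (the planted T; NA when 5' ends are excluded),
    0-based half-open hairpin bounds, 1-based ``end3_pos`` and strand.

    Raises
    ------
    CapacityError
        If the cassettes (plus minimal 50-base gaps) do not fit.
    """
    rng = np.random.default_rng(spec.seed)
    cassettes = []
    for _ in range(spec.n_cassettes):
        cassettes.append(_cassette(spec, rng))
    cass_len = len(cassettes[0][0]) if cassettes else 0
    block = spec.background_length // max(spec.n_cassettes, 1)
    if spec.n_cassettes and block < cass_len + 50:
        raise CapacityError(
            f"{spec.n_cassettes} cassettes of {cass_len} bases do not fit "
            f"in {spec.background_length} bases"
        )
    bases = np.array(["A", "T", "G", "C"])
    probs = np.asarray(spec.background_freqs, dtype=float)
    probs = probs / probs.sum()
    genome = list("".join(rng.choice(bases, size=spec.background_length, p=probs)))
    truth_rows = []
    for i, (cass, off) in enumerate(cassettes):
        start = i * block + int(rng.integers(0, block - cass_len - 1))
        genome[start : start + cass_len] = cass
        truth_rows.append(
            {
                "seq_id": spec.seq_id,
                "strand": "+",
                "cassette_start": start,
                "five_prime_pos": (
                    start + off["five_offset"] + 1
                    if off["five_offset"] is not None
                    else pd.NA
                ),
                "hairpin_left_start": start + off["hairpin_left_offset"],
                "hairpin_right_end": start + off["hairpin_right_end_offset"],
                "end3_pos": start + off["end3_offset"] + 1,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "seq_id", "strand", "cassette_start", "five_prime_pos",
            "hairpin_left_start", "hairpin_right_end", "end3_pos",
        ],
    )
    return SequenceRecord(spec.seq_id, "".join(genome)), truth


def make_toy_annotation(
    genes: list[tuple[str, str, int, int, float]],
) -> list[GeneModel]:
    """Gene models from (gene_id, seqid, start, end, cds_fraction) tuples.

    The CDS (when the fraction is positive) is a single centered
    interval covering the given fraction of the span; the whole span is
    one exon.  Overlapping genes on one sequence are rejected.
    """
    models: list[GeneModel] = []
    for gene_id, seqid, start, end, cds_frac in genes:
        span = end - start + 1
        cds_len = round(cds_frac * span)
        if cds_len > 0:
            cs = start + (span - cds_len) // 2
            cds = ((cs, cs + cds_len - 1),)
        else:
            cds = ()
        models.append(
            GeneModel(gene_id, seqid, "+", start, end, cds, ((start, end),))
        )
    by_seq: dict[str, list[GeneModel]] = {}
    for m in models:
        by_seq.setdefault(m.seqid, []).append(m)
    for seqid, ms in by_seq.items():
        ms = sorted(ms, key=lambda g: g.start)
        for a, b in zip(ms, ms[1:]):
            if b.start <= a.end:
                raise ValueError(f"genes {a.gene_id} and {b.gene_id} overlap")
    return models


@dataclass(frozen=True)
class PlantedLocus:
    """A locus with exact carrier counts per phenotype class."""

    locus: str
    carriers: dict[str, int] = field(default_factory=dict)


def make_ecotype_matrix(
    n_ecotypes: int,
    class_counts: dict[str, int],
    planted_associations: list[PlantedLocus | dict],
    seed: int = 0,
    n_random_loci: int = 0,
    phenotype_name: str = "FT",
) -> TransactionSet:
    """Synthetic ecotype x locus matrix with exact phenotype margins.

    ``class_counts`` fixes the phenotype margin (e.g. 5 late / 13
    intermediate).  Each planted association states how many carriers a
    locus has in each class; carriers are chosen by the seeded rng, so
    the requested marginal counts are reproduced exactly.  Optional
    random loci are Bernoulli(1/2) noise, independent of phenotype.

    Raises
    ------
    ConstraintError
        If class counts do not sum to ``n_ecotypes`` or a locus requests
        more carriers than a class has members.
    """
    if sum(class_counts.values()) != n_ecotypes:
        raise ConstraintError("class counts must sum to n_ecotypes")
    rng = np.random.default_rng(seed)
    ecotypes = [f"eco{i + 1:02d}" for i in range(n_ecotypes)]
    labels: list[str] = []
    for cls, cnt in class_counts.items():
        labels.extend([cls] * cnt)
    phenotype = pd.Series(labels, index=ecotypes)
    members = {
        cls: [e for e, lb in zip(ecotypes, labels) if lb == cls]
        for cls in class_counts
    }
    cols: dict[str, pd.Series] = {}
    for assoc in planted_associations:
        if isinstance(assoc, dict):
            assoc = PlantedLocus(**assoc)
        present = pd.Series(0, index=ecotypes, dtype=int)
        for cls, k in assoc.carriers.items():
            if cls not in members:
                raise ConstraintError(f"unknown class {cls!r}")
            if k > len(members[cls]):
                raise ConstraintError(
                    f"{assoc.locus}: {k} carriers requested, class {cls!r} "
                    f"has {len(members[cls])} members"
                )
            chosen = rng.choice(members[cls], size=k, replace=False)
            present.loc[list(chosen)] = 1
        cols[assoc.locus] = present
    for j in range(n_random_loci):
        cols[f"LOCR{j + 1:03d}"] = pd.Series(
            rng.integers(0, 2, size=n_ecotypes), index=ecotypes
        )
    table = pd.DataFrame(cols, index=ecotypes, dtype=int)
    return TransactionSet(table, phenotype, phenotype_name)
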