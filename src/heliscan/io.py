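"""FASTA input and the scanner's four output files.

A scan emits, per run prefix:

``<prefix>.3.txt``
    one FASTA record per candidate: the 3' terminal region (hairpin
    through motif plus a short downstream flank) on the candidate
    strand.
``<prefix>.5.fa``
    one FASTA record per 5' TC end (a candidate may have several, or
    none).
``<prefix>.full.fa``
    one record per candidate that has at least one 5' end: nearest 5'
    end through the 3' motif, i.e. the most conservative full-length
    guess.
``<prefix>.gff3``
    one feature per candidate spanning nearest 5' end to motif end
    (hairpin start when no 5' end exists), 1-based inclusive.

plus a one-row summary table (sequence count, total bases, Helitron
count, density).
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import EmptyInputError, FastaFormatError
from .scanner import (
    HelitronCandidate,
    ScanParameters,
    SequenceRecord,
    reverse_complement,
)

__all__ = ["read_fasta", "write_fasta", "write_outputs", "summarize"]

GFF_SOURCE = "heliscan"


def read_fasta(path: str) -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from a FASTA file.

    Record ids are the first whitespace-delimited header token and must
    be unique.  Raises FastaFormatError on duplicates and
    EmptyInputError if the file holds no records (raised when the
    generator is exhausted).
    """
    seen: set[str] = set()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        n += 1
        yield SequenceRecord(rec.id, str(rec.seq))
    if n == 0:
        raise EmptyInputError(f"no FASTA records in {path}")


def write_fasta(records: Iterable[SequenceRecord], path: str) -> None:
    """Write records as 60-column-wrapped FASTA."""
    SeqIO.write(
        (BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def _candidate_spans(c: HelitronCandidate) -> tuple[int, int]:
    """1-based inclusive GFF span: nearest 5' end to motif end, or hairpin
    start to motif end when no 5' end exists."""
    if c.strand == "+":
        motif = (c.end3_pos - 3, c.end3_pos)
    else:
        motif = (c.end3_pos, c.end3_pos + 3)
    hairpin = (c.hairpin.left_start + 1, c.hairpin.right_end)
    points = [*motif, *hairpin]
    if c.five_prime_positions:
        points.append(c.five_prime_positions[0])
    return min(points), max(points)


class _StrandView:
    """Candidate-strand slicing of one record (lazy reverse complement)."""

    def __init__(self, seq: str) -> None:
        self.fwd = seq.upper()
        self._rev: str | None = None

    @property
    def rev(self) -> str:
        if self._rev is None:
            self._rev = reverse_complement(self.fwd)
        return self._rev

    def slice(self, strand: str, start0: int, end0: int) -> str:
        """Scanned-strand slice [start0, end0) in scanned coordinates."""
        s = self.fwd if strand == "+" else self.rev
        return s[max(0, start0) : min(len(s), end0)]

    def scanned(self, strand: str, c: HelitronCandidate) -> tuple[int, int]:
        """(hairpin left_start 0-based, end3 1-based) on the scanned strand."""
        n = len(self.fwd)
        if strand == "+":
            return c.hairpin.left_start, c.end3_pos
        return n - c.hairpin.right_end, n - c.end3_pos + 1


def write_outputs(
    candidates: Sequence[HelitronCandidate],
    records: Iterable[SequenceRecord],
    p: ScanParameters | None = None,
    out_prefix: str = "heliscan_out",
    three_flank: int = 30,
    five_len: int = 30,
) -> dict[str, str]:
    """Write the four scan outputs; returns ``{kind: path}``.

    ``three_flank`` bases downstream of the motif are appended to each
    3'-terminus record when available; 5'-end records are ``five_len``
    bases starting at the TC.
    """
    p = p or ScanParameters()
    views = {r.id: _StrandView(r.seq) for r in records}
    by_seq: dict[str, list[HelitronCandidate]] = {}
    for c in candidates:
        by_seq.setdefault(c.seq_id, []).append(c)

    paths = {
        "three": f"{out_prefix}.3.txt",
        "five": f"{out_prefix}.5.fa",
        "full": f"{out_prefix}.full.fa",
        "gff": f"{out_prefix}.gff3",
    }
    os.makedirs(os.path.dirname(os.path.abspath(paths["gff"])), exist_ok=True)

    three: list[SequenceRecord] = []
    five: list[SequenceRecord] = []
    full: list[SequenceRecord] = []
    gff_lines = ["##gff-version 3"]

    for seq_id, view in views.items():
        cands = sorted(by_seq.get(seq_id, []), key=_candidate_spans)
        for c in cands:
            v = views[c.seq_id]
            n = len(v.fwd)
            hp_left, e3 = v.scanned(c.strand, c)
            three.append(
                SequenceRecord(c.id, v.slice(c.strand, hp_left, e3 + three_flank))
            )
            for i, fwd_pos in enumerate(c.five_prime_positions, start=1):
                t0 = fwd_pos - 1 if c.strand == "+" else n - fwd_pos
                five.append(
                    SequenceRecord(f"{c.id}.5.{i}", v.slice(c.strand, t0, t0 + five_len))
                )
            if c.five_prime_positions:
                fwd_pos = c.five_prime_positions[0]
                t0 = fwd_pos - 1 if c.strand == "+" else n - fwd_pos
                full.append(SequenceRecord(c.id, v.slice(c.strand, t0, e3)))
            start, end = _candidate_spans(c)
            attrs = ";".join(
                [
                    f"ID={c.id}",
                    f"end3_motif={c.end3_motif}",
                    f"hairpin_start={c.hairpin.left_start + 1}",
                    f"hairpin_end={c.hairpin.right_end}",
                    f"loop_len={c.hairpin.loop_len}",
                    f"n_five_prime={len(c.five_prime_positions)}",
                    f"target_site_ok={str(c.target_site_ok).lower()}",
                ]
            )
            gff_lines.append(
                "\t".join(
                    [
                        c.seq_id, GFF_SOURCE, "Helitron",
                        str(start), str(end), ".", c.strand, ".", attrs,
                    ]
                )
            )

    write_fasta(three, paths["three"])
    write_fasta(five, paths["five"])
    write_fasta(full, paths["full"])
    with open(paths["gff"], "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    return paths


def summarize(
    candidates: Sequence[HelitronCandidate],
    records: Iterable[SequenceRecord],
) -> pd.DataFrame:
    """One-row per-genome summary: sequences, bases, Helitrons, density.

    The Helitron count is the number of distinct 3' termini (candidates
    are already unique per (sequence, strand, end position)); density is
    the count divided by total length in Mb, N included.
    """
    n_seq = 0
    total = 0
    for r in records:
        n_seq += 1
        total += r.length
    if n_seq == 0:
        raise EmptyInputError("summarize received no records")
    n_hel = len(candidates)
    return pd.DataFrame(
        [
            {
                "n_sequences": n_seq,
                "total_bases": total,
                "n_helitrons": n_hel,
                "density": n_hel / (total / 1e6) if total else float("nan"),
            }
        ]
    )
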