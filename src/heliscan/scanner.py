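"""Structural scanner for Helitron 3' termini.

Helitrons are Class II (DNA) transposons that move by rolling-circle
replication.  Their 5' ends (a bare ``TC``) are poorly conserved and one
element may carry several of them, but the 3' end is a reliable
structural signature: a short GC-rich hairpin (inverted repeat arms of
6-20 nt around a small loop) followed, 2-10 nt downstream, by a
``CTRR`` terminal motif -- in practice almost always ``CTAG``.  The
scanner in this module detects that signature on both strands of
arbitrary nucleotide sequences and reports one candidate per distinct
3' terminus.

The 3' motif stringency is tiered by a *fuzzy level*:

====== =========== =======================================
level  motif       note
====== =========== =======================================
0      ``CTAGT``   canonical end plus the AT target-site T
1      ``CTAG``    default
2      ``CTRR``    R = A or G
3      ``CT..``    any two bases
====== =========== =======================================

Each stricter level matches a subset of the next looser one, so the
candidate set shrinks monotonically with stringency.

Coordinates are 0-based half-open internally (``HairpinMatch``); the
emitted 3'-terminus position (``end3_pos``) and 5'-end positions are
1-based on the forward strand of the parent record, matching GFF3
conventions downstream.
"""

from __future__ import annotations

import math
import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .errors import EmptyInputError, InvalidAlphabetError

__all__ = [
    "SequenceRecord",
    "ScanParameters",
    "HairpinMatch",
    "HelitronCandidate",
    "reverse_complement",
    "find_hairpins",
    "find_3prime_termini",
    "find_5prime_ends",
    "scan_genome",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BAD_CHAR = re.compile(r"[^ACGTNacgtn]")

#: 3' terminal motif by fuzzy level.  All levels share a 4-base core so that
#: ``end3_pos`` (last base of the core) is comparable across levels; level 0
#: additionally requires the target-site T directly after the core.
FUZZY_MOTIFS = {
    0: r"CTAG(?=T)",
    1: r"CTAG",
    2: r"CT[AG][AG]",
    3: r"CT[ACGT][ACGT]",
}
# lookahead wrapper yields overlapping matches (relevant at level 3)
_COMPILED = {k: re.compile(rf"(?=({v}))") for k, v in FUZZY_MOTIFS.items()}
_CORE_LEN = 4


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq`` (case preserved, N maps to N).

    Raises
    ------
    InvalidAlphabetError
        If any character is outside {A, C, G, T, N} (either case); the
        message names the 0-based position of the first offender.
    """
    m = _BAD_CHAR.search(seq)
    if m:
        raise InvalidAlphabetError(
            f"invalid character {m.group()!r} at position {m.start()}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (id = first token of a FASTA header)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ScanParameters:
    """Tunables of the structural scan.

    ``arm_gc_min`` is the minimum fraction of S (G/C) bases in a hairpin
    arm; arms must additionally begin and end with a run of at least
    ``arm_edge_s`` S bases, and the right arm must be the exact reverse
    complement of the left arm.  ``loop_min`` defaults to 2 because a
    shorter loop cannot physically close a stem-loop.
    ``upstream_window`` bounds how far upstream of a 3' terminus the 5'
    ``TC`` ends are searched.  ``require_target_site`` restricts 5' ends
    to ``TC`` preceded by ``A`` (the AT target-site); by default the
    target-site evidence is only reported as a flag, not filtered on.
    """

    fuzzy_level: int = 1
    arm_min: int = 6
    arm_max: int = 20
    loop_max: int = 10
    spacer_min: int = 2
    spacer_max: int = 10
    loop_min: int = 2
    upstream_window: int = 20000
    arm_gc_min: float = 0.8
    arm_edge_s: int = 2
    require_target_site: bool = False
    worker_count: int = 1

    def __post_init__(self) -> None:
        if self.fuzzy_level not in FUZZY_MOTIFS:
            raise ValueError(f"fuzzy_level must be one of {sorted(FUZZY_MOTIFS)}")
        if not (0 < self.arm_min <= self.arm_max):
            raise ValueError("require 0 < arm_min <= arm_max")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("require 0 <= spacer_min <= spacer_max")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("require 0 <= loop_min <= loop_max")
        if self.upstream_window <= 0:
            raise ValueError("upstream_window must be positive")
        if not (0.0 <= self.arm_gc_min <= 1.0):
            raise ValueError("arm_gc_min must be a fraction in [0, 1]")
        if not (1 <= self.arm_edge_s <= self.arm_min):
            raise ValueError("require 1 <= arm_edge_s <= arm_min")
        if self.worker_count < 1:
            raise ValueError("worker_count must be a positive integer")

    def min_arm_s(self, arm_len: int) -> int:
        """Minimum number of S bases required in an arm of ``arm_len``."""
        return math.ceil(self.arm_gc_min * arm_len)


@dataclass(frozen=True)
class HairpinMatch:
    """An inverted-repeat stem-loop; coordinates 0-based half-open on the
    strand the match is reported for (forward strand for candidates)."""

    left_start: int
    left_end: int
    loop_len: int
    right_start: int
    right_end: int
    arm_seq: str

    @property
    def arm_len(self) -> int:
        return self.left_end - self.left_start


@dataclass
class HelitronCandidate:
    """One putative Helitron 3' terminus.

    All coordinates refer to the forward strand of the parent record
    regardless of ``strand``.  ``end3_pos`` is the 1-based position of
    the last base of the 4-base terminal-motif core as read on the
    candidate strand (for minus-strand candidates this is the smallest
    forward coordinate of the motif).  ``five_prime_positions`` are
    1-based forward-strand positions of the T of candidate ``TC`` 5'
    ends, ordered nearest-to-the-3'-end first.
    """

    id: str
    seq_id: str
    strand: str
    hairpin: HairpinMatch
    end3_pos: int
    end3_motif: str
    five_prime_positions: list[int] = field(default_factory=list)
    target_site_ok: bool = False


def _valid_arm(seq: str, start: int, end: int, p: ScanParameters) -> bool:
    """Arm admissibility on a small slice (used by the generic hairpin scan)."""
    arm = seq[start:end]
    if "N" in arm:
        return False
    e = p.arm_edge_s
    if any(b not in "GC" for b in arm[:e]) or any(b not in "GC" for b in arm[-e:]):
        return False
    s = sum(1 for b in arm if b in "GC")
    return s >= p.min_arm_s(end - start)


def _hairpin_at(seq: str, left_start: int, p: ScanParameters) -> HairpinMatch | None:
    """Greedy hairpin anchored at a fixed left-arm start: longest admissible
    arm first, then shortest loop."""
    n = len(seq)
    max_a = min(p.arm_max, (n - left_start) // 2)
    for a in range(max_a, p.arm_min - 1, -1):
        left_end = left_start + a
        if not _valid_arm(seq, left_start, left_end, p):
            continue
        target = seq[left_start:left_end].translate(_COMPLEMENT)[::-1]
        top = min(p.loop_max, n - left_end - a)
        for loop in range(p.loop_min, top + 1):
            rs = left_end + loop
            if seq[rs : rs + a] == target:
                return HairpinMatch(left_start, left_end, loop, rs, rs + a,
                                    seq[left_start:left_end])
    return None


def find_hairpins(rec: SequenceRecord, p: ScanParameters | None = None) -> list[HairpinMatch]:
    """Non-overlapping GC-rich hairpins, left to right.

    Mimics a pattern-engine scan: the leftmost match wins, with the
    longest admissible arm and then the shortest admissible loop at that
    position; scanning resumes after the matched right arm.  Sequences
    shorter than ``2 * arm_min`` yield an empty list.
    """
    p = p or ScanParameters()
    seq = rec.seq.upper()
    n = len(seq)
    out: list[HairpinMatch] = []
    pos = 0
    limit = n - 2 * p.arm_min
    while pos <= limit:
        hit = _hairpin_at(seq, pos, p)
        if hit is None:
            pos += 1
            continue
        out.append(hit)
        pos = hit.right_end
    return out


def _scan_strand(seq: str, p: ScanParameters) -> list[tuple[HairpinMatch, int]]:
    """(hairpin, motif_core_start) pairings on one strand.

    ``seq`` must be uppercase.  One pairing is reported per motif
    occurrence that has an admissible hairpin upstream; the hairpin is
    chosen greedily (smallest spacer, then longest arm, then shortest
    loop).  The whole matched span (left arm through motif core, plus
    the level-0 target-site T) must be N-free.  Results are in ascending
    motif position, i.e. already deduplicated by 3'-end position.
    """
    n = len(seq)
    if n < 2 * p.arm_min + p.spacer_min + _CORE_LEN:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_s = (arr == 71) | (arr == 67)  # G / C
    s_byte = is_s.tobytes()  # fast scalar lookup
    cum_s = np.zeros(n + 1, dtype=np.int32)
    np.cumsum(is_s, out=cum_s[1:])
    need_s = [p.min_arm_s(a) for a in range(0, p.arm_max + 1)]

    out: list[tuple[HairpinMatch, int]] = []
    min_m = 2 * p.arm_min + p.spacer_min
    for match in _COMPILED[p.fuzzy_level].finditer(seq):
        m = match.start()
        if m < min_m:
            continue
        hit: HairpinMatch | None = None
        for spacer in range(p.spacer_min, p.spacer_max + 1):
            r = m - spacer  # right-arm end (half-open)
            if r < 2 * p.arm_min:
                break
            edge = p.arm_edge_s
            if cum_s[r] - cum_s[r - edge] < edge:
                continue
            for a in range(p.arm_max, p.arm_min - 1, -1):
                if r - 2 * a < 0:
                    continue
                if cum_s[r - a + edge] - cum_s[r - a] < edge:
                    continue
                if cum_s[r] - cum_s[r - a] < need_s[a]:
                    continue
                right = seq[r - a : r]
                if "N" in right:
                    continue
                left = right.translate(_COMPLEMENT)[::-1]
                base = r - 2 * a
                for loop in range(p.loop_min, min(p.loop_max, base) + 1):
                    ls = base - loop
                    if seq[ls : ls + a] == left:
                        hit = HairpinMatch(ls, ls + a, loop, r - a, r, left)
                        break
                if hit:
                    break
            if hit:
                break
        if hit is None:
            continue
        if "N" in seq[hit.left_start : m + _CORE_LEN]:
            continue
        out.append((hit, m))
    return out


def _map_hairpin_to_forward(hp: HairpinMatch, n: int) -> HairpinMatch:
    """Map a hairpin found on the reverse complement back to forward
    coordinates.  The structure is strand-symmetric: the scanned right arm
    becomes the forward left arm, and the forward left-arm sequence equals
    the scanned left-arm sequence."""
    return HairpinMatch(
        left_start=n - hp.right_end,
        left_end=n - hp.right_start,
        loop_len=hp.loop_len,
        right_start=n - hp.left_end,
        right_end=n - hp.left_start,
        arm_seq=hp.arm_seq,
    )


def _termini_from_strands(
    rec_id: str,
    fwd_seq: str,
    rev_seq: str,
    p: ScanParameters,
) -> list[HelitronCandidate]:
    n = len(fwd_seq)
    cands: list[HelitronCandidate] = []
    for k, (hp, m) in enumerate(_scan_strand(fwd_seq, p), start=1):
        cands.append(
            HelitronCandidate(
                id=f"{rec_id}H{k}",
                seq_id=rec_id,
                strand="+",
                hairpin=hp,
                end3_pos=m + _CORE_LEN,
                end3_motif=fwd_seq[m : m + _CORE_LEN],
            )
        )
    for k, (hp, m) in enumerate(_scan_strand(rev_seq, p), start=1):
        cands.append(
            HelitronCandidate(
                id=f"tr{rec_id}H{k}",
                seq_id=rec_id,
                strand="-",
                hairpin=_map_hairpin_to_forward(hp, n),
                end3_pos=n - (m + _CORE_LEN) + 1,
                end3_motif=rev_seq[m : m + _CORE_LEN],
            )
        )
    return cands


def find_3prime_termini(rec: SequenceRecord, p: ScanParameters | None = None) -> list[HelitronCandidate]:
    """Helitron 3'-terminus candidates on both strands (5' ends not yet
    attached).

    The forward strand is scanned first, then the reverse complement,
    with coordinates mapped back to the forward strand.  At most one
    candidate is reported per distinct (strand, 3'-end position).
    """
    p = p or ScanParameters()
    seq = rec.seq.upper()
    _validate(seq)
    return _termini_from_strands(rec.id, seq, seq.translate(_COMPLEMENT)[::-1], p)


def _validate(seq: str) -> None:
    m = _BAD_CHAR.search(seq)
    if m:
        raise InvalidAlphabetError(
            f"invalid character {m.group()!r} at position {m.start()}"
        )


def _attach_five_prime(
    cand: HelitronCandidate,
    fwd_seq: str,
    rev_seq: str,
    p: ScanParameters,
) -> HelitronCandidate:
    n = len(fwd_seq)
    if cand.strand == "+":
        s = fwd_seq
        e3 = cand.end3_pos  # 1-based on scanned strand
        hp_left = cand.hairpin.left_start
    else:
        s = rev_seq
        e3 = n - cand.end3_pos + 1
        hp_left = n - cand.hairpin.right_end
    lo = max(0, e3 - p.upstream_window)  # 0-based lower bound for the T
    positions: list[int] = []
    i = s.rfind("TC", lo, hp_left + 1)
    while i != -1:
        if not p.require_target_site or (i > 0 and s[i - 1] == "A"):
            positions.append(i)
        if i <= lo:
            break
        i = s.rfind("TC", lo, i + 1)
    # positions are 0-based on the scanned strand, nearest-first already
    end_t = e3 < n and s[e3] == "T"
    start_a = bool(positions) and positions[0] > 0 and s[positions[0] - 1] == "A"
    if cand.strand == "+":
        mapped = [t + 1 for t in positions]
    else:
        mapped = [n - t for t in positions]
    return replace(cand, five_prime_positions=mapped,
                   target_site_ok=end_t and start_a)


def find_5prime_ends(
    cand: HelitronCandidate,
    rec: SequenceRecord,
    p: ScanParameters | None = None,
) -> HelitronCandidate:
    """Populate a candidate's 5' ``TC`` start positions.

    Every ``TC`` on the candidate strand that starts upstream of the
    hairpin and within ``upstream_window`` of the 3' end is reported,
    nearest-to-the-3'-end first.  The candidate is kept even when the
    list is empty.  ``target_site_ok`` is set when the base directly 3'
    of the terminal motif is T and the base directly 5' of the nearest
    ``TC`` is A.
    """
    p = p or ScanParameters()
    seq = rec.seq.upper()
    return _attach_five_prime(cand, seq, seq.translate(_COMPLEMENT)[::-1], p)


def _scan_record(rec: SequenceRecord, p: ScanParameters) -> list[HelitronCandidate]:
    seq = rec.seq.upper()
    _validate(seq)
    rev = seq.translate(_COMPLEMENT)[::-1]
    cands = _termini_from_strands(rec.id, seq, rev, p)
    return [_attach_five_prime(c, seq, rev, p) for c in cands]


def scan_genome(
    records: Iterable[SequenceRecord],
    p: ScanParameters | None = None,
) -> list[HelitronCandidate]:
    """Scan every record for Helitron termini and attach 5' ends.

    Results are the concatenation of per-record candidate lists in input
    order (forward-strand candidates in ascending position, then
    reverse-strand candidates in reverse-complement scan order).  Output
    is identical for any ``worker_count``; parallel workers only split
    the records.

    Raises
    ------
    EmptyInputError
        If ``records`` yields nothing.
    """
    p = p or ScanParameters()
    it: Iterator[SequenceRecord] = iter(records)
    results: list[list[HelitronCandidate]] = []
    if p.worker_count == 1:
        for rec in it:
            results.append(_scan_record(rec, p))
    else:
        with ThreadPoolExecutor(max_workers=p.worker_count) as ex:
            results = list(ex.map(lambda r: _scan_record(r, p), it))
    if not results:
        raise EmptyInputError("scan_genome received no sequence records")
    return [c for sub in results for c in sub]
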