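"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration and
direct counting, sharing no code with the package implementation.
"""

from __future__ import annotations

import math
import re
from itertools import combinations

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _motif_ok(s: str, m: int, level: int) -> bool:
    core = s[m : m + 4]
    if len(core) < 4:
        return False
    if level == 0:
        return core == "CTAG" and m + 4 < len(s) and s[m + 4] == "T"
    if level == 1:
        return core == "CTAG"
    if level == 2:
        return re.fullmatch("CT[AG][AG]", core) is not None
    return re.fullmatch("CT[ACGT][ACGT]", core) is not None


def _arm_ok(arm: str, p) -> bool:
    if "N" in arm:
        return False
    e = p.arm_edge_s
    if any(b not in "GC" for b in arm[:e]) or any(b not in "GC" for b in arm[-e:]):
        return False
    return sum(b in "GC" for b in arm) >= math.ceil(p.arm_gc_min * len(arm))


def naive_termini(seq: str, p) -> set[tuple]:
    """Every (strand, forward end3_pos, hairpin) found by trying every
    (motif position, spacer, arm length, loop) combination; the hairpin
    recorded per terminus follows the same greedy preference the scanner
    documents (smallest spacer, longest arm, shortest loop)."""
    seq = seq.upper()
    n = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for m in range(n - 3):
            if not _motif_ok(s, m, p.fuzzy_level):
                continue
            chosen = None
            for spacer in range(p.spacer_min, p.spacer_max + 1):
                r = m - spacer
                for a in range(p.arm_max, p.arm_min - 1, -1):
                    for loop in range(p.loop_min, p.loop_max + 1):
                        ls = r - 2 * a - loop
                        if ls < 0 or r > m:
                            continue
                        left = s[ls : ls + a]
                        if not _arm_ok(left, p):
                            continue
                        if s[r - a : r] != revcomp(left):
                            continue
                        if "N" in s[ls : m + 4]:
                            continue
                        chosen = (ls, ls + a, loop, r - a, r)
                        break
                    if chosen:
                        break
                if chosen:
                    break
            if chosen is None:
                continue
            if strand == "+":
                end3 = m + 4
                hp = chosen
            else:
                end3 = n - (m + 4) + 1
                ls, le, loop, rs, re_ = chosen
                hp = (n - re_, n - rs, loop, n - le, n - ls)
            found.add((strand, end3, hp))
    return found


def count_rules(
    item_vectors: dict[str, list[bool]],
    consequents: list[str],
    min_support: float,
    min_confidence: float,
    min_lift: float,
    max_antecedent: int = 2,
) -> set[tuple]:
    """Direct-counting rule enumeration over boolean item columns.

    Returns {(antecedent tuple, consequent, support, confidence, lift)}
    rounded to 12 decimals for comparison.
    """
    n = len(next(iter(item_vectors.values())))
    loc_items = [k for k in item_vectors if k not in consequents]
    out = set()
    antecedents = [(i,) for i in loc_items]
    if max_antecedent >= 2:
        antecedents += [
            tuple(sorted(pair))
            for pair in combinations(loc_items, 2)
            if pair[0].rsplit("=", 1)[0] != pair[1].rsplit("=", 1)[0]
        ]
    for ant in antecedents:
        rows = [
            all(item_vectors[a][i] for a in ant) for i in range(n)
        ]
        n_ant = sum(rows)
        if n_ant == 0:
            continue
        for c in consequents:
            n_both = sum(r and item_vectors[c][i] for i, r in enumerate(rows))
            support = n_both / n
            confidence = n_both / n_ant
            p_cons = sum(item_vectors[c]) / n
            lift = confidence / p_cons if p_cons else float("inf")
            if support > min_support and confidence > min_confidence and lift > min_lift:
                out.add(
                    (ant, c, round(support, 12), round(confidence, 12), round(lift, 12))
                )
    return out
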