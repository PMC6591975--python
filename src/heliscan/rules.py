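"""Association-rule mining over insertion presence/absence and phenotype.

Transactions are ecotypes; items are locus states (``LOC006=1`` /
``LOC006=0``) plus exactly one phenotype item per ecotype
(``FT=late``).  Rules map an antecedent of one or two locus items to a
phenotype consequent, with the usual metrics

    support    = P(antecedent and consequent)
    confidence = support / P(antecedent)
    lift       = confidence / P(consequent)

Absence items are materialized explicitly so rules about missing
insertions are found too.  Thresholds are strict inequalities.  The
scale (tens of ecotypes, hundreds of loci) permits exhaustive
enumeration, which doubles as the correctness guarantee an
apriori-style pruned search would need to be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["TransactionSet", "RuleRecord", "mine_rules", "paired_rules"]


@dataclass(frozen=True)
class RuleRecord:
    """One rule ``antecedent -> consequent`` with its metrics."""

    antecedent: tuple[str, ...]
    consequent: str
    support: float
    confidence: float
    lift: float


class TransactionSet:
    """Binary item matrix over ecotypes with one phenotype item each."""

    def __init__(
        self,
        loc_table: pd.DataFrame,
        phenotype: pd.Series | Mapping[str, str],
        phenotype_name: str = "FT",
    ) -> None:
        """``loc_table``: rows = ecotypes, columns = loci, values 0/1.
        ``phenotype``: ecotype -> class label."""
        phenotype = pd.Series(phenotype)
        missing = [e for e in loc_table.index if e not in phenotype.index]
        if missing:
            raise SchemaError(f"no phenotype for ecotypes {missing}")
        self.ecotypes = list(loc_table.index)
        self.phenotype_name = phenotype_name
        items: dict[str, np.ndarray] = {}
        for loc in loc_table.columns:
            col = loc_table[loc].to_numpy()
            if not np.isin(col, (0, 1)).all():
                raise SchemaError(f"locus column {loc!r} is not binary")
            items[f"{loc}=1"] = col.astype(bool)
            items[f"{loc}=0"] = ~col.astype(bool)
        ph = phenotype.loc[self.ecotypes]
        self.classes = sorted(ph.unique())
        for cls in self.classes:
            items[f"{phenotype_name}={cls}"] = (ph == cls).to_numpy()
        self.items = items
        self.loc_items = [k for k in items if not k.startswith(phenotype_name + "=")]
        self.consequents = [f"{phenotype_name}={c}" for c in self.classes]

    @classmethod
    def from_loc_matrix(
        cls,
        loc_matrix,
        phenotype: Mapping[str, str],
        phenotype_name: str = "FT",
        use_loc_ids: bool = True,
    ) -> "TransactionSet":
        """Build transactions from a :class:`~heliscan.annotation.LocMatrix`,
        keeping only polymorphic loci and renaming them to their LOC ids."""
        t = loc_matrix.table.T  # ecotypes x marker genes
        if use_loc_ids:
            t = t[list(loc_matrix.loc_ids)].rename(columns=loc_matrix.loc_ids)
        return cls(t, phenotype, phenotype_name)

    def __len__(self) -> int:
        return len(self.ecotypes)


def _locus_of(item: str) -> str:
    return item.rsplit("=", 1)[0]


def mine_rules(
    t: TransactionSet,
    min_support: float = 0.1,
    min_confidence: float = 0.8,
    min_lift: float = 1.1,
    maxlen: int = 3,
) -> list[RuleRecord]:
    """Exhaustive rule search with phenotype consequents.

    Antecedents are all locus-item sets of size 1 to ``maxlen - 1``
    (item sets mixing the two states of one locus are contradictory and
    skipped).  A rule is returned when support, confidence and lift all
    *strictly* exceed their thresholds.  Rules are sorted by lift
    descending, then support descending, then antecedent lexicographic.
    """
    n = len(t)
    if n < 2:
        raise SchemaError("need at least two transactions")
    out: list[RuleRecord] = []
    cons_vec = {c: t.items[c] for c in t.consequents}
    cons_p = {c: v.mean() for c, v in cons_vec.items()}

    def _emit(items: tuple[str, ...], mask: np.ndarray) -> None:
        p_ant = mask.mean()
        if p_ant <= min_support:  # support(rule) <= support(antecedent)
            return
        for c, cvec in cons_vec.items():
            support = (mask & cvec).mean()
            if support <= min_support or p_ant == 0:
                continue
            confidence = support / p_ant
            if confidence <= min_confidence:
                continue
            lift = confidence / cons_p[c]
            if lift <= min_lift:
                continue
            out.append(RuleRecord(items, c, support, confidence, lift))

    single = {it: t.items[it] for it in t.loc_items}
    for it, vec in single.items():
        _emit((it,), vec)
    if maxlen - 1 >= 2:
        for a, b in combinations(t.loc_items, 2):
            if _locus_of(a) == _locus_of(b):
                continue
            _emit(tuple(sorted((a, b))), single[a] & single[b])
    out.sort(key=lambda r: (-r.lift, -r.support, r.antecedent))
    return out


def paired_rules(
    rules: Sequence[RuleRecord],
) -> list[tuple[str, RuleRecord, RuleRecord]]:
    """Loci whose presence *and* absence each support a passing rule.

    Only single-item antecedents participate.  Returns
    ``(locus, rule_for_absent, rule_for_present)`` triples sorted by
    locus; when several rules exist for one state the best-ranked one
    (input order) is kept.
    """
    by_state: dict[tuple[str, str], RuleRecord] = {}
    for r in rules:
        if len(r.antecedent) != 1:
            continue
        loc, _, state = r.antecedent[0].rpartition("=")
        if state not in ("0", "1"):
            continue
        by_state.setdefault((loc, state), r)
    loci = sorted({loc for loc, _ in by_state})
    return [
        (loc, by_state[(loc, "0")], by_state[(loc, "1")])
        for loc in loci
        if (loc, "0") in by_state and (loc, "1") in by_state
    ]


def rules_table(rules: Sequence[RuleRecord]) -> pd.DataFrame:
    """Rules as a table with left/right rule columns and metrics rounded
    to six decimals (the conventional printed precision)."""
    return pd.DataFrame(
        {
            "left_rule": [" & ".join(r.antecedent) for r in rules],
            "right_rule": [r.consequent for r in rules],
            "support": [round(float(r.support), 6) for r in rules],
            "confidence": [round(float(r.confidence), 6) for r in rules],
            "lift": [round(float(r.lift), 6) for r in rules],
        }
    )
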