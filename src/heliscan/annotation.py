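"""Insertion-site typing against gene annotation and locus markers.

A Helitron's placement is decided by its 3'-terminus position: inside a
CDS interval, inside a gene span but outside CDS (intron or UTR), or
intergenic.  Because different assemblies of one species do not share
physical coordinates, cross-ecotype comparison instead keys each
insertion to the nearest gene starting downstream of the 3' terminus;
the resulting presence/absence matrix over ecotypes ("LOC markers") is
the input of the association analysis.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .scanner import HelitronCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "InsertionCall",
    "LocMatrix",
    "read_gene_models",
    "classify_insertions",
    "insertion_summary",
    "nearest_downstream_gene",
    "build_loc_matrix",
]

CATEGORIES = ("CDS", "intron/UTR", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, CDS and exon intervals (1-based inclusive)."""

    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    cds: tuple[tuple[int, int], ...] = ()
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for s, e in self.cds:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS outside gene span")


@dataclass(frozen=True)
class InsertionCall:
    candidate_id: str
    category: str
    host_gene_id: str = ""


def read_gene_models(path: str, id_attr: str = "ID") -> list[GeneModel]:
    """Read gene models (gene spans + CDS intervals) from GFF3 or GTF.

    Uses an in-memory gffutils database; ``id_attr`` is the attribute
    naming genes in GFF3 (GTF files fall back to ``gene_id``).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = (g.attributes.get(id_attr) or g.attributes.get("gene_id") or [g.id])[0]
        cds = tuple(
            sorted((c.start, c.end) for c in db.children(g, featuretype="CDS"))
        )
        exons = tuple(
            sorted((e.start, e.end) for e in db.children(g, featuretype="exon"))
        )
        genes.append(
            GeneModel(gid, g.seqid, g.strand, g.start, g.end, cds, exons)
        )
    return genes


def _build_trees(genes: Iterable[GeneModel]):
    gene_trees: dict[str, IntervalTree] = {}
    cds_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.seqid, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        for s, e in g.cds:
            cds_trees.setdefault(g.seqid, IntervalTree()).addi(s, e + 1, g.gene_id)
    return gene_trees, cds_trees


def classify_insertions(
    candidates: Sequence[HelitronCandidate],
    genes: Sequence[GeneModel],
) -> list[InsertionCall]:
    """Assign each candidate a category by its 3'-end position.

    Overlap with any gene on either strand counts as genic.  Candidates
    on sequences absent from the annotation are logged and called
    intergenic by convention.
    """
    gene_trees, cds_trees = _build_trees(genes)
    known = set(gene_trees)
    calls: list[InsertionCall] = []
    warned: set[str] = set()
    for c in candidates:
        pos = c.end3_pos
        if c.seq_id not in known:
            if c.seq_id not in warned:
                logger.warning(
                    "sequence %r has no gene annotation; calling intergenic",
                    c.seq_id,
                )
                warned.add(c.seq_id)
            calls.append(InsertionCall(c.id, "intergenic"))
            continue
        cds_hit = cds_trees.get(c.seq_id, IntervalTree())[pos]
        if cds_hit:
            gid = sorted(iv.data for iv in cds_hit)[0]
            calls.append(InsertionCall(c.id, "CDS", gid))
            continue
        gene_hit = gene_trees[c.seq_id][pos]
        if gene_hit:
            gid = sorted(iv.data for iv in gene_hit)[0]
            calls.append(InsertionCall(c.id, "intron/UTR", gid))
        else:
            calls.append(InsertionCall(c.id, "intergenic"))
    return calls


def insertion_summary(calls: Sequence[InsertionCall]) -> pd.DataFrame:
    """Counts and percentages per category (one row per category).

    Percentages sum to 100; an empty input yields all-zero counts with
    NaN percentages (flagging that there is nothing to summarize).
    """
    counts = {cat: 0 for cat in CATEGORIES}
    for c in calls:
        counts[c.category] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "percent": [
                100.0 * counts[c] / total if total else float("nan")
                for c in CATEGORIES
            ],
        }
    )


def nearest_downstream_gene(
    cand: HelitronCandidate,
    genes: Sequence[GeneModel],
    max_distance: int = 500,
) -> str:
    """Marker gene of an insertion locus.

    The first gene on the candidate's sequence whose span starts at or
    after the 3'-end position (forward-strand reading), no farther than
    ``max_distance`` bases away; empty string when none qualifies.  The
    default distance mirrors the length of downstream flank used to
    anchor markers on assembled genomes.
    """
    starts = sorted(
        (g.start, g.gene_id) for g in genes if g.seqid == cand.seq_id
    )
    i = bisect_left(starts, (cand.end3_pos, ""))
    if i == len(starts):
        return ""
    start, gid = starts[i]
    return gid if start - cand.end3_pos <= max_distance else ""


@dataclass(frozen=True)
class LocMatrix:
    """Presence/absence of insertion loci across ecotypes.

    ``table``: 0/1 DataFrame, rows indexed by marker gene id, one column
    per ecotype.  ``loc_ids`` maps the marker genes of *polymorphic*
    loci (present in some but not all ecotypes) to LOC001... in sorted
    gene-id order.  ``shared`` lists all-1 loci.
    """

    table: pd.DataFrame
    loc_ids: dict[str, str]

    @property
    def polymorphic(self) -> list[str]:
        return list(self.loc_ids)

    @property
    def shared(self) -> list[str]:
        t = self.table
        return list(t.index[t.sum(axis=1) == t.shape[1]])


def build_loc_matrix(per_ecotype_markers: Mapping[str, set[str]]) -> LocMatrix:
    """Union the per-ecotype marker-gene sets into a 0/1 locus table.

    Rows are the sorted union of marker genes; polymorphic rows (neither
    all-0 nor all-1) get LOC ids in sorted gene-id order.
    """
    if len(per_ecotype_markers) < 2:
        raise ValueError("need at least two ecotypes")
    loci = sorted(set().union(*per_ecotype_markers.values()))
    ecotypes = list(per_ecotype_markers)
    table = pd.DataFrame(
        [
            [1 if loc in per_ecotype_markers[e] else 0 for e in ecotypes]
            for loc in loci
        ],
        index=pd.Index(loci, name="marker_gene"),
        columns=ecotypes,
        dtype=int,
    )
    sums = table.sum(axis=1)
    poly = [loc for loc in loci if 0 < sums[loc] < len(ecotypes)]
    loc_ids = {gene: f"LOC{i + 1:03d}" for i, gene in enumerate(poly)}
    return LocMatrix(table=table, loc_ids=loc_ids)
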