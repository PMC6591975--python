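"""Genome-characteristic statistics built on Helitron catalogues.

Helitron *density* -- the number of distinct 3' termini per Mb of
assembly -- is treated here as a genome-level characteristic: it is
stable across assemblies of one species while genome size and raw
counts vary, which makes the (genome size, density) plane usable for
species classification.  This module provides the density arithmetic,
dispersion summaries, seeded bootstrap correlation, sliding-window
density profiles, pooled-covariance linear discriminant classification,
median-linkage clustering and the chi-square test of insertion-site
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import DegenerateModelError, DomainError

__all__ = [
    "GenomeFeatureRow",
    "density",
    "dispersion",
    "pearson_bootstrap",
    "sliding_windows",
    "lda_classify",
    "median_cluster",
    "chisq_insertion_test",
]


@dataclass(frozen=True)
class GenomeFeatureRow:
    """(label, genome size Mb, Helitron count, density, optional group)."""

    label: str
    genome_size: float
    helitron_count: int
    density: float | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise DomainError("genome_size must be positive")
        if self.density is None:
            object.__setattr__(
                self, "density", self.helitron_count / self.genome_size
            )


def density(count: int, size_mb: float) -> float:
    """Helitron density in Helitrons per Mb: ``count / size_mb``.

    The count is the number of distinct 3' termini; tables downstream
    print the ratio to 4 decimals.
    """
    if size_mb <= 0:
        raise DomainError("genome size must be positive")
    if count < 0:
        raise DomainError("count must be non-negative")
    return count / size_mb


class Dispersion(NamedTuple):
    mean: float
    sd: float
    cv: float  # percent


def dispersion(values: Sequence[float], ddof: int = 1) -> Dispersion:
    """Mean, standard deviation and coefficient of variation (percent).

    Defaults to the sample standard deviation (n-1 divisor); ``ddof=0``
    gives the population form, which some published per-species
    aggregates use.  CV = SD / mean * 100.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("dispersion needs at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=ddof))
    if mean == 0:
        raise DomainError("coefficient of variation undefined for zero mean")
    return Dispersion(mean, sd, sd / mean * 100.0)


class PearsonBootstrap(NamedTuple):
    r: float
    p: float
    ci_low: float
    ci_high: float
    bca_low: float
    bca_high: float
    p_boot: float


def pearson_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 1234,
    confidence: float = 0.95,
) -> PearsonBootstrap:
    """Pearson correlation with parametric and BCa bootstrap intervals.

    ``r`` and ``p`` come from the product-moment correlation and its
    t-distribution test; ``ci_*`` is the Fisher-z confidence interval;
    ``bca_*`` is the bias-corrected accelerated interval from ``n_boot``
    seeded paired resamples.  The bootstrap p value is the doubled
    one-sided fraction of resampled r values on the far side of zero
    (the resampling analogue of a two-sided sign test of r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise DomainError("need at least three points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DomainError("missing values are not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for a constant vector")

    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence)

    rng = np.random.default_rng(seed)

    def _r(xs: np.ndarray, ys: np.ndarray) -> float:
        if np.std(xs) == 0 or np.std(ys) == 0:
            return np.nan
        return sps.pearsonr(xs, ys).statistic

    boot = sps.bootstrap(
        (x, y),
        _r,
        paired=True,
        vectorized=False,
        n_resamples=n_boot,
        confidence_level=confidence,
        method="BCa",
        random_state=rng,
    )
    dist = boot.bootstrap_distribution
    dist = dist[~np.isnan(dist)]
    if dist.size:
        frac_le = float(np.mean(dist <= 0))
        frac_ge = float(np.mean(dist >= 0))
        p_boot = min(1.0, 2.0 * min(frac_le, frac_ge))
    else:
        p_boot = np.nan
    return PearsonBootstrap(
        r=float(res.statistic),
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        bca_low=float(boot.confidence_interval.low),
        bca_high=float(boot.confidence_interval.high),
        p_boot=p_boot,
    )


def sliding_windows(
    candidates: Iterable,
    genes: Iterable,
    seq_lengths: Mapping[str, int],
    window: int = 1_000_000,
    step: int = 500_000,
) -> pd.DataFrame:
    """Per-window Helitron and gene counts (window 1 Mb, step 500 kb).

    A Helitron is counted in every window containing its 3'-end
    position; a gene in every window containing its start.  Windows are
    1-based inclusive, advance by ``step`` and the last partial window
    is retained.  ``candidates`` may be ``HelitronCandidate`` objects or
    ``(seqid, pos)`` pairs; ``genes`` may be ``GeneModel`` objects or
    ``(seqid, start)`` pairs.
    """
    def _points(items, attr_seq, attr_pos):
        pts: dict[str, list[int]] = {}
        for it in items:
            if isinstance(it, tuple):
                sid, pos = it
            else:
                sid = getattr(it, attr_seq)
                pos = getattr(it, attr_pos)
            pts.setdefault(sid, []).append(int(pos))
        return pts

    hel = _points(candidates, "seq_id", "end3_pos")
    gen = _points(genes, "seqid", "start")

    rows = []
    for sid, length in seq_lengths.items():
        h = np.sort(np.asarray(hel.get(sid, []), dtype=np.int64))
        g = np.sort(np.asarray(gen.get(sid, []), dtype=np.int64))
        start = 1
        while start <= length:
            end = min(start + window - 1, length)
            rows.append(
                {
                    "seqid": sid,
                    "window_start": start,
                    "window_end": end,
                    "n_helitrons": int(
                        np.searchsorted(h, end, "right")
                        - np.searchsorted(h, start, "left")
                    ),
                    "n_genes": int(
                        np.searchsorted(g, end, "right")
                        - np.searchsorted(g, start, "left")
                    ),
                }
            )
            start += step
    return pd.DataFrame(
        rows, columns=["seqid", "window_start", "window_end", "n_helitrons", "n_genes"]
    )


def _rows_to_xy(rows: Sequence[GenomeFeatureRow]) -> np.ndarray:
    return np.array([[r.genome_size, r.density] for r in rows], dtype=float)


def lda_classify(
    train: Sequence[GenomeFeatureRow],
    test: Sequence[GenomeFeatureRow],
) -> list[str]:
    """Classic pooled-covariance LDA on (genome size, density).

    Priors are class-proportional (estimated from the training rows).
    Returns the predicted class label for each test row; pass the
    training rows again as ``test`` for self-prediction.
    """
    labels = [r.class_label for r in train]
    if any(lb is None for lb in labels):
        raise DomainError("every training row needs a class_label")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DomainError("LDA needs at least two classes")
    X = _rows_to_xy(train)
    y = np.array(labels)
    # pooled within-class scatter must be non-singular for a meaningful fit
    scatter = np.zeros((2, 2))
    for c in classes:
        xc = X[y == c]
        if len(xc) > 1:
            scatter += (len(xc) - 1) * np.cov(xc, rowvar=False)
    if np.linalg.matrix_rank(scatter) < 2:
        raise DegenerateModelError(
            "pooled within-class covariance is singular; jitter the features "
            "or add replicate genomes"
        )
    model = LinearDiscriminantAnalysis(solver="svd")
    model.fit(X, y)
    return list(model.predict(_rows_to_xy(test)))


def median_cluster(rows: Sequence[GenomeFeatureRow]) -> np.ndarray:
    """Median-linkage (WPGMC) agglomeration on (genome size, density).

    Returns the SciPy linkage matrix (merge list with heights) computed
    from Euclidean distances.  Duplicate points are allowed and merge at
    height zero.
    """
    if len(rows) < 2:
        raise DomainError("clustering needs at least two rows")
    return linkage(_rows_to_xy(rows), method="median")


def chisq_insertion_test(
    observed: Sequence[float],
    expected_fractions: Sequence[float],
) -> tuple[float, int, float]:
    """Pearson chi-square of insertion counts against genome composition.

    ``observed`` are counts per category (CDS, intron/UTR, intergenic);
    ``expected_fractions`` are the genomic length fractions of the same
    categories and must sum to 1 with no zero cell.  Returns
    (statistic, degrees of freedom, p value).
    """
    obs = np.asarray(observed, dtype=float)
    frac = np.asarray(expected_fractions, dtype=float)
    if obs.shape != frac.shape:
        raise DomainError("observed and expected_fractions differ in length")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise DomainError("expected fractions must sum to 1")
    if (frac <= 0).any():
        raise DomainError("zero expected fraction gives an undefined test")
    stat, p = sps.chisquare(obs, f_exp=frac * obs.sum())
    return float(stat), obs.size - 1, float(p)
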