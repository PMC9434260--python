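"""Interval colocalization: overlaps, permutation enrichment, correlation.

QTL and eQTL support intervals (marker-snapped, closed) are compared as
genomic intervals; enrichment of observed overlaps is tested against a
null of uniformly placed random regions of matching number and mean
length on the same genome, and expression of colocalized eQTL is
correlated with the overlapping QTL's phenotype (Pearson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .cross import GeneticMap


@dataclass
class GenomicInterval:
    """Closed interval on the cM or bp axis."""

    chrom: str
    start: float
    end: float
    axis: str = "bp"  # "cM" | "bp"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.axis not in ("cM", "bp"):
            raise ValueError(f"unknown axis {self.axis!r}")

    @property
    def length(self) -> float:
        return self.end - self.start


def map_ci_to_physical(chrom, ci_start_cm: float, ci_end_cm: float,
                       gmap: GeneticMap, label: str = "") -> GenomicInterval:
    """cM support interval -> bp interval via the closest markers.

    Each endpoint becomes the bp position of the marker closest to it in
    cM (ties toward the lower-position marker); endpoints are re-ordered
    if needed.
    """
    sub = gmap.chrom_table(chrom)
    if "bp" not in sub.columns or sub["bp"].isna().any():
        raise ValueError(f"map lacks bp positions on chromosome {chrom!r}")
    lo = float(gmap.nearest_marker(chrom, ci_start_cm)["bp"])
    hi = float(gmap.nearest_marker(chrom, ci_end_cm)["bp"])
    if lo > hi:
        lo, hi = hi, lo
    return GenomicInterval(chrom=str(chrom), start=lo, end=hi, axis="bp", label=label)


def find_overlaps(set_a, set_b) -> list:
    """All (i, j) index pairs where A[i] and B[j] intersect.

    Closed-interval semantics: touching endpoints overlap.  Pairs must
    share a chromosome; mixing cM and bp intervals is an error.
    """
    axes = {iv.axis for iv in list(set_a) + list(set_b)}
    if len(axes) > 1:
        raise ValueError(f"mixed interval axes {sorted(axes)}")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(set_b):
        # half-open tree intervals: widen the end so closed touching matches
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, np.nextafter(iv.end, np.inf), j)
    pairs = []
    for i, iv in enumerate(set_a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, np.nextafter(iv.end, np.inf)):
            pairs.append((i, hit.data))
    return sorted(set(pairs))


@dataclass
class EnrichmentResult:
    """Observed overlap count against a random-placement null."""

    observed: int
    null_counts: np.ndarray
    pvalue: float
    parameters: dict = field(default_factory=dict)


def _place_random(rng, n_iv: int, length: float, chrom_lengths: np.ndarray,
                  chrom_cum: np.ndarray, size: int):
    """Uniform placement of ``n_iv`` intervals per iteration (``size`` iters).

    A start is drawn uniformly on the concatenated genome (chromosome
    chosen proportional to length); intervals running past a chromosome
    end are shifted back to fit.  Returns (chrom_idx, start, end) arrays
    of shape (size, n_iv).
    """
    total = chrom_cum[-1]
    u = rng.random((size, n_iv)) * total
    ci = np.searchsorted(chrom_cum, u, side="right")
    offset = np.concatenate([[0.0], chrom_cum])[ci]
    start = u - offset
    clen = chrom_lengths[ci]
    start = np.minimum(start, np.maximum(clen - length, 0.0))
    end = np.minimum(start + length, clen)
    # report on the concatenated axis: chromosome segments are disjoint, so
    # concatenated-coordinate intersection == same-chromosome intersection
    return ci, start + offset, end + offset


def _count_b_hit(ca, sa, ea, cb, sb, eb) -> np.ndarray:
    """Per-iteration count of B intervals overlapping >= 1 A interval.

    Coordinates are on the concatenated-genome axis, so intersection
    already implies a shared chromosome.
    """
    hit = np.zeros(sb.shape, dtype=bool)               # (iters, nB)
    for j in range(sa.shape[1]):
        hit |= (sa[:, j, None] <= eb) & (sb <= ea[:, j, None])
    return hit.sum(axis=1)


def enrichment_permutation(n_a: int, len_a: float, n_b: int, len_b: float,
                           genome: dict, observed: int, iterations: int = 10_000,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           count_rule: str = "b_any_a",
                           chunk: int = 500) -> EnrichmentResult:
    """Permutation enrichment test for interval-set overlap.

    Each iteration places ``n_a`` random regions of length ``len_a`` and
    ``n_b`` of length ``len_b`` uniformly on the genome (per-chromosome
    segments) and counts, under the default rule, the number of B
    intervals overlapping at least one A interval.  One-tailed
    p = (1 + #{null >= observed}) / (1 + iterations), never zero.
    """
    if iterations < 100:
        raise ValueError("use at least 100 iterations")
    if count_rule != "b_any_a":
        raise ValueError(f"unknown count_rule {count_rule!r}")
    if not 0 <= observed <= n_b:
        raise ValueError(f"observed count {observed} outside [0, {n_b}]")
    chrom_lengths = np.array([float(v) for v in genome.values()])
    if np.any(chrom_lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    span = chrom_lengths.max()
    if len_a > span or len_b > span:
        raise ValueError("mean interval length exceeds the largest chromosome")
    chrom_cum = np.cumsum(chrom_lengths)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(iterations, dtype=int)
    done = 0
    while done < iterations:
        c = min(chunk, iterations - done)
        ca, sa, ea = _place_random(rng, n_a, len_a, chrom_lengths, chrom_cum, c)
        cb, sb, eb = _place_random(rng, n_b, len_b, chrom_lengths, chrom_cum, c)
        null[done:done + c] = _count_b_hit(ca, sa, ea, cb, sb, eb)
        done += c
    p = (1.0 + np.sum(null >= observed)) / (1.0 + iterations)
    return EnrichmentResult(
        observed=int(observed), null_counts=null, pvalue=float(p),
        parameters={"n_a": n_a, "len_a": len_a, "n_b": n_b, "len_b": len_b,
                    "genome_length": float(chrom_lengths.sum()),
                    "iterations": iterations, "count_rule": count_rule,
                    "seed": seed},
    )


@dataclass
class CorrelationResult:
    """Pearson correlation of one (probe, trait) pair."""

    probe: str
    trait: str
    r: float
    pvalue: float
    n: int
    significant: bool


def trait_expression_correlation(expression: np.ndarray, phenotype: np.ndarray,
                                 probe: str = "", trait: str = "",
                                 alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with the two-sided t-test p (n - 2 df).

    Pairs with missing values are dropped; pairs with p < alpha are
    flagged significant (the retention rule of the reported pairs).
    """
    x = np.asarray(expression, float)
    y = np.asarray(phenotype, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one vector; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(probe=probe, trait=trait, r=float(res.statistic),
                             pvalue=float(res.pvalue), n=len(x),
                             significant=bool(res.pvalue < alpha))


def overlap_enrichment_from_sets(set_a, set_b, genome: dict,
                                 iterations: int = 10_000,
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None) -> EnrichmentResult:
    """Observed B-hit count from real interval sets + matched-null test."""
    pairs = find_overlaps(set_a, set_b)
    observed = len({j for _, j in pairs})
    len_a = float(np.mean([iv.length for iv in set_a])) if set_a else 0.0
    len_b = float(np.mean([iv.length for iv in set_b])) if set_b else 0.0
    return enrichment_permutation(len(set_a), len_a, len(set_b), len_b,
                                  genome, observed, iterations=iterations,
                                  seed=seed, rng=rng)
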