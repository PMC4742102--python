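"""Seed off-target detection by regression on 3'-UTR seed-complementary sites.

For every gene, siRNA activity is regressed on the presence (or count) of
sites complementary to each siRNA's seed in the gene's 3'-UTR; genes with a
significant negative estimate after Benjamini-Hochberg adjustment are
flagged as off-target candidates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SirnaRecord
from .seed_correction import DEFAULT_SEED_LENGTH, DEFAULT_SEED_START, extract_seed

log = logging.getLogger(__name__)

_RNA_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")


def seed_site(seed: str) -> str:
    """DNA site complementary to an RNA seed (reverse complement, U->A pairing)."""
    return seed.translate(_RNA_DNA_COMPLEMENT)[::-1]


def count_seed_matches(seed: str, utr: str) -> int:
    """Overlapping occurrences of the seed-complementary site in a DNA UTR.

    ``N`` never matches (site strings contain no N, so exact matching
    enforces this automatically).
    """
    if not 6 <= len(seed) <= 7:
        raise ValueError(f"seed length must be 6-7, got {len(seed)}")
    site = seed_site(seed)
    count = 0
    start = utr.find(site)
    while start != -1:
        count += 1
        start = utr.find(site, start + 1)
    return count


@dataclass
class SeedMatchMatrix:
    """siRNA x gene matrix of seed-complementary site counts."""

    sirna_ids: list[str]
    genes: list[str]
    counts: np.ndarray  # shape (n_sirnas, n_genes), nonnegative ints

    @property
    def binary(self) -> np.ndarray:
        return (self.counts >= 1).astype(np.int8)

    def count(self, sirna_id: str, gene: str) -> int:
        return int(self.counts[self.sirna_ids.index(sirna_id), self.genes.index(gene)])


def build_match_matrix(
    library: Sequence[SirnaRecord],
    utrs: Mapping[str, str],
    genes: Sequence[str] | None = None,
    restrict_seeds: set[str] | None = None,
    seed_start: int = DEFAULT_SEED_START,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> SeedMatchMatrix:
    """Count seed-complementary sites per (siRNA, gene).

    Rows are a pure function of the seed, so siRNAs sharing a seed have
    identical rows.  With ``restrict_seeds`` only those seeds contribute
    counts (rows of other siRNAs are zero) - the "most active seeds"
    pre-filter.  Genes without a UTR get a zero column with a warning.
    """
    if genes is None:
        genes = sorted(utrs)
    sirna_ids = [rec.sirna_id for rec in library]
    seeds = []
    for rec in library:
        if rec.seed is None:
            rec.seed = extract_seed(rec.guide_sequence, seed_start, seed_length)
        seeds.append(rec.seed)

    unique_seeds = sorted(set(seeds))
    active = unique_seeds if restrict_seeds is None else [s for s in unique_seeds if s in restrict_seeds]
    sites = {s: seed_site(s) for s in active}
    site_lengths = sorted({len(v) for v in sites.values()})

    seed_idx = {s: i for i, s in enumerate(unique_seeds)}
    per_seed = np.zeros((len(unique_seeds), len(genes)), dtype=np.int32)
    for j, gene in enumerate(genes):
        utr = utrs.get(gene)
        if utr is None:
            log.warning("gene %r has no UTR sequence; zero match column", gene)
            continue
        for L in site_lengths:
            kmer_counts = Counter(utr[i : i + L] for i in range(len(utr) - L + 1))
            for s in active:
                site = sites[s]
                if len(site) == L:
                    per_seed[seed_idx[s], j] = kmer_counts.get(site, 0)

    rows = np.array([seed_idx[s] for s in seeds])
    counts = per_seed[rows, :]
    return SeedMatchMatrix(sirna_ids=list(sirna_ids), genes=list(genes), counts=counts)


@dataclass
class HaystackResult:
    """Per-gene regression outcome of the off-target analysis."""

    gene: str
    estimate: float
    p_value: float
    q_value: float
    n_match: int
    is_candidate: bool = False


def select_active_seeds(
    corrected: Mapping[str, float],
    library: Sequence[SirnaRecord],
    percentile: float = 5.0,
    min_members: int = 2,
) -> set[str]:
    """Seeds whose group median activity lies below the given percentile.

    Groups with fewer than ``min_members`` siRNAs are never selected: a
    singleton's "group median" is its own activity, and conditioning the
    match predictor on the activity being regressed would bias every
    downstream estimate negative.
    """
    vals = np.array(list(corrected.values()), dtype=float)
    threshold = float(np.percentile(vals, percentile))
    by_seed: dict[str, list[float]] = {}
    for rec in library:
        if rec.seed is None:
            rec.seed = extract_seed(rec.guide_sequence)
        if rec.sirna_id in corrected:
            by_seed.setdefault(rec.seed, []).append(corrected[rec.sirna_id])
    return {
        s
        for s, v in by_seed.items()
        if len(v) >= min_members and float(np.median(v)) < threshold
    }


def haystack_regress(
    activities,
    matrix: SeedMatchMatrix,
    alpha: float = 0.05,
    predictor: str = "binary",
    min_group: int = 5,
) -> list[HaystackResult]:
    """Per-gene OLS of activity on the seed-match predictor.

    For the default binary predictor the slope equals the difference of
    group means (matched minus unmatched).  Genes with fewer than
    ``min_group`` matched or unmatched siRNAs are skipped with a warning.
    BH adjustment is applied across the tested genes; candidates have a
    negative estimate with ``q < alpha``.
    """
    if predictor not in ("binary", "count"):
        raise ValueError(f"unknown predictor {predictor!r}")
    if isinstance(activities, Mapping):
        amap = {k: float(v) for k, v in activities.items()}
    else:
        amap = {c.sirna_id: float(c.corrected) for c in activities}

    keep = [i for i, sid in enumerate(matrix.sirna_ids) if sid in amap]
    if len(keep) < 30:
        raise ValueError(f"haystack_regress needs >= 30 scored siRNAs, got {len(keep)}")
    if len(keep) < len(matrix.sirna_ids):
        log.warning(
            "%d siRNAs in the match matrix have no activity; dropped",
            len(matrix.sirna_ids) - len(keep),
        )
    a = np.array([amap[matrix.sirna_ids[i]] for i in keep])
    counts = matrix.counts[keep, :]
    binary = counts >= 1
    X = binary.astype(float) if predictor == "binary" else counts.astype(float)

    n = a.size
    n_match = binary.sum(axis=0)
    testable = (n_match >= min_group) & ((n - n_match) >= min_group)
    n_skipped = int((~testable).sum())
    if n_skipped:
        log.warning("%d genes skipped (fewer than %d matched or unmatched siRNAs)", n_skipped, min_group)

    Xt = X[:, testable]
    xbar = Xt.mean(axis=0)
    sxx = (Xt**2).sum(axis=0) - n * xbar**2
    abar = a.mean()
    sxa = Xt.T @ a - n * xbar * abar
    saa = float(np.sum(a**2) - n * abar**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxa / sxx
        rss = saa - slope * sxa
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(p), p, 1.0)

    if p.size == 0:
        return []
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")

    gene_names = [g for g, ok in zip(matrix.genes, testable) if ok]
    results = []
    for k, gene in enumerate(gene_names):
        results.append(
            HaystackResult(
                gene=gene,
                estimate=float(slope[k]),
                p_value=float(p[k]),
                q_value=float(q[k]),
                n_match=int(n_match[testable][k]),
                is_candidate=bool(slope[k] < 0 and q[k] < alpha),
            )
        )
    return results
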