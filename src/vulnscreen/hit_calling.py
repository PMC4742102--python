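"""Tail-model cutoffs, RSA gene ranking, hit selection and filters.

The corrected activity distribution is fit to a symmetric exponential-power
(generalized Gaussian) family, density proportional to
``exp(-|(x - mu)/alpha|**beta)``; the significance cutoff is the lower-tail
p-quantile of the fitted model (an exponential-tail mode is available as an
alternative).  Gene-level p-values come from the redundant-siRNA-activity
(RSA) rank statistic: for a gene whose siRNAs occupy ascending ranks
``r_1 < ... < r_n`` among ``N`` scored siRNAs, the reported p-value is the
minimum over ``i`` of ``P(X >= i)`` with ``X ~ Hypergeom(N, n, r_i)``.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .io_formats import ExpressionRecord, SirnaRecord, WellMeasurement
from .normalization import (
    normalize_verification,
    plate_normalize,
    robust_z_scores,
)
from .seed_correction import CorrectedActivity, group_by_seed, median_seed_correct

log = logging.getLogger(__name__)

#: RSA significance threshold used throughout: log10(0.05).
RSA_LOG10P_THRESHOLD = math.log10(0.05)  # -1.301...

#: Smoothing constants added before log2 transformation of expression values.
FPKM_PSEUDOCOUNT = 0.01
EXPECTED_COUNT_PSEUDOCOUNT = 0.6


# ---------------------------------------------------------------------------
# tail model
# ---------------------------------------------------------------------------

@dataclass
class TailModel:
    """Symmetric exponential-power fit plus descriptive sample moments."""

    location: float
    scale: float
    shape: float
    sample_skewness: float
    sample_excess_kurtosis: float
    neg_tail_scale: float = math.nan  # mean deviation below the location
    n: int = 0


def _profile_loglik(beta: float, absdev: np.ndarray) -> float:
    """Exponential-power log-likelihood profiled over the scale parameter."""
    n = absdev.size
    m = float(np.mean(absdev**beta))
    if m <= 0:
        return -np.inf
    alpha = (beta * m) ** (1.0 / beta)
    return n * (math.log(beta) - math.log(2.0) - math.log(alpha) - gammaln(1.0 / beta) - 1.0 / beta)


def fit_tail_model(corrected: Sequence[float] | np.ndarray) -> TailModel:
    """Fit location (median), scale and shape of the exponential-power family.

    The shape exponent is profiled on a coarse grid and refined by bounded
    scalar optimization; skewness and excess kurtosis are reported as
    descriptive diagnostics only.  Zero variance is a hard error.
    """
    x = np.asarray(corrected, dtype=float)
    if x.size < 3:
        raise ValueError(f"fit_tail_model needs >= 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("fit_tail_model: non-finite values")
    mu = float(np.median(x))
    absdev = np.abs(x - mu)
    if np.all(absdev == 0):
        raise ValueError("fit_tail_model: zero variance")

    grid = np.geomspace(0.3, 10.0, 40)
    lls = np.array([_profile_loglik(b, absdev) for b in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda b: -_profile_loglik(b, absdev), bounds=(lo, hi), method="bounded"
    )
    beta = float(res.x)
    alpha = float((beta * np.mean(absdev**beta)) ** (1.0 / beta))

    below = mu - x[x < mu]
    return TailModel(
        location=mu,
        scale=alpha,
        shape=beta,
        sample_skewness=float(stats.skew(x)),
        sample_excess_kurtosis=float(stats.kurtosis(x)),
        neg_tail_scale=float(np.mean(below)) if below.size else math.nan,
        n=int(x.size),
    )


def estimate_cutoff(model: TailModel, p: float = 0.05, mode: str = "quantile") -> float:
    """Lower-tail activity cutoff at significance level ``p``.

    ``quantile`` mode inverts the fitted exponential-power CDF.
    ``exponential_tail`` mode models deviations below the location as
    exponential with the fitted mean deviation, i.e. the cutoff ``c``
    solves ``0.5 * exp(-(location - c)/scale_neg) = p``.
    """
    if not 0 < p < 0.5:
        raise ValueError(f"p must be in (0, 0.5), got {p}")
    if not (model.scale > 0 and model.shape > 0):
        raise ValueError("estimate_cutoff: unfit tail model")
    if mode == "quantile":
        return float(stats.gennorm.ppf(p, model.shape, loc=model.location, scale=model.scale))
    if mode == "exponential_tail":
        if not math.isfinite(model.neg_tail_scale) or model.neg_tail_scale <= 0:
            raise ValueError("estimate_cutoff: no negative-tail scale in model")
        return float(model.location + model.neg_tail_scale * math.log(2.0 * p))
    raise ValueError(f"unknown cutoff mode {mode!r}")


def exponential_reference_moments(
    n_samples: int | None = None, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Skewness and excess kurtosis of the exponential reference distribution.

    With ``n_samples=None`` the closed-form moments are returned; otherwise
    they are estimated by Monte Carlo (rate 1; both moments are rate-free).
    """
    if n_samples is None:
        skew, exkurt = stats.expon.stats(moments="sk")
        return float(skew), float(exkurt)
    if rng is None:
        rng = np.random.default_rng()
    x = rng.exponential(size=int(n_samples))
    return float(stats.skew(x)), float(stats.kurtosis(x))


# ---------------------------------------------------------------------------
# RSA ranking
# ---------------------------------------------------------------------------

@dataclass
class GeneResult:
    """Per-gene screen outcome."""

    gene: str
    cell_line: str = ""
    rsa_log10p: float = 0.0
    best_activity: float = math.nan
    n_sirnas: int = 0
    is_hit: bool = False
    is_verified: bool = False
    passes_expression: bool = False
    log2_fpkm: float = math.nan


def _activity_map(corrected) -> dict[str, float]:
    if isinstance(corrected, Mapping):
        return {k: float(v) for k, v in corrected.items()}
    out = {}
    for c in corrected:
        if isinstance(c, CorrectedActivity):
            out[c.sirna_id] = float(c.corrected)
        else:
            out[c[0]] = float(c[1])
    return out


def rsa_rank(
    corrected,
    gene_map: Mapping[str, str],
    cell_line: str = "",
    genes: Iterable[str] | None = None,
) -> list[GeneResult]:
    """Gene-level RSA log10 p-values from ranked siRNA activities.

    Rank 1 is the most negative (most active) score; ties are broken by
    ``sirna_id`` for determinism.  Genes listed in ``genes`` but lacking any
    scored siRNA are excluded with a warning.
    """
    values = _activity_map(corrected)
    missing_gene = [sid for sid in values if sid not in gene_map]
    if missing_gene:
        raise ValueError(
            f"{len(missing_gene)} scored siRNAs missing from gene_map "
            f"(e.g. {sorted(missing_gene)[:3]})"
        )

    order = sorted(values, key=lambda sid: (values[sid], sid))
    N = len(order)
    ranks = {sid: i + 1 for i, sid in enumerate(order)}

    by_gene: dict[str, list[str]] = defaultdict(list)
    for sid in order:
        by_gene[gene_map[sid]].append(sid)

    if genes is not None:
        for g in genes:
            if g not in by_gene:
                log.warning("gene %r has no scored siRNAs; excluded from RSA", g)

    ln10 = math.log(10.0)
    results = []
    for gene, sids in by_gene.items():
        r = np.array(sorted(ranks[s] for s in sids))
        n = r.size
        i = np.arange(1, n + 1)
        # P(X >= i) with X ~ Hypergeom(population N, successes n, draws r_i)
        logsf = stats.hypergeom.logsf(i - 1, N, n, r)
        log10p = float(min(np.min(logsf) / ln10, 0.0))
        results.append(
            GeneResult(
                gene=gene,
                cell_line=cell_line,
                rsa_log10p=log10p,
                best_activity=float(min(values[s] for s in sids)),
                n_sirnas=int(n),
            )
        )
    results.sort(key=lambda gr: (gr.rsa_log10p, gr.gene))
    return results


def select_hits(
    results: Sequence[GeneResult],
    cutoff: float,
    log10p_threshold: float = RSA_LOG10P_THRESHOLD,
) -> list[GeneResult]:
    """Flag hits: significant RSA p-value AND one siRNA below the cutoff."""
    for gr in results:
        gr.is_hit = bool(gr.rsa_log10p < log10p_threshold and gr.best_activity < cutoff)
    return list(results)


def combine_across_lines(
    per_line_hits: Mapping[str, set], subgroups: Mapping[str, str]
) -> set[str]:
    """Candidate genes: hit in >= 2 lines of one subgroup, or in >= 3 lines."""
    unknown = set(per_line_hits) - set(subgroups)
    if unknown:
        raise ValueError(f"cell lines without subgroup assignment: {sorted(unknown)}")
    counts: dict[str, int] = defaultdict(int)
    sub_counts: dict[tuple[str, str], int] = defaultdict(int)
    for line, hits in per_line_hits.items():
        for gene in hits:
            counts[gene] += 1
            sub_counts[(gene, subgroups[line])] += 1
    candidates = {g for g, c in counts.items() if c >= 3}
    candidates.update(g for (g, _sub), c in sub_counts.items() if c >= 2)
    return candidates


def verify_genes(
    verification_viability: Mapping[str, float],
    gene_map: Mapping[str, str],
    cell_line: str = "",
    log10p_threshold: float = RSA_LOG10P_THRESHOLD,
) -> list[GeneResult]:
    """RSA on verification-screen relative viabilities (rank 1 = lowest).

    ``is_verified`` is set per cell line; callers combine lines with
    "verified in >= 1 line" semantics.
    """
    results = rsa_rank(dict(verification_viability), gene_map, cell_line=cell_line)
    for gr in results:
        gr.is_verified = bool(gr.rsa_log10p < log10p_threshold)
    return results


def expression_filter(
    genes: Sequence[GeneResult],
    expr: Iterable[ExpressionRecord],
    threshold: float = 0.0,
) -> list[GeneResult]:
    """Flag genes whose maximal expression reaches ``threshold`` (log2 FPKM).

    ``log2_fpkm = log2(max FPKM + 0.01)`` across the expression records of
    the gene (one record per cell line); genes absent from the table are
    treated as FPKM 0 with a warning.
    """
    best: dict[str, float] = {}
    for rec in expr:
        if rec.fpkm < 0:
            raise ValueError(f"gene {rec.gene!r}: negative FPKM {rec.fpkm}")
        best[rec.gene] = max(best.get(rec.gene, 0.0), rec.fpkm)
    for gr in genes:
        if gr.gene not in best:
            log.warning("gene %r absent from expression table; treated as FPKM 0", gr.gene)
        fpkm = best.get(gr.gene, 0.0)
        gr.log2_fpkm = math.log2(fpkm + FPKM_PSEUDOCOUNT)
        gr.passes_expression = bool(gr.log2_fpkm >= threshold)
    return list(genes)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    """Everything the discovery arm produces for one cell line."""

    results: list[GeneResult]
    tail_model: TailModel
    cutoff: float
    corrected: dict[str, float] = field(default_factory=dict)


def run_discovery(
    wells: Iterable[WellMeasurement],
    library: Sequence[SirnaRecord],
    cell_line: str = "",
    reference_role: str = "non_transfected",
    p_cutoff: float = 0.05,
    log10p_threshold: float = RSA_LOG10P_THRESHOLD,
    cutoff_mode: str = "quantile",
    seed_start: int = 2,
    seed_length: int = 6,
    min_group_size: int = 3,
    leave_one_out: bool = False,
    log_transform: bool = True,
    seed_correct: bool = True,
) -> DiscoveryResult:
    """Full discovery deconvolution for one cell line.

    plate normalization -> robust Z -> seed-median correction -> tail-model
    cutoff -> RSA ranking -> hit selection.
    """
    scores = plate_normalize(wells, reference_role=reference_role, cell_line=cell_line)
    known = {rec.sirna_id for rec in library}
    unknown = [s for s in scores if s.sirna_id not in known]
    if unknown:
        log.warning("%d library wells not in the annotation; dropped", len(unknown))
        scores = [s for s in scores if s.sirna_id in known]
    scores = robust_z_scores(scores, log_transform=log_transform)

    if seed_correct:
        groups = group_by_seed(library, start=seed_start, length=seed_length)
        corrected_list = median_seed_correct(
            scores, groups, min_group_size=min_group_size, leave_one_out=leave_one_out
        )
        corrected = {c.sirna_id: c.corrected for c in corrected_list}
    else:
        corrected = {s.sirna_id: s.robust_z for s in scores}

    model = fit_tail_model(list(corrected.values()))
    cutoff = estimate_cutoff(model, p=p_cutoff, mode=cutoff_mode)

    gene_map = {rec.sirna_id: rec.gene for rec in library}
    results = rsa_rank(corrected, gene_map, cell_line=cell_line)
    results = select_hits(results, cutoff, log10p_threshold=log10p_threshold)
    return DiscoveryResult(results=results, tail_model=model, cutoff=cutoff, corrected=corrected)


def run_verification(
    wells: Iterable[WellMeasurement],
    library: Sequence[SirnaRecord],
    cell_line: str = "",
    formula: str = "literal",
    log10p_threshold: float = RSA_LOG10P_THRESHOLD,
) -> list[GeneResult]:
    """Verification arm: control normalization followed by RSA."""
    viability = normalize_verification(wells, formula=formula)
    gene_map = {rec.sirna_id: rec.gene for rec in library}
    viability = {sid: v for sid, v in viability.items() if sid in gene_map}
    return verify_genes(viability, gene_map, cell_line=cell_line, log10p_threshold=log10p_threshold)
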