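"""hit_calling: tail model, cutoffs, RSA, selection and filters."""

import math

import numpy as np
import pytest
from scipy import stats

from vulnscreen import hit_calling as hc
from vulnscreen import synthetic_data as sd
from vulnscreen.io_formats import ExpressionRecord


# ---------------------------------------------------------------------------
# tail model
# ---------------------------------------------------------------------------

def test_fit_recovers_normal_shape(rng):
    m = hc.fit_tail_model(rng.normal(size=100_000))
    assert m.shape == pytest.approx(2.0, abs=0.15)
    assert m.sample_excess_kurtosis == pytest.approx(0.0, abs=0.1)
    assert m.sample_skewness == pytest.approx(0.0, abs=0.05)


def test_fit_recovers_laplace_shape(rng):
    m = hc.fit_tail_model(rng.laplace(size=100_000))
    assert m.shape == pytest.approx(1.0, abs=0.1)


def test_exponential_reference_moments_analytic():
    skew, exkurt = hc.exponential_reference_moments()
    assert skew == pytest.approx(2.0, abs=1e-12)
    assert exkurt == pytest.approx(6.0, abs=1e-12)
    # independent closed-form check straight from scipy
    s, k = stats.expon.stats(moments="sk")
    assert (float(s), float(k)) == (2.0, 6.0)


def test_fit_tail_model_zero_variance():
    with pytest.raises(ValueError, match="zero variance"):
        hc.fit_tail_model(np.ones(100))


# ---------------------------------------------------------------------------
# estimate_cutoff
# ---------------------------------------------------------------------------

def _model(loc, scale, shape, neg_tail=math.nan):
    return hc.TailModel(
        location=loc, scale=scale, shape=shape,
        sample_skewness=0.0, sample_excess_kurtosis=0.0,
        neg_tail_scale=neg_tail, n=1000,
    )


def test_cutoff_standard_normal_quantile():
    # gennorm with shape 2 and scale sqrt(2) is the standard normal
    c = hc.estimate_cutoff(_model(0.0, math.sqrt(2.0), 2.0), p=0.05)
    assert c == pytest.approx(-1.6449, abs=1e-4)


def test_cutoff_laplace_closed_form():
    c = hc.estimate_cutoff(_model(0.0, 1.0, 1.0), p=0.05)
    assert c == pytest.approx(math.log(0.1), abs=1e-9)


def test_cutoff_exponential_tail_mode_matches_laplace(rng):
    m = hc.fit_tail_model(rng.laplace(size=200_000))
    c = hc.estimate_cutoff(m, p=0.05, mode="exponential_tail")
    assert c == pytest.approx(math.log(0.1), abs=0.05)


def test_cutoff_quantile_recovery_within_5pct(rng):
    """Fitted cutoff on 1e5 exponential-power samples vs the true quantile."""
    beta = 0.75
    x = stats.gennorm.rvs(beta, size=100_000, random_state=rng)
    c = hc.estimate_cutoff(hc.fit_tail_model(x), p=0.05)
    true_q = stats.gennorm.ppf(0.05, beta)
    assert abs(c - true_q) / abs(true_q) < 0.05


def test_cutoff_heavy_tail_range_sanity(rng):
    """Heavy-tailed screens produce cutoffs in the low negative range."""
    x = stats.gennorm.rvs(1.2, scale=0.7, size=50_000, random_state=rng)
    c = hc.estimate_cutoff(hc.fit_tail_model(x), p=0.05)
    assert -3.0 < c < -0.5


def test_cutoff_rejects_bad_p():
    with pytest.raises(ValueError):
        hc.estimate_cutoff(_model(0.0, 1.0, 2.0), p=0.6)


def test_rsa_threshold_constant():
    assert hc.RSA_LOG10P_THRESHOLD == pytest.approx(-1.301, abs=5e-4)


# ---------------------------------------------------------------------------
# RSA
# ---------------------------------------------------------------------------

def _scores_from_ranks(rank_map):
    """Activity values whose ascending order realizes the requested ranks."""
    scores, gene_map = {}, {}
    for sid, (gene, rank) in rank_map.items():
        scores[sid] = float(rank)  # rank 1 = most negative
        gene_map[sid] = gene
    return scores, gene_map


def test_rsa_single_sirna_rank1():
    # N=10, one siRNA of gene A at rank 1 -> p = 1 - C(9,1)/C(10,1) = 0.1
    rank_map = {f"s{i}": (f"F{i}", i + 1) for i in range(1, 10)}
    rank_map["sA"] = ("A", 1)
    scores, gene_map = _scores_from_ranks(rank_map)
    results = {r.gene: r for r in hc.rsa_rank(scores, gene_map)}
    assert results["A"].rsa_log10p == pytest.approx(-1.0, abs=1e-12)


def test_rsa_worst_ranks_give_p_one():
    # N=4, gene with siRNAs at ranks {3,4} -> p = 1, log10p = 0
    rank_map = {"f1": ("F1", 1), "f2": ("F2", 2), "a1": ("A", 3), "a2": ("A", 4)}
    scores, gene_map = _scores_from_ranks(rank_map)
    results = {r.gene: r for r in hc.rsa_rank(scores, gene_map)}
    assert results["A"].rsa_log10p == 0.0


def test_rsa_matches_bruteforce_on_random_screens(rng, rsa_oracle):
    for _ in range(60):
        n_total = int(rng.integers(6, 21))
        n_genes = int(rng.integers(2, max(3, n_total // 2)))
        genes = [f"g{i}" for i in rng.integers(0, n_genes, size=n_total)]
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=n_total))}
        gene_map = {f"s{i}": genes[i] for i in range(n_total)}
        results = hc.rsa_rank(scores, gene_map)

        order = sorted(scores, key=lambda s: (scores[s], s))
        ranks = {s: i + 1 for i, s in enumerate(order)}
        for r in results:
            expect = rsa_oracle(
                [ranks[s] for s in scores if gene_map[s] == r.gene], n_total
            )
            assert r.rsa_log10p == pytest.approx(expect, rel=1e-9, abs=1e-9)


def test_rsa_monotone_in_rank(rsa_oracle):
    """Moving a gene's siRNA to a better rank never increases the p-value."""
    n_total = 15
    for r1 in range(2, 10):
        better = rsa_oracle([r1 - 1, 12], n_total)
        worse = rsa_oracle([r1, 12], n_total)
        assert better <= worse + 1e-12


def test_rsa_p_in_unit_interval(rng):
    scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
    gene_map = {f"s{i}": f"g{i % 50}" for i in range(200)}
    for r in hc.rsa_rank(scores, gene_map):
        assert r.rsa_log10p <= 0.0
        assert math.isfinite(r.rsa_log10p)


def test_rsa_best_activity_and_counts():
    scores = {"a1": -3.0, "a2": -1.0, "b1": 0.5}
    gene_map = {"a1": "A", "a2": "A", "b1": "B"}
    results = {r.gene: r for r in hc.rsa_rank(scores, gene_map)}
    assert results["A"].best_activity == -3.0
    assert results["A"].n_sirnas == 2
    assert results["B"].n_sirnas == 1


def test_rsa_warns_on_gene_without_sirnas(caplog):
    scores = {"a1": -1.0, "a2": 0.0, "b1": 1.0}
    gene_map = {"a1": "A", "a2": "A", "b1": "B"}
    with caplog.at_level("WARNING"):
        hc.rsa_rank(scores, gene_map, genes=["A", "B", "GHOST"])
    assert "GHOST" in caplog.text


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def _gr(gene, log10p, best):
    return hc.GeneResult(gene=gene, rsa_log10p=log10p, best_activity=best, n_sirnas=2)


def test_select_hits_rule_conjunction():
    cutoff = -1.5
    results = [
        _gr("A", -2.0, -1.0),   # significant p, weak activity -> no
        _gr("B", -1.2, -3.0),   # strong activity, weak p -> no
        _gr("C", -1.5, -3.0),   # both -> yes
    ]
    hc.select_hits(results, cutoff)
    assert [r.is_hit for r in results] == [False, False, True]


SUBGROUPS = {"M1": "MNA", "M2": "MNA", "N1": "non", "N2": "non"}


def test_combine_both_lines_of_subgroup():
    hits = {"M1": {"g"}, "M2": {"g"}, "N1": set(), "N2": set()}
    assert hc.combine_across_lines(hits, SUBGROUPS) == {"g"}


def test_combine_split_pair_not_candidate():
    hits = {"M1": {"g"}, "M2": set(), "N1": {"g"}, "N2": set()}
    assert hc.combine_across_lines(hits, SUBGROUPS) == set()


def test_combine_three_of_four_lines():
    hits = {"M1": {"g"}, "M2": set(), "N1": {"g"}, "N2": {"g"}}
    assert hc.combine_across_lines(hits, SUBGROUPS) == {"g"}


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def _verification_screen(n_sirnas=639, top_gene_sirnas=3):
    """Viabilities placing one gene's siRNAs at the very top of the ranking."""
    viability, gene_map = {}, {}
    for i in range(top_gene_sirnas):
        viability[f"top_{i}"] = 0.001 * (i + 1)
        gene_map[f"top_{i}"] = "TOPGENE"
    for i in range(n_sirnas - top_gene_sirnas):
        viability[f"bg_{i}"] = 0.5 + 0.0005 * i
        gene_map[f"bg_{i}"] = f"BG{i // 3}"
    return viability, gene_map


def test_verify_top_ranked_gene(rsa_oracle):
    viability, gene_map = _verification_screen()
    results = {r.gene: r for r in hc.verify_genes(viability, gene_map)}
    assert results["TOPGENE"].is_verified
    expect = rsa_oracle([1, 2, 3], 639)
    assert results["TOPGENE"].rsa_log10p == pytest.approx(expect, rel=1e-9)


def test_verify_scattered_gene_not_verified(rng, rsa_oracle):
    n = 639
    viability = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(size=n))}
    gene_map = {f"s{i}": f"g{i % 213}" for i in range(n)}
    results = hc.verify_genes(viability, gene_map)
    order = sorted(viability, key=lambda s: (viability[s], s))
    ranks = {s: i + 1 for i, s in enumerate(order)}
    # spot-check agreement with the oracle and that the typical gene fails
    n_verified = sum(r.is_verified for r in results)
    assert n_verified < 0.2 * len(results)
    some = results[len(results) // 2]
    expect = rsa_oracle(
        [ranks[s] for s in viability if gene_map[s] == some.gene], n
    )
    assert some.rsa_log10p == pytest.approx(expect, rel=1e-9)


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def test_expression_filter_zero_fpkm_smoothing():
    genes = [_gr("A", -2.0, -2.0)]
    hc.expression_filter(genes, [ExpressionRecord("A", 0.0)], threshold=0.0)
    assert genes[0].log2_fpkm == pytest.approx(math.log2(0.01), abs=1e-9)
    assert genes[0].log2_fpkm == pytest.approx(-6.644, abs=1e-3)
    assert not genes[0].passes_expression


def test_expression_filter_61_to_58():
    """61 verified genes, exactly 3 low-expressed -> 58 retained."""
    low = {"GABRD", "TINAGL1", "KIF2B"}
    names = sorted(low) + [f"V{i}" for i in range(58)]
    genes = [_gr(g, -2.0, -2.0) for g in names]
    expr = [ExpressionRecord(g, 0.0 if g in low else 12.0) for g in names]
    hc.expression_filter(genes, expr, threshold=0.0)
    retained = [g.gene for g in genes if g.passes_expression]
    assert len(retained) == 58
    assert low.isdisjoint(retained)


def test_expression_filter_identity_when_all_expressed():
    genes = [_gr("A", -2.0, -2.0), _gr("B", -2.0, -2.0)]
    expr = [ExpressionRecord("A", 5.0), ExpressionRecord("B", 7.0)]
    hc.expression_filter(genes, expr, threshold=0.0)
    assert all(g.passes_expression for g in genes)


def test_expression_filter_max_over_cell_lines():
    genes = [_gr("A", -2.0, -2.0)]
    expr = [
        ExpressionRecord("A", 0.0, cell_line="L1"),
        ExpressionRecord("A", 8.0, cell_line="L2"),
    ]
    hc.expression_filter(genes, expr, threshold=0.0)
    assert genes[0].log2_fpkm == pytest.approx(math.log2(8.01))
    assert genes[0].passes_expression


def test_expression_filter_missing_gene_warns(caplog):
    genes = [_gr("NOWHERE", -2.0, -2.0)]
    with caplog.at_level("WARNING"):
        hc.expression_filter(genes, [], threshold=0.0)
    assert "NOWHERE" in caplog.text
    assert genes[0].log2_fpkm == pytest.approx(math.log2(0.01))


# ---------------------------------------------------------------------------
# pipeline smoke
# ---------------------------------------------------------------------------

def test_run_discovery_recovers_planted_hits():
    lib = sd.gen_library(400, 2, rng_seed=5)
    genes = sorted({r.gene for r in lib})
    hits = {g: -4.0 for g in genes[:5]}
    truth = sd.make_discovery_truth(hits, {}, n_plates=3, rng_seed=5)
    wells = sd.simulate_discovery(lib, truth, noise_sd=0.5)
    res = hc.run_discovery(wells, lib, cell_line="L1")
    called = {r.gene for r in res.results if r.is_hit}
    assert set(hits) <= called
    assert res.cutoff < 0
    assert res.tail_model.scale > 0
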