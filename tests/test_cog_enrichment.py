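import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import erosionscan as es
from erosionscan.cog_enrichment import ContingencyTable, DegenerateTableError


def _table(counts):
    cats = sorted(counts)
    return ContingencyTable(cats, {c: tuple(counts[c]) for c in cats})


# ---------------------------------------------------------------------------
# build_table
# ---------------------------------------------------------------------------

def test_build_table_partitions_and_excludes():
    feats = [es.Feature(f"l{i}", "chr", 10 * i, 10 * i + 9, "+", "CDS",
                        cog_category="L") for i in range(10)]
    feats += [es.Feature(f"lp{i}", "chr", 200 + 10 * i, 209 + 10 * i, "+",
                         "pseudogene", cog_category="L") for i in range(10)]
    feats += [es.Feature(f"j{i}", "chr", 400 + 10 * i, 409 + 10 * i, "+",
                         "CDS", cog_category="J") for i in range(20)]
    feats += [es.Feature("nocat", "chr", 700, 709, "+", "CDS")]
    table = es.build_table(es.FeatureSet(feats))
    assert table.counts == {"J": (20, 0), "L": (10, 10)}
    assert table.n_excluded == 1


def test_build_table_needs_two_categories():
    with pytest.raises(DegenerateTableError):
        es.build_table(es.FeatureSet())
    only_l = es.FeatureSet([es.Feature("a", "chr", 0, 9, "+", "CDS",
                                       cog_category="L")])
    with pytest.raises(DegenerateTableError):
        es.build_table(only_l)


# ---------------------------------------------------------------------------
# Pearson statistic
# ---------------------------------------------------------------------------

def test_proportional_table_has_zero_statistic():
    stat, df = es.pearson_chisq(_table({"J": (10, 10), "L": (20, 20)}))
    assert stat == pytest.approx(0.0)
    assert df == 1


def test_diagonal_table_hand_computed():
    # (10,0; 0,10): every cell deviates by 5 from expectation 5 -> 4 * 5 = 20
    stat, _ = es.pearson_chisq(_table({"a": (10, 0), "b": (0, 10)}))
    assert stat == pytest.approx(20.0)


def test_statistic_matches_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(100):
        k = int(rng.integers(2, 8))
        counts = {}
        for i in range(k):
            counts[f"c{i}"] = (int(rng.integers(1, 50)),
                               int(rng.integers(1, 50)))
        table = _table(counts)
        stat, df = es.pearson_chisq(table)
        ref_stat, _, ref_df, _ = chi2_contingency(table.as_array(),
                                                  correction=False)
        assert stat == pytest.approx(ref_stat)
        assert df == ref_df


def test_zero_column_total_is_degenerate():
    with pytest.raises(DegenerateTableError):
        es.pearson_chisq(_table({"a": (10, 0), "b": (20, 0)}))


def test_residual_squares_sum_to_statistic():
    table = _table({"a": (13, 4), "b": (5, 19), "c": (30, 2)})
    stat, _ = es.pearson_chisq(table)
    obs = table.as_array()
    exp = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / obs.sum()
    resid = (obs - exp) / np.sqrt(exp)
    assert (resid ** 2).sum() == pytest.approx(stat)
    result = es.simulated_pvalue(table, B=10, seed=0)
    for i, c in enumerate(table.categories):
        assert result.residuals[c] == pytest.approx(resid[i, 1])


# ---------------------------------------------------------------------------
# Simulated p-value
# ---------------------------------------------------------------------------

def test_p_floor_with_zero_exceedances():
    """An observed statistic beyond every replicate gives the add-one floor
    1/2001 = 0.0004998 at B = 2000."""
    result = es.simulated_pvalue(_table({"a": (50, 0), "b": (0, 50)}),
                                 B=2000, seed=1)
    assert result.b_exceed == 0
    assert result.p_simulated == pytest.approx(1 / 2001)
    assert float(f"{result.p_simulated:.4g}") == 0.0004998


def test_proportional_table_p_is_one():
    result = es.simulated_pvalue(_table({"a": (10, 10), "b": (20, 20)}),
                                 B=500, seed=2)
    assert result.statistic == pytest.approx(0.0)
    assert result.p_simulated == pytest.approx(1.0)


def test_p_range_and_reproducibility():
    table = _table({"a": (9, 3), "b": (4, 8), "c": (7, 7)})
    r1 = es.simulated_pvalue(table, B=999, seed=7)
    r2 = es.simulated_pvalue(table, B=999, seed=7)
    assert r1.p_simulated == r2.p_simulated
    assert 1 / 1000 <= r1.p_simulated <= 1.0


def test_replicates_preserve_both_margins():
    table = _table({"a": (9, 3), "b": (4, 8), "c": (7, 7)})
    result = es.simulated_pvalue(table, B=200, seed=3, keep_replicates=True)
    rep = result.replicate_tables  # (B, k, 2)
    obs = table.as_array()
    assert (rep.sum(axis=2) == obs.sum(axis=1)).all()
    assert (rep.sum(axis=1) == obs.sum(axis=0)).all()


def _exact_permutation_p(table):
    """Exhaustive multivariate-hypergeometric null on a tiny table."""
    obs = table.as_array()
    n_per_cat = obs.sum(axis=1).astype(int)
    P = int(obs[:, 1].sum())
    N = int(obs.sum())
    stat_obs, _ = es.pearson_chisq(table)
    exp = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / N
    total = 0.0
    p = 0.0
    for ks in itertools.product(*(range(min(n, P) + 1) for n in n_per_cat)):
        if sum(ks) != P:
            continue
        prob = math.prod(math.comb(n, k) for n, k in zip(n_per_cat, ks)) \
            / math.comb(N, P)
        tab = np.array([[n - k, k] for n, k in zip(n_per_cat, ks)], float)
        stat = ((tab - exp) ** 2 / exp).sum()
        total += prob
        if stat >= stat_obs - 1e-12:
            p += prob
    assert total == pytest.approx(1.0)
    return p


def test_monte_carlo_agrees_with_exhaustive_enumeration():
    """MC p at B = 1e5 lies within the binomial 99% CI of the exact
    permutation p on an enumerable table (total n = 8)."""
    table = _table({"a": (3, 1), "b": (1, 3)})
    p_exact = _exact_permutation_p(table)
    B = 100_000
    result = es.simulated_pvalue(table, B=B, seed=11)
    se = math.sqrt(p_exact * (1 - p_exact) / B)
    assert abs(result.p_simulated - p_exact) < 2.58 * se + 2 / B


def test_b_must_be_positive():
    with pytest.raises(ValueError):
        es.simulated_pvalue(_table({"a": (1, 1), "b": (1, 1)}), B=0, seed=0)


# ---------------------------------------------------------------------------
# Residual report
# ---------------------------------------------------------------------------

def test_skewed_category_has_largest_residual(called_bundle):
    """The generator inflates pseudogene odds for category L fourfold; L
    must top the pseudogene-overrepresentation ranking."""
    table = es.build_table(called_bundle.called)
    result = es.simulated_pvalue(table, B=2000, seed=5)
    ranking = es.residual_report(result)
    assert ranking[0][0] == "L"
    assert ranking[0][1] > 0


def test_proportional_residuals_all_zero():
    result = es.simulated_pvalue(_table({"a": (10, 10), "b": (20, 20)}),
                                 B=10, seed=0)
    assert all(v == pytest.approx(0.0) for v in result.residuals.values())
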