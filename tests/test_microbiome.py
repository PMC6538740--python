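"""Alpha-diversity estimators and rank-sum differential abundance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.microbiome import (
    CountTable,
    abundance_summary,
    ace,
    alpha_diversity,
    chao1,
    diff_abundance,
    kruskal_multigroup,
    shannon,
    wilcoxon_rank_sum,
)
from netpharm.simulate import SimulationSpec, gen_otu_table

# -- Shannon -----------------------------------------------------------------


def test_shannon_uniform_is_log_richness():
    assert shannon([5] * 8) == pytest.approx(math.log(8))


def test_shannon_single_taxon_is_zero():
    assert shannon([42]) == 0.0


def test_shannon_hand_worked():
    # -(0.25 ln 0.25 * 2 + 0.5 ln 0.5) = 1.5 ln 2
    assert shannon([1, 1, 2]) == pytest.approx(1.5 * math.log(2))


def test_shannon_log2_flag():
    assert shannon([5] * 8, base=2) == pytest.approx(3.0)


def test_shannon_all_zero_raises():
    with pytest.raises(ValueError):
        shannon([0, 0])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(0, 50), min_size=1, max_size=30).filter(lambda x: sum(x) > 0),
    st.integers(2, 5),
)
def test_shannon_bounds_and_count_scaling_invariance(counts, factor):
    h = shannon(counts)
    s_obs = sum(1 for c in counts if c > 0)
    assert -1e-12 <= h <= math.log(s_obs) + 1e-12
    assert shannon([c * factor for c in counts]) == pytest.approx(h)


# -- Chao1 / ACE -------------------------------------------------------------


def test_chao1_no_singletons_equals_observed():
    assert chao1([2, 3, 4]) == 3.0


def test_chao1_hand_worked_both_variants():
    # counts (1,1,2): S_obs=3, F1=2, F2=1
    assert chao1([1, 1, 2], bias_corrected=False) == pytest.approx(5.0)
    assert chao1([1, 1, 2], bias_corrected=True) == pytest.approx(3.5)


def test_ace_all_abundant_equals_observed():
    assert ace([11, 12, 50]) == 3.0


def test_ace_all_singletons_falls_back_to_chao1():
    with pytest.warns(UserWarning, match="Chao1"):
        got = ace([1, 1, 12])
    assert got == pytest.approx(chao1([1, 1, 12]))


def _ace_oracle(counts, cutoff=10):
    """Straight transcription of the estimator as an independent check."""
    x = np.asarray(counts)
    x = x[x > 0]
    rare = x[x <= cutoff]
    s_abund = int((x > cutoff).sum())
    if rare.size == 0:
        return float(x.size)
    n_rare = rare.sum()
    f1 = int((x == 1).sum())
    c = 1 - f1 / n_rare
    ssum = sum(i * (i - 1) * int((x == i).sum()) for i in range(1, cutoff + 1))
    g2 = max(rare.size * ssum / (c * n_rare * (n_rare - 1)) - 1, 0) if n_rare > 1 else 0.0
    return s_abund + rare.size / c + f1 / c * g2


def test_ace_matches_independent_transcription_on_random_samples():
    rng = np.random.default_rng(8)
    for _ in range(50):
        counts = rng.geometric(0.15, size=int(rng.integers(5, 40)))
        if (counts[counts <= 10] == 1).all() and (counts <= 10).any():
            continue  # degenerate fallback case tested separately
        assert ace(counts) == pytest.approx(_ace_oracle(counts), rel=1e-12)


def test_estimators_match_scikit_bio():
    from skbio.diversity.alpha import ace as skb_ace
    from skbio.diversity.alpha import chao1 as skb_chao1
    from skbio.diversity.alpha import shannon as skb_shannon

    rng = np.random.default_rng(12)
    for _ in range(25):
        counts = rng.geometric(0.2, size=20)
        assert shannon(counts) == pytest.approx(skb_shannon(counts, base=math.e))
        assert chao1(counts, bias_corrected=True) == pytest.approx(
            skb_chao1(counts, bias_corrected=True)
        )
        if not (counts[counts <= 10] == 1).all():
            assert ace(counts) == pytest.approx(skb_ace(counts), rel=1e-9)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(0, 40), min_size=1, max_size=40).filter(lambda x: sum(x) > 0))
def test_summary_identities_and_estimator_lower_bounds(counts):
    s = abundance_summary(counts)
    assert sum(s.f.values()) == s.s_obs
    assert sum(i * c for i, c in s.f.items()) == s.n
    assert chao1(counts) >= s.s_obs - 1e-9
    if not ((np.asarray(counts)[(0 < np.asarray(counts)) & (np.asarray(counts) <= 10)] == 1).all() and s.s_rare):
        assert ace(counts) >= s.s_obs - 1e-9


# -- Wilcoxon rank-sum -------------------------------------------------------


def _exact_permutation_p(x, y):
    """Two-sided p by enumerating all rank assignments of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    nx_ = len(x)
    w_obs = ranks[:nx_].sum()
    mu = nx_ * (len(pooled) + 1) / 2
    stats_all = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), nx_)
    ]
    dev = abs(w_obs - mu)
    extreme = sum(1 for w in stats_all if abs(w - mu) >= dev - 1e-9)
    return extreme / len(stats_all)


def test_wilcoxon_separated_groups_exact_p():
    # (1,2,3) vs (4,5,6): 2/20 assignments as extreme -> p = 0.1
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_identical_groups_p_one():
    assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


def test_wilcoxon_exact_matches_permutation_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(10):
        nx_, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        x = rng.normal(0, 1, nx_)
        y = rng.normal(0.5, 1, ny)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            _exact_permutation_p(x, y), abs=1e-9
        )


def test_normal_approximation_close_to_exact_where_it_is_adequate():
    """Continuity-corrected normal p within 0.02 of the exact p for
    tie-free splits with at least 5 observations per group (below that
    the approximation is unreliable, which is why the decision rule
    prefers the exact test up to n = 10)."""
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(6)
    for nx_ in range(5, 9):
        for ny in range(5, 9):
            for _ in range(5):
                x = rng.normal(0, 1, nx_)
                y = rng.normal(0.8, 1, ny)
                exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
                approx = mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic", use_continuity=True
                ).pvalue
                assert abs(approx - exact) <= 0.02


def test_decision_rule_uses_exact_only_for_small_tie_free_groups():
    """p-values switch from the exact null to the tie-corrected normal
    approximation exactly when a group exceeds 10 samples or ties appear."""
    from scipy.stats import mannwhitneyu

    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    assert wilcoxon_rank_sum(x, y) == pytest.approx(
        mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    )
    x_tied = [1.0, 2.0, 2.0]
    assert wilcoxon_rank_sum(x_tied, y) == pytest.approx(
        mannwhitneyu(
            x_tied, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )
    big_x, big_y = list(map(float, range(11))), list(map(float, range(20, 31)))
    assert wilcoxon_rank_sum(big_x, big_y) == pytest.approx(
        mannwhitneyu(
            big_x, big_y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


# -- differential abundance --------------------------------------------------


def _toy_table(counts_a, counts_b):
    n_taxa = len(counts_a[0])
    taxa = [f"t{i}" for i in range(n_taxa)]
    rows = counts_a + counts_b
    counts = pd.DataFrame(rows, columns=taxa, index=[f"s{i}" for i in range(len(rows))])
    groups = pd.Series(
        ["A"] * len(counts_a) + ["B"] * len(counts_b), index=counts.index
    )
    return CountTable(counts=counts, groups=groups)


def test_identical_groups_all_p_one():
    block = [[5, 3, 2], [4, 4, 2], [6, 2, 2]]
    res = diff_abundance(_toy_table(block, block), "species", "A", "B")
    assert np.allclose(res["p"], 1.0)


def test_unknown_rank_raises():
    block = [[5, 3], [4, 4]]
    with pytest.raises(ValueError, match="rank"):
        diff_abundance(_toy_table(block, block), "subclade", "A", "B")


def test_direction_sign_follows_group_means():
    a = [[90, 10], [80, 20], [85, 15]]
    b = [[10, 90], [20, 80], [15, 85]]
    res = diff_abundance(_toy_table(a, b), "species", "A", "B").set_index("taxon")
    assert res.loc["t0", "delta"] > 0 > res.loc["t1", "delta"]


def test_planted_taxa_recovered_from_synthetic_table(default_spec):
    table, planted = gen_otu_table(default_spec)
    res = diff_abundance(table, "species", "treatment", "control")
    hits = set(res.loc[res["q"] < 0.1, "taxon"])
    recovered = len(hits & set(planted)) / len(planted)
    assert recovered >= 0.8


def test_null_table_keeps_wilcoxon_rejections_near_alpha():
    """fold change 1 for every taxon: ~5 % of raw p-values below 0.05."""
    rates = []
    for seed in range(20):
        spec = SimulationSpec(seed=seed, taxon_fold_change=1.0, n_diff_taxa=0)
        table, planted = gen_otu_table(spec)
        assert planted == []
        res = diff_abundance(table, "species", "treatment", "control")
        rates.append((res["p"] < 0.05).mean())
    assert abs(np.mean(rates) - 0.05) < 0.04


def test_alpha_diversity_table_shape_and_groups(default_spec):
    table, _ = gen_otu_table(default_spec)
    alpha = alpha_diversity(table)
    assert len(alpha) == 2 * default_spec.n_samples_per_group
    assert set(alpha.columns) == {"group", "s_obs", "ace", "chao1", "shannon"}
    assert (alpha["chao1"] >= alpha["s_obs"] - 1e-9).all()


def test_kruskal_option_flags_planted_taxa(default_spec):
    table, planted = gen_otu_table(default_spec)
    res = kruskal_multigroup(table, "species")
    hits = set(res.loc[res["q"] < 0.05, "taxon"])
    assert len(hits & set(planted)) >= 0.8 * len(planted)
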