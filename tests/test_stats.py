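"""Statistical battery against exact enumeration and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from chmet import (
    cohort_report,
    friedman_bonferroni,
    kruskal_wallis_dunn,
    mann_whitney_u,
    rank_correlation,
    roc_auc,
    weighted_kappa,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# enumeration oracles


def mwu_exact_oracle(x, y):
    """Two-sided exact p by enumerating all group labelings of the pool."""
    pool = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    us = []
    idx = range(len(pool))
    for comb in itertools.combinations(idx, n1):
        xs = set(comb)
        rest = [i for i in idx if i not in xs]
        u = sum(1 for i in comb for j in rest if pool[i] > pool[j]) + 0.5 * sum(
            1 for i in comb for j in rest if pool[i] == pool[j]
        )
        us.append(u)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


def wilcoxon_sign_oracle(d):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = d[d != 0]
    r = ss.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    n = len(d)
    ws = np.array(
        [r[list(s)].sum() for k in range(n + 1)
         for s in itertools.combinations(range(n), k)]
    )
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


def kw_h_formula(groups):
    """Independent rank-mean formula for H (tie-free data)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = ss.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    parts = np.split(ranks, splits)
    return 12.0 / (n * (n + 1)) * sum(
        len(p) * (p.mean() - (n + 1) / 2) ** 2 for p in parts
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_tiny_example():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)


def test_mwu_identical_groups():
    _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0, abs=0.05)


@pytest.mark.parametrize("seed", range(6))
def test_mwu_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 8, 2)
    pool = rng.permutation(np.arange(n1 + n2, dtype=float))
    x, y = pool[:n1], pool[n1:]
    u, p = mann_whitney_u(x, y)
    u_o, p_o = mwu_exact_oracle(x, y)
    # our U is for x; oracle counts x-over-y wins the same way
    assert u == pytest.approx(u_o)
    assert p == pytest.approx(p_o, abs=1e-12)


def test_mwu_p_decreases_with_shift():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 20)
    ps = []
    for shift in (0.0, 1.0, 2.0):
        _, p = mann_whitney_u(x, x + shift + rng.normal(0, 0.01, 20))
        ps.append(p)
    assert ps[0] > ps[1] > ps[2]


def test_mwu_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def test_kw_identical_groups():
    out = kruskal_wallis_dunn([[1, 2, 3]] * 3)
    assert out["h"] == pytest.approx(0.0, abs=1e-9)
    assert all(pair["p_adj"] == pytest.approx(1.0) for pair in out["pairs"])


def test_kw_matches_permutation_oracle():
    """(1,2,3),(4,5,6),(7,8,9): H equals the rank formula; permutation p agrees."""
    groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
    out = kruskal_wallis_dunn(groups)
    h_direct = kw_h_formula(groups)
    assert out["h"] == pytest.approx(h_direct, rel=1e-12)

    pooled = np.concatenate(groups)
    hs = []
    idx = set(range(9))
    for c1 in itertools.combinations(range(9), 3):
        rest = sorted(idx - set(c1))
        for c2 in itertools.combinations(rest, 3):
            c3 = sorted(set(rest) - set(c2))
            hs.append(
                kw_h_formula([pooled[list(c1)], pooled[list(c2)], pooled[c3]])
            )
    hs = np.array(hs)
    p_perm = (hs >= h_direct - 1e-12).mean()
    # chi-square approximation should agree with exact permutation p loosely
    assert out["p"] == pytest.approx(p_perm, abs=0.03)
    assert h_direct == pytest.approx(hs.max(), rel=1e-12)


def test_kw_monotone_invariance():
    rng = np.random.default_rng(2)
    groups = [rng.normal(i, 1, 6) for i in range(3)]
    h1 = kruskal_wallis_dunn(groups)["h"]
    h2 = kruskal_wallis_dunn([np.exp(g) for g in groups])["h"]
    assert h1 == pytest.approx(h2, rel=1e-12)


def test_kw_rejects_small_group():
    with pytest.raises(ValueError):
        kruskal_wallis_dunn([[1, 2], [3], [4, 5]])


def test_dunn_separated_groups_significant():
    out = kruskal_wallis_dunn(
        [np.arange(8.0), np.arange(8.0) + 20, np.arange(8.0) + 40],
        labels=["a", "b", "c"],
    )
    ac = next(p for p in out["pairs"] if p["a"] == "a" and p["b"] == "c")
    ab = next(p for p in out["pairs"] if p["a"] == "a" and p["b"] == "b")
    assert ac["p_adj"] < 0.05
    assert abs(ac["z"]) > abs(ab["z"])


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def test_wilcoxon_all_positive_five_pairs():
    x = np.array([1.0, 2, 3, 4, 5])
    y = x - np.array([0.5, 0.6, 0.7, 0.8, 0.9])
    _, p = wilcoxon_signed_rank(x, y)
    assert p == pytest.approx(2 / 32)


def test_wilcoxon_identical_pairs_p_one():
    x = np.array([1.0, 2, 3])
    with pytest.warns(UserWarning, match="zero"):
        _, p = wilcoxon_signed_rank(x, x)
    assert p == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_wilcoxon_matches_sign_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    d = rng.normal(0.3, 1.0, n)
    _, p = wilcoxon_signed_rank(d, np.zeros(n))
    assert p == pytest.approx(wilcoxon_sign_oracle(d), abs=1e-12)


def test_wilcoxon_antisymmetric():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=(2, 10))
    assert wilcoxon_signed_rank(x, y)[1] == pytest.approx(
        wilcoxon_signed_rank(y, x)[1]
    )


# ---------------------------------------------------------------------------
# Friedman


def test_friedman_identical_columns():
    data = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
    out = friedman_bonferroni(data)
    assert out["chi2"] == 0.0
    assert out["p"] == 1.0


def test_friedman_matches_within_block_permutation():
    """3 subjects x 3 timepoints: chi2 against the (3!)^3 permutation oracle."""
    data = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [1.5, 2.5, 3.5]])
    out = friedman_bonferroni(data)

    def chi2_of(d):
        r = ss.rankdata(d, axis=1)
        n, k = d.shape
        return 12.0 * n / (k * (k + 1)) * np.sum(
            (r.mean(axis=0) - (k + 1) / 2) ** 2
        )

    assert out["chi2"] == pytest.approx(chi2_of(data), rel=1e-12)
    perms = list(itertools.permutations(range(3)))
    chis = []
    for pa in perms:
        for pb in perms:
            for pc in perms:
                d = np.stack([data[0, list(pa)], data[1, list(pb)], data[2, list(pc)]])
                chis.append(chi2_of(d))
    chis = np.array(chis)
    p_exact = (chis >= out["chi2"] - 1e-12).mean()
    assert out["chi2"] == pytest.approx(chis.max(), rel=1e-12)
    # monotone ordering in every block is the most extreme table
    assert p_exact == pytest.approx((1 / 6) ** 3 * 6, rel=1e-12)


def test_friedman_trend_lowers_p():
    rng = np.random.default_rng(4)
    null = rng.normal(size=(8, 4))
    trend = null + np.arange(4) * 1.5
    assert friedman_bonferroni(trend)["p"] < friedman_bonferroni(null)["p"]


def test_friedman_rejects_incomplete_blocks():
    data = np.ones((4, 3))
    data[0, 1] = np.nan
    with pytest.raises(ValueError, match="imputation"):
        friedman_bonferroni(data)


# ---------------------------------------------------------------------------
# ROC / AUC


def test_auc_perfect_and_ties():
    r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], direction="higher")
    assert r.auc == 1.0
    r2 = roc_auc([5, 5, 5, 5], [0, 0, 1, 1], direction="higher")
    assert r2.auc == 0.5
    assert r2.p_value == 1.0


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(8, 25))
        labels = np.zeros(n, int)
        labels[: int(rng.integers(2, n - 1))] = 1
        rng.shuffle(labels)
        scores = np.round(rng.normal(labels * rng.uniform(0, 2), 1.0), 1)
        r = roc_auc(scores, labels, direction="higher")
        pos = scores[labels == 1][:, None]
        neg = scores[labels == 0][None, :]
        oracle = ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / pos.size / neg.shape[1]
        assert r.auc == pytest.approx(oracle, abs=1e-12)


def test_auc_trapezoid_equivalence():
    """Pair-counting AUC equals the trapezoidal integral of the ROC curve."""
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    scores = np.round(rng.normal(labels * 1.2, 1.0), 1)
    r = roc_auc(scores, labels, direction="higher")
    fpr = np.r_[0.0, r.fpr]
    tpr = np.r_[0.0, r.tpr]
    assert r.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


def test_auc_direction_handling():
    scores = np.array([4.0, 3.0, 2.0, 1.0])
    labels = np.array([0, 0, 1, 1])
    assert roc_auc(scores, labels, direction="lower").auc == 1.0
    auto = roc_auc(scores, labels, direction="auto")
    assert auto.auc == 1.0 and auto.orientation == "lower"


def test_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# correlation and kappa


def test_correlation_limits():
    x = np.arange(10.0)
    assert rank_correlation(x, x)[0] == pytest.approx(1.0)
    assert rank_correlation(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_is_pearson_on_ranks():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=(2, 15))
    r_s, _ = rank_correlation(x, y, method="spearman")
    r_p, _ = rank_correlation(ss.rankdata(x), ss.rankdata(y), method="pearson")
    assert r_s == pytest.approx(r_p, rel=1e-12)


def test_correlation_constant_undefined():
    with pytest.warns(UserWarning):
        r, p = rank_correlation(np.ones(5), np.arange(5.0))
    assert np.isnan(r)


def test_kappa_perfect_agreement():
    a = ["non-sunset", "potential", "sunset"] * 5
    assert weighted_kappa(a, list(a)) == pytest.approx(1.0)


def test_kappa_independent_ratings_near_zero():
    rng = np.random.default_rng(8)
    cats = np.array(["non-sunset", "potential", "sunset"])
    a = cats[rng.integers(0, 3, 4000)]
    b = cats[rng.integers(0, 3, 4000)]
    assert weighted_kappa(a, b, categories=list(cats)) == pytest.approx(0.0, abs=0.05)


def test_kappa_hand_computed_table():
    # confusion counts: rows = rater A, cols = rater B (categories 0,1,2)
    table = np.array([[10, 2, 0], [3, 8, 2], [0, 1, 9]])
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a += [i] * table[i, j]
            b += [j] * table[i, j]
    n = table.sum()
    obs = table / n
    exp = obs.sum(axis=1)[:, None] * obs.sum(axis=0)[None, :]
    w = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :]) / 2.0
    expected_kappa = 1 - (w * obs).sum() / (w * exp).sum()
    assert weighted_kappa(a, b, categories=[0, 1, 2]) == pytest.approx(
        expected_kappa, rel=1e-12
    )


def test_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(9)
    a = rng.integers(0, 3, 60)
    noise = rng.integers(0, 3, 60)
    b = np.where(rng.random(60) < 0.7, a, noise)
    ours = weighted_kappa(a, b, categories=[0, 1, 2], weights="linear")
    ref = cohen_kappa_score(a, b, labels=[0, 1, 2], weights="linear")
    assert ours == pytest.approx(ref, rel=1e-12)


def test_kappa_single_category_undefined():
    with pytest.warns(UserWarning):
        k = weighted_kappa(["sunset"] * 5, ["sunset"] * 5)
    assert np.isnan(k)


# ---------------------------------------------------------------------------
# cohort report


def _toy_table(rng, n_per_group=8):
    rows = []
    means = {"control": 140.0, "non-sunset": 120.0, "potential": 60.0, "sunset": 30.0}
    for g, mu in means.items():
        for i in range(n_per_group):
            chmet = rng.normal(mu, 8)
            rows.append(
                {
                    "eye_id": f"{g}{i}",
                    "group": g,
                    "chmet": chmet,
                    "chmetratio": chmet / 2,
                    "sgi": 0.5 - chmet / 1000,
                    "choroidal_thickness": rng.normal(250, 20),
                    "chmet_center": chmet * rng.uniform(0.9, 1.1),
                    "chmet_outer": chmet * rng.uniform(0.9, 1.1),
                }
            )
    return pd.DataFrame(rows)


def test_cohort_report_sections_present():
    table = _toy_table(np.random.default_rng(10))
    rep = cohort_report(table)
    assert rep["sections"]["roc_depigmentation"]["chmetratio"]["auc"] > 0.95
    assert "chmet" in rep["sections"]["group_comparison"]
    assert "chmet" in rep["sections"]["regional"]


def test_cohort_report_single_group_skips():
    table = _toy_table(np.random.default_rng(11))
    table = table[table["group"] == "control"]
    rep = cohort_report(table)
    assert rep["sections"]["group_comparison"] == {}
    assert any("skipped" in n for n in rep["notes"])


def test_cohort_report_deterministic_json():
    import json

    table = _toy_table(np.random.default_rng(12))
    a = json.dumps(cohort_report(table), sort_keys=True)
    b = json.dumps(cohort_report(table), sort_keys=True)
    assert a == b


def test_cohort_report_missing_columns_rejected():
    with pytest.raises(ValueError, match="eye_id"):
        cohort_report(pd.DataFrame({"group": ["control"]}))


def test_cohort_report_unknown_group_rejected():
    with pytest.raises(ValueError, match="unknown group"):
        cohort_report(pd.DataFrame({"eye_id": ["a"], "group": ["weird"]}))
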