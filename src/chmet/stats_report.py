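"""Nonparametric statistical battery for melanin-metric cohort tables.

The analysis plan mirrors a typical cross-sectional + longitudinal uveitis
study design: Kruskal-Wallis with Dunn's post-hoc test across the four eye
groups (healthy control, non-sunset, potential sunset, sunset), ROC/AUC
discrimination of depigmented (sunset + potential sunset) versus non-sunset
eyes, Wilcoxon signed-rank comparison of fovea-centered regions, rank
correlations of center/outer ratios with whole-area means, Friedman with
Bonferroni-corrected post-hoc tests over timepoints, and linearly weighted
kappa for ordered-grade inter-observer agreement.

Omnibus and pairwise tests delegate to scipy.stats; Dunn's z statistics,
the pair-counting AUC, and weighted kappa are computed here directly.
All tests are two-sided and rank-based, hence invariant under monotone
transforms of the inputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "mann_whitney_u",
    "kruskal_wallis_dunn",
    "wilcoxon_signed_rank",
    "friedman_bonferroni",
    "roc_auc",
    "rank_correlation",
    "weighted_kappa",
    "cohort_report",
    "GROUPS",
]

#: fixed group vocabulary, ordered by disease severity
GROUPS = ("control", "non-sunset", "potential", "sunset")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both samples have n <= 8 and no ties span
    the groups; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis_dunn(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
) -> dict:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post-hoc z tests.

    Dunn's statistic for groups i, j compares pooled-rank means:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Pairwise p-values
    are Bonferroni-adjusted over all pairs by default (``adjust=None``
    disables the correction).
    """
    if len(groups) < 3:
        raise ValueError("need at least three groups")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.unique(pooled).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    rank_means = [r.mean() for r in np.split(ranks, splits)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = []
    n_pairs = len(list(itertools.combinations(range(len(groups)), 2)))
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (rank_means[i] - rank_means[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(p_raw * n_pairs, 1.0) if adjust == "bonferroni" else p_raw
        pairs.append(
            {"a": labels[i], "b": labels[j], "z": float(z),
             "p_raw": float(p_raw), "p_adj": float(p_adj)}
        )
    return {"h": float(h), "p": float(p), "pairs": pairs, "adjust": adjust}


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; exact null distribution for <= 15
    non-zero pairs without tied magnitudes, normal approximation with tie
    correction otherwise.  All-zero differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    no_tied_mag = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 15 and no_tied_mag) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def friedman_bonferroni(data: np.ndarray, labels: list[str] | None = None) -> dict:
    """Friedman test over complete blocks with Bonferroni post-hoc Wilcoxon.

    ``data`` has shape ``(n_subjects, n_timepoints)``; incomplete blocks
    (NaN) are rejected rather than imputed.  Pairwise timepoint comparisons
    use the signed-rank test with Bonferroni factor = number of pairs.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need a (subjects x >=3 timepoints) table")
    if np.isnan(data).any():
        raise ValueError("incomplete blocks are not allowed (no imputation)")
    if labels is None:
        labels = [f"t{j}" for j in range(data.shape[1])]

    row_ranks = stats.rankdata(data, axis=1)
    if np.allclose(row_ranks.var(axis=1), 0.0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*data.T)

    k = data.shape[1]
    n_pairs = k * (k - 1) // 2
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p_raw = wilcoxon_signed_rank(data[:, i], data[:, j])
        pairs.append(
            {"a": labels[i], "b": labels[j], "w": w,
             "p_raw": p_raw, "p_adj": float(min(p_raw * n_pairs, 1.0))}
        )
    return {"chi2": float(chi2), "p": float(p), "pairs": pairs}


@dataclass
class ROCResult:
    """AUC with its orientation, operating points, and a p-value vs 0.5.

    ``orientation`` records which direction of the score marks the positive
    class ("higher" or "lower"); the reported AUC is for that orientation.
    The p-value comes from the Mann-Whitney U equivalence of the AUC.
    """

    auc: float
    orientation: str
    p_value: float
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))


def _pair_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # rank formulation of P(score_pos > score_neg) + 0.5 P(tie)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels, direction: str = "auto") -> ROCResult:
    """ROC analysis of a scalar score against binary labels.

    The AUC is the pair-counting probability that a random positive
    outscores a random negative (ties count one half), identical to the
    trapezoidal integral of the ROC curve.  ``direction`` may be
    ``"higher"``, ``"lower"`` (lower score marks the positive class — e.g.
    lower melanin thickness indicates depigmentation), or ``"auto"``,
    which reports whichever orientation gives AUC >= 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")

    auc_hi = _pair_auc(scores, labels)
    if direction == "higher":
        auc, orient = auc_hi, "higher"
    elif direction == "lower":
        auc, orient = 1.0 - auc_hi, "lower"
    elif direction == "auto":
        auc, orient = (auc_hi, "higher") if auc_hi >= 0.5 else (1.0 - auc_hi, "lower")
    else:
        raise ValueError(f"unknown direction {direction!r}")

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if np.unique(scores).size == 1:
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(pos, neg, alternative="two-sided")

    s = scores if orient == "higher" else -scores
    order = np.argsort(-s, kind="stable")
    sorted_labels = labels[order]
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    return ROCResult(
        auc=float(auc),
        orientation=orient,
        p_value=float(p),
        thresholds=s[order][distinct],
        tpr=tps / pos.size,
        fpr=fps / neg.size,
    )


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman (default) or Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need paired samples of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input: correlation undefined")
        return float("nan"), float("nan")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def weighted_kappa(
    a, b, categories: list | None = None, weights: str = "linear"
) -> float:
    """Weighted Cohen's kappa for two raters over ordered categories.

    Disagreement weights are ``|i - j| / (k - 1)`` (linear, default) or its
    square (quadratic); ``kappa = 1 - sum(w * O) / sum(w * E)`` with the
    expected table from the product of the marginals.  Returns NaN when the
    raters use a single category (agreement is then unmeasurable).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    if categories is None:
        categories = sorted(set(a.tolist()) | set(b.tolist()))
    k = len(categories)
    if k < 2:
        warnings.warn("fewer than two categories in use: kappa undefined")
        return float("nan")
    index = {c: i for i, c in enumerate(categories)}
    ia = np.array([index[v] for v in a.tolist()])
    ib = np.array([index[v] for v in b.tolist()])

    obs = np.zeros((k, k))
    np.add.at(obs, (ia, ib), 1.0)
    obs /= obs.sum()
    exp = obs.sum(axis=1)[:, None] * obs.sum(axis=0)[None, :]

    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(ii - jj) / (k - 1)
    if weights == "quadratic":
        w = w ** 2
    elif weights != "linear":
        raise ValueError(f"unknown weights {weights!r}")
    denom = (w * exp).sum()
    if denom == 0:
        warnings.warn("degenerate marginals: kappa undefined")
        return float("nan")
    return float(1.0 - (w * obs).sum() / denom)


# ---------------------------------------------------------------------------
# cohort report

REQUIRED_COLUMNS = ("eye_id", "group")
METRIC_COLUMNS = ("chmet", "chmetratio", "sgi", "choroidal_thickness")
#: metrics where the depigmented class scores LOWER
LOWER_IS_POSITIVE = {"chmet", "chmetratio"}


def cohort_report(table: pd.DataFrame, config: dict | None = None) -> dict:
    """Run the full analysis plan on a metric table; deterministic output.

    The table has one row per eye (or eye-timepoint) with columns
    ``eye_id``, ``group`` (control | non-sunset | potential | sunset),
    optional ``timepoint`` (months), the metric columns present among
    ``chmet``, ``chmetratio``, ``sgi``, ``choroidal_thickness``, optional
    regional columns ``<metric>_center`` / ``<metric>_outer``, and optional
    grader columns ``grader_a`` / ``grader_b``.

    Sections that lack the data they need are skipped with a note rather
    than failing, so the same plan runs on partial tables.
    """
    config = config or {}
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table missing required columns: {missing}")
    bad = set(table["group"].dropna()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")

    metrics = [m for m in METRIC_COLUMNS if m in table.columns]
    report: dict = {"n_rows": int(len(table)), "metrics": metrics,
                    "sections": {}, "notes": []}

    base = table
    if "timepoint" in table.columns:
        # cross-sectional sections use the earliest timepoint per eye
        base = table.sort_values("timepoint").groupby("eye_id", as_index=False).first()

    # --- four-group comparison ----------------------------------------
    groups_present = [g for g in GROUPS if (base["group"] == g).sum() >= 2]
    sec: dict = {}
    if len(groups_present) >= 3:
        for m in metrics:
            samples = [base.loc[base["group"] == g, m].dropna().to_numpy()
                       for g in groups_present]
            if any(s.size < 2 for s in samples):
                continue
            sec[m] = kruskal_wallis_dunn(samples, labels=groups_present)
    else:
        report["notes"].append(
            "group comparison skipped: fewer than three groups with n >= 2"
        )
    report["sections"]["group_comparison"] = sec

    # --- ROC: depigmented (sunset + potential) vs non-sunset ----------
    sec = {}
    depig = base["group"].isin(["sunset", "potential"])
    nonsun = base["group"] == "non-sunset"
    if depig.sum() >= 2 and nonsun.sum() >= 2:
        sub = base[depig | nonsun]
        y = sub["group"].isin(["sunset", "potential"]).astype(int).to_numpy()
        for m in metrics:
            scores = sub[m].to_numpy(dtype=float)
            ok = ~np.isnan(scores)
            if y[ok].min(initial=1) == y[ok].max(initial=0):
                continue
            direction = "lower" if m in LOWER_IS_POSITIVE else "higher"
            r = roc_auc(scores[ok], y[ok], direction=direction)
            sec[m] = {"auc": r.auc, "orientation": r.orientation, "p": r.p_value}
    else:
        report["notes"].append("ROC skipped: need >= 2 eyes in each class")
    report["sections"]["roc_depigmentation"] = sec

    # --- regional comparison and correlations -------------------------
    sec = {}
    for m in metrics:
        c, o = f"{m}_center", f"{m}_outer"
        if c in base.columns and o in base.columns:
            sub = base[[c, o, m]].dropna()
            if len(sub) >= 3:
                w, p = wilcoxon_signed_rank(sub[c].to_numpy(), sub[o].to_numpy())
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = sub[c].to_numpy() / sub[o].to_numpy()
                ok = np.isfinite(ratio)
                entry = {"wilcoxon_w": w, "wilcoxon_p": p}
                if ok.sum() >= 3:
                    r, rp = rank_correlation(
                        ratio[ok], sub[m].to_numpy()[ok],
                        method=config.get("correlation", "spearman"),
                    )
                    entry["ratio_vs_whole_r"] = r
                    entry["ratio_vs_whole_p"] = rp
                sec[m] = entry
    report["sections"]["regional"] = sec

    # --- time course ---------------------------------------------------
    sec = {}
    if "timepoint" in table.columns:
        tps = sorted(table["timepoint"].dropna().unique().tolist())
        if len(tps) >= 3:
            for m in metrics:
                wide = table.pivot_table(
                    index="eye_id", columns="timepoint", values=m, aggfunc="first"
                ).dropna()
                if len(wide) >= 2 and wide.shape[1] >= 3:
                    sec[m] = friedman_bonferroni(
                        wide.to_numpy(), labels=[str(t) for t in wide.columns]
                    )
        else:
            report["notes"].append("time course skipped: fewer than 3 timepoints")
    report["sections"]["time_course"] = sec

    # --- grader agreement ----------------------------------------------
    if {"grader_a", "grader_b"} <= set(base.columns):
        sub = base[["grader_a", "grader_b"]].dropna()
        if len(sub):
            kappa = weighted_kappa(
                sub["grader_a"].to_numpy(), sub["grader_b"].to_numpy(),
                categories=["non-sunset", "potential", "sunset"],
            )
            report["sections"]["agreement"] = {"weighted_kappa": kappa,
                                               "weights": "linear"}
    return report
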