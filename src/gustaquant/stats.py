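"""Nonparametric and parametric test battery used by the comparisons.

All statistics are computed from their defining formulas rather than
delegated, so every convention (tie correction, sums-of-squares type,
error terms, adjustment ordering) is explicit and testable against
independent references:

* Kruskal–Wallis H with tie correction, χ² approximation;
* Dunn's pairwise rank-sum z tests with optional Holm / Bonferroni
  adjustment (raw p by default, matching how per-pair p-values are
  usually reported alongside a Kruskal–Wallis test);
* two-way ANOVA — Type II sums of squares for (possibly unbalanced)
  fixed-effects layouts, or a repeated-measures decomposition when a
  subject identifier is supplied — with Holm–Šidák-adjusted pairwise
  comparisons of factor levels;
* Pearson χ² test of independence on a contingency table;
* paired two-sided t test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import StatResult

__all__ = [
    "kruskal_wallis",
    "dunn_test",
    "two_way_anova",
    "chi_square",
    "paired_t",
    "holm_sidak_adjust",
]


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(out):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return out


def _rank_setup(groups: list[np.ndarray]):
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    split = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, split)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    return n_total, group_ranks, tie_term


def kruskal_wallis(groups) -> StatResult:
    """Kruskal–Wallis rank test with tie correction.

    ``H = 12/(N(N+1)) · Σ nᵢ (R̄ᵢ − (N+1)/2)²`` divided by the tie factor
    ``1 − Σ(t³−t)/(N³−N)``; p from the χ²(k−1) approximation. Invariant
    under strictly monotone transforms of the pooled data.
    """
    gs = _as_groups(groups)
    n, group_ranks, tie_term = _rank_setup(gs)
    h = (12.0 / (n * (n + 1))) * sum(
        r.size * (r.mean() - (n + 1) / 2.0) ** 2 for r in group_ranks
    )
    tie_factor = 1.0 - tie_term / (n**3 - n)
    if tie_factor == 0.0:  # every observation identical
        h = 0.0
    else:
        h /= tie_factor
    df = len(gs) - 1
    p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    return StatResult(
        test="kruskal_wallis",
        statistic=float(h),
        df=df,
        p_value=p,
        n_per_group={i: g.size for i, g in enumerate(gs)},
    )


def dunn_test(groups, labels=None, adjust: str = "none") -> StatResult:
    """Dunn's post-hoc pairwise comparisons after Kruskal–Wallis.

    For each pair, ``z = (R̄ᵢ − R̄ⱼ) / sqrt(V·(1/nᵢ + 1/nⱼ))`` with
    ``V = N(N+1)/12 − Σ(t³−t)/(12(N−1))`` (tie-corrected pooled rank
    variance); two-sided normal p. ``adjust`` is ``none`` (default),
    ``holm`` or ``bonferroni``.
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    if len(labels) != len(gs):
        raise ValueError("one label per group required")
    n, group_ranks, tie_term = _rank_setup(gs)
    pooled_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    for i, j in combinations(range(len(gs)), 2):
        ni, nj = group_ranks[i].size, group_ranks[j].size
        se = np.sqrt(pooled_var * (1.0 / ni + 1.0 / nj))
        z = 0.0 if se == 0 else (group_ranks[i].mean() - group_ranks[j].mean()) / se
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "z": float(z),
                "p_raw": float(2 * sps.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_raw"]
    elif adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p_raw"] * len(table), 1.0)
    elif adjust == "holm":
        table["p_adj"] = _holm_adjust(table["p_raw"].to_numpy())
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["method"] = adjust
    kw = kruskal_wallis(gs)
    return StatResult(
        test="dunn",
        statistic=kw.statistic,
        df=kw.df,
        p_value=kw.p_value,
        n_per_group={labels[i]: g.size for i, g in enumerate(gs)},
        posthoc=table,
    )


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment: p(i) ← max cummax((m−i+1)·p(i)), ≤ 1."""
    m = p.size
    order = np.argsort(p)
    stepped = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def holm_sidak_adjust(p: np.ndarray) -> np.ndarray:
    """Holm–Šidák step-down: p(i) ← 1 − (1 − p(i))^(m−i+1), monotonized."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    stepped = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


# --------------------------------------------------------------------------
# two-way ANOVA


def _encode(levels: pd.Series) -> np.ndarray:
    """Full-rank treatment (drop-first) dummy coding."""
    cats = pd.Categorical(levels)
    dummies = pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)
    return dummies


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _interaction(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    if da.size == 0 or db.size == 0:
        return np.empty((da.shape[0], 0))
    return np.einsum("ni,nj->nij", da, db).reshape(da.shape[0], -1)


def two_way_anova(
    values,
    factor_a,
    factor_b,
    repeated_on=None,
    posthoc_factor: str | None = None,
) -> StatResult:
    """Two-way ANOVA with Holm–Šidák pairwise post-hoc comparisons.

    Fixed-effects layouts (``repeated_on=None``) use Type II sums of
    squares via nested least-squares model comparisons, so unbalanced
    designs are handled; every factor-level cell must be occupied.

    With ``repeated_on`` (subject identifiers), a repeated-measures
    decomposition is used. A factor that is constant within each subject
    is treated as between-subjects (split-plot design: its F uses the
    subject-within-group mean square); factors varying within subjects
    are tested against their factor×subject interaction. Sphericity is
    assumed (no correction); the result is flagged accordingly. The
    within-subject layout must be complete and balanced.

    ``posthoc_factor`` ("a" or "b", default: the factor with most levels
    first listed — "a") selects which factor's levels are compared
    pairwise at each level of the other factor, Holm–Šidák adjusted.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a),
            "b": np.asarray(factor_b),
        }
    )
    if df["y"].isna().any():
        raise ValueError("missing response values")
    cell_counts = df.groupby(["a", "b"], observed=True).size()
    full_grid = len(df["a"].unique()) * len(df["b"].unique())
    if len(cell_counts) < full_grid or (cell_counts == 0).any():
        raise ValueError("every factor-level cell needs at least one observation")

    if repeated_on is None:
        result = _anova_type2(df)
    else:
        df["subject"] = np.asarray(repeated_on)
        result = _anova_repeated(df)

    result.posthoc = _holm_sidak_posthoc(df, which=posthoc_factor or "a")
    return result


def _anova_type2(df: pd.DataFrame) -> StatResult:
    y = df["y"].to_numpy()
    n = len(y)
    ones = np.ones((n, 1))
    da, db = _encode(df["a"]), _encode(df["b"])
    dab = _interaction(da, db)

    X_full = np.hstack([ones, da, db, dab])
    X_ab = np.hstack([ones, da, db])
    X_a = np.hstack([ones, da])
    X_b = np.hstack([ones, db])

    rss_full = _rss(y, X_full)
    rss_ab = _rss(y, X_ab)
    ss_a = _rss(y, X_b) - rss_ab      # Type II: A after B, ignoring AB
    ss_b = _rss(y, X_a) - rss_ab
    ss_ab = rss_ab - rss_full

    # numerical floor: exact fits leave lstsq residuals of order eps
    tol = 1e-10 * max(float(((y - y.mean()) ** 2).sum()), 1.0)
    rss_full = 0.0 if rss_full <= tol else rss_full
    ss_a, ss_b, ss_ab = (0.0 if s <= tol else s for s in (ss_a, ss_b, ss_ab))

    df_a = da.shape[1]
    df_b = db.shape[1]
    df_ab = dab.shape[1]
    df_resid = n - X_full.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid

    table = _f_table(
        [("a", ss_a, df_a), ("b", ss_b, df_b), ("a:b", ss_ab, df_ab)],
        ms_resid,
        df_resid,
    )
    table.loc[len(table)] = ["residual", rss_full, df_resid, ms_resid, np.nan, np.nan]
    main = table.iloc[0]
    return StatResult(
        test="two_way_anova_type2",
        statistic=float(main["F"]),
        df=(int(main["df"]), df_resid),
        p_value=float(main["p"]),
        n_per_group=df.groupby("a", observed=True).size().to_dict(),
        extra={"anova_table": table, "sphericity_assumed": False},
    )


def _anova_repeated(df: pd.DataFrame) -> StatResult:
    # identify between-subject factors (constant within every subject)
    between = []
    for f in ("a", "b"):
        if (df.groupby("subject", observed=True)[f].nunique() == 1).all():
            between.append(f)
    if len(between) == 2:
        raise ValueError("both factors are between-subjects: no repeated factor")
    counts = df.groupby(["subject", "a", "b"], observed=True).size()
    if (counts != 1).any():
        raise ValueError(
            "repeated-measures layout must have exactly one observation "
            "per subject per cell"
        )
    grand = df["y"].mean()
    n = len(df)
    ss_total = float(((df["y"] - grand) ** 2).sum())

    def ss_of(groupers) -> float:
        means = df.groupby(groupers, observed=True)["y"].transform("mean")
        return float(((means - grand) ** 2).sum())

    ka = df["a"].nunique()
    kb = df["b"].nunique()
    n_subj = df["subject"].nunique()
    ss_a = ss_of(["a"])
    ss_b = ss_of(["b"])
    ss_cells = ss_of(["a", "b"])
    ss_ab = ss_cells - ss_a - ss_b
    ss_subj = ss_of(["subject"])

    rows = []
    if len(between) == 1:
        bt = between[0]
        wt = "b" if bt == "a" else "a"
        k_bt = ka if bt == "a" else kb
        k_wt = kb if bt == "a" else ka
        ss_bt = ss_a if bt == "a" else ss_b
        ss_wt = ss_b if bt == "a" else ss_a
        # subjects nested in the between factor
        ss_subj_within = ss_subj - ss_bt
        df_subj_within = n_subj - k_bt
        ss_err_within = ss_total - ss_cells - ss_subj_within
        df_bt, df_wt = k_bt - 1, k_wt - 1
        df_ab = df_bt * df_wt
        df_err_within = (n_subj - k_bt) * df_wt
        ms_sw = ss_subj_within / df_subj_within
        ms_ew = ss_err_within / df_err_within
        rows = [
            (bt, ss_bt, df_bt, ms_sw, df_subj_within),
            (wt, ss_wt, df_wt, ms_ew, df_err_within),
            ("a:b", ss_ab, df_ab, ms_ew, df_err_within),
        ]
    else:
        # fully within-subject: each effect against its subject interaction
        ss_as = ss_of(["subject", "a"]) - ss_subj - ss_a
        ss_bs = ss_of(["subject", "b"]) - ss_subj - ss_b
        ss_abs = ss_total - ss_cells - ss_subj - ss_as - ss_bs
        df_a_, df_b_ = ka - 1, kb - 1
        df_s = n_subj - 1
        rows = [
            ("a", ss_a, df_a_, ss_as / (df_a_ * df_s), df_a_ * df_s),
            ("b", ss_b, df_b_, ss_bs / (df_b_ * df_s), df_b_ * df_s),
            (
                "a:b",
                ss_ab,
                df_a_ * df_b_,
                ss_abs / (df_a_ * df_b_ * df_s),
                df_a_ * df_b_ * df_s,
            ),
        ]

    records = []
    for name, ss, dfe, ms_err, df_err in rows:
        ms = ss / dfe
        f = ms / ms_err if ms_err > 0 else (0.0 if ss <= 1e-12 else np.inf)
        p = float(sps.f.sf(f, dfe, df_err)) if np.isfinite(f) else 0.0
        records.append([name, ss, dfe, ms, f, p, df_err])
    table = pd.DataFrame(
        records, columns=["effect", "ss", "df", "ms", "F", "p", "df_error"]
    )
    main = table.iloc[0]
    return StatResult(
        test="two_way_anova_repeated",
        statistic=float(main["F"]),
        df=(int(main["df"]), int(main["df_error"])),
        p_value=float(main["p"]),
        n_per_group=df.groupby("a", observed=True)["subject"].nunique().to_dict(),
        extra={"anova_table": table, "sphericity_assumed": True},
    )


def _f_table(effects, ms_resid: float, df_resid: int) -> pd.DataFrame:
    records = []
    for name, ss, dfe in effects:
        ms = ss / dfe
        if ms_resid > 0:
            f = ms / ms_resid
            p = float(sps.f.sf(f, dfe, df_resid))
        else:
            f = 0.0 if ss <= 0.0 else np.inf
            p = 1.0 if f == 0.0 else 0.0
        records.append([name, ss, dfe, ms, f, p])
    return pd.DataFrame(records, columns=["effect", "ss", "df", "ms", "F", "p"])


def _holm_sidak_posthoc(df: pd.DataFrame, which: str = "a") -> pd.DataFrame:
    """Pairwise Welch t comparisons of one factor's levels within each
    level of the other factor, Holm–Šidák adjusted across the family."""
    other = "b" if which == "a" else "a"
    rows = []
    for lvl_other, sub in df.groupby(other, observed=True):
        levels = sorted(sub[which].unique())
        for li, lj in combinations(levels, 2):
            xi = sub.loc[sub[which] == li, "y"].to_numpy()
            xj = sub.loc[sub[which] == lj, "y"].to_numpy()
            t, p = sps.ttest_ind(xi, xj, equal_var=False)
            rows.append(
                {
                    "at": lvl_other,
                    "level_i": li,
                    "level_j": lj,
                    "t": float(t),
                    "p_raw": float(p),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = holm_sidak_adjust(table["p_raw"].to_numpy())
        table["method"] = "holm-sidak"
    return table


def chi_square(table) -> StatResult:
    """Pearson χ² test of independence on an r×c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be non-negative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all table margins must be positive")
    n = obs.sum()
    expected = np.outer(row, col) / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return StatResult(
        test="chi_square",
        statistic=stat,
        df=df,
        p_value=p,
        n_per_group={"N": int(n)},
        extra={"expected": expected},
    )


def paired_t(x, y) -> StatResult:
    """Two-sided paired t test: ``t = d̄ / (s_d / √n)``, df = n−1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            t = 0.0
        else:
            raise ValueError(
                "differences have zero variance but nonzero mean: "
                "t statistic undefined"
            )
    else:
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(
        test="paired_t",
        statistic=float(t),
        df=df,
        p_value=p,
        n_per_group={"pairs": n},
        extra={"mean_difference": float(mean)},
    )
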