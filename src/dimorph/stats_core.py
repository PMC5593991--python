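"""Shared statistical engine for factorial designs.

Implements the Gaussian identity-link GLM (ordinary least squares with
Wald/F tests) used throughout the toolkit, estimated marginal means
(EMMs) with pooled residual standard errors, the Newman-Keuls
(Student-Newman-Keuls, SNK) stepwise studentized-range post-hoc
procedure, Bonferroni pairwise correction, and a univariate
repeated-measures ANOVA with subject blocking.

Design matrices use sum-to-zero (effect) coding, so the F-test of a
term's coefficient block is the Type-III-style test that matches the
marginal-mean semantics, balanced or not.  Studentized-range quantiles
come from ``scipy.stats.studentized_range``; published q tables are used
only as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmmResult",
    "build_design",
    "factorial_glm",
    "newman_keuls",
    "bonferroni_pairs",
    "repeated_measures_glm",
]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _effect_codes(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero codes: L-1 columns; level j -> +1 on column j,
    last level -> -1 on every column."""
    idx = values.map({lv: i for i, lv in enumerate(levels)})
    if idx.isna().any():
        bad = sorted(set(values[idx.isna()]))
        raise ValueError(f"values outside declared levels: {bad}")
    idx = idx.to_numpy()
    L = len(levels)
    cols = np.zeros((len(values), L - 1))
    for j in range(L - 1):
        cols[:, j] = np.where(idx == j, 1.0, np.where(idx == L - 1, -1.0, 0.0))
    return cols


def build_design(
    data: pd.DataFrame,
    factors: dict[str, list],
    interactions: list[tuple[str, ...]],
    covariates: tuple[str, ...] = (),
) -> tuple[np.ndarray, dict[str, slice], list[str]]:
    """Build a sum-to-zero-coded design matrix.

    Returns (X, term -> column-slice map, column names).  Interaction
    columns are elementwise products of the parent main-effect columns.
    """
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    term_slices: dict[str, slice] = {"Intercept": slice(0, 1)}
    main_cols: dict[str, np.ndarray] = {}
    pos = 1
    for f, levels in factors.items():
        codes = _effect_codes(data[f], levels)
        main_cols[f] = codes
        blocks.append(codes)
        names += [f"{f}[{lv}]" for lv in levels[:-1]]
        term_slices[f] = slice(pos, pos + codes.shape[1])
        pos += codes.shape[1]
    for cv in covariates:
        col = data[cv].to_numpy(dtype=float)[:, None]
        blocks.append(col)
        names.append(cv)
        term_slices[cv] = slice(pos, pos + 1)
        pos += 1
    for combo in interactions:
        cols = main_cols[combo[0]]
        for f in combo[1:]:
            other = main_cols[f]
            cols = np.concatenate(
                [cols[:, [i]] * other for i in range(cols.shape[1])], axis=1
            )
        blocks.append(cols)
        term = ":".join(combo)
        names += [f"{term}#{j}" for j in range(cols.shape[1])]
        term_slices[term] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    X = np.concatenate(blocks, axis=1)
    return X, term_slices, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the rank deficiency
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )


# ---------------------------------------------------------------------------
# factorial GLM + EMMs
# ---------------------------------------------------------------------------

@dataclass
class EmmResult:
    """Factorial GLM fit: ANOVA table, EMMs and post-hoc inputs.

    ``emmeans`` maps each factor name (and ``"cell"`` for the full
    factorial cell grid) to a table with columns ``emm``, ``se``, ``n``.
    """

    anova: pd.DataFrame
    emmeans: dict[str, pd.DataFrame]
    coef: pd.Series
    mse: float
    df_resid: int
    nobs: int
    factors: dict[str, list] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def cell_means(self) -> pd.DataFrame:
        return self.emmeans["cell"]


def _infer_levels(data: pd.DataFrame, factors) -> dict[str, list]:
    if isinstance(factors, dict):
        return {f: list(lv) for f, lv in factors.items()}
    return {f: sorted(pd.unique(data[f])) for f in factors}


def factorial_glm(
    data: pd.DataFrame,
    response: str,
    factors,
    interactions: str | list = "full",
    covariates: tuple[str, ...] = (),
) -> EmmResult:
    """Fit a full-factorial normal/identity GLM and report Type-III-style
    F-tests plus estimated marginal means with pooled-variance SEs.

    ``interactions``: "full" (all orders), "two-way", "none", or an
    explicit list of factor tuples.
    """
    levels = _infer_levels(data, factors)
    fnames = list(levels)
    if interactions == "full":
        inter = [c for r in range(2, len(fnames) + 1) for c in combinations(fnames, r)]
    elif interactions == "two-way":
        inter = list(combinations(fnames, 2))
    elif interactions == "none":
        inter = []
    else:
        inter = [tuple(c) for c in interactions]

    # every referenced cell must be populated when its interaction is requested
    if inter:
        widest = max(inter, key=len)
        counts = data.groupby([*widest], observed=True).size()
        expected = list(product(*(levels[f] for f in widest)))
        missing = [c for c in expected if c not in counts.index]
        if missing:
            raise ValueError(f"empty design cells for {widest}: {missing}")

    X, term_slices, names = build_design(data, levels, inter, covariates)
    _check_full_rank(X, names)
    y = data[response].to_numpy(dtype=float)
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    sse = float(resid @ resid)
    mse = sse / df_resid if df_resid > 0 else np.nan

    rows = []
    for term, sl in term_slices.items():
        if term == "Intercept":
            continue
        b = beta[sl]
        V = XtX_inv[sl, sl]
        q = len(b)
        if df_resid > 0 and mse > 0:
            F = float(b @ np.linalg.solve(V, b)) / (q * mse)
            p = stats.f.sf(F, q, df_resid)
        elif df_resid > 0:  # exact fit
            F, p = 0.0 if np.allclose(b, 0) else np.inf, np.nan
            p = 1.0 if F == 0.0 else 0.0
        else:
            F, p = np.nan, np.nan
        rows.append({"term": term, "F": F, "df_num": q, "df_den": df_resid, "p": p})
    anova = pd.DataFrame(rows).set_index("term")

    # prediction rows for EMMs: full grid over factors, covariates at mean
    grid = pd.DataFrame(list(product(*(levels[f] for f in fnames))), columns=fnames)
    for cv in covariates:
        grid[cv] = data[cv].mean()
    Xg, _, _ = build_design(grid, levels, inter, covariates)
    cov_beta = mse * XtX_inv

    def _emm_from_rows(row_sets: list[np.ndarray], labels, ns) -> pd.DataFrame:
        out = []
        for lab, rows_, n_ in zip(labels, row_sets, ns):
            c = rows_.mean(axis=0)
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov_beta @ c)) if mse > 0 else 0.0
            out.append({"level": lab, "emm": est, "se": se, "n": n_})
        return pd.DataFrame(out).set_index("level")

    emmeans: dict[str, pd.DataFrame] = {}
    for f in fnames:
        labels = levels[f]
        row_sets = [Xg[(grid[f] == lv).to_numpy()] for lv in labels]
        ns = [int((data[f] == lv).sum()) for lv in labels]
        emmeans[f] = _emm_from_rows(row_sets, labels, ns)
    cell_labels = [tuple(r) for r in grid[fnames].itertuples(index=False)]
    counts = data.groupby(fnames, observed=True).size()
    ns = [int(counts.get(lab if len(lab) > 1 else lab[0], 0)) for lab in cell_labels]
    emmeans["cell"] = _emm_from_rows([Xg[[i]] for i in range(len(Xg))], cell_labels, ns)

    return EmmResult(
        anova=anova,
        emmeans=emmeans,
        coef=pd.Series(beta, index=names),
        mse=mse,
        df_resid=df_resid,
        nobs=len(y),
        factors=levels,
    )


# ---------------------------------------------------------------------------
# post-hoc procedures
# ---------------------------------------------------------------------------

def newman_keuls(emm: EmmResult, term: str = "cell", alpha: float = 0.05) -> pd.DataFrame:
    """Student-Newman-Keuls stepwise studentized-range comparisons.

    Cell means are ordered; the pair spanning r ordered means is tested
    with q = diff / sqrt(MSE / n_h) against q_crit(alpha, r, df_error),
    where n_h is the harmonic mean of the two cell sizes.  A pair
    enclosed by a span already found non-significant is blocked
    (declared non-significant without testing) — the standard SNK logic.
    """
    tab = emm.emmeans[term]
    if len(tab) < 2:
        raise ValueError("need at least two cells for a post-hoc comparison")
    order = tab["emm"].sort_values(kind="mergesort")
    labels = list(order.index)
    means = order.to_numpy()
    ns = tab.loc[labels, "n"].to_numpy(dtype=float)
    k, df = len(labels), emm.df_resid

    nonsig: list[tuple[int, int]] = []
    rows = []
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            blocked = any(a <= i and j <= b for a, b in nonsig)
            diff = means[j] - means[i]
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            se = np.sqrt(emm.mse / n_h)
            q = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            if blocked:
                sig, p = False, np.nan
            else:
                p = float(stats.studentized_range.sf(q, r, df)) if np.isfinite(q) else 0.0
                sig = p < alpha
                if not sig:
                    nonsig.append((i, j))
            rows.append(
                {
                    "level_1": labels[i],
                    "level_2": labels[j],
                    "diff": diff,
                    "span": r,
                    "q": q,
                    "p": p,
                    "significant": sig,
                    "blocked": blocked,
                }
            )
    return pd.DataFrame(rows)


def bonferroni_pairs(
    emm: EmmResult,
    pairs: list[tuple] | None = None,
    alpha: float = 0.05,
    term: str = "cell",
) -> pd.DataFrame:
    """Pooled-variance pairwise t-tests with Bonferroni adjustment
    (adjusted p = min(1, p x number of declared pairs))."""
    tab = emm.emmeans[term]
    if pairs is None:
        pairs = list(combinations(tab.index, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = tab.loc[[a], "emm"].iloc[0] - tab.loc[[b], "emm"].iloc[0]
        na, nb = tab.loc[[a], "n"].iloc[0], tab.loc[[b], "n"].iloc[0]
        se = np.sqrt(emm.mse * (1.0 / na + 1.0 / nb))
        t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = 2 * stats.t.sf(abs(t), emm.df_resid)
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "level_1": a,
                "level_2": b,
                "diff": diff,
                "t": t,
                "p": p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated measures
# ---------------------------------------------------------------------------

def repeated_measures_glm(
    data: pd.DataFrame,
    response: str,
    subject: str,
    within: str,
    between: str,
) -> pd.DataFrame:
    """Univariate repeated-measures ANOVA with one within-subject factor
    and one between-subject grouping factor.

    Classic split-plot decomposition: the between-group effect is tested
    against subjects-within-groups, the within factor and its interaction
    against the within-subject residual.  No sphericity correction is
    applied.  A single within level reduces to the between-groups GLM.
    """
    times = sorted(pd.unique(data[within]))
    groups = sorted(pd.unique(data[between]))
    T, G = len(times), len(groups)
    if T == 1:
        res = factorial_glm(data, response, [between], interactions="none")
        row = res.anova.loc[between]
        return pd.DataFrame(
            [{"term": between, "F": row["F"], "df_num": row["df_num"],
              "df_den": row["df_den"], "p": row["p"]}]
        ).set_index("term")

    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=response, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("unbalanced subject x time grid: every subject "
                         "needs a value at every within level")
    y = wide.to_numpy(dtype=float)
    grp = wide.index.get_level_values(between)
    N = y.shape[0]
    grand = y.mean()

    subj_means = y.mean(axis=1)
    ss_subjects = T * float(((subj_means - grand) ** 2).sum())
    ss_group = 0.0
    for g in groups:
        sel = grp == g
        ss_group += T * sel.sum() * (y[sel].mean() - grand) ** 2
    ss_subj_err = ss_subjects - ss_group

    time_means = y.mean(axis=0)
    ss_time = N * float(((time_means - grand) ** 2).sum())
    ss_cells = 0.0
    for g in groups:
        sel = grp == g
        cell = y[sel].mean(axis=0)
        ss_cells += sel.sum() * float(((cell - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = float(((y - grand) ** 2).sum())
    ss_within_err = ss_total - ss_subjects - ss_time - ss_inter

    df_group, df_subj_err = G - 1, N - G
    df_time, df_inter = T - 1, (G - 1) * (T - 1)
    df_within_err = (N - G) * (T - 1)

    ms = lambda ss, df: ss / df if df > 0 else np.nan
    ms_subj_err = ms(ss_subj_err, df_subj_err)
    ms_within_err = ms(ss_within_err, df_within_err)
    rows = [
        {"term": between, "F": ms(ss_group, df_group) / ms_subj_err,
         "df_num": df_group, "df_den": df_subj_err},
        {"term": within, "F": ms(ss_time, df_time) / ms_within_err,
         "df_num": df_time, "df_den": df_within_err},
        {"term": f"{within}:{between}", "F": ms(ss_inter, df_inter) / ms_within_err,
         "df_num": df_inter, "df_den": df_within_err},
    ]
    for r in rows:
        r["p"] = stats.f.sf(r["F"], r["df_num"], r["df_den"])
    return pd.DataFrame(rows).set_index("term")
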