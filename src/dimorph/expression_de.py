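"""Microarray differential-expression screen with dual-model consensus.

The screen: quantile normalization, low-signal probe filtering, first
principal component (PC1) extraction as a technical covariate, per-probe
least-squares fits under two factorial models —

    A:  Sex + Diet + Stress
    B:  PC1 + Sex + Diet + Stress

— empirical-Bayes variance moderation with B-statistic (log posterior
odds of differential expression) ranking, intersection of the top-K
probes of both models, and a direction-consistency validation against an
independent male replication batch (p < alpha_rep with the same log2
fold-change sign).

The moderation follows the standard empirical-Bayes treatment for
microarray linear models: per-probe residual variances s^2 with d
degrees of freedom are shrunk toward a prior (d0, s0^2) estimated by
moment-matching log s^2 against the log scaled-inverse-chi-square
(digamma/trigamma inversion); moderated t uses
stilde^2 = (d0 s0^2 + d s^2)/(d0 + d) with d0 + d degrees of freedom,
and the B-statistic mixes a prior DE proportion p_de with a prior
fold-change variance estimated from the top tail of the t-statistics.

Factor coding is treatment coding with reference levels Sex=F,
Diet=CTRL, Stress=none, so reported log2 fold changes read M vs F,
LPD vs CTRL, swim vs none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .synthgen import ExpressionExperiment

__all__ = [
    "quantile_normalize",
    "low_signal_filter",
    "pc1_scores",
    "ProbeFit",
    "fit_probe_lm",
    "build_treatment_design",
    "fit_models",
    "ebayes_moderate",
    "consensus_top_k",
    "replication_validate",
    "relative_scale",
    "run_de_screen",
    "ConsensusResult",
]

REFERENCE_LEVELS = {"sex": "F", "diet": "CTRL", "stress": "none"}
STRESS_COEF = "stress[swim]"


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every array (column) onto the common distribution given by
    the row-wise mean of the sorted columns, preserving within-column
    ranks (average-tie rule)."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def low_signal_filter(
    matrix: pd.DataFrame,
    background_quantile: float = 0.1,
    min_fraction: float = 0.5,
) -> tuple[pd.Index, dict]:
    """Keep probes whose intensity exceeds the per-array background
    quantile in at least ``min_fraction`` of the arrays.

    Returns (kept probe index, filter log with counts).
    """
    if not (0 < background_quantile < 1):
        raise ValueError("background_quantile must lie in (0, 1)")
    if not (0 <= min_fraction <= 1):
        raise ValueError("min_fraction must lie in [0, 1]")
    X = matrix.to_numpy(dtype=float)
    bg = np.quantile(X, background_quantile, axis=0)
    above = (X > bg[None, :]).mean(axis=1)
    keep = above >= min_fraction if min_fraction > 0 else np.ones(len(X), bool)
    kept = matrix.index[keep]
    log = {
        "n_probes_in": int(X.shape[0]),
        "n_probes_kept": int(keep.sum()),
        "n_probes_removed": int((~keep).sum()),
        "background_quantile": background_quantile,
        "min_fraction": min_fraction,
    }
    return kept, log


def pc1_scores(matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-sample scores on the first principal component of the
    probe-centered matrix, plus the variance fraction it explains.

    The sign is fixed so the first sample's score is non-negative.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    # right singular vectors of the probe-centered matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = vt[0] * s[0]
    if scores[0] < 0:
        scores = -scores
    var_fraction = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return pd.Series(scores, index=matrix.columns, name="PC1"), var_fraction


def relative_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Scale each transcript (row) by its maximum so the largest entry
    is exactly 1 (the 'Relative' heatmap transform)."""
    mx = values.max(axis=1)
    if (mx == 0).any():
        raise ValueError("row with maximum 0 cannot be scaled")
    return values.div(mx, axis=0)


# ---------------------------------------------------------------------------
# per-probe linear models
# ---------------------------------------------------------------------------

def build_treatment_design(
    samples: pd.DataFrame,
    factors: tuple[str, ...] = ("sex", "diet", "stress"),
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Treatment-coded design matrix with the declared reference levels.
    Single-level factors (e.g. sex in the male-only replication batch)
    are dropped."""
    cols = {"Intercept": np.ones(len(samples))}
    for f in factors:
        levels = sorted(pd.unique(samples[f]))
        if len(levels) < 2:
            continue
        ref = REFERENCE_LEVELS.get(f, levels[-1])
        for lv in levels:
            if lv == ref:
                continue
            cols[f"{f}[{lv}]"] = (samples[f] == lv).astype(float).to_numpy()
    for cv in covariates:
        cols[cv] = samples[cv].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(R))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(f"rank-deficient design; aliased columns: {aliased}")
    return X


@dataclass
class ProbeFit:
    """Per-probe OLS results for one shared design matrix.

    After :func:`ebayes_moderate`, also carries the moderated
    statistics (t, p, lods) and hyperparameters (d0, s0_sq, var_prior).
    """

    coefficients: pd.DataFrame          # probes x coefficients (log2 scale)
    stdev_unscaled: pd.Series           # per coefficient, sqrt of (X'X)^-1 diag
    sigma2: pd.Series                   # per-probe residual variance s^2
    df_resid: int
    design: pd.DataFrame
    d0: float | None = None
    s0_sq: float | None = None
    s2_post: pd.Series | None = None
    t: pd.DataFrame | None = None
    p: pd.DataFrame | None = None
    lods: pd.DataFrame | None = None
    df_total: float | None = None
    var_prior: pd.Series | None = None
    p_de: float = 0.01

    def table(self, coef: str) -> pd.DataFrame:
        """Flat per-probe results for one coefficient."""
        out = pd.DataFrame({"logFC": self.coefficients[coef]})
        if self.t is not None:
            out["t"] = self.t[coef]
            out["p"] = self.p[coef]
            out["B"] = self.lods[coef]
        return out


def fit_probe_lm(matrix: pd.DataFrame, design: pd.DataFrame) -> ProbeFit:
    """Ordinary least squares of every probe on a shared design matrix."""
    X = design.to_numpy(dtype=float)
    Y = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n != Y.shape[1]:
        raise ValueError("design rows must match matrix columns")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T                      # probes x p
    resid = Y - beta @ X.T
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=1) / df
    return ProbeFit(
        coefficients=pd.DataFrame(beta, index=matrix.index, columns=design.columns),
        stdev_unscaled=pd.Series(np.sqrt(np.diag(XtX_inv)), index=design.columns),
        sigma2=pd.Series(sigma2, index=matrix.index, name="sigma2"),
        df_resid=df,
        design=design,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def fit_scaled_invchisq(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s^2 against the log scaled-inverse-chi-square
    distribution implied by s^2 ~ s0^2 chi2_df / df scaled by an
    inverse-chi-square prior; returns (d0, s0_sq).

    d0 is infinite when the observed log-variance spread is no larger
    than sampling noise alone (all-equal variances branch).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def _tmixture(tstat: np.ndarray, stdev_unscaled: float, df: float,
              proportion: float, v0_lim: tuple[float, float]) -> float:
    """Estimate the prior (unscaled) variance of non-null coefficients
    from the top tail of the moderated t-statistics."""
    ngenes = len(tstat)
    ntarget = math.ceil(proportion / 2.0 * ngenes)
    if ntarget < 1:
        return float("nan")
    p = max(ntarget / ngenes, proportion)
    at = np.abs(tstat)
    order = np.argsort(at)[::-1][:ntarget]
    tt = at[order]
    v1 = np.full(ntarget, stdev_unscaled**2)
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, df)
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(v0.mean())


def ebayes_moderate(fit: ProbeFit, p_de: float = 0.01,
                    stdev_coef_lim: tuple[float, float] = (0.1, 4.0)) -> ProbeFit:
    """Empirical-Bayes moderation: shrink per-probe variances toward the
    moment-matched prior, compute moderated t, p and the B-statistic
    (log posterior odds of differential expression) per coefficient."""
    s2 = fit.sigma2.to_numpy()
    if (s2 > 0).sum() < 30:
        raise ValueError("need >= 30 probes with positive residual variance "
                         "for stable hyperparameter estimation")
    d0, s0_sq = fit_scaled_invchisq(s2, fit.df_resid)
    d = fit.df_resid
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = float(len(s2) * d)          # effectively pooled
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = min(d0 + d, len(s2) * d)

    coefs = fit.coefficients.to_numpy()
    su = fit.stdev_unscaled.to_numpy()
    tmat = coefs / (np.sqrt(s2_post)[:, None] * su[None, :])
    pmat = 2.0 * stats.t.sf(np.abs(tmat), df_total)

    v0_lim = (stdev_coef_lim[0] ** 2 / s0_sq, stdev_coef_lim[1] ** 2 / s0_sq)
    lods = np.empty_like(tmat)
    var_prior = np.empty(tmat.shape[1])
    for j in range(tmat.shape[1]):
        v0 = _tmixture(tmat[:, j], su[j], df_total, p_de, v0_lim)
        if not np.isfinite(v0):
            v0 = 1.0 / s0_sq
        var_prior[j] = v0
        r = (su[j] ** 2 + v0) / su[j] ** 2
        t2 = tmat[:, j] ** 2
        if math.isinf(df_total):
            kernel = t2 * (1.0 - 1.0 / r) / 2.0
        else:
            kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
        lods[:, j] = math.log(p_de / (1.0 - p_de)) - math.log(r) / 2.0 + kernel

    idx, cols = fit.coefficients.index, fit.coefficients.columns
    fit.d0, fit.s0_sq = d0, s0_sq
    fit.s2_post = pd.Series(s2_post, index=idx, name="s2_post")
    fit.t = pd.DataFrame(tmat, index=idx, columns=cols)
    fit.p = pd.DataFrame(pmat, index=idx, columns=cols)
    fit.lods = pd.DataFrame(lods, index=idx, columns=cols)
    fit.df_total = df_total
    fit.var_prior = pd.Series(var_prior, index=cols)
    fit.p_de = p_de
    return fit


def fit_models(
    exp: ExpressionExperiment,
    pc1: pd.Series | None = None,
    p_de: float = 0.01,
) -> dict[str, ProbeFit]:
    """Fit the dual factorial models on the main batch.

    Model A: Sex + Diet + Stress.  Model B adds the PC1 covariate
    (computed from the main-batch matrix if not supplied).
    """
    main = exp.batch("main")
    if pc1 is None:
        pc1, _ = pc1_scores(main.matrix)
    samples = main.samples.copy()
    samples["PC1"] = pc1.reindex(samples.index).to_numpy()
    XA = build_treatment_design(samples)
    XB = build_treatment_design(samples, covariates=("PC1",))
    fits = {
        "A": ebayes_moderate(fit_probe_lm(main.matrix, XA), p_de=p_de),
        "B": ebayes_moderate(fit_probe_lm(main.matrix, XB), p_de=p_de),
    }
    return fits


# ---------------------------------------------------------------------------
# consensus + replication validation
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Dual-model top-K candidates and their replication-validated subset."""

    k: int
    alpha_rep: float
    candidates: pd.Index
    validated: pd.Index = field(default_factory=lambda: pd.Index([]))
    top_a: pd.Index = field(default_factory=lambda: pd.Index([]))
    top_b: pd.Index = field(default_factory=lambda: pd.Index([]))


def _top_k(fit: ProbeFit, coef: str, k: int) -> pd.Index:
    tab = fit.table(coef)
    tab = tab.assign(_probe=tab.index.astype(str))
    ranked = tab.sort_values(["B", "p", "_probe"],
                             ascending=[False, True, True], kind="mergesort")
    return ranked.index[:k]


def consensus_top_k(fit_a: ProbeFit, fit_b: ProbeFit, coef: str = STRESS_COEF,
                    k: int = 1000) -> ConsensusResult:
    """Intersect the top-K probes of both models ranked by descending
    B-statistic for the named coefficient (ties: p ascending, then probe id)."""
    if not fit_a.coefficients.index.equals(fit_b.coefficients.index):
        raise ValueError("fits must cover the identical probe universe")
    top_a, top_b = _top_k(fit_a, coef, k), _top_k(fit_b, coef, k)
    candidates = top_a.intersection(top_b).sort_values()
    return ConsensusResult(k=k, alpha_rep=np.nan, candidates=candidates,
                           top_a=top_a, top_b=top_b)


def replication_validate(
    candidates: pd.Index,
    fit_main: ProbeFit,
    fit_rep: ProbeFit,
    coef: str = STRESS_COEF,
    alpha_rep: float = 0.1,
) -> pd.Index:
    """Keep candidates whose replication-batch fit shows p < alpha_rep
    with the same log2 fold-change sign as the main fit (sign 0 matches
    nothing)."""
    main_fc = fit_main.coefficients.loc[candidates, coef]
    rep_fc = fit_rep.coefficients.loc[candidates, coef]
    rep_p = fit_rep.p.loc[candidates, coef]
    same_sign = (np.sign(main_fc) == np.sign(rep_fc)) & (np.sign(main_fc) != 0)
    keep = (rep_p < alpha_rep) & same_sign
    return candidates[keep.to_numpy()]


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def run_de_screen(
    exp: ExpressionExperiment,
    k: int = 1000,
    alpha_rep: float = 0.1,
    p_de: float = 0.01,
    coef: str = STRESS_COEF,
    normalize: bool = True,
    background_quantile: float = 0.1,
    min_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Run the full replication-validated dual-model screen.

    Quantile normalization is applied per batch (main and replication
    arrays were hybridized/scanned separately).  Returns the per-probe
    results table and a summary dict with filter accounting.
    """
    if normalize:
        parts = []
        for b in ("main", "replication"):
            sel = exp.samples.index[exp.samples["batch"] == b]
            if len(sel):
                parts.append(quantile_normalize(exp.matrix[sel]))
        matrix = pd.concat(parts, axis=1)[exp.samples.index]
    else:
        matrix = exp.matrix
    kept, filter_log = low_signal_filter(matrix, background_quantile, min_fraction)
    exp2 = ExpressionExperiment(matrix.loc[kept], exp.samples, exp.truth)

    main = exp2.batch("main")
    pc1, pc1_frac = pc1_scores(main.matrix)
    fits = fit_models(exp2, pc1=pc1, p_de=p_de)

    rep = exp2.batch("replication")
    X_rep = build_treatment_design(rep.samples)
    fit_rep = ebayes_moderate(fit_probe_lm(rep.matrix, X_rep), p_de=p_de)

    cons = consensus_top_k(fits["A"], fits["B"], coef=coef, k=k)
    validated = replication_validate(cons.candidates, fits["B"], fit_rep,
                                     coef=coef, alpha_rep=alpha_rep)
    cons.validated = validated
    cons.alpha_rep = alpha_rep

    ta, tb, tr = fits["A"].table(coef), fits["B"].table(coef), fit_rep.table(coef)
    results = pd.DataFrame(
        {
            "logFC_A": ta["logFC"], "B_A": ta["B"], "p_A": ta["p"],
            "logFC_B": tb["logFC"], "B_B": tb["B"], "p_B": tb["p"],
            "logFC_rep": tr["logFC"], "p_rep": tr["p"],
        }
    )
    results["candidate"] = results.index.isin(cons.candidates)
    results["validated"] = results.index.isin(validated)

    summary = {
        "filter": filter_log,
        "pc1_variance_fraction": pc1_frac,
        "k": k,
        "alpha_rep": alpha_rep,
        "p_de": p_de,
        "coef": coef,
        "n_candidates": int(len(cons.candidates)),
        "n_validated": int(len(validated)),
        "d0": {"A": fits["A"].d0, "B": fits["B"].d0, "rep": fit_rep.d0},
        "s0_sq": {"A": fits["A"].s0_sq, "B": fits["B"].s0_sq, "rep": fit_rep.s0_sq},
    }
    summary["fits"] = {"A": fits["A"], "B": fits["B"], "rep": fit_rep}
    summary["consensus"] = cons
    return results, summary
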