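"""Repeated-measures analysis of per-CpG percent methylation.

Neighbouring CpGs within one pyrosequencing assay are never independent,
so each assay is analysed with a linear mixed model on the raw percent
scale:

    pct ~ Sex + Diet + Sex:Diet + CpG (fixed) + animal (random intercept)

fitted by REML (statsmodels MixedLM).  The random intercept induces
compound symmetry across the CpGs of an animal.  Term F-tests use Wald
contrasts on the fixed effects with containment denominator degrees of
freedom: between-animal terms (Sex, Diet, Sex:Diet) are tested on
n_animals - n_cells df, the within-animal CpG term on
N - n_animals - (n_cpg - 1) df.

Global-methylation (retrotransposon B1/IAP) assays are checked with the
ordinary factorial GLM of :mod:`dimorph.stats_core` on per-animal means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import stats_core

__all__ = [
    "MixedModelResult",
    "fit_cpg_mixed_model",
    "pairwise_cells",
    "global_methylation_check",
]


@dataclass
class MixedModelResult:
    """Fixed-effect F-tests, variance components and Sex x Diet cell means."""

    assay: str
    anova: pd.DataFrame                 # term -> F, df_num, df_den, p
    cell_means: pd.DataFrame            # (sex, diet) -> emm, se, n_animals
    animal_var: float
    residual_var: float
    n_animals: int
    n_cpgs: int
    singular: bool = False              # random-effect variance hit 0 / OLS fallback
    _contrast_cache: dict | None = None


def _validate(table: pd.DataFrame, assay: str) -> pd.DataFrame:
    sub = table[table["assay"] == assay].copy()
    if sub.empty:
        raise ValueError(f"no rows for assay {assay!r}")
    if sub["pct_methylation"].lt(0).any() or sub["pct_methylation"].gt(100).any():
        raise ValueError("pct_methylation outside [0, 100]")
    n_cpg = sub["cpg_index"].nunique()
    cells = sub.groupby(["sex", "diet"])["animal_id"].nunique()
    if len(cells) < 4 or (cells < 2).any():
        raise ValueError("need >= 2 animals in every Sex x Diet cell")
    return sub, n_cpg


def _design(sub: pd.DataFrame, n_cpg: int, cpg_fixed: bool):
    """Sum-to-zero fixed-effect design: Sex, Diet, Sex:Diet (+ CpG)."""
    factors = {"sex": sorted(sub["sex"].unique()), "diet": sorted(sub["diet"].unique())}
    inter = [("sex", "diet")]
    if cpg_fixed and n_cpg > 1:
        factors["cpg_index"] = sorted(sub["cpg_index"].unique())
    X, slices, names = stats_core.build_design(sub, factors, inter)
    return X, slices, names, factors


def fit_cpg_mixed_model(
    table: pd.DataFrame,
    assay: str,
    cpg_fixed: bool = True,
) -> MixedModelResult:
    """Fit the repeated-measures mixed model for one assay.

    With a single CpG the animal and residual variances are not
    separately identifiable, so the fit reduces to the factorial GLM on
    the per-animal values (flagged ``singular``).
    """
    sub, n_cpg = _validate(table, assay)
    n_animals = sub["animal_id"].nunique()
    X, slices, names, _ = _design(sub, n_cpg, cpg_fixed)
    y = sub["pct_methylation"].to_numpy(dtype=float)

    if n_cpg == 1:
        res = stats_core.factorial_glm(sub, "pct_methylation", ["sex", "diet"],
                                       interactions="full")
        return _from_ols(assay, res, n_animals, n_cpg, singular=True)

    import statsmodels.api as sm

    exog = pd.DataFrame(X, columns=names, index=sub.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=sub["animal_id"])
        try:
            fit = model.fit(reml=True)
        except Exception:
            res = stats_core.factorial_glm(
                sub, "pct_methylation", ["sex", "diet"], interactions="full")
            return _from_ols(assay, res, n_animals, n_cpg, singular=True)

    fe = fit.fe_params.to_numpy()
    cov = np.asarray(fit.cov_params())[: len(fe), : len(fe)]
    animal_var = float(fit.cov_re.iloc[0, 0])
    resid_var = float(fit.scale)
    singular = animal_var < 1e-10

    n_cells = 4
    ddf_between = max(n_animals - n_cells, 1)
    ddf_within = max(len(sub) - n_animals - (n_cpg - 1), 1)

    rows = []
    for term, sl in slices.items():
        if term == "Intercept":
            continue
        b = fe[sl]
        V = cov[sl, sl]
        q = len(b)
        F = float(b @ np.linalg.solve(V, b)) / q
        ddf = ddf_within if term == "cpg_index" else ddf_between
        rows.append({"term": _pretty(term), "F": F, "df_num": q, "df_den": ddf,
                     "p": stats.f.sf(F, q, ddf)})
    anova = pd.DataFrame(rows).set_index("term")

    # Sex x Diet cell means (EMMs averaging over CpG levels)
    cell_rows, cache = [], {}
    counts = sub.groupby(["sex", "diet"])["animal_id"].nunique()
    for sex in sorted(sub["sex"].unique()):
        for diet in sorted(sub["diet"].unique()):
            c = _cell_row(sub, sex, diet, n_cpg, cpg_fixed, names, slices)
            est = float(c @ fe)
            se = float(np.sqrt(c @ cov @ c))
            cell_rows.append({"sex": sex, "diet": diet, "emm": est, "se": se,
                              "n_animals": int(counts.loc[(sex, diet)])})
            cache[(sex, diet)] = c
    cell_means = pd.DataFrame(cell_rows).set_index(["sex", "diet"])

    return MixedModelResult(
        assay=assay, anova=anova, cell_means=cell_means,
        animal_var=animal_var, residual_var=resid_var,
        n_animals=n_animals, n_cpgs=n_cpg, singular=singular,
        _contrast_cache={"fe": fe, "cov": cov, "rows": cache,
                         "ddf": ddf_between, "sm_result": fit, "sm_model": model},
    )


def _pretty(term: str) -> str:
    return {"sex": "Sex", "diet": "Diet", "sex:diet": "Sex:Diet",
            "cpg_index": "CpG"}.get(term, term)


def _cell_row(sub, sex, diet, n_cpg, cpg_fixed, names, slices) -> np.ndarray:
    """Design row for a Sex x Diet cell, averaged over CpG levels."""
    grid = pd.DataFrame({
        "sex": [sex] * max(n_cpg, 1),
        "diet": [diet] * max(n_cpg, 1),
        "cpg_index": sorted(sub["cpg_index"].unique()),
    })
    factors = {"sex": sorted(sub["sex"].unique()), "diet": sorted(sub["diet"].unique())}
    if cpg_fixed and n_cpg > 1:
        factors["cpg_index"] = sorted(sub["cpg_index"].unique())
    Xg, _, _ = stats_core.build_design(grid, factors, [("sex", "diet")])
    return Xg.mean(axis=0)


def _from_ols(assay, res: stats_core.EmmResult, n_animals, n_cpg, singular) -> MixedModelResult:
    anova = res.anova.rename(index=_pretty)
    cm = res.emmeans["cell"].copy()
    cm.index = pd.MultiIndex.from_tuples(cm.index, names=["sex", "diet"])
    cm = cm.rename(columns={"n": "n_animals"})
    return MixedModelResult(
        assay=assay, anova=anova, cell_means=cm,
        animal_var=0.0, residual_var=res.mse,
        n_animals=n_animals, n_cpgs=n_cpg, singular=singular,
        _contrast_cache={"ols": res},
    )


def pairwise_cells(result: MixedModelResult, correction: str = "bonferroni",
                   alpha: float = 0.05) -> pd.DataFrame:
    """Within-sex LPD vs CTRL contrasts on the model cell means,
    Bonferroni-corrected across the declared contrasts."""
    cache = result._contrast_cache or {}
    sexes = sorted({s for s, _ in result.cell_means.index})
    pairs = [((s, "LPD"), (s, "CTRL")) for s in sexes
             if (s, "LPD") in result.cell_means.index
             and (s, "CTRL") in result.cell_means.index]
    m = len(pairs) if correction == "bonferroni" else 1
    rows = []
    for a, b in pairs:
        if "ols" in cache:
            res: stats_core.EmmResult = cache["ols"]
            tab = stats_core.bonferroni_pairs(res, pairs=[(a, b)])
            diff, t, p = tab.loc[0, ["diff", "t", "p"]]
            ddf = res.df_resid
        else:
            c = cache["rows"][a] - cache["rows"][b]
            diff = float(c @ cache["fe"])
            se = float(np.sqrt(c @ cache["cov"] @ c))
            t = diff / se if se > 0 else np.inf
            ddf = cache["ddf"]
            p = 2 * stats.t.sf(abs(t), ddf)
        p_adj = min(1.0, p * m)
        rows.append({"sex": a[0], "contrast": "LPD - CTRL", "diff": diff,
                     "t": t, "df": ddf, "p": p, "p_adj": p_adj,
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows)


def global_methylation_check(
    table: pd.DataFrame,
    assays: tuple[str, ...] = ("B1", "IAP"),
) -> dict[str, stats_core.EmmResult]:
    """Factorial Sex x Diet GLM on per-animal mean methylation of the
    repeat-element (global methylation) assays."""
    out = {}
    for assay in assays:
        sub = table[table["assay"] == assay]
        if sub.empty:
            raise ValueError(f"no rows for assay {assay!r}")
        per_animal = (sub.groupby(["animal_id", "sex", "diet"], as_index=False)
                      ["pct_methylation"].mean())
        out[assay] = stats_core.factorial_glm(
            per_animal, "pct_methylation", ["sex", "diet"], interactions="full")
    return out
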