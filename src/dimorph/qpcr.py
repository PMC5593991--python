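"""dCt / ddCt quantitative-PCR analysis.

Per sample, dCt = Ct_target - mean(Ct of the two housekeeping genes)
(arithmetic mean of Cts = geometric mean on the linear scale).  Fold
change is 2^-(dCt - mean dCt of the reference group); the default
reference group is the control-diet group within each brain region, so
control marginal means hover near 1.  Gene-level statistics run on the
fold changes through the shared factorial GLM (Sex x Diet with
interaction), with estimated marginal means and Bonferroni pairwise
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_core

__all__ = ["delta_ct", "fold_change", "analyze_gene", "FoldChangeResult"]


def delta_ct(
    table: pd.DataFrame,
    hk_genes: tuple[str, str] = ("Gapdh", "Actb"),
) -> tuple[pd.DataFrame, dict]:
    """Normalize target Cts to the mean of the two housekeeping genes.

    Samples (animal x region) missing any housekeeping value are
    excluded and recorded in the log.  Returns (long dCt table, log).
    """
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    hk = table[table["gene"].isin(hk_genes)]
    hk_mean = hk.groupby(["animal_id", "region"])["ct"].agg(["mean", "size"])
    complete = hk_mean[hk_mean["size"] == len(hk_genes)]["mean"]
    targets = table[~table["gene"].isin(hk_genes)].copy()
    key = pd.MultiIndex.from_frame(targets[["animal_id", "region"]])
    targets["hk_mean"] = complete.reindex(key).to_numpy()
    dropped = targets[targets["hk_mean"].isna()]
    kept = targets.dropna(subset=["hk_mean"]).copy()
    kept["delta_ct"] = kept["ct"] - kept["hk_mean"]
    log = {
        "hk_genes": list(hk_genes),
        "n_samples_excluded": int(dropped[["animal_id", "region"]]
                                  .drop_duplicates().shape[0]),
        "excluded": dropped[["animal_id", "region"]].drop_duplicates()
                    .to_dict("records"),
    }
    return kept.drop(columns=["hk_mean"]), log


def fold_change(
    delta_cts: pd.DataFrame,
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """ddCt fold changes: FC = 2^-(dCt - reference-group mean dCt),
    computed per gene within each region.

    ``reference`` selects the reference group by factor levels
    (default {"diet": "CTRL"}); its mean fold change is 1 by construction.
    """
    reference = reference or {"diet": "CTRL"}
    out = delta_cts.copy()
    mask = np.ones(len(out), dtype=bool)
    for col, lv in reference.items():
        mask &= (out[col] == lv).to_numpy()
    if not mask.any():
        raise ValueError(f"reference group {reference} selects no samples")
    ref_means = (out[mask].groupby(["region", "gene"])["delta_ct"].mean()
                 .rename("ref_dct"))
    key = pd.MultiIndex.from_frame(out[["region", "gene"]])
    out["fold_change"] = 2.0 ** -(out["delta_ct"].to_numpy()
                                  - ref_means.reindex(key).to_numpy())
    return out


@dataclass
class FoldChangeResult:
    gene: str
    region: str
    glm: stats_core.EmmResult
    posthoc: pd.DataFrame


def analyze_gene(
    fold_changes: pd.DataFrame,
    gene: str,
    region: str,
    response: str = "fold_change",
    log2: bool = False,
) -> FoldChangeResult:
    """Two-way Sex x Diet GLM on a gene's fold changes in one region,
    with marginal means and Bonferroni pairwise cell contrasts.

    ``log2=True`` analyses log2 fold changes (equivalently, centred
    negative dCt) instead of the fold-change scale.
    """
    sub = fold_changes[(fold_changes["gene"] == gene)
                       & (fold_changes["region"] == region)].copy()
    if sub.empty:
        raise ValueError(f"no rows for gene {gene!r} in region {region!r}")
    if log2:
        sub["_resp"] = np.log2(sub[response])
        response = "_resp"
    glm = stats_core.factorial_glm(sub, response, ["sex", "diet"],
                                   interactions="full")
    posthoc = stats_core.bonferroni_pairs(glm)
    return FoldChangeResult(gene=gene, region=region, glm=glm, posthoc=posthoc)
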