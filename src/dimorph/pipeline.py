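"""Orchestration: configuration, file I/O and the end-to-end replay.

``run_end_to_end`` chains the stages — simulate inputs, run the
replication-validated DE screen, call consensus peaks, fit the
methylation mixed models, run the qPCR fold-change analysis and the
behavioral factorial GLM — on synthetic data, writing every intermediate
table plus a structured JSON report with per-stage filter accounting.
The orchestrator adds no computation of its own; every stage is
invocable standalone with file inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression_de, methylation, peak_consensus, qpcr, stats_core, synthgen

__all__ = ["RunConfig", "run_end_to_end", "load_config",
           "write_expression", "read_expression"]

log = logging.getLogger("dimorph")


# ---------------------------------------------------------------------------
# I/O helpers (TSV / BED, all plain text)
# ---------------------------------------------------------------------------

def write_expression(exp: synthgen.ExpressionExperiment, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.matrix.to_csv(outdir / "matrix.tsv", sep="\t")
    exp.samples.to_csv(outdir / "samples.tsv", sep="\t")
    if exp.truth is not None:
        exp.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_expression(matrix_path, samples_path) -> synthgen.ExpressionExperiment:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return synthgen.ExpressionExperiment(matrix, samples)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat per-stage parameters for the end-to-end replay."""

    seed: int = 0
    outdir: str = "dimorph_run"
    stages: tuple[str, ...] = ("expression", "peaks", "methylation", "qpcr", "behavior")

    # expression / DE screen
    n_probes: int = 20_000
    n_spiked: int = 100
    spike_log2fc: float = 1.0
    k: int = 1000
    alpha_rep: float = 0.1
    p_de: float = 0.01
    background_quantile: float = 0.1
    min_fraction: float = 0.5

    # peaks
    n_peak_samples: int = 18
    consensus_m: int = 14
    presence_prob: float = 16 / 18
    jitter_sd: float = 10.0
    noise_rate: float = 5.0

    # methylation
    meth_n_per_cell: int = 12
    cpgs_per_assay: int = 5
    interaction_effect_pct: float = 3.0

    # qpcr
    qpcr_n_per_cell: int = 12
    lpd_ct_shift: float = -1.0

    # behavior
    behavior_n_per_cell: int = 15
    crossover_sd_units: float = 1.0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    if "stages" in raw:
        cfg.stages = tuple(raw["stages"])
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.ndarray, pd.Index)):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_expression(cfg: RunConfig, outdir: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    design = synthgen.SimDesign(n_probes=cfg.n_probes, seed=int(rng.integers(2**31)))
    spiked = [f"P{i:06d}" for i in
              rng.choice(cfg.n_probes, size=cfg.n_spiked, replace=False)]
    signs = np.where(rng.random(cfg.n_spiked) < 0.5, -1.0, 1.0)
    effects = [synthgen.EffectSpec([p], "Stress", float(s * cfg.spike_log2fc))
               for p, s in zip(spiked, signs)]
    exp = synthgen.simulate_expression(design, effects)
    write_expression(exp, outdir / "expression")
    results, summary = expression_de.run_de_screen(
        exp, k=cfg.k, alpha_rep=cfg.alpha_rep, p_de=cfg.p_de,
        background_quantile=cfg.background_quantile, min_fraction=cfg.min_fraction)
    results.to_csv(outdir / "expression" / "de_results.tsv", sep="\t")
    validated = results.index[results["validated"]]
    recall = len(validated.intersection(pd.Index(spiked))) / max(len(spiked), 1)
    report = {
        "n_probes": cfg.n_probes,
        "filter": summary["filter"],
        "pc1_variance_fraction": summary["pc1_variance_fraction"],
        "n_candidates": summary["n_candidates"],
        "n_validated": summary["n_validated"],
        "spiked_recall": recall,
        "n_false_validated": int((~validated.isin(spiked)).sum()),
    }
    log.info("expression: %d candidates, %d validated, recall %.3f",
             report["n_candidates"], report["n_validated"], recall)
    return report


def _stage_peaks(cfg: RunConfig, outdir: Path) -> dict:
    rng = np.random.default_rng(cfg.seed + 1)
    true_loci = [("chrT", int(s), int(s) + 400)
                 for s in rng.integers(1_000, 990_000, 12) * 1]
    true_loci = peak_consensus.normalize_intervals(
        pd.DataFrame(true_loci, columns=["contig", "start", "end"])
    )[["contig", "start", "end"]].itertuples(index=False)
    true_loci = [tuple(t) for t in true_loci]
    input_loci = [("chrT", 995_000, 995_400)]
    colls, input_coll, truth = synthgen.simulate_peaksets(
        cfg.n_peak_samples, true_loci, presence_prob=cfg.presence_prob,
        jitter_sd=cfg.jitter_sd, noise_rate=cfg.noise_rate,
        input_loci=input_loci, seed=cfg.seed + 1)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(parents=True, exist_ok=True)
    for c in colls:
        peak_consensus.write_bed(c.intervals, peak_dir / f"{c.sample_id}.bed")
    peak_consensus.write_bed(input_coll.intervals, peak_dir / "input.bed")
    cons = peak_consensus.call_consensus(colls, input_coll, m=cfg.consensus_m)
    peak_consensus.write_bed(cons.to_frame(), peak_dir / "consensus.bed")
    report = {
        "n_samples": cfg.n_peak_samples,
        "m": cfg.consensus_m,
        "n_true_loci": len(true_loci),
        "n_consensus_regions": int(len(cons.regions)),
        "n_excluded_by_input": int(len(cons.excluded)),
    }
    log.info("peaks: %d consensus regions (%d excluded)",
             report["n_consensus_regions"], report["n_excluded_by_input"])
    return report


def _stage_methylation(cfg: RunConfig, outdir: Path) -> dict:
    table, truth = synthgen.simulate_methylation(
        n_per_cell=cfg.meth_n_per_cell, cpgs_per_assay=cfg.cpgs_per_assay,
        interaction_effect_pct=cfg.interaction_effect_pct, seed=cfg.seed + 2)
    mdir = outdir / "methylation"
    mdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(mdir / "methylation.tsv", sep="\t", index=False)
    report = {}
    for assay in ("promoter", "intron1a", "intron1b"):
        res = methylation.fit_cpg_mixed_model(table, assay)
        pw = methylation.pairwise_cells(res)
        res.anova.to_csv(mdir / f"{assay}_anova.tsv", sep="\t")
        report[assay] = {
            "interaction_F": float(res.anova.loc["Sex:Diet", "F"]),
            "interaction_p": float(res.anova.loc["Sex:Diet", "p"]),
            "female_lpd_vs_ctrl_p_adj": float(
                pw.set_index("sex").loc["F", "p_adj"]),
        }
    glob = methylation.global_methylation_check(table)
    report["global"] = {a: {"diet_p": float(r.anova.loc["diet", "p"])}
                        for a, r in glob.items()}
    log.info("methylation: intron1a interaction p=%.4g",
             report["intron1a"]["interaction_p"])
    return report


def _stage_qpcr(cfg: RunConfig, outdir: Path) -> dict:
    ct = synthgen.simulate_ct(
        n_per_cell=cfg.qpcr_n_per_cell,
        ct_effects={("Npy", "diet", "LPD"): cfg.lpd_ct_shift},
        seed=cfg.seed + 3)
    qdir = outdir / "qpcr"
    qdir.mkdir(parents=True, exist_ok=True)
    ct.to_csv(qdir / "ct.tsv", sep="\t", index=False)
    dct, dlog = qpcr.delta_ct(ct)
    fc = qpcr.fold_change(dct)
    fc.to_csv(qdir / "fold_changes.tsv", sep="\t", index=False)
    report = {"excluded_samples": dlog["n_samples_excluded"], "genes": {}}
    for gene in ("Npy", "Npy1r"):
        res = qpcr.analyze_gene(fc, gene, "amygdala")
        emm = res.glm.emmeans["diet"]
        report["genes"][gene] = {
            "diet_p": float(res.glm.anova.loc["diet", "p"]),
            "lpd_mean_fc": float(emm.loc["LPD", "emm"]),
            "ctrl_mean_fc": float(emm.loc["CTRL", "emm"]),
        }
    log.info("qpcr: Npy LPD mean FC %.3f", report["genes"]["Npy"]["lpd_mean_fc"])
    return report


def _stage_behavior(cfg: RunConfig, outdir: Path) -> dict:
    d = cfg.crossover_sd_units
    cells = {("M", "LPD"): -d, ("M", "CTRL"): d, ("F", "LPD"): d, ("F", "CTRL"): -d}
    beh = synthgen.simulate_behavior(cells, sd=1.0,
                                     n_per_cell=cfg.behavior_n_per_cell,
                                     seed=cfg.seed + 4)
    bdir = outdir / "behavior"
    bdir.mkdir(parents=True, exist_ok=True)
    beh.to_csv(bdir / "behavior.tsv", sep="\t", index=False)
    res = stats_core.factorial_glm(beh, "response", ["sex", "diet"],
                                   interactions="full")
    snk = stats_core.newman_keuls(res)
    snk.to_csv(bdir / "snk.tsv", sep="\t", index=False)
    return {
        "interaction_F": float(res.anova.loc["sex:diet", "F"]),
        "interaction_p": float(res.anova.loc["sex:diet", "p"]),
        "n_significant_snk_pairs": int(snk["significant"].sum()),
    }


STAGES = {
    "expression": _stage_expression,
    "peaks": _stage_peaks,
    "methylation": _stage_methylation,
    "qpcr": _stage_qpcr,
    "behavior": _stage_behavior,
}


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run the selected stages and write report.json + the echoed config."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    report = {"seed": cfg.seed, "stages": {}}
    for name in cfg.stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        report["stages"][name] = STAGES[name](cfg, outdir)
    report = _jsonable(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    summary_lines = [f"dimorph end-to-end replay (seed {cfg.seed})"]
    for name, stage in report["stages"].items():
        summary_lines.append(f"  [{name}] " + ", ".join(
            f"{k}={v}" for k, v in stage.items() if not isinstance(v, dict)))
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return report
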