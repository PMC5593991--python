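"""Synthetic data generators for the sex-by-diet factorial study designs.

Every generator is a pure function of its configuration plus a seed and
emits, alongside the simulated tables, a ground-truth record sufficient
to score recovery in the downstream modules.

The expression generator emulates a pooled two-color-free single-channel
microarray experiment: a 2x2x2 factorial (Sex x Diet x Stress) with two
arrays per cell (16 arrays, 32 animals pooled 2-by-2) plus a male-only
technical replication batch of 8 arrays.  Per-probe technical variances
are drawn from a scaled inverse-chi-square distribution (so the
empirical-Bayes moderation downstream sees its own generative model) and
a rank-1 technical batch component (per-array score x per-probe loading)
makes the first principal component the technical axis by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "SimDesign",
    "EffectSpec",
    "NoiseModel",
    "ExpressionExperiment",
    "simulate_expression",
    "simulate_peaksets",
    "simulate_methylation",
    "simulate_ct",
    "simulate_behavior",
]

SEX_LEVELS = ("M", "F")
DIET_LEVELS = ("LPD", "CTRL")
STRESS_LEVELS = ("swim", "none")


# ---------------------------------------------------------------------------
# expression arrays
# ---------------------------------------------------------------------------

@dataclass
class SimDesign:
    """Factorial array layout.

    Defaults give 16 main arrays (2 per Sex x Diet x Stress cell, each a
    pool of 2 animals) plus 8 male-only replication arrays.
    """

    n_probes: int = 60_000
    arrays_per_cell: int = 2
    pool_size: int = 2
    replication_arrays: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.arrays_per_cell < 1 or self.pool_size < 1:
            raise ValueError("counts must be positive")
        if self.replication_arrays % 4 != 0:
            raise ValueError("replication arrays spread over 4 male cells; "
                             "count must be a multiple of 4")

    @property
    def n_main_arrays(self) -> int:
        return self.arrays_per_cell * 8


@dataclass
class EffectSpec:
    """Spike-in truth: a signed log2 shift on a probe set for one factor
    (optionally an interaction with a second factor).  Main effects are
    applied at the factor's first level (M / LPD / swim); an interaction
    adds the shift only when both named factors sit at their first level.
    """

    probe_ids: list
    factor: str
    log2_effect: float
    interaction: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_effect):
            raise ValueError("log2_effect must be finite")


@dataclass
class NoiseModel:
    """Per-probe technical variances sigma_p^2 ~ s0_sq * d0 / chi2(d0),
    plus a rank-1 batch term whose share of the per-probe technical
    variance is ``batch_var_fraction`` and an animal-level biological sd
    (halved in variance by 2-animal pooling)."""

    d0: float = 4.0
    s0_sq: float = 0.04
    batch_var_fraction: float = 0.4
    bio_sd: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    dead_fraction: float = 0.0
    dead_level: float = 2.0

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.s0_sq < 0:
            raise ValueError("d0 must be positive and s0_sq non-negative")
        if not 0 <= self.batch_var_fraction < 1:
            raise ValueError("batch_var_fraction in [0, 1)")


@dataclass
class ExpressionExperiment:
    """Probe x sample log2 matrix with its factorial sample sheet."""

    matrix: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("matrix columns must match sample sheet index")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("expression matrix must be finite")

    def batch(self, name: str) -> "ExpressionExperiment":
        keep = self.samples.index[self.samples["batch"] == name]
        return ExpressionExperiment(self.matrix[keep], self.samples.loc[keep], self.truth)


def _sample_sheet(design: SimDesign) -> pd.DataFrame:
    rows = []
    for sex, diet, stress in product(SEX_LEVELS, DIET_LEVELS, STRESS_LEVELS):
        for r in range(design.arrays_per_cell):
            rows.append((f"main_{sex}_{diet}_{stress}_{r+1}", sex, diet, stress, "main"))
    per_cell = design.replication_arrays // 4
    for diet, stress in product(DIET_LEVELS, STRESS_LEVELS):
        for r in range(per_cell):
            rows.append((f"rep_M_{diet}_{stress}_{r+1}", "M", diet, stress, "replication"))
    return pd.DataFrame(
        rows, columns=["sample_id", "sex", "diet", "stress", "batch"]
    ).set_index("sample_id")


def _effect_matrix(design: SimDesign, effects: list[EffectSpec],
                   probe_ids: pd.Index, samples: pd.DataFrame) -> np.ndarray:
    first = {"Sex": "M", "Diet": "LPD", "Stress": "swim"}
    col_of = {"Sex": "sex", "Diet": "diet", "Stress": "stress"}
    seen: set[tuple] = set()
    delta = np.zeros((len(probe_ids), len(samples)))
    pos = pd.Series(np.arange(len(probe_ids)), index=probe_ids)
    for eff in effects:
        key_factors = tuple(sorted([eff.factor] + ([eff.interaction] if eff.interaction else [])))
        for p in eff.probe_ids:
            key = (p, key_factors)
            if key in seen:
                raise ValueError(f"overlapping effect specs for probe {p} on {key_factors}")
            seen.add(key)
        on = (samples[col_of[eff.factor]] == first[eff.factor]).to_numpy()
        if eff.interaction:
            on = on & (samples[col_of[eff.interaction]] == first[eff.interaction]).to_numpy()
        rows = pos.loc[list(eff.probe_ids)].to_numpy()
        delta[np.ix_(rows, np.where(on)[0])] += eff.log2_effect
    return delta


def simulate_expression(
    design: SimDesign,
    effects: list[EffectSpec] | None = None,
    noise: NoiseModel | None = None,
) -> ExpressionExperiment:
    """Simulate the factorial array experiment.

    Each array value is the mean of ``pool_size`` animal-level draws
    (baseline + design effects + N(0, bio_sd^2)) plus the rank-1 batch
    term and probe-specific technical noise N(0, sigma_p^2).
    """
    effects = effects or []
    noise = noise or NoiseModel()
    rng = np.random.default_rng(design.seed)
    samples = _sample_sheet(design)
    probe_ids = pd.Index([f"P{i:06d}" for i in range(design.n_probes)], name="probe")
    n_p, n_s = design.n_probes, len(samples)

    baseline = rng.normal(noise.baseline_mean, noise.baseline_sd, n_p)
    # spiked probes emulate immediate-early genes, which are robustly
    # expressed: reflect their baselines above the array median so the
    # low-signal filter sees them as real signals
    if effects:
        pos = pd.Series(np.arange(n_p), index=probe_ids)
        spiked_rows = pos.loc[sorted({p for e in effects for p in e.probe_ids})]
        baseline[spiked_rows] = noise.baseline_mean + np.abs(
            baseline[spiked_rows] - noise.baseline_mean)
    n_dead = int(round(noise.dead_fraction * n_p))
    dead = rng.choice(n_p, size=n_dead, replace=False) if n_dead else np.array([], int)
    baseline[dead] = noise.dead_level

    if np.isinf(noise.d0):
        sigma2 = np.full(n_p, noise.s0_sq)
    else:
        sigma2 = noise.s0_sq * noise.d0 / rng.chisquare(noise.d0, n_p)

    delta = _effect_matrix(design, effects, probe_ids, samples)
    signal = baseline[:, None] + delta

    # pooling: average pool_size animal draws of the biological noise
    bio = rng.normal(0.0, noise.bio_sd, (n_p, n_s, design.pool_size)).mean(axis=2) \
        if noise.bio_sd > 0 else 0.0

    f = noise.batch_var_fraction
    if f > 0:
        # main and replication batches ran on different scanners in
        # different labs: each gets its own technical axis (independent
        # per-probe loading signs), with per-array scores
        scores = rng.normal(0.0, 1.0, n_s)
        scale = np.sqrt(f / (1 - f) * sigma2)
        batch_term = np.zeros((n_p, n_s))
        for b in ("main", "replication"):
            cols = (samples["batch"] == b).to_numpy()
            if cols.any():
                loadings = scale * np.sign(rng.normal(size=n_p))
                batch_term[:, cols] = loadings[:, None] * scores[None, cols]
    else:
        scores = np.zeros(n_s)
        batch_term = 0.0

    tech = rng.normal(0.0, 1.0, (n_p, n_s)) * np.sqrt(sigma2)[:, None]
    mat = pd.DataFrame(signal + bio + batch_term + tech,
                       index=probe_ids, columns=samples.index)

    truth_rows = [
        {"probe": p, "factor": e.factor, "interaction": e.interaction or "",
         "log2_effect": e.log2_effect}
        for e in effects for p in e.probe_ids
    ]
    truth = pd.DataFrame(truth_rows, columns=["probe", "factor", "interaction", "log2_effect"])
    samples = samples.copy()
    samples["batch_score"] = scores
    truth.attrs["dead_probes"] = list(probe_ids[dead])
    return ExpressionExperiment(mat, samples, truth)


# ---------------------------------------------------------------------------
# replicate peak sets
# ---------------------------------------------------------------------------

def simulate_peaksets(
    n_samples: int,
    true_loci: list[tuple[str, int, int]],
    presence_prob: float = 14 / 18,
    jitter_sd: float = 0.0,
    noise_rate: float = 0.0,
    input_loci: list[tuple[str, int, int]] | None = None,
    contig: str = "chrT",
    contig_length: int = 1_000_000,
    noise_width: int = 200,
    seed: int = 0,
):
    """Simulate replicate peak-call interval sets on a toy contig.

    Each sample carries each true locus with probability
    ``presence_prob``, boundaries jittered by N(0, jitter_sd) and clamped
    at 0; Poisson noise peaks arrive at ``noise_rate`` per Mb.  Returns
    (list of per-sample interval DataFrames, input DataFrame, truth table).
    """
    from .peak_consensus import PeakCollection

    rng = np.random.default_rng(seed)
    input_loci = input_loci or []
    for c, s, e in list(true_loci) + list(input_loci):
        if s < 0 or e > contig_length or s >= e:
            raise ValueError(f"invalid interval ({c},{s},{e}) on toy contig")

    collections = []
    presence = np.zeros((len(true_loci), n_samples), dtype=bool)
    for k in range(n_samples):
        rows = []
        for i, (c, s, e) in enumerate(true_loci):
            if rng.random() < presence_prob:
                presence[i, k] = True
                if jitter_sd > 0:
                    s2 = max(0, int(round(s + rng.normal(0, jitter_sd))))
                    e2 = max(s2 + 1, int(round(e + rng.normal(0, jitter_sd))))
                else:
                    s2, e2 = s, e
                rows.append((c, s2, min(e2, contig_length)))
        n_noise = rng.poisson(noise_rate * contig_length / 1e6)
        for _ in range(n_noise):
            start = int(rng.integers(0, max(1, contig_length - noise_width)))
            rows.append((contig, start, start + noise_width))
        df = pd.DataFrame(rows, columns=["contig", "start", "end"])
        collections.append(PeakCollection(f"rep{k+1:02d}", df))
    input_df = pd.DataFrame(input_loci, columns=["contig", "start", "end"])
    input_collection = PeakCollection("input", input_df)
    truth = pd.DataFrame(
        [{"contig": c, "start": s, "end": e, "n_present": int(presence[i].sum())}
         for i, (c, s, e) in enumerate(true_loci)]
    )
    return collections, input_collection, truth


# ---------------------------------------------------------------------------
# CpG methylation
# ---------------------------------------------------------------------------

INTRON_ASSAYS = ("intron1a", "intron1b")
DEFAULT_ASSAYS = ("promoter", "intron1a", "intron1b", "B1", "IAP")


def simulate_methylation(
    n_per_cell: int = 12,
    assays: tuple[str, ...] = DEFAULT_ASSAYS,
    cpgs_per_assay: int = 5,
    baseline_pct: float = 5.0,
    animal_sd: float = 1.5,
    residual_sd: float = 1.5,
    interaction_effect_pct: float = 3.0,
    cpg_spread_pct: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal per-CpG percent methylation in a Sex x Diet design.

    A per-(animal, assay) random intercept induces the within-animal
    correlation across CpGs; the Sex x Diet interaction (LPD females
    shifted by ``interaction_effect_pct``) is confined to the intron
    assays.  Values are clamped to [0, 100].  Returns (long table, truth).
    """
    if not 0 <= baseline_pct <= 100:
        raise ValueError("baseline_pct must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    cpg_offsets = (np.linspace(-1.0, 1.0, cpgs_per_assay) * cpg_spread_pct
                   if cpgs_per_assay > 1 else np.zeros(1))
    rows = []
    aid = 0
    for sex, diet in product(SEX_LEVELS, DIET_LEVELS):
        for _ in range(n_per_cell):
            aid += 1
            animal = f"A{aid:03d}"
            for assay in assays:
                intercept = rng.normal(0.0, animal_sd) if animal_sd > 0 else 0.0
                shift = (interaction_effect_pct
                         if assay in INTRON_ASSAYS and sex == "F" and diet == "LPD"
                         else 0.0)
                for c in range(cpgs_per_assay):
                    eps = rng.normal(0.0, residual_sd) if residual_sd > 0 else 0.0
                    val = baseline_pct + cpg_offsets[c] + intercept + shift + eps
                    rows.append((animal, sex, diet, assay, c + 1,
                                 float(np.clip(val, 0.0, 100.0))))
    table = pd.DataFrame(
        rows, columns=["animal_id", "sex", "diet", "assay", "cpg_index", "pct_methylation"]
    )
    truth = pd.DataFrame(
        [{"assay": a,
          "lpd_female_shift_pct": interaction_effect_pct if a in INTRON_ASSAYS else 0.0}
         for a in assays]
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct(
    n_per_cell: int = 12,
    targets: tuple[str, ...] = ("Npy", "Npy1r"),
    hk_genes: tuple[str, str] = ("Gapdh", "Actb"),
    region: str = "amygdala",
    ct_effects: dict[tuple[str, str, str], float] | None = None,
    base_ct: float = 25.0,
    hk_means: tuple[float, float] = (18.0, 20.0),
    sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample Ct table for a Sex x Diet design with two stable
    housekeeping genes.

    ``ct_effects`` maps (target, factor, level) -> Ct shift in cycles
    (negative shift = more expression), e.g. {("Npy", "diet", "LPD"): -1.0}.
    """
    rng = np.random.default_rng(seed)
    ct_effects = ct_effects or {}
    rows = []
    aid = 0
    for sex, diet in product(SEX_LEVELS, DIET_LEVELS):
        for _ in range(n_per_cell):
            aid += 1
            animal = f"A{aid:03d}"
            level = {"sex": sex, "diet": diet}
            for hk, mu in zip(hk_genes, hk_means):
                ct = mu + (rng.normal(0, sd) if sd > 0 else 0.0)
                rows.append((animal, sex, diet, region, hk, ct))
            for tg in targets:
                shift = sum(
                    v for (t, f, lv), v in ct_effects.items()
                    if t == tg and level.get(f) == lv
                )
                ct = base_ct + shift + (rng.normal(0, sd) if sd > 0 else 0.0)
                rows.append((animal, sex, diet, region, tg, ct))
    return pd.DataFrame(rows, columns=["animal_id", "sex", "diet", "region", "gene", "ct"])


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    cell_means: dict[tuple[str, str], float],
    sd: float = 1.0,
    n_per_cell: int = 15,
    response: str = "response",
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-animal responses with declared Sex x Diet cell means
    (e.g. a pure crossover interaction)."""
    rng = np.random.default_rng(seed)
    rows = []
    aid = 0
    for (sex, diet), mu in cell_means.items():
        for _ in range(n_per_cell):
            aid += 1
            val = mu + (rng.normal(0, sd) if sd > 0 else 0.0)
            rows.append((f"A{aid:03d}", sex, diet, val))
    return pd.DataFrame(rows, columns=["animal_id", "sex", "diet", response])
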