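"""Synthetic data with known ground truth for the two study designs.

Two generators are provided:

:func:`simulate_perturbation`
    A small bead-array style perturbation experiment — two conditions
    (control vs. transcription-factor overexpression), two time points, two
    replicate cultures each — on the raw intensity scale with
    intensity-dependent noise, detection calls and a planted set of truly
    differential genes.  The noise model is

    .. math:: x = 2^{\\mu + \\delta}(1 + \\varepsilon_m) + \\varepsilon_a

    with per-probe baseline :math:`\\mu \\sim N(7, 1.5^2)` on the log2 scale,
    multiplicative noise :math:`\\varepsilon_m \\sim N(0, \\mathrm{cv}^2)` and
    additive background noise :math:`\\varepsilon_a \\sim N(0, \\sigma_a^2)`,
    clipped at zero.  This reproduces the mean–variance relationship
    (variance :math:`\\approx \\sigma_a^2 + \\mathrm{cv}^2\\mu^2`) that
    motivates the variance-stabilizing transformation.

:func:`simulate_cohort`
    A ~75-sample skin-biopsy style cohort on a centered log-ratio scale,
    partitioned into molecular subsets, in which a supplied signature is
    expressed concordantly in the two "diffuse" subsets and only partially
    (default 14% of genes) in the "inflammatory" subset.

Both are deterministic given their config seed (one RNG stream per call, no
global state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import (
    ConfigError,
    ExpressionDataset,
    GeneSignature,
    InputError,
    SyntheticTruth,
)

CONTROL = "control"
PERTURBED = "perturbed"

COHORT_SUBSETS = ("diffuse1", "diffuse2", "inflammatory", "limited", "normal-like")
DIFFUSE_SUBSETS = ("diffuse1", "diffuse2")


@dataclass
class PerturbationSimConfig:
    """Design and noise parameters of the simulated perturbation experiment."""

    n_probes: int = 13000
    n_replicates: int = 2
    time_points: tuple[str, ...] = ("24h", "48h")
    n_planted_48: int = 600
    n_planted_24: int = 220
    lfc_range: tuple[float, float] = (1.2, 3.0)
    frac_up: float = 0.4
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.5
    additive_sd: float = 30.0
    multiplicative_cv: float = 0.12
    frac_all_absent: float = 0.07
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_probes, self.n_replicates) <= 0:
            raise ConfigError("n_probes and n_replicates must be positive")
        if not self.time_points:
            raise ConfigError("time_points must be non-empty")
        if self.n_planted_48 < 0 or self.n_planted_24 < 0:
            raise ConfigError("planted counts must be non-negative")
        if not self.n_planted_24 <= self.n_planted_48 <= self.n_probes:
            raise ConfigError(
                "invariant violated: n_planted_24 <= n_planted_48 <= n_probes"
            )
        if not 0 < self.lfc_range[0] <= self.lfc_range[1]:
            raise ConfigError("lfc_range must satisfy 0 < lo <= hi")
        if not 0 <= self.frac_up <= 1:
            raise ConfigError("frac_up must be in [0, 1]")
        if not 0 <= self.frac_all_absent < 1:
            raise ConfigError("frac_all_absent must be in [0, 1)")
        if self.baseline_log_sd < 0 or self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ConfigError("noise scales must be non-negative")


@dataclass
class CohortSimConfig:
    """Design of the simulated projection cohort.

    ``subset_proportions`` partitions the samples into the five molecular
    subsets; the planted signature is fully expressed in the two "diffuse"
    subsets and in ``inflammatory_concordant_frac`` of its genes in the
    inflammatory subset.  ``platform_coverage`` drops a fraction of
    signature genes from the cohort platform, emulating cross-platform gene
    matching losses.  ``n_background_genes`` non-signature genes fill out
    the platform.
    """

    n_samples: int = 75
    subset_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "diffuse1": 0.12,
            "diffuse2": 0.12,
            "inflammatory": 0.24,
            "limited": 0.28,
            "normal-like": 0.24,
        }
    )
    signature_effect: float = 1.0
    inflammatory_concordant_frac: float = 0.14
    gene_noise_sd: float = 0.6
    platform_coverage: float = 0.85
    n_background_genes: int = 4000
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        total = sum(self.subset_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subset proportions must sum to 1 (got {total})")
        if any(p < 0 for p in self.subset_proportions.values()):
            raise ConfigError("subset proportions must be non-negative")
        if not 0 <= self.inflammatory_concordant_frac <= 1:
            raise ConfigError("inflammatory_concordant_frac must be in [0, 1]")
        if not 0 < self.platform_coverage <= 1:
            raise ConfigError("platform_coverage must be in (0, 1]")
        if self.signature_effect < 0 or self.gene_noise_sd < 0:
            raise ConfigError("signature_effect and gene_noise_sd must be >= 0")
        if self.n_background_genes < 0:
            raise ConfigError("n_background_genes must be >= 0")


def _largest_remainder(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Allocate n items to labels by the largest-remainder method.

    Deterministic: remainder ties broken by label order as given."""
    labels = list(proportions)
    quotas = np.array([proportions[l] * n for l in labels])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # stable sort by descending remainder; ties keep label order
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(labels, counts.tolist()))


def simulate_perturbation(
    config: PerturbationSimConfig,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the two-condition × time-points × replicates experiment.

    Returns raw (linear-scale) intensities with detection flags, plus the
    ground-truth record of planted genes and their log2 effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = [f"G{i:05d}" for i in range(1, n + 1)]

    # all-absent probes: pure additive noise around background, flagged absent
    n_absent = int(round(config.frac_all_absent * n))
    absent_idx = rng.choice(n, size=n_absent, replace=False)
    absent_mask = np.zeros(n, dtype=bool)
    absent_mask[absent_idx] = True
    present_idx = np.flatnonzero(~absent_mask)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    # Planted genes are drawn from *expressed* present probes: baseline
    # intensity above the additive-noise scale sigma_a/cv (the glog
    # transition), below which a fold-change is not measurable on this
    # platform.  Falls back to the brightest present probes if too few
    # clear the floor.
    if config.multiplicative_cv > 0 and config.additive_sd > 0:
        floor = np.log2(config.additive_sd / config.multiplicative_cv)
    else:
        floor = -np.inf
    expressed = present_idx[baseline[present_idx] >= floor]
    if expressed.size < config.n_planted_48:
        order = np.argsort(-baseline[present_idx], kind="stable")
        expressed = present_idx[order[: max(config.n_planted_48, 1)]]
    planted48 = rng.choice(expressed, size=config.n_planted_48, replace=False)
    planted24 = rng.choice(planted48, size=config.n_planted_24, replace=False) \
        if config.n_planted_24 else np.array([], dtype=int)
    lo, hi = config.lfc_range
    magnitudes = rng.uniform(lo, hi, size=config.n_planted_48)
    signs = np.where(rng.random(config.n_planted_48) < config.frac_up, 1.0, -1.0)
    effects48 = magnitudes * signs

    effect_by_probe_time = np.zeros((n, len(config.time_points)))
    last_t = len(config.time_points) - 1
    t24 = 0  # first listed time point carries the nested early set
    effect_by_probe_time[planted48, last_t] = effects48
    if config.n_planted_24:
        pos = {p: i for i, p in enumerate(planted48)}
        e24 = np.array([effects48[pos[p]] for p in planted24])
        effect_by_probe_time[planted24, t24] = e24

    background_level = max(2.0 * config.additive_sd, 1.0)

    sample_ids: list[str] = []
    ann_rows: list[dict[str, str]] = []
    columns: list[np.ndarray] = []
    for ti, time in enumerate(config.time_points):
        for condition in (CONTROL, PERTURBED):
            for rep in range(1, config.n_replicates + 1):
                mu = baseline.copy()
                if condition == PERTURBED:
                    mu = mu + effect_by_probe_time[:, ti]
                eps_m = rng.normal(0.0, config.multiplicative_cv, size=n)
                eps_a = rng.normal(0.0, config.additive_sd, size=n)
                x = np.exp2(mu) * (1.0 + eps_m) + eps_a
                # absent probes carry no true signal: background + additive noise
                x[absent_mask] = background_level + eps_a[absent_mask]
                columns.append(np.clip(x, 0.0, None))
                sid = f"{'C' if condition == CONTROL else 'E'}{time}_r{rep}"
                sample_ids.append(sid)
                ann_rows.append({"condition": condition, "time": time})

    values = pd.DataFrame(
        np.column_stack(columns), index=probe_ids, columns=sample_ids
    )
    detection = pd.DataFrame(
        np.tile(~absent_mask[:, None], (1, len(sample_ids))),
        index=probe_ids, columns=sample_ids,
    )
    annotations = pd.DataFrame(ann_rows, index=sample_ids)

    planted: dict[str, dict[str, float]] = {}
    time48 = config.time_points[last_t]
    time24 = config.time_points[t24]
    p24 = set(planted24.tolist())
    for p, eff in zip(planted48.tolist(), effects48.tolist()):
        entry = {time48: eff}
        if p in p24 and time24 != time48:
            entry[time24] = eff
        planted[probe_ids[p]] = entry

    truth = SyntheticTruth(
        planted_genes=planted,
        configs={"perturbation": asdict(config)},
    )
    dataset = ExpressionDataset(values, "linear", annotations, detection)
    return dataset, truth


def simulate_cohort(
    signature: GeneSignature, config: CohortSimConfig
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the projection cohort on a centered log-ratio scale.

    Signature genes surviving platform coverage are shifted by
    ``signature_effect × direction`` in the diffuse subsets and, for the
    concordant fraction only, in the inflammatory subset.
    """
    config.validate()
    if len(signature) == 0:
        raise InputError("signature must be non-empty")
    rng = np.random.default_rng(config.seed)

    sig_genes = list(signature.genes)
    n_cov = int(round(config.platform_coverage * len(sig_genes)))
    n_cov = max(n_cov, 0)
    covered = sorted(
        rng.choice(len(sig_genes), size=n_cov, replace=False).tolist()
    )
    covered_genes = [sig_genes[i] for i in covered]
    directions = signature.directions.loc[covered_genes].to_numpy(dtype=float)

    background_genes = [f"B{i:05d}" for i in range(1, config.n_background_genes + 1)]
    gene_ids = covered_genes + background_genes
    n_genes = len(gene_ids)

    counts = _largest_remainder(config.n_samples, config.subset_proportions)
    subsets: list[str] = []
    for label in config.subset_proportions:
        subsets.extend([label] * counts[label])
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    subset_by_sample = dict(zip(sample_ids, subsets))

    values = rng.normal(0.0, config.gene_noise_sd, size=(n_genes, config.n_samples))

    n_inflam = int(round(config.inflammatory_concordant_frac * n_cov))
    inflam_sel = rng.choice(n_cov, size=n_inflam, replace=False) if n_inflam else np.array([], dtype=int)

    shift = config.signature_effect * directions
    for j, label in enumerate(subsets):
        if label in DIFFUSE_SUBSETS:
            values[:n_cov, j] += shift
        elif label == "inflammatory" and n_inflam:
            values[inflam_sel, j] += shift[inflam_sel]

    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    annotations = pd.DataFrame({"subset": subsets}, index=sample_ids)
    dataset = ExpressionDataset(df, "log-ratio", annotations)

    inflam_genes = {covered_genes[i] for i in inflam_sel.tolist()}
    truth = SyntheticTruth(
        cohort_subsets=subset_by_sample,
        cohort_shifted_genes={
            "diffuse1": set(covered_genes),
            "diffuse2": set(covered_genes),
            "inflammatory": inflam_genes,
        },
        configs={"cohort": asdict(config)},
    )
    return dataset, truth
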