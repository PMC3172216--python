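"""Empirical-Bayes moderated two-group differential expression.

With only two replicate cultures per condition, per-gene variance estimates
are unusable on their own.  The classical remedy is to borrow strength
across genes: assume the true residual variances σ² follow a scaled
inverse-chi-square prior with hyper-parameters (d0, s0²), estimate those by
moment matching on log sample variances, and replace each gene's s² by the
posterior mean

    s̃² = (d0·s0² + df·s²) / (d0 + df).

The moderated statistic t = lfc / sqrt(s̃²·(1/n1 + 1/n2)) then follows a t
distribution on d0 + df degrees of freedom under the null, which is what
makes small-sample microarray inference tractable.  Multiple testing is
controlled by Benjamini–Hochberg step-up FDR, and signatures are derived by
a joint FDR + fold-change threshold.

The model-level interface is :class:`ModeratedTTest` /
:class:`ModeratedTTestResults`; the individual computational steps are
exposed as module functions (``fit_gene_models``, ``estimate_prior``,
``moderate_t``, ``bh_adjust``, ``derive_signature``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import (
    ConfigError,
    ExpressionDataset,
    GeneSignature,
    InputError,
)
from .simulate import CONTROL, PERTURBED

D0_INFINITE_CAP = 1e6  # d0 at or above this is treated as infinite


@dataclass
class EBayesPrior:
    """Scaled inverse-chi-square prior on gene-wise residual variances."""

    d0: float  # prior degrees of freedom; math.inf allowed
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 >= 0 or math.isinf(self.d0)):
            raise ConfigError("d0 must be >= 0 or infinite")
        if not self.s0_sq > 0:
            raise ConfigError("s0_sq must be positive")

    @property
    def infinite(self) -> bool:
        return math.isinf(self.d0) or self.d0 >= D0_INFINITE_CAP


# ---------------------------------------------------------------------------
# per-gene two-group statistics
# ---------------------------------------------------------------------------

def fit_gene_models(
    dataset: ExpressionDataset,
    contrast: tuple[str, str] = (CONTROL, PERTURBED),
    time: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-group summaries for one contrast at one time point.

    ``contrast`` is (reference, perturbation); lfc = mean(perturbation) −
    mean(reference) on the log scale.  Returns a DataFrame indexed by gene
    with columns lfc, s_sq (pooled within-group variance, ddof=1),
    df_residual, mean_expr, n1, n2.
    """
    if dataset.scale == "linear":
        raise InputError("fit_gene_models expects log-scale data")
    ref_label, pert_label = contrast
    sel = {"condition": ref_label}
    if time is not None:
        sel["time"] = time
    ref_samples = dataset.samples_where(**sel)
    sel["condition"] = pert_label
    pert_samples = dataset.samples_where(**sel)
    n1, n2 = len(ref_samples), len(pert_samples)
    if n1 < 2 or n2 < 2:
        raise InputError(
            f"each group needs >=2 samples (got {n1} {ref_label!r}, "
            f"{n2} {pert_label!r}"
            + (f" at time {time!r})" if time is not None else ")")
        )
    ref = dataset.values[ref_samples].to_numpy(float)
    pert = dataset.values[pert_samples].to_numpy(float)
    lfc = pert.mean(axis=1) - ref.mean(axis=1)
    v1 = ref.var(axis=1, ddof=1)
    v2 = pert.var(axis=1, ddof=1)
    s_sq = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "s_sq": s_sq,
            "df_residual": float(n1 + n2 - 2),
            "mean_expr": np.column_stack([ref, pert]).mean(axis=1),
            "n1": n1,
            "n2": n2,
        },
        index=dataset.feature_ids,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes prior estimation (moment matching on log variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s_sq: np.ndarray, df_residual: float) -> EBayesPrior:
    """Estimate (d0, s0²) by moment matching on z = log(s²).

    Under the model s² ~ s0²·F(df, d0), z has mean
    log s0² + ψ(df/2) − log(df/2) − ψ(d0/2) + log(d0/2) and variance
    ψ'(df/2) + ψ'(d0/2).  The excess of Var(z) over the pure sampling term
    ψ'(df/2) identifies d0 through the trigamma function; no excess means
    the variances are exchangeable and d0 is reported infinite.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    finite = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if finite.size < 10:
        raise InputError(
            f"need >=10 finite positive variances to estimate the prior "
            f"(got {finite.size}); use a fixed EBayesPrior instead"
        )
    df = float(df_residual)
    z = np.log(finite)
    e_mean = float(z.mean())
    e_var = float(z.var(ddof=1))
    digamma_df = float(special.digamma(df / 2))
    trigamma_df = float(special.polygamma(1, df / 2))
    excess = e_var - trigamma_df
    if excess <= 0:
        d0 = math.inf
        log_s0 = e_mean - digamma_df + math.log(df / 2)
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        if d0 >= D0_INFINITE_CAP:
            d0 = math.inf
            log_s0 = e_mean - digamma_df + math.log(df / 2)
        else:
            log_s0 = (
                e_mean
                - digamma_df
                + math.log(df / 2)
                + float(special.digamma(half_d0))
                - math.log(half_d0)
            )
    return EBayesPrior(d0=d0, s0_sq=float(math.exp(log_s0)))


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def moderate_t(gene_stats: pd.DataFrame, prior: EBayesPrior) -> pd.DataFrame:
    """Shrink variances toward the prior and compute moderated t and p.

    Adds columns s_tilde_sq, t_mod, p to a copy of ``gene_stats``.  With
    d0 = 0 the ordinary pooled two-sample t is recovered; with d0 infinite
    every s̃² equals s0² and the reference distribution is normal.
    """
    out = gene_stats.copy()
    s_sq = out["s_sq"].to_numpy(float)
    df = out["df_residual"].to_numpy(float)
    lfc = out["lfc"].to_numpy(float)
    inv_n = 1.0 / out["n1"].to_numpy(float) + 1.0 / out["n2"].to_numpy(float)
    if prior.infinite:
        s_tilde = np.full_like(s_sq, prior.s0_sq)
        total_df = np.full_like(df, math.inf)
    else:
        s_tilde = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        total_df = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s_tilde * inv_n)
    if prior.infinite:
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out["s_tilde_sq"] = s_tilde
    out["t_mod"] = t
    out["p"] = p
    out["df_total"] = total_df
    return out


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} m·p_(j)/j, capped at 1; input order restored.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("all p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# signature derivation
# ---------------------------------------------------------------------------

def derive_signature(
    table: pd.DataFrame,
    fdr: float = 0.01,
    fold: float = 2.0,
    name: str = "signature",
    time: str | None = None,
    use_raw_p: bool = False,
) -> GeneSignature:
    """Threshold a differential table into a directional gene signature.

    Selects genes with q < fdr (or raw p < fdr when ``use_raw_p``) and
    |lfc| >= log2(fold); weights are the log2 fold-changes.
    """
    if not 0 < fdr < 1:
        raise ConfigError("fdr must be in (0, 1)")
    if fold < 1:
        raise ConfigError("fold must be >= 1")
    crit = table["p"] if use_raw_p else table["q"]
    lfc = table["lfc"]
    selected = table[(crit < fdr) & (lfc.abs() >= np.log2(fold))]
    entries = pd.DataFrame(
        {
            "direction": np.sign(selected["lfc"]).astype(int).to_numpy(),
            "weight": selected["lfc"].to_numpy(float),
        },
        index=selected.index,
    )
    return GeneSignature(name=name, entries=entries, time=time, fdr=fdr, fold=fold)


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class ModeratedTTest:
    """Empirical-Bayes moderated two-group comparison at one time point.

    Parameters
    ----------
    dataset
        Log-scale expression data with condition/time annotations.
    contrast
        (reference condition, perturbation condition).
    time
        Time-point label selecting the samples; None uses all samples.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        contrast: tuple[str, str] = (CONTROL, PERTURBED),
        time: str | None = None,
    ):
        self.dataset = dataset
        self.contrast = contrast
        self.time = time

    def fit(self, prior: EBayesPrior | None = None) -> "ModeratedTTestResults":
        """Fit per-gene models, estimate (or accept) the prior, moderate,
        and BH-adjust.  Returns a results object holding the full table."""
        gene_stats = fit_gene_models(self.dataset, self.contrast, self.time)
        if prior is None:
            prior = estimate_prior(
                gene_stats["s_sq"].to_numpy(),
                float(gene_stats["df_residual"].iloc[0]),
            )
        table = moderate_t(gene_stats, prior)
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["direction"] = np.sign(table["lfc"]).astype(int)
        table["time"] = self.time
        return ModeratedTTestResults(self, prior, table)


class ModeratedTTestResults:
    """Results of a moderated two-group comparison.

    Attributes
    ----------
    table : pandas.DataFrame
        Per-gene lfc, s_sq, df_residual, mean_expr, s_tilde_sq, t_mod, p, q,
        direction, time.
    prior : EBayesPrior
        The (estimated or supplied) variance prior.
    """

    def __init__(self, model: ModeratedTTest, prior: EBayesPrior, table: pd.DataFrame):
        self.model = model
        self.prior = prior
        self.table = table

    def derive_signature(
        self,
        fdr: float = 0.01,
        fold: float = 2.0,
        name: str | None = None,
        use_raw_p: bool = False,
    ) -> GeneSignature:
        if name is None:
            t = self.model.time or "all"
            name = f"{self.model.contrast[1]}-{t}"
        return derive_signature(
            self.table, fdr=fdr, fold=fold, name=name,
            time=self.model.time, use_raw_p=use_raw_p,
        )

    def summary(self, fdr: float = 0.01, fold: float = 2.0, top: int = 10) -> str:
        """Plain-text summary in the spirit of a model-results table."""
        t = self.table
        sig = t[(t["q"] < fdr) & (t["lfc"].abs() >= np.log2(fold))]
        d0 = "inf" if self.prior.infinite else f"{self.prior.d0:.3g}"
        lines = [
            "Moderated two-group comparison",
            "=" * 46,
            f"contrast:        {self.model.contrast[1]} - {self.model.contrast[0]}",
            f"time point:      {self.model.time}",
            f"genes tested:    {len(t)}",
            f"prior d0:        {d0}",
            f"prior s0^2:      {self.prior.s0_sq:.6g}",
            f"q<{fdr:g} & |lfc|>=log2({fold:g}): "
            f"{len(sig)} ({int((sig['lfc'] > 0).sum())} up, "
            f"{int((sig['lfc'] < 0).sum())} down)",
            "",
            f"top {top} genes by p-value:",
            t.nsmallest(top, "p")[["lfc", "t_mod", "p", "q"]].to_string(
                float_format=lambda x: f"{x:.4g}"
            ),
        ]
        return "\n".join(lines)
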