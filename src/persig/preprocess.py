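"""Preprocessing chain for raw bead-array intensities.

The chain runs, in order:

1. :func:`filter_absent_probes` — drop probes called "absent" (below array
   background) in *every* sample;
2. :func:`apply_vst` — a generalized-log variance-stabilizing transform
   glog2(x) = log2((x + sqrt(x² + c²)) / 2), with the offset c fitted from
   the replicate mean–variance trend by :func:`fit_vst`;
3. :func:`quantile_normalize` — force every sample to a common empirical
   distribution.

The glog2 family is asymptotically log2(x) for x >> c and linear near zero,
so with c = σ_additive / cv_multiplicative it stabilizes the variance of the
two-component (additive + multiplicative) intensity noise model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ConfigError, ExpressionDataset, InputError

logger = logging.getLogger(__name__)

C_MIN = 1e-3
C_MAX = 1e6


@dataclass
class VstParams:
    """Fitted parameters of the generalized-log transform.

    c is the glog offset; when fitted from the replicate trend
    Var ≈ a + b·mean², a is the additive variance, b the squared
    multiplicative CV, and c = sqrt(a/b).
    """

    c: float
    fitted_from: str = "fixed"  # {"replicate-trend", "fixed"}
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ConfigError("VST offset c must be positive")
        if self.a is not None and self.a < 0:
            raise ConfigError("additive variance a must be >= 0")
        if self.b is not None and self.b < 0:
            raise ConfigError("multiplicative variance slope b must be >= 0")


# ---------------------------------------------------------------------------
# detection filtering
# ---------------------------------------------------------------------------

def filter_absent_probes(
    dataset: ExpressionDataset,
    background_quantile: float | None = None,
) -> tuple[ExpressionDataset, list[str]]:
    """Remove probes undetected in every sample.

    A probe is removed iff its detection flag is False in all samples.  When
    the dataset carries no detection matrix, a fallback rule may be enabled
    by passing ``background_quantile`` (e.g. 0.05): a probe is then removed
    iff its intensity lies below that quantile of each sample's intensities
    in every sample.

    Returns the filtered dataset (probe order preserved) and the list of
    removed probe ids.
    """
    if dataset.detection is not None:
        keep = dataset.detection.to_numpy(bool).any(axis=1)
    elif background_quantile is not None:
        if not 0 < background_quantile < 1:
            raise ConfigError("background_quantile must be in (0, 1)")
        vals = dataset.values.to_numpy(float)
        thresh = np.quantile(vals, background_quantile, axis=0)
        keep = (vals >= thresh[None, :]).any(axis=1)
    else:
        raise ConfigError(
            "dataset has no detection flags; pass background_quantile to "
            "enable the background-intensity fallback rule"
        )
    removed = dataset.feature_ids[~keep]
    filtered = dataset.with_values(dataset.values.loc[keep])
    return filtered, list(removed)


# ---------------------------------------------------------------------------
# variance-stabilizing transformation
# ---------------------------------------------------------------------------

def _replicate_groups_from_annotations(dataset: ExpressionDataset) -> list[list[str]]:
    ann = dataset.sample_annotations
    if ann is None:
        raise InputError(
            "dataset has no sample annotations; pass replicate_groups explicitly"
        )
    cols = [c for c in ("condition", "time") if c in ann.columns]
    if not cols:
        raise InputError("annotations lack condition/time columns")
    ann = ann.loc[dataset.sample_ids]
    groups = [list(g.index) for _, g in ann.groupby(cols, sort=False)]
    return groups


def fit_vst(
    dataset: ExpressionDataset,
    replicate_groups: list[list[str]] | None = None,
    n_bins: int = 50,
) -> VstParams:
    """Fit the glog offset c from the replicate mean–variance trend.

    Per-probe replicate variance (ddof=0, pooled over all groups with >=2
    replicates) is regressed on squared per-probe mean over binned probes:
    Var ≈ a + b·mean², giving c = sqrt(a/b), capped to [1e-3, 1e6].  Using
    the population (ddof=0) denominator makes the fit invariant to
    duplicating every sample; the constant bias factor cancels in a/b.
    """
    if dataset.scale != "linear":
        raise InputError(f"fit_vst expects linear-scale data, got {dataset.scale!r}")
    if replicate_groups is None:
        replicate_groups = _replicate_groups_from_annotations(dataset)
    groups = [g for g in replicate_groups if len(g) >= 2]
    if not groups:
        raise InputError(
            "no replicate group has >=2 samples; use a fixed c "
            "(VstParams(c=..., fitted_from='fixed')) instead"
        )
    vals = dataset.values
    per_group_var = np.column_stack(
        [vals[g].to_numpy(float).var(axis=1, ddof=0) for g in groups]
    )
    per_group_mean = np.column_stack(
        [vals[g].to_numpy(float).mean(axis=1) for g in groups]
    )
    probe_var = per_group_var.mean(axis=1)
    probe_mean = per_group_mean.mean(axis=1)

    # bin probes by mean (quantile bins) and regress binned var on mean^2
    n_bins = min(n_bins, max(len(probe_mean) // 5, 1))
    order = np.argsort(probe_mean, kind="stable")
    bins = np.array_split(order, n_bins)
    m2 = np.array([np.mean(probe_mean[b] ** 2) for b in bins])
    v = np.array([np.mean(probe_var[b]) for b in bins])
    b_slope = max(float(np.polyfit(m2, v, 1)[0]), 0.0)
    # The additive variance is the trend's level at low intensity, where the
    # multiplicative term vanishes; the OLS intercept is dominated by
    # high-leverage bright bins, so estimate a from the dimmest decile of
    # bins instead, and zero it when not distinguishable from noise.
    low = max(2, n_bins // 10)
    resid = v[:low] - b_slope * m2[:low]
    a = float(np.mean(resid))
    se = float(np.std(resid, ddof=1) / np.sqrt(low)) if low > 1 else 0.0
    a = a if a > 2.0 * se else 0.0
    a = max(a, 0.0)
    b = b_slope
    if b == 0.0:
        c = C_MAX
    elif a == 0.0:
        c = C_MIN
    else:
        c = float(np.sqrt(a / b))
    c = float(np.clip(c, C_MIN, C_MAX))
    return VstParams(c=c, fitted_from="replicate-trend", a=a, b=b)


def glog2(x: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2: log2((x + sqrt(x² + c²)) / 2); log2(x) as c→0."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def apply_vst(dataset: ExpressionDataset, params: VstParams) -> ExpressionDataset:
    """Apply the glog2 transform; output is tagged "log2-vst".

    Strictly monotone in x.  Inputs below −c (possible only for corrupted
    data; the generators clip at 0) are clipped to the transform's value at
    0 and counted in a warning.
    """
    if dataset.scale != "linear":
        raise InputError(f"apply_vst expects linear-scale data, got {dataset.scale!r}")
    x = dataset.values.to_numpy(float)
    c = params.c
    out = glog2(x, c)
    below = x < -c
    n_below = int(below.sum())
    if n_below:
        out[below] = np.log2(c / 2.0)
        logger.warning("apply_vst: %d values below -c clipped to glog2(0)", n_below)
    values = pd.DataFrame(out, index=dataset.feature_ids, columns=dataset.sample_ids)
    return dataset.with_values(values, scale="log2-vst")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the mean empirical distribution.

    After normalization every column's sorted values equal the across-column
    mean of sorted values; ties within a column receive the mean of the
    quantile values they span.  Idempotent.  NAs are rejected; with a single
    sample the data are returned unchanged with a warning.
    """
    vals = dataset.values.to_numpy(float)
    if np.isnan(vals).any():
        raise InputError("quantile_normalize: NA values are not allowed")
    n, m = vals.shape
    if m < 2:
        logger.warning("quantile_normalize: single sample; returning input unchanged")
        return dataset.with_values(dataset.values.copy())
    target = np.sort(vals, axis=0).mean(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(target)))
    out = np.empty_like(vals)
    for j in range(m):
        col = vals[:, j]
        idx = np.argsort(col, kind="stable")
        sorted_col = col[idx]
        # runs of tied values share the mean of the target values they span
        starts = np.concatenate(([0], np.flatnonzero(np.diff(sorted_col)) + 1))
        ends = np.concatenate((starts[1:], [n]))
        run_means = (csum[ends] - csum[starts]) / (ends - starts)
        out[idx, j] = np.repeat(run_means, ends - starts)
    values = pd.DataFrame(out, index=dataset.feature_ids, columns=dataset.sample_ids)
    return dataset.with_values(values)


def preprocess(
    dataset: ExpressionDataset,
    background_quantile: float | None = None,
    vst_params: VstParams | None = None,
    replicate_groups: list[list[str]] | None = None,
) -> tuple[ExpressionDataset, list[str], VstParams]:
    """Run the full chain: filter → fit VST (unless given) → glog2 → quantile.

    Returns the normalized dataset, the removed probe ids, and the VST
    parameters used.
    """
    filtered, removed = filter_absent_probes(dataset, background_quantile)
    if vst_params is None:
        vst_params = fit_vst(filtered, replicate_groups)
    transformed = apply_vst(filtered, vst_params)
    normalized = quantile_normalize(transformed)
    return normalized, removed, vst_params
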