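"""Project a perturbation signature onto an independent cohort.

The signature's per-gene log2 fold-changes form a *centroid* vector; each
cohort sample is scored by the Pearson correlation between the centroid and
the sample's expression over the matched genes.  Samples that recapitulate
the perturbation program score high; per-subset summaries, a Welch t
contrast between target subsets and the rest, per-subset direction
concordance fractions, and an average-linkage correlation clustering of the
samples complete the characterization.

Model-level interface: :class:`SignatureProjection` /
:class:`SignatureProjectionResults`.  Computational steps are the module
functions ``build_centroid``, ``score_samples``, ``compare_subsets``,
``concordance_fractions``, ``cluster_samples``, ``overlap_signatures``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datasets import ExpressionDataset, GeneSignature, InputError, UP, DOWN

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SUBSETS = ("diffuse1", "diffuse2")


@dataclass
class Centroid:
    """The signature's representative expression-change vector on a cohort
    platform: matched gene ids, one weight per gene, and the fraction of
    signature genes that matched."""

    genes: list[str]
    values: np.ndarray
    coverage: float

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise InputError("centroid needs >=2 genes (correlation undefined)")
        if len(self.genes) != len(self.values):
            raise InputError("genes and values must align")
        if np.ptp(self.values) == 0:
            raise InputError("centroid values are all equal; correlation undefined")
        if not 0 < self.coverage <= 1:
            raise InputError("coverage must lie in (0, 1]")


@dataclass
class ClusterTree:
    """Agglomerative clustering of cohort samples over signature genes."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    leaf_order: list[str]
    sample_ids: list[str]
    metric: str = "1-pearson"
    method: str = "average"

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..n_clusters) indexed by sample id."""
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick serialization with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return rec(tree, tree.dist) + ";"


def _collapse_by_iqr(values: pd.DataFrame) -> pd.DataFrame:
    """Keep the highest-IQR row per duplicated feature id."""
    if not values.index.has_duplicates:
        return values
    iqr = values.quantile(0.75, axis=1) - values.quantile(0.25, axis=1)
    order = np.argsort(-iqr.to_numpy(), kind="stable")
    keep = ~values.index[order].duplicated()
    return values.iloc[np.sort(order[keep])]


def build_centroid(
    signature: GeneSignature,
    cohort: ExpressionDataset,
    weighting: str = "lfc",
) -> Centroid:
    """Match signature genes to the cohort platform and build the centroid.

    ``weighting`` is "lfc" (signature log2 fold-changes) or "sign" (±1).
    Matching is by uppercased gene symbol; a coverage warning is issued
    below 50%.
    """
    if weighting not in ("lfc", "sign"):
        raise InputError(f"weighting must be 'lfc' or 'sign', got {weighting!r}")
    cohort_values = _collapse_by_iqr(cohort.values)
    cohort_ids = pd.Index([str(g).upper() for g in cohort_values.index])
    sig_ids = pd.Index([str(g).upper() for g in signature.genes])
    matched = [g for g in sig_ids if g in set(cohort_ids)]
    if len(matched) < 2:
        raise InputError(
            f"only {len(matched)} signature genes matched the cohort platform"
        )
    coverage = len(matched) / len(sig_ids)
    if coverage < 0.5:
        logger.warning("centroid coverage %.2f is below 0.5", coverage)
    weights = signature.weights.copy()
    weights.index = sig_ids
    vals = weights.loc[matched].to_numpy(float)
    if weighting == "sign":
        vals = np.sign(vals)
    return Centroid(genes=matched, values=vals, coverage=coverage)


def score_samples(
    centroid: Centroid,
    cohort: ExpressionDataset,
    center_genes: bool = True,
) -> pd.DataFrame:
    """Pearson-correlation score of every cohort sample against the centroid.

    When ``center_genes`` each matched gene's cohort row is median-centered
    across samples first (appropriate for ratio-style cohort data).  NA
    genes are dropped pairwise per sample; samples with fewer than two
    usable genes get an NA score with a warning.  Returns a DataFrame with
    columns ``score`` and ``n_genes_used`` indexed by sample id.
    """
    values = _collapse_by_iqr(cohort.values)
    values = values.set_axis([str(g).upper() for g in values.index], axis=0)
    missing = [g for g in centroid.genes if g not in values.index]
    if missing:
        raise InputError(f"cohort lacks centroid genes, e.g. {missing[:5]}")
    sub = values.loc[centroid.genes]
    if center_genes:
        sub = sub.sub(sub.median(axis=1, skipna=True), axis=0)
    c = centroid.values
    scores = {}
    counts = {}
    for sample in sub.columns:
        col = sub[sample].to_numpy(float)
        ok = np.isfinite(col)
        counts[sample] = int(ok.sum())
        if ok.sum() < 2 or np.ptp(col[ok]) == 0 or np.ptp(c[ok]) == 0:
            logger.warning("sample %s: score undefined; set to NA", sample)
            scores[sample] = np.nan
            continue
        r = np.corrcoef(c[ok], col[ok])[0, 1]
        scores[sample] = float(np.clip(r, -1.0, 1.0))
    return pd.DataFrame(
        {"score": pd.Series(scores), "n_genes_used": pd.Series(counts)}
    ).loc[list(sub.columns)]


@dataclass
class SubsetContrast:
    """Welch comparison of scores in target subsets vs. all other samples."""

    target_mean: float
    target_sd: float
    target_n: int
    rest_mean: float
    rest_sd: float
    rest_n: int
    difference: float
    t_stat: float
    p_value: float
    target_subsets: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_subsets(
    scores: pd.Series,
    subset_labels: pd.Series,
    target_subsets: tuple[str, ...] = DEFAULT_TARGET_SUBSETS,
) -> SubsetContrast:
    """Mean ± SD per group (ddof=1) and Welch two-sided t test."""
    scores = scores.dropna()
    labels = subset_labels.loc[scores.index]
    in_target = labels.isin(target_subsets)
    a = scores[in_target].to_numpy(float)
    b = scores[~in_target].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise InputError(
            f"need >=2 samples per group (target {len(a)}, rest {len(b)})"
        )
    t_res = stats.ttest_ind(a, b, equal_var=False)
    p = float(t_res.pvalue)
    if p == 0.0:  # Welch p underflow (e.g. zero within-group variance)
        p = float(np.nextafter(0.0, 1.0))
    return SubsetContrast(
        target_mean=float(a.mean()),
        target_sd=float(a.std(ddof=1)),
        target_n=len(a),
        rest_mean=float(b.mean()),
        rest_sd=float(b.std(ddof=1)),
        rest_n=len(b),
        difference=float(a.mean() - b.mean()),
        t_stat=float(t_res.statistic),
        p_value=p,
        target_subsets=tuple(target_subsets),
    )


def concordance_fractions(
    signature: GeneSignature,
    cohort: ExpressionDataset,
    subset_labels: pd.Series | None = None,
    null_band: float = 0.0,
    center_genes: bool = True,
) -> dict[str, float]:
    """Per-subset fraction of matched signature genes moving the signature's
    way.

    For each subset S and matched gene g, g is *concordant* in S iff the
    sign of g's mean (gene-centered) expression over S equals g's signature
    direction and the mean's magnitude exceeds ``null_band``.  With the
    default band of 0 this is a pure sign test; a positive band ignores
    shifts smaller than that many log units.  Empty subsets yield NaN.
    """
    if subset_labels is None:
        if cohort.sample_annotations is None or "subset" not in cohort.sample_annotations.columns:
            raise InputError("no subset labels available")
        subset_labels = cohort.sample_annotations.loc[cohort.sample_ids, "subset"]
    values = _collapse_by_iqr(cohort.values)
    values = values.set_axis([str(g).upper() for g in values.index], axis=0)
    sig_ids = pd.Index([str(g).upper() for g in signature.genes])
    matched = [g for g in sig_ids if g in set(values.index)]
    if not matched:
        raise InputError("no signature genes matched the cohort platform")
    sub = values.loc[matched]
    if center_genes:
        sub = sub.sub(sub.median(axis=1, skipna=True), axis=0)
    directions = signature.directions.copy()
    directions.index = sig_ids
    d = directions.loc[matched].to_numpy(float)
    out: dict[str, float] = {}
    for subset in pd.unique(subset_labels):
        cols = subset_labels.index[subset_labels == subset]
        cols = [c for c in cols if c in sub.columns]
        if not cols:
            out[str(subset)] = float("nan")
            continue
        means = sub[cols].mean(axis=1).to_numpy(float)
        concordant = (np.sign(means) == d) & (np.abs(means) > null_band)
        out[str(subset)] = float(concordant.sum() / len(matched))
    return out


def cluster_samples(
    cohort: ExpressionDataset,
    genes: list[str] | None = None,
    center_genes: bool = True,
) -> ClusterTree:
    """Average-linkage clustering of samples with 1 − Pearson distance.

    ``genes`` restricts the matrix (typically to the signature genes); all
    rows are used when None.  ``center_genes`` median-centers each gene
    across samples first, as for scoring: on ratio-style data this gives
    unactivated samples their shared below-average pattern, which is what
    separates activated from unactivated branches.  A sample with constant
    expression has no defined correlation and raises an error naming it.
    """
    values = _collapse_by_iqr(cohort.values)
    values = values.set_axis([str(g).upper() for g in values.index], axis=0)
    if genes is not None:
        genes = [str(g).upper() for g in genes]
        genes = [g for g in genes if g in set(values.index)]
        if len(genes) < 2:
            raise InputError("need >=2 matched genes to cluster on")
        values = values.loc[genes]
    if values.shape[1] < 2:
        raise InputError("need >=2 samples to cluster")
    if center_genes:
        values = values.sub(values.median(axis=1), axis=0)
    mat = values.to_numpy(float).T  # samples x genes
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        bad = values.columns[np.flatnonzero(sds == 0)[0]]
        raise InputError(f"sample {bad!r} is constant; correlation undefined")
    dist = pdist(mat, metric="correlation")
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    sample_ids = list(values.columns)
    return ClusterTree(
        linkage=Z,
        leaf_order=[sample_ids[i] for i in order],
        sample_ids=sample_ids,
    )


@dataclass
class OverlapReport:
    """Venn-style comparison of two directional signatures."""

    name_a: str
    name_b: str
    size_a: int
    size_b: int
    intersection: int
    concordant_up: int
    concordant_down: int
    discordant: int
    only_a: list[str] = field(default_factory=list)
    only_b: list[str] = field(default_factory=list)
    concordant_up_genes: list[str] = field(default_factory=list)
    concordant_down_genes: list[str] = field(default_factory=list)
    discordant_genes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def overlap_signatures(sig_a: GeneSignature, sig_b: GeneSignature) -> OverlapReport:
    """Count shared genes and their direction agreement between signatures."""
    if len(sig_a) == 0 or len(sig_b) == 0:
        raise InputError("both signatures must be non-empty")
    da = {str(g).upper(): int(d) for g, d in sig_a.directions.items()}
    db = {str(g).upper(): int(d) for g, d in sig_b.directions.items()}
    shared = sorted(set(da) & set(db))
    up = [g for g in shared if da[g] == UP and db[g] == UP]
    down = [g for g in shared if da[g] == DOWN and db[g] == DOWN]
    disc = [g for g in shared if da[g] != db[g]]
    return OverlapReport(
        name_a=sig_a.name,
        name_b=sig_b.name,
        size_a=len(da),
        size_b=len(db),
        intersection=len(shared),
        concordant_up=len(up),
        concordant_down=len(down),
        discordant=len(disc),
        only_a=sorted(set(da) - set(db)),
        only_b=sorted(set(db) - set(da)),
        concordant_up_genes=up,
        concordant_down_genes=down,
        discordant_genes=disc,
    )


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class SignatureProjection:
    """Project a signature onto a labelled cohort.

    Parameters
    ----------
    cohort
        Expression data for the cohort (ratio-style scale), with a
        ``subset`` annotation column.
    signature
        The directional, weighted gene signature to project.
    weighting
        Centroid weighting, "lfc" or "sign".
    center_genes
        Median-center each matched gene across samples before correlating.
    target_subsets
        The subsets expected to express the signature (scored against the
        rest in the Welch contrast).
    concordance_null_band
        Minimum |subset mean| (log units) for a gene to count as
        concordant; the default 0.5 requires a material shift rather than a
        bare sign agreement.
    """

    def __init__(
        self,
        cohort: ExpressionDataset,
        signature: GeneSignature,
        weighting: str = "lfc",
        center_genes: bool = True,
        target_subsets: tuple[str, ...] = DEFAULT_TARGET_SUBSETS,
        concordance_null_band: float = 0.5,
    ):
        self.cohort = cohort
        self.signature = signature
        self.weighting = weighting
        self.center_genes = center_genes
        self.target_subsets = tuple(target_subsets)
        self.concordance_null_band = concordance_null_band

    def fit(self, cluster: bool = True) -> "SignatureProjectionResults":
        centroid = build_centroid(self.signature, self.cohort, self.weighting)
        score_table = score_samples(centroid, self.cohort, self.center_genes)
        labels = self.cohort.sample_annotations.loc[
            self.cohort.sample_ids, "subset"
        ]
        contrast = compare_subsets(
            score_table["score"], labels, self.target_subsets
        )
        concordance = concordance_fractions(
            self.signature,
            self.cohort,
            labels,
            null_band=self.concordance_null_band,
            center_genes=self.center_genes,
        )
        tree = (
            cluster_samples(self.cohort, list(centroid.genes)) if cluster else None
        )
        return SignatureProjectionResults(
            self, centroid, score_table, labels, contrast, concordance, tree
        )


class SignatureProjectionResults:
    """Per-sample scores, subset contrast, concordance and sample tree."""

    def __init__(self, model, centroid, score_table, labels, contrast,
                 concordance, tree):
        self.model = model
        self.centroid = centroid
        self.score_table = score_table
        self.subset_labels = labels
        self.contrast = contrast
        self.concordance = concordance
        self.tree = tree

    @property
    def scores(self) -> pd.Series:
        return self.score_table["score"]

    def subset_summary(self) -> pd.DataFrame:
        """Mean ± SD (ddof=1) of scores per subset."""
        df = pd.DataFrame(
            {"score": self.scores, "subset": self.subset_labels}
        ).dropna()
        g = df.groupby("subset", sort=True)["score"]
        return pd.DataFrame(
            {"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()}
        )

    def summary(self) -> str:
        c = self.contrast
        lines = [
            "Signature projection",
            "=" * 46,
            f"signature:       {self.model.signature.name} "
            f"({len(self.model.signature)} genes)",
            f"centroid genes:  {len(self.centroid.genes)} "
            f"(coverage {self.centroid.coverage:.3f})",
            f"samples scored:  {int(self.scores.notna().sum())}",
            "",
            "per-subset scores (mean +/- sd):",
            self.subset_summary().to_string(
                float_format=lambda x: f"{x:.4f}"
            ),
            "",
            f"target {list(c.target_subsets)}: "
            f"{c.target_mean:.4f} +/- {c.target_sd:.4f} (n={c.target_n})",
            f"rest: {c.rest_mean:.4f} +/- {c.rest_sd:.4f} (n={c.rest_n})",
            f"Welch t = {c.t_stat:.4f}, two-sided p = {c.p_value:.3g}",
            "",
            "concordance fractions "
            f"(null band {self.model.concordance_null_band:g}):",
        ]
        for subset in sorted(self.concordance):
            lines.append(f"  {subset}: {self.concordance[subset]:.3f}")
        return "\n".join(lines)
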