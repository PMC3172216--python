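"""End-to-end pipeline: simulate → preprocess → test → signature → enrich →
project, with every stage's output written to plain-text files.

Used by the CLI `report` subcommand and by reproducibility checks: all
stages are deterministic given the seed, so two runs with the same
configuration produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as pio
from .datasets import ConfigError, ExpressionDataset, GeneSetCollection, GeneSignature
from .differential import ModeratedTTest
from .enrichment import enrich
from .preprocess import preprocess
from .projection import SignatureProjection, overlap_signatures
from .simulate import (
    CohortSimConfig,
    PerturbationSimConfig,
    simulate_cohort,
    simulate_perturbation,
)

FLOAT_FMT = pio.FLOAT_FMT


@dataclass
class PipelineConfig:
    """Thresholds and options shared across pipeline stages."""

    de_fdr: float = 0.01
    de_fold: float = 2.0
    enrichment_p: float = 0.001
    background_quantile: float | None = None  # detection-flag fallback rule
    projection_weighting: str = "lfc"
    projection_center_genes: bool = True
    target_subsets: tuple[str, ...] = ("diffuse1", "diffuse2")
    concordance_null_band: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.de_fdr < 1:
            raise ConfigError("de_fdr must be in (0, 1)")
        if self.de_fold < 1:
            raise ConfigError("de_fold must be >= 1")
        if not 0 < self.enrichment_p < 1:
            raise ConfigError("enrichment_p must be in (0, 1)")


@dataclass
class PipelineOutputs:
    """In-memory handles to everything the pipeline computed."""

    normalized: ExpressionDataset
    removed_probes: list[str]
    de_results: dict[str, object]
    signatures: dict[str, GeneSignature]
    enrichment: pd.DataFrame | None
    cohort: ExpressionDataset
    projection: object
    overlap: object | None
    files: dict[str, str] = field(default_factory=dict)


def _write_de_table(table: pd.DataFrame, path: str) -> None:
    cols = ["lfc", "t_mod", "p", "q", "direction", "time"]
    table[cols].to_csv(
        path, sep="\t", index_label="gene", float_format=FLOAT_FMT,
        lineterminator="\n",
    )


def run_pipeline(
    outdir: str,
    perturb_config: PerturbationSimConfig | None = None,
    cohort_config: CohortSimConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> PipelineOutputs:
    """Run every stage at the given configs, writing outputs under outdir.

    The perturbation experiment is simulated and preprocessed; moderated-t
    comparisons run at each time point; the late signature is projected
    onto a simulated cohort; the early and late signatures are overlapped;
    gene sets, when given, are tested for enrichment of the late signature.
    """
    pcfg = pipeline_config or PipelineConfig()
    pcfg.validate()
    sim_cfg = perturb_config or PerturbationSimConfig(seed=pcfg.seed)
    coh_cfg = cohort_config or CohortSimConfig(seed=pcfg.seed + 1)
    os.makedirs(outdir, exist_ok=True)
    files: dict[str, str] = {}

    def path(name: str) -> str:
        files[name] = os.path.join(outdir, name)
        return files[name]

    # simulate + preprocess
    raw, truth = simulate_perturbation(sim_cfg)
    pio.write_expression_tsv(raw, path("raw_matrix.tsv"))
    pio.write_annotations_tsv(raw.sample_annotations, path("sample_annotations.tsv"))
    pio.write_detection_tsv(raw.detection, path("detection.tsv"))
    pio.write_json(truth.planted_genes, path("truth_planted.json"))
    normalized, removed, vst_params = preprocess(
        raw, background_quantile=pcfg.background_quantile
    )
    pio.write_expression_tsv(normalized, path("normalized_matrix.tsv"))
    with open(path("removed_probes.txt"), "wt", newline="\n") as fh:
        fh.writelines(f"{p}\n" for p in removed)
    pio.write_json(
        {
            "vst": {"c": vst_params.c, "a": vst_params.a, "b": vst_params.b,
                    "fitted_from": vst_params.fitted_from},
            "n_removed": len(removed),
            "thresholds": {"de_fdr": pcfg.de_fdr, "de_fold": pcfg.de_fold,
                           "enrichment_p": pcfg.enrichment_p},
            "seed": pcfg.seed,
        },
        path("provenance.json"),
    )

    # differential testing + signatures per time point
    de_results: dict[str, object] = {}
    signatures: dict[str, GeneSignature] = {}
    for time in sim_cfg.time_points:
        res = ModeratedTTest(normalized, time=time).fit()
        de_results[time] = res
        _write_de_table(res.table, path(f"de_{time}.tsv"))
        sig = res.derive_signature(fdr=pcfg.de_fdr, fold=pcfg.de_fold)
        signatures[time] = sig
        pio.write_signature_tsv(
            sig, path(f"signature_{time}.tsv"), path(f"signature_{time}.json")
        )

    late = sim_cfg.time_points[-1]
    early = sim_cfg.time_points[0]
    late_sig = signatures[late]

    # signature overlap across time points
    overlap = None
    if len(sim_cfg.time_points) > 1 and len(signatures[early]) and len(late_sig):
        overlap = overlap_signatures(signatures[early], late_sig)
        pio.write_json(overlap.as_dict(), path("overlap.json"))

    # enrichment of the late signature
    enrichment_table = None
    if gene_sets is not None and len(late_sig):
        universe = list(normalized.feature_ids)
        enrichment_table = enrich(late_sig, gene_sets, universe, pcfg.enrichment_p)
        out = enrichment_table.copy()
        out["overlap_genes"] = out["overlap_genes"].map(";".join)
        out.to_csv(path("enrichment.tsv"), sep="\t", index=False,
                   float_format=FLOAT_FMT, lineterminator="\n")

    # cohort projection
    cohort, cohort_truth = simulate_cohort(late_sig, coh_cfg)
    pio.write_expression_tsv(cohort, path("cohort_matrix.tsv"))
    pio.write_annotations_tsv(cohort.sample_annotations, path("cohort_annotations.tsv"))
    proj = SignatureProjection(
        cohort,
        late_sig,
        weighting=pcfg.projection_weighting,
        center_genes=pcfg.projection_center_genes,
        target_subsets=pcfg.target_subsets,
        concordance_null_band=pcfg.concordance_null_band,
    ).fit()
    proj.score_table.to_csv(
        path("scores.tsv"), sep="\t", index_label="sample_id",
        float_format=FLOAT_FMT, lineterminator="\n",
    )
    pio.write_json(
        {
            "contrast": proj.contrast.as_dict(),
            "subset_summary": {
                s: {"mean": row["mean"], "sd": row["sd"], "n": int(row["n"])}
                for s, row in proj.subset_summary().iterrows()
            },
        },
        path("subset_summary.json"),
    )
    conc = pd.Series(proj.concordance, name="concordance_fraction").sort_index()
    conc.to_csv(path("concordance.tsv"), sep="\t", index_label="subset",
                float_format=FLOAT_FMT, lineterminator="\n")
    with open(path("samples.nwk"), "wt", newline="\n") as fh:
        fh.write(proj.tree.to_newick() + "\n")

    return PipelineOutputs(
        normalized=normalized,
        removed_probes=removed,
        de_results=de_results,
        signatures=signatures,
        enrichment=enrichment_table,
        cohort=cohort,
        projection=proj,
        overlap=overlap,
        files=files,
    )
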