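"""Orchestration of the full clustering-comparison protocol.

Runs both scenarios — all molecules, and non-outlier molecules after the
nearest-neighbor filter — for every enabled method and cutoff, writes
per-scenario quality tables, cluster assignments, size summaries and average
similarity matrices, and a final method-comparison table with best-per-column
flags.  Every number in the emitted tables is reproducible by re-invoking the
corresponding module operation with the logged parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ChemclustError, ValidationError
from .mol_io import FingerprintSet, read_fingerprints, read_molecule_table, compute_fingerprints
from .similarity import pairwise_distances, nearest_neighbor_profile
from .outliers import flag_outliers, histogram_gap_cutoff
from .clustering import (
    UmapConfig,
    ward_linkage,
    cut_tree,
    butina_cluster,
    umap_embed,
    agglomerative_on_embedding,
)
from .quality import QualityReport, quality_report, average_similarity_matrix
from .synthetic_data import SyntheticSpec, generate_with_outliers

logger = logging.getLogger(__name__)


class PipelineStageError(ChemclustError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one comparison run needs.

    Exactly one input source must be set: a synthetic spec, a fingerprint
    TSV, or a molecule table (CSV/smi, fingerprinted on the fly).  Cutoff
    lists default to desk-scale analogues of the protocol's scan ranges.
    """

    synthetic: SyntheticSpec | None = None
    fingerprint_table: str | None = None
    molecule_table: str | None = None
    outlier_cutoff: float | str = "auto"  # similarity cutoff, or "auto" = histogram gap
    ward_cutoffs: list[float] = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
    butina_cutoffs: list[float] = field(
        default_factory=lambda: [0.35, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.97, 0.99]
    )
    umap: UmapConfig = field(default_factory=lambda: UmapConfig(n_neighbors=15))
    umap_k_list: list[int] = field(default_factory=lambda: [4, 7])
    metric_space: str = "fingerprints"  # space for Ward/Butina indices
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        sources = [self.synthetic, self.fingerprint_table, self.molecule_table]
        if sum(s is not None for s in sources) != 1:
            raise ValidationError("exactly one input source must be configured")
        for c in self.butina_cutoffs:
            if not 0.0 < c <= 1.0:
                raise ValidationError("butina cutoffs must lie in (0, 1]")
        for c in self.ward_cutoffs:
            if c <= 0:
                raise ValidationError("ward cutoffs must be positive heights")
        if not (self.ward_cutoffs or self.butina_cutoffs or self.umap_k_list):
            raise ValidationError("at least one clustering method must be enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "umap" in raw and raw["umap"] is not None:
            raw["umap"] = UmapConfig(**raw["umap"])
        return cls(**raw)


def _load_input(config: PipelineConfig) -> FingerprintSet:
    if config.synthetic is not None:
        return generate_with_outliers(config.synthetic)
    if config.fingerprint_table is not None:
        return read_fingerprints(config.fingerprint_table)
    records = read_molecule_table(config.molecule_table)
    return compute_fingerprints(records)


def _report_row(method: str, scenario: str, param_name: str, param: float,
                rep: QualityReport) -> dict:
    return {
        "method": method,
        "scenario": scenario,
        "param": param_name,
        "value": param,
        "n_clusters": rep.n_clusters,
        "silhouette": rep.silhouette,
        "calinski_harabasz": rep.calinski_harabasz,
        "davies_bouldin": rep.davies_bouldin,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full comparison protocol; return (and optionally write) the bundle.

    The bundle maps: ``quality`` to the per-run metric table, ``comparison``
    to the final cross-method table, ``assignments`` to per-run label
    vectors, ``similarity_matrices`` to per-method average-similarity
    matrices, ``outliers`` to the filter report, and ``log`` to the recorded
    parameters and seeds.
    """
    stage = "load_input"
    try:
        fps = _load_input(config)
        stage = "nearest_neighbor_profile"
        profile = nearest_neighbor_profile(fps)
        stage = "outlier_filter"
        if config.outlier_cutoff == "auto":
            cutoff = histogram_gap_cutoff(profile.nn_sim)
        else:
            cutoff = float(config.outlier_cutoff)
        outlier_report = flag_outliers(profile, cutoff)
        id_to_row = {m: i for i, m in enumerate(fps.ids)}
        retained = fps.subset([id_to_row[m] for m in outlier_report.retained_ids])

        scenarios: dict[str, FingerprintSet] = {"all": fps}
        if 2 <= retained.n < fps.n:
            scenarios["non_outlier"] = retained

        quality_rows: list[dict] = []
        assignments: dict[str, pd.DataFrame] = {}
        sim_matrices: dict[str, pd.DataFrame] = {}
        best_reports: list[dict] = []

        for scen, sfps in scenarios.items():
            stage = f"distances[{scen}]"
            dmat = pairwise_distances(sfps)

            stage = f"ward[{scen}]"
            tree = ward_linkage(dmat)
            ward_runs = []
            for hc in config.ward_cutoffs:
                assign = cut_tree(tree, hc, ids=sfps.ids)
                if assign.n_clusters < 2 or assign.n_clusters >= sfps.n:
                    continue
                rep = quality_report(sfps, assign.labels, metric_space=config.metric_space)
                quality_rows.append(_report_row("ward", scen, "height_cutoff", hc, rep))
                ward_runs.append((hc, assign, rep))

            stage = f"butina[{scen}]"
            butina_runs = []
            for sc in config.butina_cutoffs:
                assign = butina_cluster(dmat, sc)
                if assign.n_clusters < 2 or assign.n_clusters >= sfps.n:
                    continue
                rep = quality_report(sfps, assign.labels, metric_space=config.metric_space)
                quality_rows.append(_report_row("butina", scen, "similarity_cutoff", sc, rep))
                butina_runs.append((sc, assign, rep))

            stage = f"umap[{scen}]"
            umap_runs = []
            if config.umap_k_list:
                embedding = umap_embed(sfps, config.umap)
                for k in config.umap_k_list:
                    if not 2 <= k < sfps.n:
                        continue
                    assign = agglomerative_on_embedding(embedding, k, ids=sfps.ids)
                    rep = quality_report(embedding, assign.labels, metric_space="embedding")
                    quality_rows.append(_report_row("umap", scen, "n_clusters", k, rep))
                    umap_runs.append((k, assign, rep))

            stage = f"reports[{scen}]"
            for method, runs in (("ward", ward_runs), ("butina", butina_runs), ("umap", umap_runs)):
                if not runs:
                    continue
                # representative run per method/scenario: best mean silhouette
                param, assign, rep = max(runs, key=lambda r: r[2].silhouette)
                best_reports.append(
                    {**_report_row(method, scen, "selected", param, rep)}
                )
                assignments[f"{method}_{scen}"] = pd.DataFrame(
                    {
                        "id": assign.ids,
                        "cluster_id": assign.labels,
                        **(
                            {"butina_role": assign.butina_role}
                            if assign.butina_role is not None
                            else {}
                        ),
                    }
                )
                asm = average_similarity_matrix(sfps, assign.labels)
                sim_matrices[f"{method}_{scen}"] = pd.DataFrame(asm.matrix)

        stage = "comparison"
        comparison = comparison_table(best_reports)
        bundle = {
            "quality": pd.DataFrame(quality_rows),
            "comparison": comparison,
            "assignments": assignments,
            "similarity_matrices": sim_matrices,
            "outliers": {
                "cutoff": cutoff,
                "n_total": fps.n,
                "n_removed": outlier_report.n_removed,
                "n_retained": len(outlier_report.retained_ids),
            },
            "log": {
                "seed": config.seed,
                "umap_seed": config.umap.seed,
                "outlier_cutoff": cutoff,
                "ward_cutoffs": list(config.ward_cutoffs),
                "butina_cutoffs": list(config.butina_cutoffs),
                "umap_k_list": list(config.umap_k_list),
                "metric_space": config.metric_space,
                "umap": dataclasses.asdict(config.umap),
            },
        }
        if config.outdir is not None:
            stage = "write_outputs"
            _write_bundle(bundle, Path(config.outdir))
        return bundle
    except ChemclustError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["quality"].to_csv(outdir / "quality.tsv", sep="\t", index=False)
    bundle["comparison"].to_csv(outdir / "comparison.tsv", sep="\t", index=False)
    for name, df in bundle["assignments"].items():
        df.to_csv(outdir / f"assignment_{name}.tsv", sep="\t", index=False)
    for name, df in bundle["similarity_matrices"].items():
        df.to_csv(outdir / f"avg_similarity_{name}.csv", index=False)
    with (outdir / "run_log.json").open("w") as fh:
        json.dump({**bundle["log"], "outliers": bundle["outliers"]}, fh, indent=2)


def comparison_table(reports: list[dict]) -> pd.DataFrame:
    """Cross-method comparison with best-per-column flags.

    One row per method/scenario report; the best finite silhouette and
    Calinski–Harabasz (max) and Davies–Bouldin (min) get a flag per
    scenario.  Sentinel (non-finite) metric values are excluded from the
    contests.
    """
    if not reports:
        raise ValidationError("need at least one report to compare")
    df = pd.DataFrame(reports)
    for col, best in (("silhouette", "max"), ("calinski_harabasz", "max"), ("davies_bouldin", "min")):
        flag = np.zeros(len(df), dtype=bool)
        for scen in df["scenario"].unique():
            mask = (df["scenario"] == scen) & np.isfinite(df[col])
            if not mask.any():
                continue
            target = df.loc[mask, col].max() if best == "max" else df.loc[mask, col].min()
            flag |= mask & (df[col] == target)
        df[f"best_{col}"] = flag
    return df
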