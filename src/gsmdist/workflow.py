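"""End-to-end workflow driver.

Runs the full distance-based analysis over a directory of models: per-metric
distance matrices (Jaccard, WLS kernel, flux correlation), per-metric
hierarchical labelings, consensus clustering, kernel-PCA embeddings (with
optional paired trajectories), Mantel comparisons between every metric pair,
and the Kruskal-Wallis screen of the normalized flux matrix against the
consensus labels. All outputs are TSV plus JSON sidecars; a manifest records
every parameter and derived seed so any run is reproducible from the manifest
alone. Identical config + master seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    flag_outlier_fluxes,
    kernel_pca,
    kruskal_wallis_screen,
    mantel,
    pathway_counts,
    trajectories,
)
from .clustering import ConsensusResult, Labeling, consensus, hierarchical_labels
from .io import build_universe, read_model
from .metrics import CurrencyPolicy, DistanceMatrix, jaccard_matrix, wls_distance_matrix
from .model import MetabolicModel
from .sampling import (
    MediumSpec,
    build_flux_matrix,
    derive_seeds,
    flux_distance_matrix,
    normalize_flux_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "run_workflow"]

VALID_METRICS = ("jaccard", "wls", "flux")


@dataclass
class WorkflowConfig:
    model_dir: str
    template_path: str
    output_dir: str
    metrics: tuple[str, ...] = VALID_METRICS
    medium_path: str | None = None
    pairs_path: str | None = None
    n_samples: int = 1000
    wl_iterations: int = 3
    k: int = 2
    alpha: float = 0.05
    n_permutations: int = 9999
    n_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.metrics = tuple(self.metrics)
        unknown = set(self.metrics) - set(VALID_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if not self.metrics:
            raise ValueError("at least one metric is required")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for path_attr in ("model_dir", "template_path", "medium_path", "pairs_path"):
            value = getattr(self, path_attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{path_attr}: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "metrics" in doc and isinstance(doc["metrics"], str):
            doc["metrics"] = tuple(doc["metrics"].split(","))
        return cls(**doc)


def _load_models(model_dir: str | Path) -> list[MetabolicModel]:
    paths = sorted(
        p for p in Path(model_dir).iterdir() if p.suffix.lower() in (".json", ".xml", ".sbml")
    )
    if len(paths) < 2:
        raise ValueError(f"need at least 2 model files in {model_dir}")
    return [read_model(p) for p in paths]


def _write_labeling(labeling: Labeling, path: Path) -> None:
    frame = pd.DataFrame(sorted(labeling.labels.items()), columns=["model_id", "label"])
    frame.to_csv(path, sep="\t", index=False)


def run_workflow(cfg: WorkflowConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            **{k: v for k, v in cfg.__dict__.items()},
            "metrics": list(cfg.metrics),
        },
        "outputs": [],
        "notes": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    models = _load_models(cfg.model_dir)
    template = read_model(cfg.template_path)
    universe = build_universe(template)
    medium = MediumSpec.from_tsv(cfg.medium_path) if cfg.medium_path else None
    stage_seeds = dict(
        zip(("flux", "consensus", "mantel"), derive_seeds(cfg.seed, 3, "workflow"))
    )
    manifest["stage_seeds"] = stage_seeds

    distance_matrices: dict[str, DistanceMatrix] = {}
    nfm = None
    for metric in cfg.metrics:
        if metric == "jaccard":
            dm = jaccard_matrix(models, universe)
        elif metric == "wls":
            dm = wls_distance_matrix(models, CurrencyPolicy(), h=cfg.wl_iterations)
        else:
            fm = build_flux_matrix(
                models, universe, medium=medium,
                n_samples=cfg.n_samples, seed=stage_seeds["flux"],
            )
            subsystems = {r.id: r.subsystem for r in template.reactions}
            nfm = normalize_flux_matrix(fm, subsystems)
            fm.to_tsv(emit("flux_matrix.tsv"))
            nfm.to_tsv(emit("normalized_flux_matrix.tsv"))
            (out / "flux_matrix.meta.json").write_text(
                json.dumps(
                    {
                        "n_samples": fm.n_samples,
                        "seed": fm.seed,
                        "dropped_columns": nfm.dropped,
                        "absent_entries": {
                            mid: [rid for rid, absent in zip(fm.reaction_ids, row) if absent]
                            for mid, row in zip(fm.model_ids, fm.mask)
                            if row.any()
                        },
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            manifest["outputs"].append("flux_matrix.meta.json")
            dm = flux_distance_matrix(nfm)
        distance_matrices[metric] = dm
        dm.to_tsv(emit(f"distance_{metric}.tsv"))
        (out / f"distance_{metric}.meta.json").write_text(
            json.dumps({"metric": metric, "n_models": dm.n}, indent=1)
        )

    labelings = {m: hierarchical_labels(dm, cfg.k) for m, dm in distance_matrices.items()}
    for metric, lab in labelings.items():
        _write_labeling(lab, emit(f"labels_{metric}.tsv"))

    lab_list = list(labelings.values())
    if len(lab_list) >= 2:
        cres = consensus(lab_list, cfg.k, seed=stage_seeds["consensus"])
        consensus_labeling = cres.labeling
        consensus_meta = {"selected": cres.selected, "mean_nmi": cres.scores}
    else:
        consensus_labeling = lab_list[0]
        consensus_meta = {"selected": "single-metric passthrough", "mean_nmi": {}}
        manifest["notes"].append("single metric: consensus is the input labeling")
    _write_labeling(consensus_labeling, emit("consensus_labels.tsv"))
    (out / "consensus.json").write_text(json.dumps(consensus_meta, indent=1, sort_keys=True))
    manifest["outputs"].append("consensus.json")

    pairs = None
    if cfg.pairs_path:
        pframe = pd.read_csv(cfg.pairs_path, sep="\t")
        pairs = [tuple(map(str, row)) for row in pframe.itertuples(index=False, name=None)]
    for metric, dm in distance_matrices.items():
        emb = kernel_pca(dm, n_components=cfg.n_components)
        cols = [f"PC{i+1}" for i in range(emb.coordinates.shape[1])]
        frame = pd.DataFrame(emb.coordinates, index=emb.ids, columns=cols)
        frame.to_csv(emit(f"embedding_{metric}.tsv"), sep="\t", index_label="model_id",
                     float_format="%.12g")
        (out / f"embedding_{metric}.meta.json").write_text(
            json.dumps(
                {
                    "explained_variance": [float(v) for v in emb.explained_variance],
                    "negative_eigenvalue_mass": emb.negative_eigenvalue_mass,
                },
                indent=1,
            )
        )
        if pairs:
            trs = trajectories(emb, pairs)
            tframe = pd.DataFrame(
                [
                    (t.subject_id, t.start_id, t.end_id, t.magnitude, *t.displacement)
                    for t in trs
                ],
                columns=["subject_id", "start_id", "end_id", "magnitude"]
                + [f"d{c}" for c in cols],
            )
            tframe.to_csv(emit(f"trajectories_{metric}.tsv"), sep="\t", index=False,
                          float_format="%.12g")

    mantel_rows = []
    names = list(distance_matrices)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = mantel(
                distance_matrices[names[i]], distance_matrices[names[j]],
                n_permutations=cfg.n_permutations, seed=stage_seeds["mantel"],
            )
            mantel_rows.append((names[i], names[j], res.r, res.p_value, res.n_permutations))
    if mantel_rows:
        pd.DataFrame(
            mantel_rows, columns=["metric_a", "metric_b", "r", "p_value", "n_permutations"]
        ).to_csv(emit("mantel.tsv"), sep="\t", index=False, float_format="%.12g")

    if nfm is not None:
        try:
            screen = kruskal_wallis_screen(nfm, consensus_labeling, alpha=cfg.alpha)
        except ValueError as exc:
            manifest["notes"].append(f"screen skipped: {exc}")
        else:
            pd.DataFrame(
                [
                    (r.reaction_id, r.statistic, r.p_value, r.significant, r.subsystem)
                    for r in screen
                ],
                columns=["reaction_id", "H", "p", "significant", "subsystem"],
            ).to_csv(emit("screen.tsv"), sep="\t", index=False, float_format="%.12g")
            pd.DataFrame(
                pathway_counts(screen).items(), columns=["subsystem", "n_significant"]
            ).to_csv(emit("pathway_counts.tsv"), sep="\t", index=False)
            pd.DataFrame(
                flag_outlier_fluxes(nfm), columns=["model_id", "reaction_id", "z"]
            ).to_csv(emit("flux_outliers.tsv"), sep="\t", index=False, float_format="%.12g")
    else:
        manifest["notes"].append("flux metric not computed: screen skipped")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
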