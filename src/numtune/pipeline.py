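"""End-to-end analysis pipeline and configuration.

Ties the stages together: signal standardization and cleaning, grid-search
tuning estimation with split-half cross-validation, statistical vertex
selection, surface clustering with map assignment, and topographic
summaries.  All outputs are plain-text tables plus a provenance record
(package version, seeds, thresholds) so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import StimulusTimeline
from .prf import NumerosityPRF, ParameterGrid
from .selection import ThresholdSpec, select_vertices, selection_summary
from .surface import (
    MapAtlas,
    SurfaceMesh,
    assign_maps,
    clusters_to_frame,
    connected_clusters,
    filter_clusters,
)
from .topography import bin_by_mu, numerosity_range, poly_topo_cv

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Analysis settings; paths are resolved by the CLI layer."""

    hemi: str = "L"
    alpha: float = 0.05
    n_scans: int = 145
    bonferroni_vertices: int | None = None  # default: mesh vertex count
    a_min: float = 50.0
    d_max: float = 25.0
    bin_width: float = 0.5
    poly_degree: int = 5
    poly_folds: int = 10
    seed: int = 0
    linear_tuning: bool = False
    block_sustained: bool = False
    standardize: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def run_pipeline(
    timeline: StimulusTimeline,
    runs,
    mesh: SurfaceMesh,
    confounds=None,
    atlas: MapAtlas | None = None,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run signals -> fit -> selection -> clustering -> topography.

    Returns a result bundle (fits table, selection summary, cluster
    table, bin summary, per-cluster topography models); when ``out_dir``
    is given, writes fits.tsv, clusters.tsv, bins.tsv, topo.json,
    selection.json and provenance.json there.
    """
    config = config or PipelineConfig()

    try:
        model = NumerosityPRF(
            runs,
            timeline,
            confounds=confounds,
            standardize=config.standardize,
            tuning="linear" if config.linear_tuning else "log",
            block_sustained=config.block_sustained,
        )
        results = model.fit()
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", str(e)) from e

    if mesh.n_vertices != results.n_vertices:
        raise PipelineError(
            "fit",
            f"mesh has {mesh.n_vertices} vertices but signals have "
            f"{results.n_vertices}",
        )

    try:
        spec = ThresholdSpec(
            alpha=config.alpha,
            n_scans=config.n_scans,
            n_vertices=config.bonferroni_vertices or mesh.n_vertices,
        )
        selected = select_vertices(results.frame, spec)
        sel_summary = selection_summary(results.frame, spec)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("selection", str(e)) from e

    try:
        clusters = connected_clusters(mesh, selected)
        clusters = filter_clusters(clusters, a_min=config.a_min)
        mu = results.frame["mu"].to_numpy()
        for c in clusters:
            c.mu_range = numerosity_range(mu[c.vertices])
        if atlas is not None:
            clusters = assign_maps(
                clusters, atlas, mesh, hemi=config.hemi, d_max=config.d_max
            )
        cluster_frame = clusters_to_frame(clusters, hemi=config.hemi)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cluster", str(e)) from e

    try:
        bins = bin_by_mu(
            mu,
            results.frame["fwhm"].to_numpy(),
            mesh,
            selected,
            width=config.bin_width,
        )
        topo_models = {}
        min_vertices = 3 * config.poly_degree + 2
        for i, c in enumerate(clusters):
            if c.n_vertices < min_vertices:
                continue
            topo_models[i] = poly_topo_cv(
                mesh.vertex_coords_standard[c.vertices],
                mu[c.vertices],
                degree=config.poly_degree,
                folds=config.poly_folds,
                seed=config.seed,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("topography", str(e)) from e

    bundle = {
        "fits": results.frame,
        "selected": selected,
        "selection": sel_summary,
        "clusters": clusters,
        "cluster_table": cluster_frame,
        "bins": bins,
        "bin_table": bins.to_frame(hemi=config.hemi),
        "topography": topo_models,
        "results": results,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_tsv(out / "fits.tsv", hemi=config.hemi, selected=selected)
        cluster_frame.to_csv(out / "clusters.tsv", sep="\t", index=False)
        bundle["bin_table"].to_csv(out / "bins.tsv", sep="\t", index=False)
        with open(out / "topo.json", "w") as fh:
            json.dump({str(k): m.to_dict() for k, m in topo_models.items()}, fh, indent=2)
        with open(out / "selection.json", "w") as fh:
            json.dump(sel_summary, fh, indent=2)
        provenance = {
            "numtune_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": asdict(config),
            "n_runs": len(runs),
            "n_vertices": mesh.n_vertices,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)

    return bundle
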