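"""End-to-end pipeline: simulate → enrich → shape → polymers → design → model.

A :class:`RunConfig` captures every stage parameter and seed, serialises to
YAML, and a run writes a manifest (config hash, per-file SHA-1, seeds) so
any numeric output is traceable and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .enrichment import enrichment_scalars
from .model import DeltaIDDLasso, build_design, normalization_search
from .polymers import membrane_fraction, summarize_polymers
from .shape import shape_record
from .fileio import save_fit_json

log = logging.getLogger("curvedcell")

FEATURE_FAMILIES = {
    "n_per_cell": "number",
    "n_per_area": "number",
    "n_per_volume": "number",
    "total_length_per_cell": "length",
    "total_length_per_area": "length",
    "total_length_per_volume": "length",
    "enrichment_low": "enrichment",
    "enrichment_high": "enrichment",
    "mean_length_gt200": "length_mean",
    "angle_mean": "angle",
    "membrane_fraction": "membrane",
}


@dataclass
class RunConfig:
    """Every stage parameter and seed of a pipeline run."""

    strains: list[str] = field(
        default_factory=lambda: [
            "wt",
            "rodz",
            "rodz_complement",
            "s14a",
            "e143a",
            "y183n",
            "e143a_rodz",
        ]
    )
    baseline: str = "wt"
    n_cells: int = 20
    master_seed: int = 0
    out_dir: str = "curvedcell_run"
    curvature_cutoff: float = 2.0       # μm⁻²
    p_threshold: float = 5e-3
    polymer_threshold_nm: float = 200.0
    cv_folds: int = 10
    use_segmentation: bool = False      # ground-truth polymer bypass by default
    nm_per_px: float = 15.0
    write_meshes: bool = False

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()


def strain_features(
    cells, polymer_sets, truth: pd.DataFrame, cutoff: float = 2.0
) -> dict:
    """Per-strain feature means in every normalisation variant."""
    shapes = [shape_record(c) for c in cells]
    summaries = []
    for cell, pset, shape in zip(cells, polymer_sets, shapes):
        mf = membrane_fraction(cell) if cell.face_intensity is not None else np.nan
        summaries.append(summarize_polymers(pset, shape, membrane_frac=mf))
    sc = enrichment_scalars(cells, cutoff=cutoff)
    n = np.array([s.n_polymers for s in summaries], dtype=float)
    tot = np.array([s.total_length_nm for s in summaries])
    area = np.array([s_.surface_area for s_ in shapes])
    vol = np.array([s_.volume for s_ in shapes])
    mean_gt = np.array([s.mean_length_gt200 for s in summaries])
    angles = truth["angle_mean_deg"].to_numpy(dtype=float)
    return {
        "idd": float(np.mean([s_.idd for s_ in shapes])),
        "n_per_cell": float(n.mean()),
        "n_per_area": float((n / area).mean()),
        "n_per_volume": float((n / vol).mean()),
        "total_length_per_cell": float(tot.mean()),
        "total_length_per_area": float((tot / area).mean()),
        "total_length_per_volume": float((tot / vol).mean()),
        "enrichment_low": sc.below,
        "enrichment_high": sc.above,
        "mean_length_gt200": float(np.nanmean(mean_gt)),
        "angle_mean": float(np.nanmean(angles)),
        "membrane_fraction": float(
            np.nanmean([s.membrane_fraction for s in summaries])
        ),
        "n_cells": len(cells),
    }


def pipeline_run(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``.

    Returns a manifest dict (also written to ``manifest.json``) listing
    every output file with its hash, the seeds used, and headline numbers.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    strain_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(config.strains, ss.spawn(len(config.strains)))
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "strain_seeds": strain_seeds,
        "files": {},
        "stages": [],
    }

    features_rows = []
    for name in config.strains:
        stage_t = time.time()
        try:
            strain = synthetic.preset(name)
            cells, psets, truth = synthetic.generate_population(
                strain, config.n_cells, strain_seeds[name]
            )
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed for strain {name!r}") from exc
        truth_path = out / f"truth_{name}.csv"
        truth.to_csv(truth_path, index=False)
        manifest["files"][truth_path.name] = _sha1(truth_path)
        if config.write_meshes:
            from .fileio import save_cell

            mesh_dir = out / f"meshes_{name}"
            for cell in cells:
                save_cell(cell, mesh_dir)
        try:
            feats = strain_features(cells, psets, truth, cutoff=config.curvature_cutoff)
        except Exception as exc:
            raise RuntimeError(f"stage features failed for strain {name!r}") from exc
        feats["strain"] = name
        features_rows.append(feats)
        log.info("strain %s: %d cells in %.1fs", name, len(cells), time.time() - stage_t)
        manifest["stages"].append({"strain": name, "seconds": time.time() - stage_t})
        if config.n_cells == 1:
            log.warning("strain %s has a single cell; SEMs are degenerate", name)

    features = pd.DataFrame(features_rows).set_index("strain")
    features_path = out / "features.csv"
    features.to_csv(features_path)
    manifest["files"][features_path.name] = _sha1(features_path)

    comparisons = pd.DataFrame(
        [
            {
                "strain1": name,
                "strain2": config.baseline,
                "observed_didd": features.loc[name, "idd"]
                - features.loc[config.baseline, "idd"],
            }
            for name in config.strains
            if name != config.baseline
        ]
    )
    comp_path = out / "comparisons.csv"
    comparisons.to_csv(comp_path, index=False)
    manifest["files"][comp_path.name] = _sha1(comp_path)

    results = None
    search = None
    if len(comparisons) >= 4:
        try:
            design = build_design(
                comparisons,
                features.reset_index(),
                feature_columns=list(FEATURE_FAMILIES),
                families=FEATURE_FAMILIES,
            )
            model = DeltaIDDLasso(design)
            results = model.fit(
                k=min(config.cv_folds, design.n), seed=config.master_seed
            )
        except Exception as exc:
            raise RuntimeError("stage model failed") from exc
        fit_path = out / "fit.json"
        save_fit_json(results, fit_path)
        manifest["files"][fit_path.name] = _sha1(fit_path)
        if design.n >= 6:
            search = normalization_search(
                design, k=min(config.cv_folds, design.n), seed=config.master_seed
            )
    else:
        log.warning(
            "only %d comparisons; skipping the regression stage (needs >= 4)",
            len(comparisons),
        )
    manifest["results"] = {
        "lambda": results.lam if results else None,
        "nonzero": results.nonzero_features if results else None,
        "r2_insample": (
            results.rsquared if results and results.nonzero_features else None
        ),
        "best_triple": list(search.best_triple) if search else None,
        "seconds_total": time.time() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    return manifest


def setup_logging(quiet: bool = False, json_log: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    if json_log:
        class _Json(logging.Formatter):
            def format(self, record):
                return json.dumps(
                    {
                        "stage": record.name,
                        "level": record.levelname,
                        "msg": record.getMessage(),
                    }
                )

        handler.setFormatter(_Json())
    else:
        handler.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    logging.basicConfig(
        level=logging.ERROR if quiet else logging.INFO, handlers=[handler], force=True
    )
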