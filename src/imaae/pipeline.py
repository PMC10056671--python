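"""Sequential orchestration of the full correction workflow with a manifest.

``run_all`` executes simulate (or load) -> preprocess -> anchor -> train ->
correct -> evaluate, writing every intermediate artifact plus a single JSON
manifest that records the configs, seeds and SHA-256 hashes of every file so
a run can be audited and reproduced stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anchor import (
    build_training_mapping,
    select_anchor_balanced,
    select_anchor_custom,
    select_anchor_max_std,
)
from .correct import apply_correction
from .datamodel import AnnotatedMatrix, PipelineConfig, read_matrix, write_matrix
from .evaluate import evaluate_all
from .model import AAEConfig, train
from .preprocess import preprocess_pipeline
from .simulate import SimulationConfig, simulate_counts

log = logging.getLogger("imaae")


@dataclass
class RunManifest:
    tool_version: str
    started: str
    finished: str | None = None
    stages: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: RunManifest, stage: str, config: dict, outputs: dict[str, Path]) -> None:
    manifest.stages[stage] = {
        "config": config,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
    }


def run_all(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Run every stage described by ``config`` (a dict or a TOML/YAML file path).

    Recognised sections: ``input`` (path/format of an existing dataset) or
    ``simulation`` (SimulationConfig fields), ``preprocess`` (PipelineConfig
    fields), ``anchor`` (mode, batch_id, max_per_type, seed), ``train``
    (AAEConfig fields) and ``evaluate`` (n_pcs, seed).
    """
    from . import __version__

    if not isinstance(config, dict):
        import tomllib

        import yaml

        path = Path(config)
        text = path.read_text()
        config = tomllib.loads(text) if path.suffix == ".toml" else yaml.safe_load(text)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(tool_version=__version__, started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    try:
        # ---- input or simulation ---------------------------------------
        if "input" in config:
            inp = config["input"]
            m = read_matrix(inp["path"], inp.get("format", "h5_container"))
            manifest.stages["input"] = {"config": dict(inp)}
        else:
            sim_cfg = SimulationConfig(**config.get("simulation", {}))
            manifest.seeds["simulate"] = sim_cfg.seed
            log.info("simulate: %s scenario, %d batches", sim_cfg.scenario, sim_cfg.n_batches)
            m = simulate_counts(sim_cfg)
            raw_path = outdir / "raw.h5ad"
            write_matrix(m, raw_path, "h5_container")
            _record(manifest, "simulate", sim_cfg.__dict__, {"raw": raw_path})

        # ---- preprocess -------------------------------------------------
        prep_cfg = PipelineConfig(**config.get("preprocess", {}))
        log.info("preprocess: %d cells x %d genes in", m.n_cells, m.n_genes)
        prep, graph = preprocess_pipeline(m, prep_cfg)
        prep_path = outdir / "prep.h5ad"
        write_matrix(prep, prep_path, "h5_container")
        _record(manifest, "preprocess", prep_cfg.__dict__, {"prep": prep_path})

        # ---- anchor -----------------------------------------------------
        a_cfg = dict(config.get("anchor", {}))
        mode = a_cfg.get("mode", "balanced")
        max_per_type = int(a_cfg.get("max_per_type", 1000))
        a_seed = int(a_cfg.get("seed", prep_cfg.random_seed))
        manifest.seeds["anchor"] = a_seed
        if mode == "balanced":
            anchors = select_anchor_balanced(prep, graph, max_per_type, a_seed)
        elif mode == "max_std":
            anchors = select_anchor_max_std(prep, max_per_type, a_seed)
        elif mode == "custom":
            anchors = select_anchor_custom(prep, a_cfg["batch_id"], max_per_type, a_seed)
        else:
            raise ValueError(f"unknown anchor mode {mode!r}")
        mapping = build_training_mapping(
            prep, anchors, graph, a_seed, a_cfg.get("missing_anchor", "error")
        )
        manifest.stages["anchor"] = {
            "config": {"mode": mode, "max_per_type": max_per_type, "seed": a_seed},
            "n_profiles": int(len(anchors.anchor_types)),
            "n_passthrough": int(mapping.passthrough_mask.sum()),
        }

        # ---- train ------------------------------------------------------
        t_cfg = dict(config.get("train", {}))
        latent = int(t_cfg.pop("latent_dim", min(32, prep.n_genes)))
        aae_cfg = AAEConfig.for_data(prep.n_genes, latent, **t_cfg)
        manifest.seeds["train"] = aae_cfg.seed
        log.info("train: mode=%s epochs=%d latent=%d", aae_cfg.mode, aae_cfg.epochs, latent)
        model = train(prep, mapping, anchors, aae_cfg)
        model_path = outdir / "model.npz"
        model.save(model_path)
        _record(manifest, "train", {k: str(v) for k, v in aae_cfg.__dict__.items()}, {"model": model_path})

        # ---- correct ----------------------------------------------------
        result = apply_correction(model, prep, mapping)
        corrected = prep.with_values(result.corrected_expression, "lognormalized")
        corr_path = outdir / "corrected.h5ad"
        write_matrix(corrected, corr_path, "h5_container")
        np.save(outdir / "latent.npy", result.latent)
        _record(manifest, "correct", result.provenance, {"corrected": corr_path})

        # ---- evaluate ---------------------------------------------------
        e_cfg = dict(config.get("evaluate", {}))
        e_seed = int(e_cfg.get("seed", 0))
        manifest.seeds["evaluate"] = e_seed
        report = evaluate_all(
            result, prep.batch, prep.cell_type, n_pcs=int(e_cfg.get("n_pcs", 50)), seed=e_seed
        )
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        _record(manifest, "evaluate", e_cfg, {"report": report_path})
    except Exception as exc:
        manifest.failure = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
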