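"""End-to-end pipeline driver: YAML/dict config in, TSV tables + manifest out.

Wraps :class:`~cisprog.model.CisplatinResponseModel` with file handling so a
whole run — simulate or load bundles, fit, enrich, write every stage table —
is reproducible from a single config and seed.  Outputs are plain TSV plus a
JSON manifest recording parameters, seeds, per-stage row counts and a SHA-256
checksum of every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSetCollection, read_gmt, results_frame
from .io import read_bundle, write_bundle
from .model import CisplatinResponseModel, CisplatinResponseResults
from .simulate import Condition, SimConfig, generate_replicate_set

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs; echoed verbatim into the manifest."""

    output_dir: str
    input_dir: Optional[str] = None  # directory of bundle subdirectories
    simulation: Optional[dict] = None  # SimConfig field overrides
    gmt: Optional[str] = None  # gene-set collection for enrichment
    top_n: int = 1000
    bottom_n: int = 10000
    sensitivity_fraction: float = 0.25
    n_pcs: int = 10
    d_sens_min: float = 0.5
    d_phase_max: float = 0.5
    linkage: str = "average"
    cut_height: float = 0.7
    n_clusters: Optional[int] = None
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_fdr_max: float = 0.05
    gsea_gene_ratio_min: float = 0.4
    seed: int = 0
    write_bundles: bool = False

    def __post_init__(self) -> None:
        if self.input_dir is None and self.simulation is None:
            raise ValueError("config needs either input_dir or a simulation block")
        if not 0 < self.sensitivity_fraction <= 0.5:
            raise ValueError("sensitivity_fraction must be in (0, 0.5]")
        for name in ("top_n", "bottom_n", "n_pcs", "gsea_n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        overrides = dict(self.simulation or {})
        if "conditions" in overrides:
            overrides["conditions"] = tuple(
                Condition(*c) if not isinstance(c, Condition) else c
                for c in overrides["conditions"]
            )
        overrides.setdefault("seed", self.seed)
        return SimConfig(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write outputs; returns the manifest dict.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    whatever was already written is moved under ``<output_dir>/failed/``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }
    stage = "setup"
    try:
        stage = "load"
        if config.input_dir is not None:
            root = Path(config.input_dir)
            dirs = sorted(d for d in root.iterdir() if (d / "matrix.mtx").exists())
            if not dirs:
                raise FileNotFoundError(f"no bundles under {root}")
            bundles = [read_bundle(d) for d in dirs]
        else:
            stage = "simulate"
            sim = config.sim_config()
            bundles = generate_replicate_set(sim)
            if config.write_bundles:
                for b in bundles:
                    write_bundle(b, out / "bundles" / b.experiment_id)
        manifest["stages"]["experiments"] = len(bundles)

        stage = "fit"
        model = CisplatinResponseModel(
            bundles,
            top_n=config.top_n,
            bottom_n=config.bottom_n,
            sensitivity_fraction=config.sensitivity_fraction,
            n_pcs=config.n_pcs,
            d_sens_min=config.d_sens_min,
            d_phase_max=config.d_phase_max,
            linkage=config.linkage,
            cut_height=config.cut_height,
            n_clusters=config.n_clusters,
            seed=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results = model.fit()

        stage = "write-signatures"
        sig_table = pd.concat([s.series for s in results.signatures], axis=1)
        sig_table["universal"] = results.universal.series
        sig_out = sig_table.reset_index().rename(columns={"index": "gene_id"})
        _write_tsv(sig_out, out / "signatures.tsv")
        if results.agreement is not None:
            _write_tsv(
                results.agreement.reset_index().rename(columns={"index": "experiment_id"}),
                out / "signature_agreement.tsv",
            )
        manifest["stages"]["signature_genes"] = int(len(sig_table))

        stage = "write-sensitivity"
        sens = results.sensitivity_table()
        _write_tsv(sens, out / "sensitivity_calls.tsv")
        manifest["stages"]["stratum_cells"] = int(len(sens))

        stage = "write-programs"
        prog = results.program_table()
        _write_tsv(prog, out / "pc_programs.tsv")
        manifest["stages"]["candidate_pcs"] = int(len(prog))
        manifest["stages"]["selected_pcs"] = int(prog["selected"].sum())

        stage = "write-consensus"
        if len(results.similarity):
            _write_tsv(
                results.similarity.reset_index().rename(columns={"index": "program_id"}),
                out / "program_similarity.tsv",
            )
            _write_tsv(
                results.cluster_labels.rename_axis("program_id").reset_index(),
                out / "program_clusters.tsv",
            )
        for cp in results.consensus_programs:
            table = pd.DataFrame(
                {
                    "gene_id": cp.median_weights.index,
                    "mean_loading": cp.mean_loadings.to_numpy(),
                    "median_weight": cp.median_weights.to_numpy(),
                }
            )
            _write_tsv(table, out / f"consensus_cluster{cp.cluster_id}.tsv")
        manifest["stages"]["consensus_clusters"] = len(results.consensus_programs)

        if config.gmt:
            stage = "gsea"
            collection = read_gmt(config.gmt)
            gsea = results.run_gsea(
                collection,
                n_perm=config.gsea_n_perm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                fdr_max=config.gsea_fdr_max,
                gene_ratio_min=config.gsea_gene_ratio_min,
                seed=config.seed,
            )
            for cid, tables in gsea.items():
                _write_tsv(results_frame(tables["results"]), out / f"gsea_cluster{cid}.tsv")
                _write_tsv(
                    results_frame(tables["filtered"]), out / f"gsea_cluster{cid}_filtered.tsv"
                )
            manifest["stages"]["gsea_clusters"] = len(gsea)

    except Exception as exc:  # noqa: BLE001 - stage context is the point
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.glob("*.tsv"):
            shutil.move(str(f), failed / f.name)
        raise PipelineError(stage, str(exc)) from exc

    stage = "manifest"
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
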