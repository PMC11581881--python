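"""End-to-end orchestration: methylation quantification -> single-sample
networks -> degree matrices -> fold changes -> LET screens -> GA selection ->
methylation-correlation annotation -> hub ranking.

Driven by a declarative config (YAML via the CLI or a :class:`PipelineConfig`
in code); every output table is tab-separated and the run manifest records
inputs, parameters, seed, per-stage gene tallies, and a SHA-256 checksum of
every file, so two runs with identical config and seed produce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as ssio
from .ga import GAConfig, run_ga
from .methylation import CytosineCoverage, build_methylation_matrices
from .screen import (fold_change, hub_genes, let_screen,
                     methylation_correlation)
from .ssn import build_ssns, degree_matrix, overlap_with_ppi
from .types import OmicsMatrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    expression: str
    metadata: str
    ppi: str
    outdir: str
    seed: int
    gff3: str | None = None
    coverage_dir: str | None = None
    stage: str = "tillering"
    layers: dict = field(default_factory=lambda: {
        "expression": True, "meth_promoter": True, "meth_body": True})
    tau: float = 0.5
    min_ppi_score: float = 0.0
    pcc_threshold: float = 0.5
    alpha: float = 0.05
    upstream_bp: int = 2000
    sf_only_methylation: bool = False
    hub_top_k: int = 5
    ga: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.pop("inputs", {})
        params = raw.pop("params", {})
        return cls(**{**inputs, **params, **raw})

    def __post_init__(self):
        for name, lo, hi in (("tau", 0, None), ("pcc_threshold", 0, 1),
                             ("alpha", 0, 1)):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ValueError(f"{name}={v} out of range")
        for key in ("expression", "metadata", "ppi"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} input not found: {p}")
        if (self.layers.get("meth_promoter") or self.layers.get("meth_body")):
            if not (self.gff3 and self.coverage_dir):
                raise ValueError("methylation layers need gff3 and coverage_dir")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured workflow; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}
    current_stage = "setup"

    def emit(name: str, frame, index=True) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=index)
        outputs[name] = str(path)

    try:
        current_stage = "read_inputs"
        meta = ssio.read_metadata(config.metadata)
        expr = ssio.read_expression_matrix(config.expression)
        ppi = ssio.read_ppi(config.ppi, min_score=config.min_ppi_score)

        # zero-expression filtering: a gene silent in every sample carries no
        # signal for correlation or networks
        current_stage = "expression_filter"
        nonzero = (expr.frame != 0).any(axis=1)
        counts["expression_genes_in"] = int(len(expr.frame))
        counts["expression_genes_zero_dropped"] = int((~nonzero).sum())
        expr = OmicsMatrix(expr.frame.loc[nonzero], layer="expression")
        counts["expression_genes_kept"] = int(len(expr.frame))

        layers: dict[str, OmicsMatrix] = {}
        if config.layers.get("expression", True):
            layers["expression"] = expr
        if config.layers.get("meth_promoter") or config.layers.get("meth_body"):
            current_stage = "methylation_quant"
            annotation = ssio.read_annotation_gff3(config.gff3)
            covdir = Path(config.coverage_dir)
            coverage = {p.stem: CytosineCoverage.from_bismark(p)
                        for p in sorted(covdir.glob("*.cov"))}
            prom, body = build_methylation_matrices(
                coverage, annotation, upstream_bp=config.upstream_bp)
            if config.layers.get("meth_promoter"):
                layers["meth_promoter"] = prom
                counts["meth_promoter_genes"] = int(len(prom.frame))
            if config.layers.get("meth_body"):
                layers["meth_body"] = body
                counts["meth_body_genes"] = int(len(body.frame))
            for name in ("meth_promoter", "meth_body"):
                if name in layers:
                    emit(f"matrix_{name}", layers[name].frame)

        # --- SSNs and degree matrices per layer -------------------------
        degrees: dict[str, pd.DataFrame] = {}
        for name, matrix in layers.items():
            current_stage = f"ssn_{name}"
            ssns = build_ssns(matrix)
            binaries = [overlap_with_ppi(s, ppi, tau=config.tau) for s in ssns]
            deg = degree_matrix(binaries)
            degrees[name] = deg
            counts[f"degree_genes_{name}"] = int(len(deg))
            emit(f"degrees_{name}", deg)

        # --- six fold-change matrices ------------------------------------
        current_stage = "fold_change"
        fc_tables = {}
        for name, matrix in layers.items():
            fc_tables[(name, "level")] = fold_change(matrix, meta, "level")
        for name, deg in degrees.items():
            fc_tables[(name, "degree")] = fold_change(
                pd.DataFrame(deg), meta, "degree")
        for (name, mode), fc in fc_tables.items():
            emit(f"fc_{name}_{mode}", fc.frame)

        # --- LET screens --------------------------------------------------
        current_stage = "let_screen"
        screens = {}
        for (name, mode), fc in fc_tables.items():
            table = let_screen(fc, meta, mode=mode,
                               pcc_threshold=config.pcc_threshold,
                               alpha=config.alpha)
            table = table.assign(stage=config.stage)
            screens[(name, mode)] = table
            counts[f"let_related_{name}_{mode}"] = int(table["is_hit"].sum())
            emit(f"let_screen_{name}_{mode}", table)

        # --- GA models on the expression-layer FC matrices ----------------
        current_stage = "ga_selection"
        ga_results = {}
        if "expression" in layers:
            base = {k: v for k, v in config.ga.items()}
            for model, key, seed_offset in (
                    ("expression_model", ("expression", "level"), 0),
                    ("degree_model", ("expression", "degree"), 1)):
                if key not in fc_tables:
                    continue
                ga_cfg = GAConfig(rng_seed=config.seed + seed_offset, **base)
                result = run_ga(fc_tables[key], meta, ga_cfg)
                ga_results[model] = result
                counts[f"{model}_selected_genes"] = len(result.selected_gene_ids)
                payload = {
                    "config": dataclasses.asdict(ga_cfg),
                    "selected_gene_ids": result.selected_gene_ids,
                    "loocv_r2": result.fit.r_squared,
                    "pcc_actual_vs_predicted": result.fit.pcc_actual_vs_predicted,
                    "pcc_p_value": result.fit.p_value,
                    "intercept": result.fit.intercept,
                    "coefficients": list(result.fit.coefficients),
                    "loocv_predictions": dict(zip(
                        fc_tables[key].sample_ids,
                        result.fit.loocv_predictions.tolist())),
                    "fitness_history": result.fitness_history.to_dict("records"),
                }
                path = outdir / f"ga_{model}.json"
                with open(path, "w") as fh:
                    json.dump(payload, fh, indent=2, sort_keys=True)
                outputs[f"ga_{model}"] = str(path)

        # --- methylation-correlation annotation ---------------------------
        current_stage = "methylation_correlation"
        have_meth = {n for n in ("meth_promoter", "meth_body") if n in layers}
        if have_meth and "expression" in layers and ga_results:
            meth_sf = None
            if config.sf_only_methylation:
                meth_sf = meta.sf_ids
            for model, primary in (
                    ("expression_model", layers["expression"].frame),
                    ("degree_model", degrees.get("expression"))):
                if model not in ga_results or primary is None:
                    continue
                genes = ga_results[model].selected_gene_ids
                rows = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
                for name in sorted(have_meth):
                    methyl = (layers[name].frame if model == "expression_model"
                              else degrees.get(name))
                    if methyl is None:
                        continue
                    corr = methylation_correlation(
                        primary, methyl, genes, alpha=config.alpha,
                        samples=meth_sf)
                    suffix = name.replace("meth_", "")
                    rows[f"pcc_{suffix}"] = corr["pcc"]
                    rows[f"p_{suffix}"] = corr["p_value"]
                    rows[f"is_hit_{suffix}"] = corr["is_hit"].astype("boolean")
                emit(f"radiation_responsive_{model}", rows)
            # LET-methylation genes: LET-related genes (expression layer)
            # whose level/degree correlates with methylation
            for mode in ("level", "degree"):
                key = ("expression", mode)
                if key not in screens:
                    continue
                hits = screens[key].index[screens[key]["is_hit"]].tolist()
                if not hits:
                    continue
                primary = (layers["expression"].frame if mode == "level"
                           else degrees.get("expression"))
                if primary is None:
                    continue
                rows = pd.DataFrame(index=pd.Index(hits, name="gene_id"))
                for name in sorted(have_meth):
                    methyl = (layers[name].frame if mode == "level"
                              else degrees.get(name))
                    if methyl is None:
                        continue
                    corr = methylation_correlation(
                        primary, methyl, hits, alpha=config.alpha,
                        samples=meth_sf)
                    suffix = name.replace("meth_", "")
                    rows[f"pcc_{suffix}"] = corr["pcc"]
                    rows[f"p_{suffix}"] = corr["p_value"]
                    rows[f"is_hit_{suffix}"] = corr["is_hit"].astype("boolean")
                hit_cols = [c for c in rows.columns if c.startswith("is_hit")]
                n_hits = int(rows[hit_cols].any(axis=1).sum()) if hit_cols else 0
                counts[f"let_methylation_genes_{mode}"] = n_hits
                emit(f"let_methylation_{mode}", rows)

        # --- hub ranking ---------------------------------------------------
        current_stage = "hubs"
        for (name, mode), table in screens.items():
            hits = table.index[table["is_hit"]].tolist()
            if not hits:
                continue
            hubs = hub_genes(hits, ppi, top_k=config.hub_top_k)
            emit(f"hubs_{name}_{mode}", hubs)

        current_stage = "manifest"
        manifest = {
            "software": {"name": "ssnlet", "version": __version__},
            "stage_label": config.stage,
            "seed": config.seed,
            "parameters": {
                "tau": config.tau, "min_ppi_score": config.min_ppi_score,
                "pcc_threshold": config.pcc_threshold, "alpha": config.alpha,
                "upstream_bp": config.upstream_bp,
                "hub_top_k": config.hub_top_k,
                "sf_only_methylation": config.sf_only_methylation,
                "ga": config.ga,
            },
            "inputs": {
                "expression": str(config.expression),
                "metadata": str(config.metadata),
                "ppi": str(config.ppi),
                "gff3": str(config.gff3) if config.gff3 else None,
                "coverage_dir": (str(config.coverage_dir)
                                 if config.coverage_dir else None),
            },
            "counts": counts,
            "outputs": {name: {"path": str(Path(p).name),
                               "sha256": _sha256(Path(p))}
                        for name, p in sorted(outputs.items())},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        marker = outdir / "FAILED"
        marker.write_text(f"stage: {current_stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current_stage, str(exc)) from exc
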