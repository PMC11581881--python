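"""Ground-truthed synthetic multi-omics datasets mirroring the study design.

The emulated experiment: 3 ground-control (GC) rice plants plus 22
spaceflight (SF) plants each hit by a single galactic-cosmic-ray heavy ion,
with linear energy transfer (LET) spanning 0-250.8 keV/um; expression is
profiled for all 25 plants, whole-genome bisulfite methylation for the 3 GC
plants and 8 of the SF plants.  A planted subset of genes responds linearly
in LET (multiplicatively, with log-normal noise) and the same genes' promoter
and gene-body methylation tracks their expression through a logistic link, so
every downstream screen has a known answer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as ssio
from .methylation import CytosineCoverage
from .types import GeneAnnotation, OmicsMatrix, PPINetwork, SampleMetadata

logger = logging.getLogger(__name__)

#: LET values (keV/um) of the 22 flown plants profiled by RNA-seq; SF1 was
#: flown but not hit by any heavy ion, hence LET = 0.
DEFAULT_SF_LET = (
    0.0, 18.2679, 19.8511, 20.4151, 52.7435, 53.7153, 54.9614, 70.9111,
    74.8003, 77.7099, 100.74, 107.6414, 107.6414, 136.8396, 136.8545,
    159.4854, 184.0827, 186.1181, 206.4886, 213.3132, 248.0167, 250.8219,
)

#: 1-based SF sample numbers with methylation (WGBS) profiling.
DEFAULT_WGBS_SF = (1, 5, 6, 11, 12, 14, 17, 18)


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    ``let_values="table1"`` uses the 22 measured LET values above.  Planted
    LET genes get a multiplicative response 1 + beta * LET / LET_max with
    beta drawn from ``beta_range``; ``noise_sd`` is the standard deviation of
    the log-normal measurement noise on every expression value.
    """

    seed: int
    n_genes: int = 500
    n_gc: int = 3
    n_sf: int = 22
    n_meth_sf: int = 8
    let_values: tuple | str = "table1"
    k_planted: int = 5
    beta_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.1
    coverage_depth: int = 30
    sites_per_region: int = 10
    meth_strength_range: tuple[float, float] = (1.5, 3.0)
    stage: str = "tillering"
    upstream_bp: int = 2000

    def resolved_let(self) -> list[float]:
        if isinstance(self.let_values, str):
            if self.let_values != "table1":
                raise ValueError(f"unknown LET preset {self.let_values!r}")
            vals = list(DEFAULT_SF_LET)
        else:
            vals = [float(v) for v in self.let_values]
        if len(vals) != self.n_sf:
            raise ValueError(f"{len(vals)} LET values for {self.n_sf} SF samples")
        return vals

    def __post_init__(self):
        if self.k_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.n_meth_sf > self.n_sf:
            raise ValueError("more methylation SF samples than SF samples")
        self.resolved_let()


@dataclass
class SimulationTruth:
    """What was planted, for recovery scoring."""

    planted_let_genes: dict[str, dict]   # gene -> {beta, noise_sd}
    planted_meth_genes: dict[str, dict]  # gene -> {sign, strength}
    seed: int


@dataclass
class SimulatedDataset:
    expression: OmicsMatrix
    metadata: SampleMetadata
    annotation: GeneAnnotation
    ppi: PPINetwork
    coverage: dict[str, pd.DataFrame]  # Bismark-dialect frames per sample
    truth: SimulationTruth
    config: SimConfig

    def coverage_objects(self) -> dict[str, CytosineCoverage]:
        return {s: CytosineCoverage(f.rename(columns={"start": "pos"})[
            ["chrom", "pos", "count_meth", "count_unmeth"]])
            for s, f in self.coverage.items()}


def scenario_a(seed: int) -> SimConfig:
    """The reference recovery scenario: 500 genes, 5 planted responders with
    beta in [0.5, 2], log-noise 0.1, the measured LET design."""
    return SimConfig(seed=seed)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _annotation(gene_ids: list[str]) -> GeneAnnotation:
    """Genes of 2 kb laid out every 10 kb across five chromosomes, so no
    promoter window can overlap a neighbouring gene."""
    n_chrom = 5
    rows = []
    per_chrom = -(-len(gene_ids) // n_chrom)
    for i, g in enumerate(gene_ids):
        chrom = f"chr{i // per_chrom + 1}"
        start = 10000 + (i % per_chrom) * 10000
        strand = "+" if i % 2 == 0 else "-"
        rows.append((g, chrom, strand, start, start + 1999))
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start",
                                        "end"]).set_index("gene_id")
    return GeneAnnotation(frame)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full fixture bundle plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gc_ids = [f"GC{i + 1}" for i in range(config.n_gc)]
    sf_ids = [f"SF{i + 1}" for i in range(config.n_sf)]
    let = np.array(config.resolved_let())
    let_max = let.max() if let.max() > 0 else 1.0

    # --- metadata -------------------------------------------------------
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": gc_ids + sf_ids,
        "group": ["GC"] * config.n_gc + ["SF"] * config.n_sf,
        "let_value": [np.nan] * config.n_gc + list(let),
        "stage": config.stage,
    }))

    # --- expression -----------------------------------------------------
    planted_idx = np.sort(rng.choice(config.n_genes, size=config.k_planted,
                                     replace=False))
    betas = rng.uniform(*config.beta_range, size=config.k_planted)
    baseline = rng.lognormal(mean=3.0, sigma=1.0, size=config.n_genes)
    n_samples = config.n_gc + config.n_sf
    factor = np.ones((config.n_genes, n_samples))
    for k, gi in enumerate(planted_idx):
        factor[gi, config.n_gc:] = 1.0 + betas[k] * let / let_max
    noise = np.exp(rng.normal(0.0, config.noise_sd,
                              size=(config.n_genes, n_samples)))
    values = baseline[:, None] * factor * noise
    expr = OmicsMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                                    columns=gc_ids + sf_ids), layer="expression")

    planted_let = {genes[gi]: {"beta": float(betas[k]),
                               "noise_sd": config.noise_sd}
                   for k, gi in enumerate(planted_idx)}

    # --- methylation coverage ------------------------------------------
    annotation = _annotation(genes)
    meth_sf = ([f"SF{i}" for i in DEFAULT_WGBS_SF]
               if (config.n_sf, config.n_meth_sf) == (22, 8)
               else sf_ids[:config.n_meth_sf])
    meth_samples = gc_ids + meth_sf

    # planted methylation responders = the planted LET genes: their promoter
    # and body methylation follows expression through a logistic link
    meth_sign = rng.choice([-1.0, 1.0], size=config.k_planted)
    meth_strength = rng.uniform(*config.meth_strength_range,
                                size=config.k_planted)
    planted_meth = {genes[gi]: {"sign": float(meth_sign[k]),
                                "strength": float(meth_strength[k])}
                    for k, gi in enumerate(planted_idx)}

    base_p = rng.uniform(0.15, 0.85, size=(config.n_genes, 2))  # promoter, body
    log_expr = np.log(values + 1e-9)
    col_of = {s: i for i, s in enumerate(gc_ids + sf_ids)}
    meth_cols = [col_of[s] for s in meth_samples]
    z = log_expr[:, meth_cols]
    z = (z - z.mean(axis=1, keepdims=True)) / np.where(
        z.std(axis=1, keepdims=True) == 0, 1, z.std(axis=1, keepdims=True))

    ann = annotation.frame
    coverage: dict[str, pd.DataFrame] = {}
    # per-gene proportions for each meth sample, region r in {promoter, body}
    logit = np.log(base_p / (1 - base_p))  # (genes, 2)
    p = np.repeat(logit[:, None, :], len(meth_samples), axis=1)  # g x s x 2
    for k, gi in enumerate(planted_idx):
        p[gi, :, :] += (meth_sign[k] * meth_strength[k] * z[gi])[:, None]
    p = 1.0 / (1.0 + np.exp(-p))

    for j, sample in enumerate(meth_samples):
        records = []
        for i, g in enumerate(genes):
            row = ann.loc[g]
            body = (row.start, row.end)
            if row.strand == "+":
                prom = (max(1, row.start - config.upstream_bp), row.start - 1)
            else:
                prom = (row.end + 1, row.end + config.upstream_bp)
            for r, (lo, hi) in enumerate((prom, body)):
                sites = np.linspace(lo, hi, config.sites_per_region).astype(int)
                sites = np.unique(sites)
                cm = rng.binomial(config.coverage_depth, p[i, j, r],
                                  size=sites.size)
                cu = config.coverage_depth - cm
                for pos, a, b in zip(sites, cm, cu):
                    records.append((row.chrom, int(pos), int(pos), a, b))
        frame = pd.DataFrame(records, columns=["chrom", "start", "end",
                                               "count_meth", "count_unmeth"])
        frame.insert(3, "percent", np.where(
            frame.count_meth + frame.count_unmeth > 0,
            100.0 * frame.count_meth /
            (frame.count_meth + frame.count_unmeth).clip(lower=1), 0.0))
        coverage[sample] = frame

    # --- PPI: preferential-attachment graph over the gene universe ------
    ba = nx.barabasi_albert_graph(config.n_genes, 2,
                                  seed=int(rng.integers(0, 2 ** 31)))
    ppi = nx.relabel_nodes(ba, {i: genes[i] for i in range(config.n_genes)})
    nx.set_edge_attributes(ppi, 900.0, "score")

    truth = SimulationTruth(planted_let_genes=planted_let,
                            planted_meth_genes=planted_meth,
                            seed=config.seed)
    return SimulatedDataset(expr, meta, annotation, ppi, coverage, truth, config)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write every file format the pipeline reads; returns name -> path.

    Output is deterministic: the same config and seed reproduce every file
    byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def register(name, p):
        paths[name] = str(p)
        return p

    ssio.write_matrix(ds.expression, register("expression", outdir / "expression.tsv"))
    ssio.write_metadata(ds.metadata, register("metadata", outdir / "metadata.tsv"))
    ssio.write_annotation_gff3(ds.annotation,
                               register("annotation", outdir / "annotation.gff3"))
    ssio.write_ppi(ds.ppi, register("ppi", outdir / "ppi.tsv"))
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    for sample, frame in ds.coverage.items():
        p = covdir / f"{sample}.cov"
        frame.to_csv(p, sep="\t", header=False, index=False,
                     float_format="%.6f")
        paths[f"coverage/{sample}"] = str(p)
    with open(register("truth", outdir / "truth.json"), "w") as fh:
        json.dump(asdict(ds.truth), fh, indent=2, sort_keys=True)
    return paths
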