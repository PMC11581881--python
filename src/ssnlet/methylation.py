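"""Aggregate per-cytosine bisulfite counts into per-gene methylation levels.

The methylation level of a region is read-weighted: all methylated read counts
inside the region are pooled, all unmethylated counts are pooled, and the
level is mC / (mC + umC).  CpG/CHG/CHH contexts are not distinguished (the
Bismark coverage dialect consumed here does not separate them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GeneAnnotation, OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_BP = 2000


@dataclass(frozen=True)
class RegionSpec:
    """A promoter or gene-body region, 1-based inclusive coordinates."""

    gene_id: str
    region: str  # "promoter" | "body"
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.region not in ("promoter", "body"):
            raise ValueError(f"unknown region kind {self.region!r}")
        # end == start - 1 encodes an empty window (gene at chromosome start
        # has no upstream promoter); anything shorter is malformed
        if self.start < 1 or self.end < self.start - 1:
            raise ValueError(f"invalid region [{self.start}, {self.end}]")


def promoter_region(gene, upstream_bp: int = DEFAULT_UPSTREAM_BP) -> RegionSpec:
    """Strand-aware upstream promoter window of a gene.

    For a + strand gene spanning [s, e] the promoter is [s - upstream_bp,
    s - 1], clipped at position 1 near the chromosome start; for a - strand
    gene it mirrors to [e + 1, e + upstream_bp].
    """
    if upstream_bp < 1:
        raise ValueError("upstream_bp must be >= 1")
    if gene.strand == "+":
        start = max(1, gene.start - upstream_bp)
        end = gene.start - 1  # end 0 for a gene at position 1: empty window
    else:
        start = gene.end + 1
        end = gene.end + upstream_bp
    return RegionSpec(str(gene.Index), "promoter", gene.chrom, start, end,
                      gene.strand)


def body_region(gene) -> RegionSpec:
    """The annotated gene span itself."""
    return RegionSpec(str(gene.Index), "body", gene.chrom, gene.start, gene.end,
                      gene.strand)


class CytosineCoverage:
    """Per-cytosine methylated/unmethylated read counts for one sample,
    indexed by chromosome with sorted positions for range queries."""

    def __init__(self, frame: pd.DataFrame):
        # columns: chrom, pos (1-based), count_meth, count_unmeth
        if (frame[["count_meth", "count_unmeth"]].to_numpy() < 0).any():
            raise ValueError("negative read counts")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            self._by_chrom[str(chrom)] = (
                sub["pos"].to_numpy(dtype=np.int64),
                sub["count_meth"].to_numpy(dtype=np.int64),
                sub["count_unmeth"].to_numpy(dtype=np.int64),
            )
        self.n_sites = int(len(frame))

    @classmethod
    def from_bismark(cls, path) -> "CytosineCoverage":
        """Read a Bismark coverage file: chrom, start(1-based), end, percent,
        count_methylated, count_unmethylated.  The percentage column is
        ignored and always recomputed from the counts."""
        frame = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "percent", "count_meth",
                   "count_unmeth"],
            dtype={"chrom": str},
        )
        frame = frame.rename(columns={"start": "pos"})
        return cls(frame[["chrom", "pos", "count_meth", "count_unmeth"]])

    def region_counts(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Pooled (methylated, unmethylated) counts inside [start, end]."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return 0, 0
        pos, cm, cu = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return int(cm[lo:hi].sum()), int(cu[lo:hi].sum())


def region_methylation_level(coverage: CytosineCoverage,
                             region: RegionSpec) -> float:
    """Pooled-count methylation level mC / (mC + umC) of a region.

    Returns NaN when no covered cytosine falls in the region (level
    undefined), which downstream matrix assembly treats as missing.
    """
    mc, umc = coverage.region_counts(region.chrom, region.start, region.end)
    if mc + umc == 0:
        logger.debug("no covered cytosines in %s %s region", region.gene_id,
                     region.region)
        return float("nan")
    return mc / (mc + umc)


def build_methylation_matrices(
    coverage_per_sample: dict[str, CytosineCoverage],
    annotation: GeneAnnotation,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    drop_incomplete: bool = True,
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Build the promoter and gene-body methylation-level matrices.

    Both matrices share the annotation's gene universe.  A gene with no
    covered cytosines in a sample's region is NaN there; by default any gene
    that is missing in at least one sample is dropped from that layer, because
    the downstream correlation and network steps need complete vectors (the
    number dropped is logged).
    """
    if not coverage_per_sample:
        raise ValueError("at least one coverage sample required")
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    for sample, cov in coverage_per_sample.items():
        if cov.n_sites == 0:
            raise ValueError(f"sample {sample!r} has zero covered cytosines")

    samples = list(coverage_per_sample)
    out = {}
    for kind, region_fn in (("promoter", promoter_region), ("body", body_region)):
        regions = [region_fn(g, upstream_bp) if kind == "promoter" else region_fn(g)
                   for g in annotation]
        data = np.full((len(regions), len(samples)), np.nan)
        for j, sample in enumerate(samples):
            cov = coverage_per_sample[sample]
            for i, region in enumerate(regions):
                data[i, j] = region_methylation_level(cov, region)
        frame = pd.DataFrame(data, index=[r.gene_id for r in regions],
                             columns=samples)
        frame.index.name = "gene_id"
        if drop_incomplete:
            complete = frame.notna().all(axis=1)
            n_drop = int((~complete).sum())
            if n_drop:
                logger.info("%s layer: dropped %d/%d genes with missing "
                            "coverage in >=1 sample", kind, n_drop, len(frame))
            frame = frame.loc[complete]
        out[kind] = OmicsMatrix(frame, layer=f"meth_{kind}")
    return out["promoter"], out["body"]
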