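"""Fold-change construction and correlation-based gene screening.

Fold change of gene i in spaceflight sample s against the ground-control
mean:

    level mode:   FC = g_sf / mean(g_gc)            (GC-mean-zero genes dropped)
    degree mode:  FC = (d_sf + 1) / (mean(d_gc) + 1)  (always finite, > 0)

A gene is LET-related when its FC vector correlates with the LET vector of
the SF samples: |PCC| > 0.5 and p < 0.05 for levels, p < 0.05 alone for
degrees.  p-values come from the two-sided t test with n - 2 degrees of
freedom; a Benjamini-Hochberg column is reported for information but plays
no part in the hit rule.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import FCMatrix, OmicsMatrix, PPINetwork, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_PCC_THRESHOLD = 0.5
DEFAULT_ALPHA = 0.05


def fold_change(matrix: OmicsMatrix | pd.DataFrame, metadata: SampleMetadata,
                mode: str) -> FCMatrix:
    """Per-gene fold changes of every SF sample against the GC mean."""
    if isinstance(matrix, OmicsMatrix):
        frame, layer = matrix.frame, matrix.layer
    else:
        frame, layer = matrix, "expression"
    gc = [s for s in metadata.gc_ids if s in frame.columns]
    sf = [s for s in metadata.sf_ids if s in frame.columns]
    if not gc:
        raise ValueError("no ground-control samples present in the matrix")
    if not sf:
        raise ValueError("no spaceflight samples present in the matrix")
    gc_vals = frame[gc].to_numpy(float)
    sf_vals = frame[sf].to_numpy(float)
    if mode == "level":
        gc_mean = gc_vals.mean(axis=1)
        keep = gc_mean > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("level FC: dropped %d/%d genes with GC mean 0",
                        n_drop, len(frame))
        fc = sf_vals[keep] / gc_mean[keep, None]
        out = pd.DataFrame(fc, index=frame.index[keep], columns=sf)
    elif mode == "degree":
        gc_mean = (gc_vals + 1).mean(axis=1)
        fc = (sf_vals + 1) / gc_mean[:, None]
        out = pd.DataFrame(fc, index=frame.index, columns=sf)
    else:
        raise ValueError(f"unknown FC mode {mode!r}")
    out.index.name = "gene_id"
    return FCMatrix(out, mode=mode, layer=layer)


def _rowwise_pearson(values: np.ndarray, y: np.ndarray):
    """Pearson r of each row against y, with the two-sided t-test p-value
    (n - 2 df).  Zero-variance rows yield (NaN, NaN)."""
    n = values.shape[1]
    if n != len(y):
        raise ValueError(f"row length {n} != target length {len(y)}")
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("target vector has zero variance")
    vc = values - values.mean(axis=1, keepdims=True)
    sv = np.sqrt((vc ** 2).sum(axis=1))
    zero = sv == 0
    safe = np.where(zero, 1.0, sv)
    r = (vc @ yc) / (safe * sy)
    np.clip(r, -1.0, 1.0, out=r)
    r[zero] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p[zero] = np.nan
    return r, p


def let_screen(fc: FCMatrix, metadata: SampleMetadata, mode: str | None = None,
               pcc_threshold: float = DEFAULT_PCC_THRESHOLD,
               alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Screen genes whose FC vector tracks LET across the SF samples.

    Returns a per-gene table (pcc, p_value, bh_fdr, is_hit).  ``mode``
    defaults to the FC matrix's own mode; in level mode a hit needs
    |PCC| > pcc_threshold and p < alpha, in degree mode p < alpha alone.
    Genes with a constant FC vector get NaN statistics and is_hit False.
    """
    mode = mode or fc.mode
    if mode not in ("level", "degree"):
        raise ValueError(f"unknown screen mode {mode!r}")
    sf = fc.sample_ids
    if len(sf) < 4:
        raise ValueError(f"need >= 4 SF samples to screen, got {len(sf)}")
    let = metadata.let(sf)
    r, p = _rowwise_pearson(fc.frame.to_numpy(float), let)
    n_const = int(np.isnan(r).sum())
    if n_const:
        logger.info("let_screen: %d gene(s) with constant FC vector", n_const)
    bh = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        bh[valid] = stats.false_discovery_control(p[valid], method="bh")
    if mode == "level":
        is_hit = valid & (np.abs(np.nan_to_num(r)) > pcc_threshold) & \
            (np.nan_to_num(p, nan=1.0) < alpha)
    else:
        is_hit = valid & (np.nan_to_num(p, nan=1.0) < alpha)
    rule = (f"|PCC|>{pcc_threshold} and p<{alpha}" if mode == "level"
            else f"p<{alpha}")
    out = pd.DataFrame({
        "pcc": r, "p_value": p, "bh_fdr": bh, "is_hit": is_hit,
        "mode": mode, "layer": fc.layer, "rule": rule,
    }, index=fc.frame.index)
    out.index.name = "gene_id"
    return out


def methylation_correlation(primary: OmicsMatrix | pd.DataFrame,
                            methyl: OmicsMatrix | pd.DataFrame,
                            gene_set: list[str],
                            alpha: float = DEFAULT_ALPHA,
                            samples: list[str] | None = None) -> pd.DataFrame:
    """Per-gene Pearson correlation between a primary signal (expression
    level or SSN degree) and the matched methylation signal (level or
    methylation degree) over the samples the two matrices share.

    Genes absent from either matrix are excluded (logged); a hit is p < alpha.
    """
    pf = primary.frame if isinstance(primary, OmicsMatrix) else primary
    mf = methyl.frame if isinstance(methyl, OmicsMatrix) else methyl
    shared = [s for s in pf.columns if s in set(mf.columns)]
    if samples is not None:
        shared = [s for s in shared if s in set(samples)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    genes = [g for g in gene_set if g in pf.index and g in mf.index]
    skipped = len(gene_set) - len(genes)
    if skipped:
        logger.info("methylation_correlation: %d gene(s) absent from one "
                    "matrix, excluded", skipped)
    if not genes:
        out = pd.DataFrame(columns=["pcc", "p_value", "is_hit"])
        out.index.name = "gene_id"
        return out
    pv = pf.loc[genes, shared].to_numpy(float)
    mv = mf.loc[genes, shared].to_numpy(float)
    # correlate row i of primary with row i of methylation
    n = len(shared)
    pc = pv - pv.mean(axis=1, keepdims=True)
    mc = mv - mv.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc ** 2).sum(axis=1) * (mc ** 2).sum(axis=1))
    zero = denom == 0
    r = np.where(zero, np.nan, (pc * mc).sum(axis=1) / np.where(zero, 1, denom))
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p[zero] = np.nan
    out = pd.DataFrame({
        "pcc": r, "p_value": p,
        "is_hit": ~np.isnan(p) & (np.nan_to_num(p, nan=1.0) < alpha),
    }, index=pd.Index(genes, name="gene_id"))
    return out


def hub_genes(gene_set: list[str], ppi: PPINetwork,
              top_k: int = 5) -> pd.DataFrame:
    """Rank genes by degree in the PPI subgraph induced on ``gene_set``.

    Returns the top_k genes plus every gene tied with the k-th degree, sorted
    by degree descending then gene id.  Isolated genes (degree 0) are not
    reported.
    """
    if top_k < 1:
        raise ValueError("top_k must be positive")
    if not gene_set:
        raise ValueError("empty gene set")
    sub = ppi.subgraph([g for g in gene_set if g in ppi])
    ranked = sorted(((g, d) for g, d in sub.degree() if d > 0),
                    key=lambda gd: (-gd[1], gd[0]))
    if not ranked:
        logger.warning("hub_genes: induced PPI subgraph has no edges")
        out = pd.DataFrame(columns=["degree"])
        out.index.name = "gene_id"
        return out
    if len(ranked) > top_k:
        cutoff = ranked[top_k - 1][1]
        ranked = [gd for gd in ranked if gd[1] >= cutoff]
    out = pd.DataFrame(ranked, columns=["gene_id", "degree"]).set_index("gene_id")
    return out
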