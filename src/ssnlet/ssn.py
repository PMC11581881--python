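"""LIONESS single-sample networks, PPI overlap, and degree matrices.

The aggregate network over N samples is the all-pairs Pearson correlation
matrix.  LIONESS attributes an edge-weight matrix to each sample q by linear
interpolation between the aggregate network with and without that sample:

    w_q(i, j) = N * r_all(i, j) - (N - 1) * r_without_q(i, j)

A pair involving a gene with zero variance on the relevant sample set gets
r = 0 by convention (logged), so the construction is total.  Weighted
networks become binary gene-interaction networks by intersecting with the
PPI network and keeping edges with |w| >= tau; a gene's degree in the i-th
binary network is its neighbour count there (0 if absent), and stacking those
degrees over the n networks of a layer yields the degree matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import OmicsMatrix, PPINetwork

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.5


@dataclass
class AggregateNetwork:
    """All-pairs Pearson correlations of genes over a sample set."""

    gene_ids: list[str]
    r: np.ndarray  # symmetric, [-1, 1]; rows/cols of zero-variance genes are 0


@dataclass
class WeightedSSN:
    """LIONESS edge weights attributed to one sample (unbounded reals)."""

    sample_id: str
    gene_ids: list[str]
    weights: np.ndarray  # symmetric, zero diagonal


def _pearson(values: np.ndarray) -> np.ndarray:
    """Correlation matrix of rows; zero-variance rows give r = 0 (their
    diagonal too, harmless since self-edges never exist)."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        logger.debug("%d zero-variance gene(s); their correlations set to 0",
                     int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    r = (centered @ centered.T) / np.outer(safe, safe)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, np.where(zero, 0.0, 1.0))
    return r


def pearson_matrix(matrix: OmicsMatrix | pd.DataFrame,
                   sample_subset: list[str] | None = None) -> AggregateNetwork:
    """Aggregate co-expression network over a sample subset (>= 3 samples)."""
    frame = matrix.frame if isinstance(matrix, OmicsMatrix) else matrix
    if sample_subset is not None:
        frame = frame[list(sample_subset)]
    if frame.shape[1] < 3:
        raise ValueError(f"need >= 3 samples for a correlation network, "
                         f"got {frame.shape[1]}")
    return AggregateNetwork(frame.index.tolist(), _pearson(frame.to_numpy(float)))


def lioness_weights(matrix: OmicsMatrix | pd.DataFrame, sample_q: str) -> WeightedSSN:
    """LIONESS edge weights for one sample (requires N >= 4 so the
    leave-one-out correlation is defined on >= 3 samples)."""
    frame = matrix.frame if isinstance(matrix, OmicsMatrix) else matrix
    n = frame.shape[1]
    if n < 4:
        raise ValueError(f"LIONESS needs >= 4 samples, got {n}")
    if sample_q not in frame.columns:
        raise KeyError(f"unknown sample {sample_q!r}")
    r_all = _pearson(frame.to_numpy(float))
    r_minus = _pearson(frame.drop(columns=[sample_q]).to_numpy(float))
    w = n * r_all - (n - 1) * r_minus
    np.fill_diagonal(w, 0.0)
    return WeightedSSN(sample_q, frame.index.tolist(), w)


def build_ssns(matrix: OmicsMatrix | pd.DataFrame) -> list[WeightedSSN]:
    """LIONESS networks for every sample, computing the aggregate
    correlation once."""
    frame = matrix.frame if isinstance(matrix, OmicsMatrix) else matrix
    n = frame.shape[1]
    if n < 4:
        raise ValueError(f"LIONESS needs >= 4 samples, got {n}")
    values = frame.to_numpy(float)
    r_all = _pearson(values)
    genes = frame.index.tolist()
    ssns = []
    for q, sample in enumerate(frame.columns):
        r_minus = _pearson(np.delete(values, q, axis=1))
        w = n * r_all - (n - 1) * r_minus
        np.fill_diagonal(w, 0.0)
        ssns.append(WeightedSSN(str(sample), genes, w))
    return ssns


def overlap_with_ppi(ssn: WeightedSSN, ppi: PPINetwork,
                     tau: float = DEFAULT_TAU) -> nx.Graph:
    """Intersect a weighted network with the PPI network.

    An edge survives iff it is a PPI edge between genes present in the SSN
    and its LIONESS weight satisfies |w| >= tau; genes left without any edge
    are removed, so the result's node set is exactly its non-isolated genes.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    index = {g: i for i, g in enumerate(ssn.gene_ids)}
    out = nx.Graph(sample_id=ssn.sample_id)
    for a, b in ppi.edges():
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        if abs(ssn.weights[ia, ib]) >= tau:
            out.add_edge(a, b)
    if out.number_of_edges() == 0:
        logger.warning("sample %s: empty SSN after PPI overlap", ssn.sample_id)
    return out


def degree_matrix(ssns: list[nx.Graph]) -> pd.DataFrame:
    """Stack per-network degrees into a genes x networks integer matrix.

    Rows cover the union of genes appearing in any network; a gene absent
    from a network contributes degree 0 in that column.  Genes in no network
    at all do not get a row.
    """
    if not ssns:
        raise ValueError("need at least one SSN")
    genes = sorted(set().union(*(g.nodes for g in ssns)))
    if not genes:
        logger.warning("all SSNs empty; degree matrix has no rows")
    columns = [g.graph.get("sample_id", str(i)) for i, g in enumerate(ssns)]
    data = np.zeros((len(genes), len(ssns)), dtype=np.int64)
    for j, g in enumerate(ssns):
        degs = dict(g.degree())
        for i, gene in enumerate(genes):
            data[i, j] = degs.get(gene, 0)
    frame = pd.DataFrame(data, index=genes, columns=columns)
    frame.index.name = "gene_id"
    return frame
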