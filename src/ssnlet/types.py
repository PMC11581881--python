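"""Core domain containers shared by every pipeline stage.

All gene-by-sample matrices are oriented genes in rows, samples in columns;
readers are responsible for transposing foreign layouts.  Genomic coordinates
are 1-based inclusive throughout the package (the convention of both GFF3 and
Bismark coverage files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_GC = "GC"
GROUP_SF = "SF"
STAGES = ("tillering", "heading")
LAYERS = ("expression", "meth_promoter", "meth_body")

#: A protein-protein interaction network is an undirected simple graph whose
#: nodes are gene ids; edge attribute ``score`` holds the confidence channel
#: value when the input file provides one.
PPINetwork = nx.Graph


class SampleMetadata:
    """Sample sheet: ids, ground-control (GC) vs spaceflight (SF) group,
    per-SF linear energy transfer in keV/um, and developmental stage.

    A flown-but-unhit plant legitimately carries LET = 0, so a missing LET is
    encoded as NaN (GC rows only), never as zero.
    """

    REQUIRED_COLUMNS = ("sample_id", "group", "let_value", "stage")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in self.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        frame["let_value"] = pd.to_numeric(frame["let_value"], errors="raise")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad_group = set(frame["group"]) - {GROUP_GC, GROUP_SF}
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_stage = set(frame["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stage labels: {sorted(bad_stage)}")
        sf = frame["group"] == GROUP_SF
        if frame.loc[sf, "let_value"].isna().any():
            bad = frame.loc[sf & frame["let_value"].isna(), "sample_id"].tolist()
            raise ValueError(f"SF samples without a LET value: {bad}")
        if (frame.loc[sf, "let_value"] < 0).any():
            raise ValueError("negative LET value")
        if frame.loc[~sf, "let_value"].notna().any():
            bad = frame.loc[~sf & frame["let_value"].notna(), "sample_id"].tolist()
            raise ValueError(f"GC samples must not carry a LET value: {bad}")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def gc_ids(self) -> list[str]:
        f = self.frame
        return f.loc[f["group"] == GROUP_GC, "sample_id"].tolist()

    @property
    def sf_ids(self) -> list[str]:
        f = self.frame
        return f.loc[f["group"] == GROUP_SF, "sample_id"].tolist()

    def let(self, sample_ids: list[str]) -> np.ndarray:
        """LET values (keV/um) aligned to ``sample_ids``; raises on GC ids."""
        s = self.frame.set_index("sample_id")["let_value"]
        missing = [i for i in sample_ids if i not in s.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        vals = s.loc[list(sample_ids)].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("requested LET for samples without a LET value")
        return vals

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self.frame.equals(other.frame)


@dataclass
class OmicsMatrix:
    """Gene-by-sample measurement matrix.

    ``layer`` distinguishes FPKM expression (nonnegative) from promoter/body
    methylation levels (bounded in [0, 1]; NaN marks a region with no covered
    cytosines in that sample).
    """

    frame: pd.DataFrame
    layer: str

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.frame.to_numpy(dtype=float)
        if self.layer == "expression":
            if np.isnan(vals).any():
                raise ValueError("expression matrix contains missing values")
            if (vals < 0).any():
                raise ValueError("negative expression values")
        else:
            with np.errstate(invalid="ignore"):
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError("methylation levels outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


class GeneAnnotation:
    """Per-gene genomic spans: chrom, strand, 1-based inclusive start/end."""

    COLUMNS = ("chrom", "strand", "start", "end")

    def __init__(self, frame: pd.DataFrame):
        # expected index: gene_id; columns per COLUMNS
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dup}")
        if not set(frame["strand"]) <= {"+", "-"}:
            bad = sorted(set(frame["strand"]) - {"+", "-"})
            raise ValueError(f"undefined strand value(s): {bad}")
        if (frame["start"] > frame["end"]).any():
            raise ValueError("gene with start > end")
        if (frame["start"] < 1).any():
            raise ValueError("coordinates are 1-based; start < 1")
        self.frame = frame.copy()

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.frame.itertuples())


@dataclass
class FCMatrix:
    """Fold changes of SF samples against the ground-control mean.

    ``mode='level'`` is the plain ratio on expression/methylation levels (genes
    whose GC mean is zero are dropped before construction); ``mode='degree'``
    adds one to every degree before forming the ratio so the value is always
    finite and strictly positive.
    """

    frame: pd.DataFrame
    mode: str
    layer: str

    def __post_init__(self):
        if self.mode not in ("level", "degree"):
            raise ValueError(f"unknown FC mode {self.mode!r}")
        vals = self.frame.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite fold change")
        if self.mode == "degree" and (vals <= 0).any():
            raise ValueError("degree-mode fold changes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.columns.tolist()
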