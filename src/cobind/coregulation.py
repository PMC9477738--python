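"""DEG filtering, gene-set overlap, direction consistency and the cooperative set.

The endpoint of the pipeline is a stringent list of cooperatively regulated
genes: genes differentially expressed in both mutants, bound by both
transcription factors, and bound less strongly when the partner factor is
absent.  Everything here is set algebra plus two small tests — a
hypergeometric upper tail for overlap significance and a direction-agreement
partition for shared DEGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DEGTable

__all__ = [
    "DEGFilterConfig",
    "OverlapTest",
    "DirectionConsistency",
    "CooperativeSet",
    "filter_degs",
    "overlap_test",
    "direction_consistency",
    "cooperative_genes",
    "zscore_rows",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGFilterConfig:
    """|fold change| >= threshold (inclusive) and padj < threshold (strict)."""

    fold_change_threshold: float = 1.5
    padj_threshold: float = 0.05

    def __post_init__(self):
        if self.fold_change_threshold <= 0 or self.padj_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def filter_degs(
    table: DEGTable, config: DEGFilterConfig | None = None
) -> dict[str, int]:
    """Genes passing the DEG filter, mapped to direction (+1 up, -1 down).

    A gene is retained iff |log2fc| >= log2(fold_change_threshold) AND
    padj < padj_threshold.  The fold-change boundary is inclusive, the padj
    boundary strict.
    """
    cfg = config or DEGFilterConfig()
    df = table.records
    lfc_cut = np.log2(cfg.fold_change_threshold)
    keep = (df["log2fc"].abs() >= lfc_cut) & (df["padj"] < cfg.padj_threshold)
    sub = df.loc[keep]
    return {
        str(g): (1 if fc > 0 else -1)
        for g, fc in zip(sub["gene_id"], sub["log2fc"])
    }


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric upper-tail test of the overlap of two gene sets."""

    n_universe: int
    n_setA: int
    n_setB: int
    n_overlap: int
    p: float


def overlap_test(
    setA: set[str], setB: set[str], universe: set[str]
) -> OverlapTest:
    """P(X >= |A ∩ B|) drawing |A| genes from a universe with |B| successes."""
    if not setA <= universe or not setB <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    a, b = len(setA), len(setB)
    k = len(setA & setB)
    p = float(stats.hypergeom.sf(k - 1, n, b, a))
    return OverlapTest(n_universe=n, n_setA=a, n_setB=b, n_overlap=k, p=min(p, 1.0))


@dataclass(frozen=True)
class DirectionConsistency:
    n_same_up: int
    n_same_down: int
    n_opposite: int
    fraction_opposite: float | None  # None when the intersection is empty


def direction_consistency(
    degA: Mapping[str, int], degB: Mapping[str, int]
) -> DirectionConsistency:
    """Partition shared DEGs by direction agreement between two genotypes."""
    shared = set(degA) & set(degB)
    same_up = sum(1 for g in shared if degA[g] > 0 and degB[g] > 0)
    same_down = sum(1 for g in shared if degA[g] < 0 and degB[g] < 0)
    opposite = len(shared) - same_up - same_down
    frac = opposite / len(shared) if shared else None
    return DirectionConsistency(same_up, same_down, opposite, frac)


@dataclass
class CooperativeSet:
    """Genes passing all four evidence layers, with per-gene provenance."""

    tissue: str
    gene_ids: list[str]
    provenance: dict[str, list[str]]


_LAYERS = ("shared_deg", "bound_by_A", "bound_by_B", "reduced_binding")


def cooperative_genes(
    shared_degs: set[str],
    bound_by_A: set[str],
    bound_by_B: set[str],
    reduced_binding_genes: set[str],
    tissue: str = "",
) -> CooperativeSet:
    """Exact four-way intersection of the evidence layers.

    ``reduced_binding_genes`` should come from differential-binding peaks with
    significant negative log2fc, mapped through peak-gene links.
    """
    members = shared_degs & bound_by_A & bound_by_B & reduced_binding_genes
    provenance = {g: list(_LAYERS) for g in sorted(members)}
    return CooperativeSet(
        tissue=tissue, gene_ids=sorted(members), provenance=provenance
    )


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z scores (population SD); constant rows become all zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns per row")
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population SD
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("%d constant rows z-scored to zeros", int(constant.sum()))
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
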