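"""Topography layers on the fixed SOM grid.

A topography assigns one value to every node of a trained map: the mean
normalized transcription of the node's genes under one substrate, the
global mean over all conditions, a boolean high-transcription mask, or
the count of secreted proteins whose genes sit in the node.  Because the
node positions are fixed, all layers over one model are directly
comparable by eye and by rank statistics.

Node means pool genes × replicate samples; a node with no genes carries
a missing value (NaN) rather than zero so that empty nodes do not drag
down map statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SecretomeTable
from .normalization import NormalizedMatrix
from .som import SomModel

__all__ = [
    "Topography",
    "condition_mean_topography",
    "global_mean_topography",
    "high_transcription_mask",
    "threshold_percentile",
    "secretion_topography",
    "unmapped_proteins",
]

LAYER_KINDS = ("condition_mean", "global_mean", "secretion_count", "high_mask")


@dataclass
class Topography:
    """One value per node on a fixed hexagonal grid."""

    values: np.ndarray  # (n_nodes,), float (NaN = missing) or bool for masks
    layer_kind: str
    grid_shape: tuple[int, int]
    condition: str | None = None
    grid_ref: str | None = None

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise ValueError(
                f"unknown layer_kind {self.layer_kind!r}; expected one of "
                f"{LAYER_KINDS}"
            )
        self.values = np.asarray(self.values)
        n = self.grid_shape[0] * self.grid_shape[1]
        if self.values.shape != (n,):
            raise ValueError(
                f"expected {n} node values for grid {self.grid_shape}, "
                f"got {self.values.shape}"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def node_value(self, node_id: int) -> float | bool:
        return self.values[node_id - 1]


def _node_means(model: SomModel, values: np.ndarray) -> np.ndarray:
    """Mean of ``values`` (genes × columns) pooled per node; NaN if empty."""
    n = model.map_units
    sums = np.zeros(n)
    counts = np.zeros(n)
    idx = model.assignment - 1
    np.add.at(sums, idx, values.sum(axis=1))
    np.add.at(counts, idx, values.shape[1])
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def condition_mean_topography(
    model: SomModel, nm: NormalizedMatrix, substrate: str
) -> Topography:
    """Node-wise mean of normalized log2 values over the biological
    replicates of one substrate."""
    cols = nm.substrate_columns(substrate)  # raises on unknown substrate
    return Topography(
        values=_node_means(model, nm.values[:, cols]),
        layer_kind="condition_mean",
        grid_shape=model.grid_shape,
        condition=substrate,
    )


def global_mean_topography(model: SomModel, nm: NormalizedMatrix) -> Topography:
    """Node-wise mean over all genes in the node and all samples."""
    return Topography(
        values=_node_means(model, nm.values),
        layer_kind="global_mean",
        grid_shape=model.grid_shape,
    )


def high_transcription_mask(topo: Topography, threshold: float = 12.0) -> Topography:
    """Boolean layer: node condition mean strictly above ``threshold``.

    The threshold is strict; a node mean exactly at the threshold is not
    "high".  Empty nodes (missing mean) are False.
    """
    if topo.layer_kind == "high_mask":
        raise ValueError("cannot threshold a mask layer again")
    if topo.layer_kind not in ("condition_mean", "global_mean"):
        raise ValueError(f"cannot threshold a {topo.layer_kind!r} layer")
    with np.errstate(invalid="ignore"):
        mask = np.asarray(topo.values, dtype=float) > threshold
    return Topography(
        values=mask,
        layer_kind="high_mask",
        grid_shape=topo.grid_shape,
        condition=topo.condition,
        grid_ref=topo.grid_ref,
    )


def threshold_percentile(nm: NormalizedMatrix, threshold: float = 12.0) -> float:
    """Percentile of gene-level global means at or below ``threshold``.

    Diagnostic for where the high-transcription cutoff sits in the gene
    population (the reference analysis placed it near the 75th
    percentile).
    """
    gene_means = nm.values.mean(axis=1)
    return float(100.0 * np.mean(gene_means <= threshold))


def secretion_topography(
    model: SomModel, st: SecretomeTable, mode: str = "distinct"
) -> Topography:
    """Secreted-protein counts per node.

    ``distinct`` counts each protein once if detected in at least one
    condition; ``summed`` counts every (protein, condition) detection
    event.  Proteins whose gene is not in the trained model are skipped
    with a warning (use :func:`unmapped_proteins` to list them).
    """
    if mode not in ("distinct", "summed"):
        raise ValueError(f"mode must be 'distinct' or 'summed', got {mode!r}")
    gene_to_node = dict(zip(model.gene_ids, model.assignment))
    counts = np.zeros(model.map_units)
    unmapped: set[str] = set()
    seen: set[str] = set()
    for rec in st.detected_records():
        node = gene_to_node.get(rec.gene_id)
        if node is None:
            unmapped.add(rec.protein_id)
            continue
        if mode == "summed":
            counts[node - 1] += 1
        elif rec.protein_id not in seen:
            seen.add(rec.protein_id)
            counts[node - 1] += 1
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} secreted protein(s) map to genes absent from "
            f"the model and were not counted"
        )
    return Topography(
        values=counts,
        layer_kind="secretion_count",
        grid_shape=model.grid_shape,
    )


def unmapped_proteins(model: SomModel, st: SecretomeTable) -> list[str]:
    """Protein IDs whose gene is not among the model's genes."""
    known = set(model.gene_ids)
    out: list[str] = []
    for rec in st.records:
        if rec.gene_id not in known and rec.protein_id not in out:
            out.append(rec.protein_id)
    return out
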