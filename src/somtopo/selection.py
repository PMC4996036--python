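"""Node- and gene-selection rules.

Two complementary mining strategies operate on the topography layers:

* transcription-oriented: nodes highly transcribed (strictly above the
  log2 threshold) on a complex biomass substrate but on none of the
  simple-carbon controls, with the member genes then filtered by
  differential-expression statistics against the reference substrate;
* secretion-oriented: the nodes holding the top-k highest secreted
  protein counts, with ties at the kth rank included (so "top three" can
  legitimately return four nodes when two tie).

All inequalities are strict: mean > threshold, |log2FC| side > 1 means
log2FC > 1, adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationTable, DETable, SecretomeTable
from .som import SomModel
from .topography import Topography

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "substrate_specific_nodes",
    "common_nodes",
    "de_filter",
    "top_secretion_nodes",
    "summarize_selection",
    "select_substrate_genes",
]


@dataclass
class SelectionConfig:
    high_threshold: float = 12.0  # log2 units
    lfc_threshold: float = 1.0  # log2 fold change
    padj_threshold: float = 0.05
    reference_substrate: str = "maltose"
    control_substrates: frozenset[str] = frozenset({"maltose", "avicel"})
    top_k_secretion: int = 3

    def __post_init__(self) -> None:
        for name in ("high_threshold", "lfc_threshold", "padj_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        self.control_substrates = frozenset(self.control_substrates)
        if self.top_k_secretion < 1:
            raise ValueError("top_k_secretion must be >= 1")


@dataclass
class SelectionResult:
    """Selected nodes and filtered gene lists, per substrate."""

    nodes: dict[str, set[int]] = field(default_factory=dict)
    common: set[int] = field(default_factory=set)
    genes: dict[str, pd.DataFrame] = field(default_factory=dict)
    secretion_hotspots: list[int] = field(default_factory=list)
    config: SelectionConfig = field(default_factory=SelectionConfig)


def substrate_specific_nodes(
    masks: dict[str, Topography],
    substrate: str,
    config: SelectionConfig | None = None,
) -> set[int]:
    """Nodes high on ``substrate`` and high on no control substrate."""
    config = config or SelectionConfig()
    if substrate in config.control_substrates:
        raise ValueError(
            f"{substrate!r} is a control substrate; substrate-specific "
            f"selection is defined only for test substrates"
        )
    if substrate not in masks:
        raise KeyError(f"no high-transcription mask for {substrate!r}")
    missing = config.control_substrates - set(masks)
    if missing:
        raise KeyError(f"missing control masks: {sorted(missing)}")
    keep = np.asarray(masks[substrate].values, dtype=bool).copy()
    for ctrl in config.control_substrates:
        keep &= ~np.asarray(masks[ctrl].values, dtype=bool)
    return set((np.flatnonzero(keep) + 1).tolist())


def common_nodes(
    masks: dict[str, Topography],
    substrates: list[str],
    config: SelectionConfig | None = None,
) -> set[int]:
    """Intersection of the substrate-specific node sets across
    ``substrates`` (nodes selected for every one of them)."""
    if len(substrates) < 2:
        raise ValueError("need at least two substrates to intersect")
    sets = [substrate_specific_nodes(masks, s, config) for s in substrates]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def de_filter(
    nodes: set[int],
    model: SomModel,
    de: DETable,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Genes of the selected nodes passing the DE thresholds.

    Returns a DataFrame (gene_id, node_id, log2fc, pvalue, padj) sorted
    by node then gene.  Genes without a DE entry are dropped with a
    warning count.
    """
    config = config or SelectionConfig()
    rows = []
    n_missing = 0
    for gene, node in zip(model.gene_ids, model.assignment):
        if int(node) not in nodes:
            continue
        if gene not in de:
            n_missing += 1
            continue
        rec = de.frame.loc[gene]
        rows.append(
            {
                "gene_id": gene,
                "node_id": int(node),
                "log2fc": float(rec["log2fc"]),
                "pvalue": float(rec["pvalue"]),
                "padj": float(rec["padj"]),
            }
        )
    if n_missing:
        warnings.warn(f"{n_missing} gene(s) in selected nodes had no DE entry")
    df = pd.DataFrame(rows, columns=["gene_id", "node_id", "log2fc", "pvalue", "padj"])
    keep = (df["log2fc"] > config.lfc_threshold) & (df["padj"] < config.padj_threshold)
    return df[keep].sort_values(["node_id", "gene_id"]).reset_index(drop=True)


def top_secretion_nodes(secretion: Topography, k: int = 3) -> list[int]:
    """The k nodes with the highest secreted-protein counts, ties at the
    kth rank included; ranked by count descending, then node ID."""
    if secretion.layer_kind != "secretion_count":
        raise ValueError("top_secretion_nodes needs a secretion_count layer")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.asarray(secretion.values, dtype=float)
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
    if k >= len(counts):
        return [i + 1 for i in order]
    cutoff = counts[order[k - 1]]
    selected = [i + 1 for i in order if counts[i] >= cutoff]
    if np.all(counts == counts[0]):
        warnings.warn("all nodes tied on secretion count; returning the full grid")
    return selected


def select_substrate_genes(
    masks: dict[str, Topography],
    model: SomModel,
    de_tables: dict[str, DETable],
    substrates: list[str],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the full transcription-oriented selection for each test substrate."""
    config = config or SelectionConfig()
    result = SelectionResult(config=config)
    for s in substrates:
        nodes = substrate_specific_nodes(masks, s, config)
        result.nodes[s] = nodes
        if s in de_tables:
            result.genes[s] = de_filter(nodes, model, de_tables[s], config)
    if len(substrates) >= 2:
        result.common = common_nodes(masks, substrates, config)
    return result


def summarize_selection(
    result: SelectionResult,
    annotations: AnnotationTable | None = None,
    secretome: SecretomeTable | None = None,
) -> pd.DataFrame:
    """Per-substrate summary: nodes, genes, detected/predicted secreted
    (with percentage), CAZyme-annotated count, and unannotated predicted
    secreted ("unknown") count."""
    annotations = annotations or AnnotationTable()
    detected_genes: set[str] = set()
    if secretome is not None:
        detected_genes = {r.gene_id for r in secretome.detected_records()}
    rows = []
    for substrate in sorted(result.nodes):
        genes_df = result.genes.get(substrate)
        gene_ids = [] if genes_df is None else genes_df["gene_id"].tolist()
        predicted = [g for g in gene_ids if g in annotations.predicted_secreted]
        detected = [g for g in predicted if g in detected_genes]
        annotated = [g for g in gene_ids if annotations.label(g)]
        unknown = [
            g for g in predicted if not annotations.label(g)
        ]
        pct = round(100 * len(detected) / len(predicted)) if predicted else 0
        rows.append(
            {
                "substrate": substrate,
                "nodes": len(result.nodes[substrate]),
                "genes": len(gene_ids),
                "secreted_detected": len(detected),
                "secreted_predicted": len(predicted),
                "secreted": f"{len(detected)}/{len(predicted)} ({pct}%)",
                "cazymes": len(annotated),
                "unknown": len(unknown),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "substrate", "nodes", "genes", "secreted_detected",
            "secreted_predicted", "secreted", "cazymes", "unknown",
        ],
    )
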