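"""Tabular input/output and the shared domain types.

The workflow consumes four kinds of tables:

* a raw gene × sample read-count matrix (TSV, genes in rows),
* a sample sheet assigning each sequencing library to a carbon-source
  substrate and replicate number (CSV),
* a secretome table listing which proteins were detected in the culture
  medium under which growth condition (TSV), and
* optional gene annotations (CAZy family labels, predicted-secretion flags)
  and an optional externally computed differential-expression table.

All outputs written here are plain TSV with headers so that round trips
are lossless and diff-able.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "ExpressionMatrix",
    "SecretomeRecord",
    "SecretomeTable",
    "AnnotationTable",
    "DETable",
    "read_counts",
    "read_secretome",
    "read_annotations",
    "read_de_table",
    "write_de_table",
    "write_topography",
    "read_topography",
]


@dataclass(frozen=True)
class SampleInfo:
    """One sequencing library: which substrate, which replicate."""

    sample_id: str
    substrate: str
    replicate: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(
                f"replicate must be a positive integer, got {self.replicate} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class ExpressionMatrix:
    """Raw read counts for all genes across all libraries.

    Counts are whole numbers as produced by an upstream read-counting
    step; missing values are rejected rather than imputed.
    """

    gene_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples), non-negative integers
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicated gene ID: {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicated sample ID: {_first_duplicate(ids)!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.all(np.isfinite(self.counts)) or np.any(
                np.abs(self.counts - rounded) > 1e-9
            ):
                raise ValueError("counts must be finite integers")
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            g, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.samples[j].sample_id!r}"
            )
        # replicate numbers must be unique within a substrate
        seen: set[tuple[str, int]] = set()
        for s in self.samples:
            key = (s.substrate, s.replicate)
            if key in seen:
                raise ValueError(
                    f"duplicate replicate {s.replicate} for substrate {s.substrate!r}"
                )
            seen.add(key)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def substrates(self) -> list[str]:
        """Substrates in first-appearance order."""
        out: list[str] = []
        for s in self.samples:
            if s.substrate not in out:
                out.append(s.substrate)
        return out

    def substrate_columns(self, substrate: str) -> np.ndarray:
        """Column indices of the replicates grown on ``substrate``."""
        idx = [j for j, s in enumerate(self.samples) if s.substrate == substrate]
        if not idx:
            raise KeyError(f"unknown substrate {substrate!r}; have {self.substrates}")
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class SecretomeRecord:
    protein_id: str
    gene_id: str
    condition: str
    detected: bool = True
    unmapped: bool = False


@dataclass
class SecretomeTable:
    """Protein detections from the culture medium, keyed by condition.

    Detection is boolean per (protein, condition): the overlay counts
    proteins, not abundances.
    """

    records: list[SecretomeRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        pairs = [(r.protein_id, r.condition) for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError(
                f"duplicate (protein, condition) pair: {_first_duplicate(pairs)!r}"
            )

    @property
    def proteins(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.protein_id not in out:
                out.append(r.protein_id)
        return out

    def detected_records(self) -> list[SecretomeRecord]:
        return [r for r in self.records if r.detected]

    def flag_unmapped(self, known_genes: set[str]) -> "SecretomeTable":
        """Return a copy with records re-flagged against ``known_genes``."""
        recs = [
            SecretomeRecord(
                r.protein_id, r.gene_id, r.condition, r.detected,
                unmapped=r.gene_id not in known_genes,
            )
            for r in self.records
        ]
        return SecretomeTable(recs, provenance=self.provenance)


@dataclass
class AnnotationTable:
    """Gene → functional label (typically a CAZy family string) plus an
    optional predicted-secretion flag."""

    labels: dict[str, str] = field(default_factory=dict)
    predicted_secreted: set[str] = field(default_factory=set)

    def label(self, gene_id: str) -> str:
        return self.labels.get(gene_id, "")


@dataclass
class DETable:
    """Per-gene differential-expression statistics versus a reference
    substrate.  Backed by a DataFrame indexed by gene_id with columns
    ``log2fc``, ``pvalue``, ``padj``."""

    frame: pd.DataFrame
    substrate: str = ""
    reference: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        required = {"log2fc", "pvalue", "padj"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise ValueError("DE table has duplicated gene IDs")
        for col in ("pvalue", "padj"):
            v = self.frame[col].to_numpy(dtype=float)
            ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
            if not np.all(ok):
                raise ValueError(f"{col} outside [0, 1]")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index


def _first_duplicate(items) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, sample_sheet) -> ExpressionMatrix:
    """Read a gene × sample count TSV together with its sample sheet.

    The TSV has a header row of sample IDs and gene IDs in the first
    column.  The sample sheet (CSV: sample_id, substrate, replicate,
    is_control) fixes the column order of the returned matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated gene ID in {path}: {dup!r}")
    sheet = pd.read_csv(sample_sheet, dtype={"sample_id": str})
    required = {"sample_id", "substrate", "replicate", "is_control"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")

    samples = []
    for row in sheet.itertuples(index=False):
        if row.sample_id not in df.columns:
            raise ValueError(
                f"sample {row.sample_id!r} listed in the sample sheet is "
                f"absent from the count matrix"
            )
        samples.append(
            SampleInfo(
                sample_id=str(row.sample_id),
                substrate=str(row.substrate),
                replicate=int(row.replicate),
                is_control=_as_bool(row.is_control),
            )
        )
    extra = [c for c in df.columns if c not in set(sheet["sample_id"])]
    if extra:
        warnings.warn(f"count columns not in sample sheet ignored: {extra}")
    ordered = df[[s.sample_id for s in samples]]
    values = ordered.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~ordered.map(_is_number).to_numpy())
        g, j = bad[0]
        raise ValueError(
            f"non-numeric count for gene {ordered.index[g]!r}, "
            f"sample {ordered.columns[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in ordered.index], counts=values, samples=samples
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in {"true", "1", "yes", "t"}


def read_secretome(
    path,
    valid_conditions: list[str] | None = None,
    known_genes: set[str] | None = None,
) -> SecretomeTable:
    """Read a secretome detection TSV (protein_id, gene_id, condition).

    Duplicate (protein, condition) rows are collapsed with a warning.
    Unknown conditions fail loudly; proteins whose gene is absent from
    the expression matrix are kept but flagged unmapped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "gene_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"secretome table missing columns: {sorted(missing)}")
    if valid_conditions is not None:
        bad = sorted(set(df["condition"]) - set(valid_conditions))
        if bad:
            raise ValueError(
                f"unknown condition(s) {bad}; valid conditions: "
                f"{sorted(valid_conditions)}"
            )
    n_before = len(df)
    df = df.drop_duplicates(subset=["protein_id", "condition"])
    if len(df) < n_before:
        warnings.warn(
            f"collapsed {n_before - len(df)} duplicate (protein, condition) rows"
        )
    records = [
        SecretomeRecord(
            protein_id=r.protein_id,
            gene_id=r.gene_id,
            condition=r.condition,
            detected=True,
            unmapped=(known_genes is not None and r.gene_id not in known_genes),
        )
        for r in df.itertuples(index=False)
    ]
    return SecretomeTable(records, provenance=str(path))


def write_secretome(table: SecretomeTable, path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in table.records],
            "gene_id": [r.gene_id for r in table.records],
            "condition": [r.condition for r in table.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> AnnotationTable:
    """Read a gene annotation TSV: gene_id, label[, predicted_secreted]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "gene_id" not in df.columns or "label" not in df.columns:
        raise ValueError("annotation table needs columns gene_id, label")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicated gene ID in annotations: {dup!r}")
    labels = {r.gene_id: r.label for r in df.itertuples(index=False) if r.label}
    secreted: set[str] = set()
    if "predicted_secreted" in df.columns:
        secreted = {
            r.gene_id
            for r in df.itertuples(index=False)
            if _as_bool(r.predicted_secreted)
        }
    return AnnotationTable(labels=labels, predicted_secreted=secreted)


def write_annotations(ann: AnnotationTable, path, gene_ids: list[str]) -> None:
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": [ann.label(g) for g in gene_ids],
            "predicted_secreted": [g in ann.predicted_secreted for g in gene_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> DETable:
    """Read an externally computed DE table (gene_id, log2fc, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError("DE table needs a gene_id column")
    df = df.set_index("gene_id")
    meta = {c: "" for c in ("substrate", "reference", "method")}
    for c in list(meta):
        if c in df.columns:
            vals = df[c].dropna().unique()
            meta[c] = str(vals[0]) if len(vals) else ""
            df = df.drop(columns=c)
    return DETable(frame=df, **meta)


def write_de_table(de: DETable, path) -> None:
    df = de.frame.copy()
    df.insert(0, "gene_id", df.index)
    df["substrate"] = de.substrate
    df["reference"] = de.reference
    df["method"] = de.method
    df.to_csv(path, sep="\t", index=False)


def write_topography(topo, path) -> None:
    """Write a topography as TSV: node_id, grid_row, grid_col, value.

    Node IDs are 1-based (as on the rendered maps); grid coordinates are
    0-based row-major.  Missing node values are written as ``NA``.
    """
    rows, cols = topo.grid_shape
    ids = np.arange(1, rows * cols + 1)
    out = pd.DataFrame(
        {
            "node_id": ids,
            "grid_row": (ids - 1) // cols,
            "grid_col": (ids - 1) % cols,
            "value": [_format_value(v) for v in topo.values],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# layer_kind={topo.layer_kind}\tcondition={topo.condition or ''}"
                 f"\tgrid={rows}x{cols}\tgrid_ref={topo.grid_ref or ''}\n")
        out.to_csv(fh, sep="\t", index=False)


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    return repr(float(v))


def read_topography(path):
    """Read a topography TSV written by :func:`write_topography`."""
    from .topography import Topography

    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path} is not a topography file")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
        )
        df = pd.read_csv(fh, sep="\t", dtype={"value": str})
    rows, cols = (int(x) for x in meta["grid"].split("x"))
    df = df.sort_values("node_id")
    raw = df["value"].tolist()
    if meta["layer_kind"] == "high_mask":
        values = np.array([v == "True" for v in raw], dtype=bool)
    else:
        values = np.array(
            [np.nan if v == "NA" else float(v) for v in raw], dtype=float
        )
    return Topography(
        values=values,
        layer_kind=meta["layer_kind"],
        grid_shape=(rows, cols),
        condition=meta.get("condition") or None,
        grid_ref=meta.get("grid_ref") or None,
    )
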