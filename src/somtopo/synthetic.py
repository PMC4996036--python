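"""Desk-scale synthetic datasets with planted structure.

The generator emulates the statistical shape of a fungal
substrate-response experiment: a few thousand genes observed across five
carbon sources with three biological replicates each, negative-binomial
count noise, modest library-size variation, and a secretome whose
detection probability rises with transcription.

Genes belong to planted pattern groups: a constitutively high
housekeeping-like block, one specifically induced group per substrate, a
cellulose + lignocellulose co-induced group, a lignocellulose-only
group, and flat/low background blocks.  Each group carries a fixed
baseline offset around the genome-wide center (8 log2) and genes within
a group scatter around it with a small jitter, so groups are coherent
blocks whose separation dominates the within-group noise — the planted
node-level structure the map is supposed to recover.  Induced groups are
shifted +5 log2, landing their condition means in the 12–14 log2 band
where node selection operates, and the group fractions and offsets are
calibrated so the 12-log2 cutoff sits near the 75th percentile of
gene-level global means.

Secretion: a fixed fraction of genes encode secreted proteins; each such
protein is detected in a condition with probability
logistic(a + b · planted condition mean log2), so highly transcribed
genes are detected more often — the association the integration score
is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    AnnotationTable,
    ExpressionMatrix,
    SampleInfo,
    SecretomeRecord,
    SecretomeTable,
    write_annotations,
    write_secretome,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "truth_metrics",
           "write_dataset"]

DEFAULT_SUBSTRATES = ("maltose", "avicel", "wheat_straw", "pine", "aspen")

# (group name, genome fraction, induced substrates, baseline log2 offset)
DEFAULT_GROUPS: tuple[tuple[str, float, tuple[str, ...], float], ...] = (
    ("constitutive_high", 0.17, DEFAULT_SUBSTRATES, 1.5),
    ("cellulose_coinduced", 0.13, ("avicel", "wheat_straw", "pine", "aspen"), 0.3),
    ("lignocellulose", 0.10, ("wheat_straw", "pine", "aspen"), 0.0),
    ("maltose_specific", 0.06, ("maltose",), 0.0),
    ("avicel_specific", 0.06, ("avicel",), 0.0),
    ("wheat_straw_specific", 0.06, ("wheat_straw",), 0.0),
    ("pine_specific", 0.06, ("pine",), 0.0),
    ("aspen_specific", 0.06, ("aspen",), 0.0),
    ("flat_background", 0.20, (), -0.5),
    ("low_background", 0.10, (), -2.0),
)

_CAZY_LABELS = (
    "CBM1-GH6", "CBM1-GH5_7", "AA9-CBM1", "GH7", "GH10", "GH28", "CE16",
    "CBM1-CE1", "CBM1-GH3", "GH12", "GH43", "AA2", "AA3_1", "GH115",
    "CBM1-CE15", "GH131-CBM1", "CE8", "AA5_1", "GH47", "GH92",
)


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults are the package's reference
    study conditions."""

    n_genes: int = 3500
    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES
    replicates: int = 3
    baseline_mean: float = 8.0  # log2 scale, genome-wide center
    within_group_sd: float = 0.5  # per-gene log2 jitter around the group baseline
    effect_size: float = 5.0  # log2 shift for induced groups
    dispersion: float = 0.05
    secreted_fraction: float = 0.1
    detection_intercept: float = -12.0  # logistic a
    detection_slope: float = 1.0  # logistic b, per log2 unit
    libsize_sd: float = 0.2  # lognormal sigma of library factors
    groups: tuple[tuple[str, float, tuple[str, ...], float], ...] = DEFAULT_GROUPS
    drop_substrate: str | None = None  # emulate an unanalyzable condition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("n_genes and replicates must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.secreted_fraction <= 1:
            raise ValueError("secreted_fraction must be in [0, 1]")
        total = sum(f for _, f, _, _ in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group fractions must sum to 1, got {total}")

    def group_sizes(self) -> list[int]:
        """Largest-remainder apportionment of genes to groups."""
        fracs = np.array([f for _, f, _, _ in self.groups])
        raw = fracs * self.n_genes
        sizes = np.floor(raw).astype(int)
        short = self.n_genes - sizes.sum()
        order = np.argsort(-(raw - sizes))
        sizes[order[:short]] += 1
        if np.any(sizes == 0):
            i = int(np.flatnonzero(sizes == 0)[0])
            raise ValueError(
                f"group {self.groups[i][0]!r} covers no genes at "
                f"n_genes={self.n_genes}"
            )
        return sizes.tolist()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["substrates"] = list(self.substrates)
        d["groups"] = [
            {"name": n, "fraction": f, "induced": list(ind), "baseline_offset": b}
            for n, f, ind, b in self.groups
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class SyntheticDataset:
    em: ExpressionMatrix
    secretome: SecretomeTable
    annotations: AnnotationTable
    truth: pd.DataFrame  # gene_id, group, secreted, baseline, effect_<substrate>
    spec: SyntheticSpec

    @property
    def groups(self) -> np.ndarray:
        return self.truth["group"].to_numpy()


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw a complete dataset (counts, secretome, annotations, truth)."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    substrates = [s for s in spec.substrates if s != spec.drop_substrate]
    if not substrates:
        raise ValueError("dropping the only substrate leaves no samples")

    sizes = spec.group_sizes()
    group_of = np.repeat(np.arange(len(sizes)), sizes)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]

    # planted log2 means: group baseline + jitter + group condition effects
    offsets = np.array([b for _n, _f, _ind, b in spec.groups])
    baseline = (
        spec.baseline_mean
        + offsets[group_of]
        + rng.normal(0.0, spec.within_group_sd, spec.n_genes)
    )
    effects = np.zeros((spec.n_genes, len(spec.substrates)))
    sub_index = {s: i for i, s in enumerate(spec.substrates)}
    for gi, (_name, _f, induced, _b) in enumerate(spec.groups):
        rows = group_of == gi
        for s in induced:
            effects[rows, sub_index[s]] = spec.effect_size

    samples: list[SampleInfo] = []
    for s in substrates:
        for r in range(1, spec.replicates + 1):
            samples.append(
                SampleInfo(
                    sample_id=f"{s}_r{r}",
                    substrate=s,
                    replicate=r,
                    is_control=s in ("maltose", "avicel"),
                )
            )
    lib = rng.lognormal(mean=0.0, sigma=spec.libsize_sd, size=len(samples))

    mean_log2 = baseline[:, None] + effects[:, [sub_index[s.substrate] for s in samples]]
    mu = lib[None, :] * np.exp2(mean_log2)
    if spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    em = ExpressionMatrix(gene_ids=gene_ids, counts=counts, samples=samples)

    # secretome: detection per (protein, condition) via the logistic model
    secreted = rng.random(spec.n_genes) < spec.secreted_fraction
    records: list[SecretomeRecord] = []
    cond_mean = baseline[:, None] + effects  # planted, all substrates
    detect_p = _logistic(
        spec.detection_intercept + spec.detection_slope * cond_mean
    )
    draws = rng.random(detect_p.shape)
    for g in np.flatnonzero(secreted):
        for s in substrates:
            c = sub_index[s]
            if draws[g, c] < detect_p[g, c]:
                records.append(
                    SecretomeRecord(
                        protein_id=f"P{gene_ids[g][1:]}",
                        gene_id=gene_ids[g],
                        condition=s,
                    )
                )
    secretome = SecretomeTable(records, provenance="synthetic")

    # annotations: CAZy-style labels for secreted genes of the induced groups
    labels: dict[str, str] = {}
    label_groups = {"cellulose_coinduced", "lignocellulose", "avicel_specific",
                    "wheat_straw_specific", "pine_specific", "aspen_specific"}
    group_names = [g[0] for g in spec.groups]
    li = 0
    for g in range(spec.n_genes):
        if secreted[g] and group_names[group_of[g]] in label_groups:
            li += 1
            if li % 5 == 0:
                continue  # leave some secreted proteins function-unknown
            labels[gene_ids[g]] = _CAZY_LABELS[li % len(_CAZY_LABELS)]
    annotations = AnnotationTable(
        labels=labels,
        predicted_secreted={gene_ids[g] for g in np.flatnonzero(secreted)},
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group": [group_names[i] for i in group_of],
            "secreted": secreted,
            "baseline_log2": baseline,
            **{
                f"effect_{s}": effects[:, sub_index[s]]
                for s in spec.substrates
            },
        }
    )
    return SyntheticDataset(
        em=em, secretome=secretome, annotations=annotations, truth=truth,
        spec=spec,
    )


def truth_metrics(
    assignment: np.ndarray,
    groups: np.ndarray,
    node_coords: np.ndarray | None = None,
) -> dict[str, float]:
    """Clustering quality against the planted groups.

    ``purity``: size-weighted mean over clusters of the majority-group
    fraction.  ``pair_recall``: fraction of same-group gene pairs placed
    on the same cluster or (when ``node_coords`` is given) on clusters
    whose lattice positions are within unit distance.
    """
    assignment = np.asarray(assignment)
    groups = np.asarray(groups)
    if assignment.shape != groups.shape:
        raise ValueError("assignment and truth groups must align")
    df = pd.DataFrame({"node": assignment, "group": groups})
    ct = pd.crosstab(df["node"], df["group"])  # clusters x groups
    purity = float(ct.max(axis=1).sum() / len(assignment))

    table = ct.to_numpy()
    same_node_pairs = (table * (table - 1) // 2).sum()
    adjacent_pairs = 0
    if node_coords is not None:
        # map cluster labels (1-based node IDs) to coordinate rows
        ids = ct.index.to_numpy()
        coords = node_coords[ids - 1]
        d = coords[:, None, :] - coords[None, :, :]
        adj = np.abs(np.sqrt((d**2).sum(axis=2)) - 1.0) < 1e-9
        adjacent_pairs = int(
            sum(
                0.5 * col @ adj @ col
                for col in table.T
            )
        )
    n_per_group = table.sum(axis=0)
    total_pairs = (n_per_group * (n_per_group - 1) // 2).sum()
    recall = float((same_node_pairs + adjacent_pairs) / total_pairs) \
        if total_pairs else 1.0
    return {"purity": purity, "pair_recall": recall}


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the dataset in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(
        ds.em.counts, index=pd.Index(ds.em.gene_ids, name="gene_id"),
        columns=ds.em.sample_ids,
    )
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in ds.em.samples],
            "substrate": [s.substrate for s in ds.em.samples],
            "replicate": [s.replicate for s in ds.em.samples],
            "is_control": [s.is_control for s in ds.em.samples],
        }
    ).to_csv(outdir / "samples.csv", index=False)
    write_secretome(ds.secretome, outdir / "secretome.tsv")
    write_annotations(ds.annotations, outdir / "annotations.tsv", ds.em.gene_ids)
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    ds.spec.to_yaml(outdir / "spec.yaml")
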