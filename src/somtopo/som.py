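"""Hexagonal self-organizing map for expression profiles.

A self-organizing map (SOM) places a fixed grid of prototype vectors
("codebook") into the data space and trains them online: each presented
gene profile pulls its best-matching unit (BMU) and the units within a
shrinking lattice neighborhood toward itself.  The result is a
two-dimensional layout in which genes with similar transcription
patterns occupy the same or neighboring nodes, so downstream statistics
can be drawn per node on a fixed map.

The lattice is hexagonal (each interior node has six equidistant
neighbors), laid out as offset rows: odd rows are shifted half a unit in
x and rows are √3/2 apart, giving unit spacing between adjacent nodes.
Node IDs are 1-based row-major, matching the labeling used on rendered
maps.

Sizing follows the "genes per node" heuristic: the number of map units
is the gene count divided by a target occupancy (default 35 genes per
node), factored into a near-square grid.  Training runs for 100
presentations per map unit by default, with a bubble neighborhood whose
radius decays linearly from the two-thirds quantile of inter-unit
distances to zero, and a learning rate decaying linearly 0.05 → 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SomConfig",
    "SomModel",
    "near_square_shape",
    "build_grid",
    "init_codebook",
    "train",
    "assign_bmu",
    "quantization_error",
    "save_model",
    "load_model",
]


@dataclass
class SomConfig:
    """Training hyper-parameters.

    ``map_units`` may be given explicitly; otherwise it is derived as
    round(n_genes / target_genes_per_node) when training starts.
    ``total_steps`` defaults to steps_per_unit × map_units single-profile
    presentations.
    """

    target_genes_per_node: int = 35
    map_units: int | None = None
    steps_per_unit: int = 100
    total_steps: int | None = None
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None  # default: 2/3 quantile of unit distances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_genes_per_node < 1:
            raise ValueError("target_genes_per_node must be positive")
        if not (self.alpha_start > self.alpha_end > 0):
            raise ValueError("need alpha_start > alpha_end > 0")

    def resolve_units(self, n_genes: int) -> int:
        if self.map_units is not None:
            if self.map_units < 1:
                raise ValueError("map_units must be >= 1")
            return int(self.map_units)
        return max(1, round(n_genes / self.target_genes_per_node))

    def resolve_steps(self, map_units: int) -> int:
        steps = (
            int(self.total_steps)
            if self.total_steps is not None
            else self.steps_per_unit * map_units
        )
        # 0 steps = assignment against the initial codebook only
        if steps != 0 and steps < map_units:
            raise ValueError("total_steps must be at least map_units (or 0)")
        return steps


@dataclass
class SomModel:
    """A trained map: lattice geometry, codebook, and gene→node assignment."""

    config: SomConfig
    grid_shape: tuple[int, int]  # (rows, cols)
    node_coords: np.ndarray  # (map_units, 2) offset hex positions
    codebook: np.ndarray  # (map_units, n_features)
    assignment: np.ndarray  # (n_genes,) 1-based node IDs
    gene_ids: list[str]
    feature_names: list[str]

    @property
    def map_units(self) -> int:
        return self.codebook.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def genes_in_node(self, node_id: int) -> list[str]:
        mask = self.assignment == node_id
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def node_sizes(self) -> np.ndarray:
        """Number of genes per node, indexed 0-based (node_id - 1)."""
        return np.bincount(self.assignment - 1, minlength=self.map_units)

    def lattice_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between node positions."""
        d = self.node_coords[:, None, :] - self.node_coords[None, :, :]
        return np.sqrt((d**2).sum(axis=2))


def near_square_shape(map_units: int) -> tuple[int, int]:
    """Factor ``map_units`` as rows × cols with |rows − cols| minimal,
    rows ≥ cols.  A prime count > 3 degenerates to a single column."""
    if map_units < 1:
        raise ValueError("map_units must be >= 1")
    best = None
    for c in range(1, int(np.sqrt(map_units)) + 1):
        if map_units % c == 0:
            best = (map_units // c, c)
    rows, cols = best
    if cols == 1 and map_units > 3:
        warnings.warn(
            f"map_units={map_units} is prime; falling back to a "
            f"{map_units}x1 grid"
        )
    return rows, cols


def hex_coordinates(rows: int, cols: int) -> np.ndarray:
    """Offset hexagonal lattice positions, unit spacing, row-major order.

    Odd rows are shifted +0.5 in x; rows are √3/2 apart in y.
    """
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y]).astype(float)


def build_grid(map_units: int) -> tuple[np.ndarray, list[list[int]]]:
    """Node coordinates and per-node neighbor lists (unit-distance)."""
    rows, cols = near_square_shape(map_units)
    coords = hex_coordinates(rows, cols)
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d**2).sum(axis=2))
    neighbors = [
        sorted(np.flatnonzero(np.abs(dist[i] - 1.0) < 1e-9).tolist())
        for i in range(map_units)
    ]
    return coords, neighbors


def init_codebook(data: np.ndarray, map_units: int, seed: int) -> np.ndarray:
    """Random initialization: codebook rows sampled uniformly without
    replacement from the data rows."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < map_units:
        raise ValueError(
            f"{data.shape[0]} genes cannot seed {map_units} map units; "
            f"increase target_genes_per_node or reduce map_units"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.shape[0], size=map_units, replace=False)
    return data[idx].copy()


def assign_bmu(profile: np.ndarray, codebook: np.ndarray) -> int:
    """1-based ID of the best-matching unit (squared Euclidean distance,
    ties broken by lowest node ID)."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (codebook.shape[1],):
        raise ValueError(
            f"profile has {profile.shape} features, codebook expects "
            f"{codebook.shape[1]}"
        )
    d2 = ((codebook - profile) ** 2).sum(axis=1)
    return int(np.argmin(d2)) + 1


def _assign_all(data: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    # ||x-w||^2 = ||x||^2 - 2 x.w + ||w||^2 ; argmin over w
    cross = data @ codebook.T
    d2 = (codebook**2).sum(axis=1)[None, :] - 2.0 * cross
    return np.argmin(d2, axis=1) + 1


def train(
    data: np.ndarray,
    config: SomConfig | None = None,
    gene_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
    initial_codebook: np.ndarray | None = None,
) -> SomModel:
    """Train an online hexagonal SOM on gene profile rows.

    At step t the next profile of a seeded per-epoch shuffle is
    presented; the BMU and every unit whose lattice distance from it is
    within the current radius move toward the profile by the current
    learning rate (bubble neighborhood).  Radius decays linearly to 0 —
    at the end only the BMU is updated — and the learning rate decays
    linearly alpha_start → alpha_end.  The final assignment is each
    gene's BMU against the trained codebook.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (genes x features)")
    if not np.all(np.isfinite(data)):
        g = int(np.flatnonzero(~np.isfinite(data).all(axis=1))[0])
        name = gene_ids[g] if gene_ids is not None else f"row {g}"
        raise ValueError(f"non-finite values in profile of gene {name}")
    if config is None:
        config = SomConfig()
    n_genes = data.shape[0]
    map_units = config.resolve_units(n_genes)
    if n_genes < map_units:
        raise ValueError(
            f"{n_genes} genes cannot fill {map_units} map units; "
            f"increase target_genes_per_node"
        )
    total_steps = config.resolve_steps(map_units)
    rows, cols = near_square_shape(map_units)
    coords = hex_coordinates(rows, cols)
    diff = coords[:, None, :] - coords[None, :, :]
    lattice = np.sqrt((diff**2).sum(axis=2))
    if config.radius_start is not None:
        radius_start = float(config.radius_start)
    else:
        radius_start = float(np.quantile(lattice[np.triu_indices(map_units, 1)], 2 / 3)) \
            if map_units > 1 else 0.0

    rng = np.random.default_rng(config.seed)
    if initial_codebook is not None:
        codebook = np.array(initial_codebook, dtype=float)
        if codebook.shape != (map_units, data.shape[1]):
            raise ValueError(
                f"initial codebook shape {codebook.shape} does not match "
                f"({map_units}, {data.shape[1]})"
            )
    else:
        idx = rng.choice(n_genes, size=map_units, replace=False)
        codebook = data[idx].copy()

    order = np.empty(0, dtype=int)
    for t in range(total_steps):
        pos = t % n_genes
        if pos == 0:
            order = rng.permutation(n_genes)
        x = data[order[pos]]
        d2 = ((codebook - x) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))
        frac = t / total_steps
        alpha = config.alpha_start + (config.alpha_end - config.alpha_start) * frac
        radius = radius_start * (1.0 - frac)
        hood = lattice[bmu] <= radius  # always includes the BMU itself
        codebook[hood] += alpha * (x - codebook[hood])

    assignment = _assign_all(data, codebook)
    return SomModel(
        config=config,
        grid_shape=(rows, cols),
        node_coords=coords,
        codebook=codebook,
        assignment=assignment,
        gene_ids=list(gene_ids) if gene_ids is not None else
        [f"g{i}" for i in range(n_genes)],
        feature_names=list(feature_names) if feature_names is not None else
        [f"f{i}" for i in range(data.shape[1])],
    )


def quantization_error(codebook: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance from each profile to its BMU prototype."""
    data = np.asarray(data, dtype=float)
    assignment = _assign_all(data, codebook)
    d = data - codebook[assignment - 1]
    return float(np.mean(np.sqrt((d**2).sum(axis=1))))


# ---------------------------------------------------------------------------
# serialization (a directory of small text files)


def save_model(model: SomModel, outdir) -> None:
    """Serialize a model as YAML config + three TSVs in ``outdir``."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {
        "target_genes_per_node": model.config.target_genes_per_node,
        "map_units": model.map_units,
        "steps_per_unit": model.config.steps_per_unit,
        "total_steps": model.config.total_steps,
        "alpha_start": model.config.alpha_start,
        "alpha_end": model.config.alpha_end,
        "radius_start": model.config.radius_start,
        "seed": model.config.seed,
        "grid_rows": model.grid_shape[0],
        "grid_cols": model.grid_shape[1],
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    pd.DataFrame(model.codebook, columns=model.feature_names).to_csv(
        outdir / "codebook.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {"gene_id": model.gene_ids, "node_id": model.assignment}
    ).to_csv(outdir / "assignment.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "node_id": np.arange(1, model.map_units + 1),
            "x": model.node_coords[:, 0],
            "y": model.node_coords[:, 1],
        }
    ).to_csv(outdir / "coords.tsv", sep="\t", index=False, float_format="%.17g")


def load_model(indir) -> SomModel:
    import pandas as pd
    from pathlib import Path

    indir = Path(indir)
    cfg = yaml.safe_load((indir / "config.yaml").read_text())
    codebook_df = pd.read_csv(indir / "codebook.tsv", sep="\t")
    assign_df = pd.read_csv(indir / "assignment.tsv", sep="\t", dtype={"gene_id": str})
    coords_df = pd.read_csv(indir / "coords.tsv", sep="\t")
    config = SomConfig(
        target_genes_per_node=cfg["target_genes_per_node"],
        map_units=cfg["map_units"],
        steps_per_unit=cfg["steps_per_unit"],
        total_steps=cfg["total_steps"],
        alpha_start=cfg["alpha_start"],
        alpha_end=cfg["alpha_end"],
        radius_start=cfg["radius_start"],
        seed=cfg["seed"],
    )
    return SomModel(
        config=config,
        grid_shape=(cfg["grid_rows"], cfg["grid_cols"]),
        node_coords=coords_df[["x", "y"]].to_numpy(),
        codebook=codebook_df.to_numpy(),
        assignment=assign_df["node_id"].to_numpy(),
        gene_ids=assign_df["gene_id"].tolist(),
        feature_names=list(codebook_df.columns),
    )
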