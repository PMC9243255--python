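"""Parcellation geometry, pairwise distances and structural connectomes.

Every spatial kernel and every distance-resolved functional-connectivity
curve in the package is built on a :class:`ParcellationGeometry`: an ordered
set of parcel (node) identifiers with 3D coordinates in millimetres.  The
structural connectome follows the exponential distance rule (EDR),
``C_np = exp(-lambda_c * r(n, p))`` with ``r`` the Euclidean distance
between parcels, optionally augmented with explicit long-range entries that
stand in for tractography-derived connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

__all__ = [
    "ParcellationGeometry",
    "generate_parcellation",
    "load_parcellation",
    "pairwise_distances",
    "build_connectome",
]

DEFAULT_BALL_RADIUS_MM = 70.0


@dataclass(frozen=True)
class ParcellationGeometry:
    """Node identifiers, 3D coordinates (mm) and a network partition.

    ``network_label`` is a per-node categorical tag playing the role of
    resting-state-network membership for node-attribution summaries.
    """

    node_ids: tuple[str, ...]
    coords: np.ndarray  # (n_nodes, 3), mm
    network_label: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("a parcellation needs at least 2 nodes")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(self.node_ids) != coords.shape[0]:
            raise ValueError("node_ids and coords length mismatch")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be distinct")
        if self.network_label and len(self.network_label) != coords.shape[0]:
            raise ValueError("network_label length mismatch")
        object.__setattr__(self, "coords", coords)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        """Write coordinates as TSV: node_id, x, y, z[, network]."""
        with open(path, "w") as fh:
            fh.write("node_id\tx\ty\tz\tnetwork\n")
            for i, nid in enumerate(self.node_ids):
                net = self.network_label[i] if self.network_label else ""
                x, y, z = self.coords[i]
                fh.write(f"{nid}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{net}\n")


def _assign_networks(coords: np.ndarray, n_networks: int, seed: int) -> tuple[str, ...]:
    # spatially contiguous-ish partition via k-means on coordinates
    if n_networks <= 1:
        return tuple("net0" for _ in range(coords.shape[0]))
    km = KMeans(n_clusters=n_networks, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    return tuple(f"net{int(l)}" for l in labels)


def generate_parcellation(
    n_nodes: int,
    layout: str = "uniform_ball",
    n_networks: int = 4,
    seed: int = 0,
    radius_mm: float = DEFAULT_BALL_RADIUS_MM,
    grid_spacing_mm: float = 10.0,
) -> ParcellationGeometry:
    """Generate a synthetic parcellation geometry.

    ``uniform_ball`` draws nodes uniformly inside a ball of ``radius_mm``
    (default 70 mm, the linear scale of a human hemisphere-ish volume);
    ``grid`` fills a cubic lattice with ``grid_spacing_mm`` spacing.
    Deterministic for a fixed ``seed``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rng = np.random.default_rng(seed)
    if layout == "uniform_ball":
        # uniform in ball: direction x radius ~ U^(1/3)
        z = rng.standard_normal((n_nodes, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        r = radius_mm * rng.uniform(0.0, 1.0, n_nodes) ** (1.0 / 3.0)
        coords = z * r[:, None]
    elif layout == "grid":
        side = int(np.ceil(n_nodes ** (1.0 / 3.0)))
        pts = np.array(
            [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
            dtype=float,
        )[:n_nodes]
        coords = pts * grid_spacing_mm
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'uniform_ball' or 'grid'")
    node_ids = tuple(f"node{i:04d}" for i in range(n_nodes))
    networks = _assign_networks(coords, n_networks, seed)
    return ParcellationGeometry(node_ids=node_ids, coords=coords, network_label=networks)


def load_parcellation(path: str | Path) -> ParcellationGeometry:
    """Read a coordinate TSV (node_id, x, y, z[, network]); header optional."""
    node_ids: list[str] = []
    coords: list[list[float]] = []
    networks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("node_id", "id", "node"):
                continue
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 4 tab-separated "
                    f"fields (node_id, x, y, z), got {len(parts)}"
                )
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed coordinate: {exc}") from None
            node_ids.append(parts[0])
            coords.append(xyz)
            networks.append(parts[4] if len(parts) > 4 else "net0")
    return ParcellationGeometry(
        node_ids=tuple(node_ids), coords=np.asarray(coords), network_label=tuple(networks)
    )


def pairwise_distances(geom: ParcellationGeometry) -> np.ndarray:
    """Node-by-node Euclidean distance matrix in millimetres."""
    return squareform(pdist(geom.coords, metric="euclidean"))


def build_connectome(
    dist: np.ndarray,
    lambda_c: float = 0.18,
    long_range: list[tuple[int, int, float]] | None = None,
    zero_diagonal: bool = True,
) -> np.ndarray:
    """Exponential-distance-rule connectome ``exp(-lambda_c * dist)``.

    ``long_range`` entries (n, p, weight) are added symmetrically on top of
    the EDR kernel, standing in for tractography-derived long-range
    connections.  ``lambda_c`` is the structural decay constant in 1/mm
    (default 0.18, a literature-typical EDR scale).
    """
    if lambda_c <= 0:
        raise ValueError("lambda_c must be > 0")
    dist = np.asarray(dist, dtype=float)
    weights = np.exp(-lambda_c * dist)
    if zero_diagonal:
        np.fill_diagonal(weights, 0.0)
    n = weights.shape[0]
    for entry in long_range or []:
        i, j, w = entry
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"long_range entry references unknown node: {entry}")
        weights[i, j] += w
        weights[j, i] += w
    return weights
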