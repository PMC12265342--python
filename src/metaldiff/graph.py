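"""Heterogeneous multi-scale geometric graphs.

A structure plus the current candidate metal positions and diffusion time t is
turned into a graph with three node types (residue, atom, metal) and four
typed distance-cutoff edge sets:

* residue-residue within ``r_res`` (coarse backbone contacts),
* atom-atom within ``r_atom`` (local chemistry),
* metal-residue within the time-dependent ``r_far(t) = max(r_far_base,
  r_far_sigma_mult * sigma(t))`` so that heavily noised, distant candidates
  stay connected to the protein,
* metal-atom within ``r_near`` — atomic detail is engaged only once a
  candidate is close; this is the multi-scale rule that keeps graphs small.

Edges are stored in both directions.  A per-node nearest-neighbor cap bounds
memory; ties are broken deterministically by node index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError, EmptyStructureError
from .structure import ProteinStructure

RESIDUE_VOCAB = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL UNK"
).split()
ELEMENT_VOCAB = ["C", "N", "O", "S", "P", "X"]  # X = other


@dataclass(frozen=True)
class GraphConfig:
    """Cutoffs and featurization sizes for graph construction."""

    r_res: float = 15.0  # A, residue-residue cutoff
    r_atom: float = 5.0  # A, atom-atom cutoff
    r_near: float = 8.0  # A, metal-atom cutoff (atomic detail radius)
    r_far_base: float = 30.0  # A, floor of the metal-residue cutoff
    r_far_sigma_mult: float = 3.0  # r_far(t) = max(base, mult * sigma(t))
    n_rbf: int = 16
    max_neighbors: int = 32
    t_embed_dim: int = 16

    def r_far(self, sigma_t: float | None = None) -> float:
        if sigma_t is None:
            return self.r_far_base
        return max(self.r_far_base, self.r_far_sigma_mult * float(sigma_t))


def graph_config_hash(cfg: GraphConfig) -> str:
    """Stable hash of a graph configuration (checked at inference time)."""
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


@dataclass(frozen=True)
class EdgeSet:
    """Directed edges between two node sets, with cached distances."""

    src: np.ndarray  # (n_edges,) int
    dst: np.ndarray  # (n_edges,) int
    dist: np.ndarray  # (n_edges,) float, Euclidean A

    @property
    def n_edges(self) -> int:
        return int(self.src.shape[0])

    def undirected_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted((int(a), int(b)))) for a, b in zip(self.src, self.dst)}


@dataclass(frozen=True)
class HeteroGraph:
    """Multi-scale graph over residues, atoms, and candidate metals at time t."""

    residue_coords: np.ndarray
    residue_onehot: np.ndarray  # (n_res, 21)
    atom_coords: np.ndarray
    atom_onehot: np.ndarray  # (n_atom, 6)
    metal_coords: np.ndarray  # (n_metal, 3)
    t: float
    t_embed: np.ndarray
    res_res: EdgeSet
    atom_atom: EdgeSet
    metal_res: EdgeSet  # src = metal index, dst = residue index
    metal_atom: EdgeSet  # src = metal index, dst = atom index
    config: GraphConfig
    config_hash: str

    @property
    def n_metals(self) -> int:
        return int(self.metal_coords.shape[0])


def embed_time(t: float, dim: int = 16) -> np.ndarray:
    """Sinusoidal embedding of diffusion time t in [0, 1].

    Geometric frequency ladder from 1 to 1000 cycles over the unit interval
    (sin and cos channels); injective on a 1e-3 grid for dim >= 8.
    """
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"time t={t} outside [0, 1]")
    if dim < 2 or dim % 2:
        raise DomainError("embedding dim must be an even integer >= 2")
    half = dim // 2
    freqs = np.geomspace(1.0, 1000.0, half)
    ang = np.pi * freqs * t
    return np.concatenate([np.sin(ang), np.cos(ang)])


def rbf_expand(d: np.ndarray, cutoff: float, n: int = 16) -> np.ndarray:
    """Gaussian radial basis expansion of distances on [0, cutoff]."""
    centers = np.linspace(0.0, cutoff, n)
    width = centers[1] - centers[0] if n > 1 else cutoff
    return np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))


def _onehot(labels: list[str] | tuple[str, ...], vocab: list[str]) -> np.ndarray:
    out = np.zeros((len(labels), len(vocab)))
    fallback = len(vocab) - 1
    index = {v: i for i, v in enumerate(vocab)}
    for i, lab in enumerate(labels):
        out[i, index.get(lab, fallback)] = 1.0
    return out


def _cap_neighbors(
    src: np.ndarray, dst: np.ndarray, dist: np.ndarray, cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep at most `cap` nearest outgoing edges per source node.

    Deterministic: sorted by (src, dist, dst).
    """
    if src.size == 0:
        return src, dst, dist
    order = np.lexsort((dst, dist, src))
    src, dst, dist = src[order], dst[order], dist[order]
    keep = np.ones(src.size, dtype=bool)
    # rank within each src run
    change = np.r_[True, src[1:] != src[:-1]]
    start = np.maximum.accumulate(np.where(change, np.arange(src.size), 0))
    rank = np.arange(src.size) - start
    keep = rank < cap
    return src[keep], dst[keep], dist[keep]


def _radius_edges(
    a: np.ndarray, b: np.ndarray | None, r: float, cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All directed pairs within radius r; self-pairs excluded when b is None."""
    if a.shape[0] == 0 or (b is not None and b.shape[0] == 0):
        z = np.zeros(0, dtype=int)
        return z, z.copy(), np.zeros(0)
    if b is None:
        tree = cKDTree(a)
        pairs = tree.query_pairs(r, output_type="ndarray")
        if pairs.size == 0:
            z = np.zeros(0, dtype=int)
            return z, z.copy(), np.zeros(0)
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        dist = np.linalg.norm(a[src] - a[dst], axis=1)
    else:
        tree = cKDTree(b)
        hits = tree.query_ball_point(a, r)
        src = np.concatenate(
            [np.full(len(h), i, dtype=int) for i, h in enumerate(hits)]
        ) if any(hits) else np.zeros(0, dtype=int)
        dst = (
            np.concatenate([np.asarray(h, dtype=int) for h in hits if True])
            if any(hits)
            else np.zeros(0, dtype=int)
        )
        dist = (
            np.linalg.norm(a[src] - b[dst], axis=1) if src.size else np.zeros(0)
        )
    return _cap_neighbors(src, dst, dist, cap)


def build_hetero_graph(
    s: ProteinStructure,
    metals: np.ndarray,
    t: float,
    cfg: GraphConfig | None = None,
    sigma_t: float | None = None,
) -> HeteroGraph:
    """Assemble the heterogeneous graph for a structure + candidate metals.

    Parameters
    ----------
    s
        Cleaned structure.
    metals
        (n, 3) candidate metal positions; may be empty (protein-only graph).
    t
        Diffusion time in [0, 1].
    sigma_t
        Noise level sigma(t); widens the metal-residue cutoff when given.
    """
    cfg = cfg or GraphConfig()
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"time t={t} outside [0, 1]")
    if s.n_residues == 0:
        raise EmptyStructureError("cannot build a graph over an empty structure")
    metals = np.asarray(metals, dtype=float).reshape(-1, 3)

    rr = EdgeSet(*_radius_edges(s.residue_coords, None, cfg.r_res, cfg.max_neighbors))
    aa = EdgeSet(*_radius_edges(s.atom_coords, None, cfg.r_atom, cfg.max_neighbors))
    r_far = cfg.r_far(sigma_t)
    mr = EdgeSet(*_radius_edges(metals, s.residue_coords, r_far, cfg.max_neighbors))
    ma = EdgeSet(*_radius_edges(metals, s.atom_coords, cfg.r_near, cfg.max_neighbors))

    return HeteroGraph(
        residue_coords=s.residue_coords,
        residue_onehot=_onehot(s.residue_names, RESIDUE_VOCAB),
        atom_coords=s.atom_coords,
        atom_onehot=_onehot(list(s.atom_elements), ELEMENT_VOCAB),
        metal_coords=metals,
        t=float(t),
        t_embed=embed_time(float(t), cfg.t_embed_dim),
        res_res=rr,
        atom_atom=aa,
        metal_res=mr,
        metal_atom=ma,
        config=cfg,
        config_hash=graph_config_hash(cfg),
    )
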