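"""Desk-scale synthetic metal-binding complexes and analytic sampling targets.

The generator emulates the geometry that matters to the pipeline without any
download: a pseudo-protein is a self-avoiding C-alpha chain (bond length
3.8 +/- 0.2 A, 3.0 A clash radius) whose residues carry 3-5 pseudo-atoms.
Each binding pocket is a known metal position surrounded by 3-4 coordinating
pseudo-atoms placed 2.0-2.3 A away in a near-tetrahedral arrangement --
mimicking zinc coordination distances and the requirement of at least three
liganding atoms.  Residues hosting coordinating atoms are relabeled with
zinc-favoring types (His/Cys/Asp/Glu), giving the networks a learnable
chemical signal; the same types appear in the background at a low rate so the
signal is informative rather than trivial.

Pocket sites are pairwise >= 12 A apart, so distinct sites never fall within
one clustering radius of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError
from .sde import MixtureTarget
from .structure import ProteinStructure

COORDINATING_RESIDUES = ("HIS", "CYS", "ASP", "GLU")
BACKGROUND_RESIDUES = (
    "ALA", "LEU", "VAL", "GLY", "SER", "THR", "PHE", "ILE", "PRO", "LYS",
    "ARG", "TRP", "TYR", "MET", "ASN", "GLN",
)
_COORD_ELEMENT = {"HIS": "N", "CYS": "S", "ASP": "O", "GLU": "O"}

_TETRAHEDRON = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
) / np.sqrt(3.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Geometry and composition knobs for the generator."""

    bond_length: float = 3.8  # A, C-alpha spacing
    bond_jitter: float = 0.2
    clash_radius: float = 3.0  # A, self-avoidance
    atoms_per_residue: tuple[int, int] = (3, 5)
    side_atom_dist: tuple[float, float] = (1.2, 1.8)
    coord_dist: tuple[float, float] = (2.0, 2.3)  # A, metal-ligand band
    coord_atoms: tuple[int, int] = (3, 4)
    min_pocket_sep: float = 12.0  # A
    pocket_offset: tuple[float, float] = (4.0, 6.0)  # A from anchor CA
    background_coord_prob: float = 0.1  # His/Cys/Asp/Glu rate away from pockets


@dataclass(frozen=True)
class SyntheticComplex:
    """A generated pseudo-protein with known metal sites."""

    structure: ProteinStructure
    pockets: tuple[tuple[np.ndarray, tuple[int, ...]], ...]  # (site, atom idxs)
    seed: int


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _self_avoiding_chain(
    n: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    for _restart in range(30):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _try in range(60):
                step = _random_unit(rng) * (
                    cfg.bond_length + rng.uniform(-cfg.bond_jitter, cfg.bond_jitter)
                )
                cand = pts[-1] + step
                d = np.linalg.norm(np.array(pts) - cand, axis=1)
                if d.min() >= cfg.clash_radius:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise GeometryError(
        f"failed to place a self-avoiding {n}-residue chain "
        f"(clash radius {cfg.clash_radius} A)"
    )


def make_toy_complex(
    n_residues: int,
    n_pockets: int,
    rng: np.random.Generator | int,
    cfg: SyntheticConfig | None = None,
) -> SyntheticComplex:
    """Generate one synthetic complex; deterministic for a fixed seed."""
    if n_residues < 10:
        raise DomainError("need at least 10 residues")
    if n_pockets < 1:
        raise DomainError("need at least one pocket")
    cfg = cfg or SyntheticConfig()
    seed = int(rng) if isinstance(rng, (int, np.integer)) else -1
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    ca = _self_avoiding_chain(n_residues, cfg, rng)

    res_names = []
    atom_elements: list[str] = []
    atom_coords: list[np.ndarray] = []
    atom_parent: list[int] = []
    for i in range(n_residues):
        if rng.uniform() < cfg.background_coord_prob:
            res_names.append(str(rng.choice(COORDINATING_RESIDUES)))
        else:
            res_names.append(str(rng.choice(BACKGROUND_RESIDUES)))
        atom_elements.append("C")  # the C-alpha itself
        atom_coords.append(ca[i])
        atom_parent.append(i)
        k = int(rng.integers(cfg.atoms_per_residue[0], cfg.atoms_per_residue[1] + 1))
        for _ in range(k - 1):
            off = _random_unit(rng) * rng.uniform(*cfg.side_atom_dist)
            atom_elements.append("C" if rng.uniform() < 0.7 else str(rng.choice(["N", "O"])))
            atom_coords.append(ca[i] + off)
            atom_parent.append(i)

    sites: list[np.ndarray] = []
    pockets: list[tuple[np.ndarray, tuple[int, ...]]] = []
    for _p in range(n_pockets):
        placed = False
        for _try in range(400):
            anchor = int(rng.integers(0, n_residues))
            site = ca[anchor] + _random_unit(rng) * rng.uniform(*cfg.pocket_offset)
            if sites and min(
                np.linalg.norm(site - s) for s in sites
            ) < cfg.min_pocket_sep:
                continue
            d_atoms = np.linalg.norm(np.array(atom_coords) - site, axis=1)
            if d_atoms.min() < cfg.clash_radius:
                continue
            placed = True
            break
        if not placed:
            raise GeometryError(
                f"failed to place pocket {_p} with separation "
                f">= {cfg.min_pocket_sep} A"
            )
        n_c = int(rng.integers(cfg.coord_atoms[0], cfg.coord_atoms[1] + 1))
        rot = _random_rotation(rng)
        dirs = _TETRAHEDRON[:n_c] @ rot.T
        idxs = []
        for v in dirs:
            pos = site + v * rng.uniform(*cfg.coord_dist)
            parent = int(np.argmin(np.linalg.norm(ca - pos, axis=1)))
            res_names[parent] = str(rng.choice(COORDINATING_RESIDUES))
            idxs.append(len(atom_coords))
            atom_elements.append(_COORD_ELEMENT[res_names[parent]])
            atom_coords.append(pos)
            atom_parent.append(parent)
        sites.append(site)
        pockets.append((site, tuple(idxs)))

    structure = ProteinStructure(
        residue_chains=tuple("A" for _ in range(n_residues)),
        residue_indices=np.arange(1, n_residues + 1),
        residue_names=tuple(res_names),
        residue_coords=ca,
        residue_het=np.zeros(n_residues, dtype=bool),
        atom_elements=tuple(atom_elements),
        atom_coords=np.array(atom_coords),
        atom_parent=np.array(atom_parent, dtype=int),
        metal_sites=np.array(sites),
        source_id=f"synth-{seed}" if seed >= 0 else "synth",
        cleaned=True,
    )
    structure.validate()
    return SyntheticComplex(structure=structure, pockets=tuple(pockets), seed=seed)


def make_dataset(
    n_complexes: int,
    cfg: SyntheticConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_residues: int = 30,
    n_pockets: int = 2,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> tuple[list[SyntheticComplex], dict[str, list[int]]]:
    """Generate a reproducible dataset with train/val/test split indices."""
    if n_complexes < 1:
        raise DomainError("need at least one complex")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    seeds = rng.integers(0, 2**31 - 1, size=n_complexes)
    complexes = [
        make_toy_complex(n_residues, n_pockets, int(s), cfg) for s in seeds
    ]
    n_train = int(round(split[0] * n_complexes))
    n_val = int(round(split[1] * n_complexes))
    splits = {
        "train": list(range(0, n_train)),
        "val": list(range(n_train, min(n_train + n_val, n_complexes))),
        "test": list(range(min(n_train + n_val, n_complexes), n_complexes)),
    }
    return complexes, splits


def make_mixture_target(
    k_modes: int,
    spacing: float,
    base_var: float,
    rng: np.random.Generator | int | None = None,
) -> MixtureTarget:
    """Equal-weight isotropic Gaussian mixture with pairwise-separated means."""
    if k_modes < 1:
        raise DomainError("need at least one mode")
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    half = spacing * (k_modes ** (1.0 / 3.0) + 1.0)
    means: list[np.ndarray] = []
    for _ in range(k_modes):
        for _try in range(2000):
            m = rng.uniform(-half, half, size=3)
            if not means or min(np.linalg.norm(m - x) for x in means) >= spacing:
                means.append(m)
                break
        else:
            raise GeometryError(
                f"failed to place {k_modes} modes with spacing {spacing}"
            )
    return MixtureTarget(
        weights=np.full(k_modes, 1.0 / k_modes),
        means=np.array(means),
        base_var=float(base_var),
    )
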